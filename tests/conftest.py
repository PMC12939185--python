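"""Shared fixtures: small simulated frames and synthetic feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scatteromics.features import FEATURE_COLUMNS
from scatteromics.imaging import ParametricMap, WindowSpec
from scatteromics.phantom import AcquisitionSpec, simulate_rf_frame


@pytest.fixture(scope="session")
def acq() -> AcquisitionSpec:
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def speckle_frame(acq):
    """Fully developed speckle frame (dense scatterers)."""
    return simulate_rf_frame(20.0, (512, 48), acq, seed=42)


@pytest.fixture(scope="session")
def sparse_frame(acq):
    """Sparse-scatterer (pre-Rayleigh) frame."""
    return simulate_rf_frame(0.5, (512, 48), acq, seed=43)


def make_map(values: np.ndarray, parameter_id: str = "m", side: int = 4) -> ParametricMap:
    """Wrap a value grid in a ParametricMap with a simple window geometry."""
    window = WindowSpec(
        side_axial=side,
        side_lateral=side,
        step_axial=(side + 1) // 2,
        step_lateral=(side + 1) // 2,
        multiplier=3,
    )
    origin = ((side - 1) / 2.0, (side - 1) / 2.0)
    return ParametricMap(
        values=np.asarray(values, dtype=float),
        parameter_id=parameter_id,
        window=window,
        origin=origin,
    )


def synthetic_feature_table(
    n_subjects: int = 40,
    seed: int = 0,
    informative: tuple[str, ...] = ("m_mean", "alpha_mean"),
    effect: float = 2.0,
) -> pd.DataFrame:
    """A synthetic 52-feature table with a known class signal.

    All features are standard-normal noise; the ``informative`` columns get
    a mean shift of ``effect`` for the positive class.
    """
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n_subjects // 2)[:n_subjects]
    data = rng.normal(size=(n_subjects, len(FEATURE_COLUMNS)))
    table = pd.DataFrame(data, columns=list(FEATURE_COLUMNS))
    for col in informative:
        table[col] += effect * y
    table.insert(0, "label", y)
    table.insert(0, "subject_id", [f"S{i:03d}" for i in range(n_subjects)])
    return table
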