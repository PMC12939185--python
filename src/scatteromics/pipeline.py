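"""End-to-end convenience pipeline: cohort -> maps -> features.

Glue used by the CLI, the test-suite and the acceptance script: simulate a
phantom cohort, compute the four parametric maps per subject with the
standard window multipliers (3x pulse for Nakagami, 5x for homodyned-K,
1x for entropy), and assemble the 52-feature table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import imaging
from .estimators import EstimatorConfig, hk_estimate_xu
from .features import build_feature_table
from .imaging import ParametricMap
from .phantom import PhantomSpec, RFFrame, generate_cohort

__all__ = ["subject_maps", "cohort_feature_table", "single_parameter_aurocs"]


def subject_maps(
    frame: RFFrame, config: EstimatorConfig | None = None
) -> dict[str, ParametricMap]:
    """The four parametric maps of one subject.

    The homodyned-K alpha and k maps share one sliding-window pass (the X/U
    statistics and the inversion are computed once per window).
    """
    cfg = config or EstimatorConfig()
    env = imaging.envelope_from_rf(frame)
    out: dict[str, ParametricMap] = {}

    w3 = imaging.window_spec_from_pulse(frame.pulse_length, 3, frame)
    out["m"] = imaging.sliding_window_map(env, "m", w3, cfg)

    w5 = imaging.window_spec_from_pulse(frame.pulse_length, 5, frame)
    views = imaging._window_views(env.values, w5)
    g_ax, g_lat = views.shape[:2]
    alpha = np.full((g_ax, g_lat), np.nan)
    k = np.full((g_ax, g_lat), np.nan)
    for i in range(g_ax):
        for j in range(g_lat):
            try:
                est = hk_estimate_xu(views[i, j].ravel(), cfg)
            except ValueError:
                continue
            alpha[i, j], k[i, j] = est.alpha, est.k
    origin = ((w5.side_axial - 1) / 2.0, (w5.side_lateral - 1) / 2.0)
    out["alpha"] = ParametricMap(values=alpha, parameter_id="alpha", window=w5, origin=origin)
    out["k"] = ParametricMap(values=k, parameter_id="k", window=w5, origin=origin)

    w1 = imaging.window_spec_from_pulse(frame.pulse_length, 1, frame)
    out["H"] = imaging.sliding_window_map(env, "H", w1, cfg)
    return out


def cohort_feature_table(
    spec: PhantomSpec, config: EstimatorConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and extract its feature table.

    Returns ``(feature_table, ground_truth)``.
    """
    frames, masks, labels, truth = generate_cohort(spec)
    maps = [subject_maps(f, config) for f in frames]
    table = build_feature_table(maps, masks, labels, subject_ids=truth["subject_id"])
    return table, truth


def single_parameter_aurocs(table: pd.DataFrame) -> dict[str, float]:
    """AUROC of each parameter's subject-mean ROI value used alone.

    Direction-free (an AUROC below 0.5 is folded), mirroring how a single
    parametric-imaging readout would be thresholded in either direction.
    """
    from .evaluation import auroc

    y = table["label"].to_numpy(dtype=int)
    out = {}
    for p in ("m", "alpha", "k", "H"):
        a = auroc(table[f"{p}_mean"].to_numpy(), y).value
        out[p] = max(a, 1 - a)
    return out
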