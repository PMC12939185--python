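"""Sliding-window parametric imaging of envelope statistics.

Converts beamformed RF frames to envelope images (analytic-signal magnitude)
and computes Nakagami m, homodyned-K alpha / k and entropy H maps on a grid
of overlapping windows.  Window side lengths are expressed in pulse lengths
(3x for Nakagami, 5x for homodyned-K, 1x for entropy) and converted per axis
to samples / scan lines; the overlap ratio is fixed at 50% (step =
ceil(side / 2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.signal import hilbert

from .estimators import (
    EstimatorConfig,
    entropy_histogram,
    hk_estimate_xu,
    nakagami_m,
)

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import RFFrame

__all__ = [
    "EnvelopeImage",
    "WindowSpec",
    "ParametricMap",
    "envelope_from_rf",
    "window_spec_from_pulse",
    "sliding_window_map",
    "PARAMETER_IDS",
    "WINDOW_MULTIPLIERS",
]

PARAMETER_IDS = ("m", "alpha", "k", "H")
#: pulse-length window multiplier per parameter family
WINDOW_MULTIPLIERS = {"m": 3, "alpha": 5, "k": 5, "H": 1}

MIN_WINDOW_SAMPLES = 10


@dataclass
class EnvelopeImage:
    """Envelope magnitude on the RF grid, with inherited geometry metadata."""

    values: np.ndarray
    fs: float
    f0: float
    pulse_length: float  # mm
    lateral_pitch: float  # mm
    sound_speed: float = 1540.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("envelope must be 2-D (axial x lateral)")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")

    @property
    def axial_spacing_mm(self) -> float:
        return self.sound_speed / (2 * self.fs) * 1e3


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: sides in samples/lines, steps = ceil(side/2)."""

    side_axial: int
    side_lateral: int
    step_axial: int
    step_lateral: int
    multiplier: float

    def __post_init__(self) -> None:
        if self.side_axial < 1 or self.side_lateral < 1:
            raise ValueError("window sides must be >= 1")
        if self.step_axial != math.ceil(self.side_axial / 2) or self.step_lateral != math.ceil(
            self.side_lateral / 2
        ):
            raise ValueError("steps must equal ceil(side / 2) (50% overlap)")
        if self.side_axial * self.side_lateral < MIN_WINDOW_SAMPLES:
            raise ValueError(
                f"window holds {self.side_axial * self.side_lateral} samples; "
                f">= {MIN_WINDOW_SAMPLES} required for moment estimation"
            )

    @property
    def n_samples(self) -> int:
        return self.side_axial * self.side_lateral


@dataclass
class ParametricMap:
    """Windowed estimate grid for one of {m, alpha, k, H}.

    ``values[i, j]`` is the estimate for the window whose top-left corner is
    at (i * step_axial, j * step_lateral); failed estimates are NaN
    (flagged-invalid, never exceptions).  ``origin`` holds the (axial,
    lateral) coordinates of the first window center on the image grid.
    """

    values: np.ndarray
    parameter_id: str
    window: WindowSpec
    origin: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.parameter_id not in PARAMETER_IDS:
            raise ValueError(f"unknown parameter_id {self.parameter_id!r}")

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Window-center coordinates (axial, lateral) on the image grid."""
        g_ax, g_lat = self.values.shape
        ax = self.origin[0] + self.window.step_axial * np.arange(g_ax)
        lat = self.origin[1] + self.window.step_lateral * np.arange(g_lat)
        return ax, lat


def envelope_from_rf(frame: "RFFrame") -> EnvelopeImage:
    """Per-scan-line analytic-signal (Hilbert) envelope of an RF frame."""
    rf = frame.samples
    if rf.shape[0] < 8:
        raise ValueError("need at least 8 axial samples for the analytic signal")
    env = np.abs(hilbert(rf, axis=0))
    return EnvelopeImage(
        values=env,
        fs=frame.fs,
        f0=frame.f0,
        pulse_length=frame.pulse_length,
        lateral_pitch=frame.lateral_pitch,
        sound_speed=frame.sound_speed,
    )


def window_spec_from_pulse(
    pulse_length_mm: float, multiplier: float, frame: "RFFrame | EnvelopeImage"
) -> WindowSpec:
    """Window sides of ``multiplier`` pulse lengths, converted per axis.

    Windows are square in physical units: the axial side is
    ``round(multiplier * pulse_length / axial sample spacing)`` and the
    lateral side ``round(multiplier * pulse_length / lateral pitch)``.
    """
    if pulse_length_mm <= 0:
        raise ValueError("pulse length must be positive")
    axial_spacing = frame.sound_speed / (2 * frame.fs) * 1e3
    side_ax = int(round(multiplier * pulse_length_mm / axial_spacing))
    side_lat = int(round(multiplier * pulse_length_mm / frame.lateral_pitch))
    if side_ax < 1 or side_lat < 1:
        raise ValueError("window side shorter than one sample spacing")
    shape = frame.samples.shape if hasattr(frame, "samples") else frame.values.shape
    if side_ax > shape[0] or side_lat > shape[1]:
        raise ValueError("window exceeds frame dimensions")
    return WindowSpec(
        side_axial=side_ax,
        side_lateral=side_lat,
        step_axial=math.ceil(side_ax / 2),
        step_lateral=math.ceil(side_lat / 2),
        multiplier=multiplier,
    )


def _window_views(values: np.ndarray, window: WindowSpec) -> np.ndarray:
    """(grid_ax, grid_lat, side_ax, side_lat) view of all window positions."""
    sw = np.lib.stride_tricks.sliding_window_view(
        values, (window.side_axial, window.side_lateral)
    )
    return sw[:: window.step_axial, :: window.step_lateral]


def sliding_window_map(
    env: EnvelopeImage,
    estimator_id: str,
    window: WindowSpec,
    config: EstimatorConfig | None = None,
) -> ParametricMap:
    """Apply a named envelope-statistics estimator over the sliding windows.

    Grid dimensions are ``floor((dim - side) / step) + 1`` per axis.
    Estimator failures (degenerate windows) produce NaN cells.  A 1x1-grid
    map equals the direct estimator call on the window's flattened samples.
    """
    if estimator_id not in PARAMETER_IDS:
        raise ValueError(f"unknown estimator_id {estimator_id!r}")
    n_ax, n_lat = env.values.shape
    if window.side_axial > n_ax or window.side_lateral > n_lat:
        raise ValueError("window larger than image")
    cfg = config or EstimatorConfig()

    views = _window_views(env.values, window)
    g_ax, g_lat = views.shape[:2]
    out = np.full((g_ax, g_lat), np.nan)

    if estimator_id in ("alpha", "k"):
        for i in range(g_ax):
            for j in range(g_lat):
                try:
                    est = hk_estimate_xu(views[i, j].ravel(), cfg)
                except ValueError:
                    continue
                out[i, j] = est.alpha if estimator_id == "alpha" else est.k
    elif estimator_id == "m":
        for i in range(g_ax):
            for j in range(g_lat):
                try:
                    out[i, j], _ = nakagami_m(views[i, j].ravel())
                except ValueError:
                    continue
    else:  # entropy
        for i in range(g_ax):
            for j in range(g_lat):
                try:
                    out[i, j] = entropy_histogram(views[i, j].ravel(), cfg.entropy_bins)
                except ValueError:
                    continue

    origin = ((window.side_axial - 1) / 2.0, (window.side_lateral - 1) / 2.0)
    return ParametricMap(values=out, parameter_id=estimator_id, window=window, origin=origin)
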