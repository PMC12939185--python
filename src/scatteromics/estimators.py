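"""Point estimators for ultrasound envelope statistics.

Maps a vector of envelope amplitudes to the parameters of the three standard
backscatter models:

* Nakagami shape ``m`` and scale ``Omega`` via the intensity moment estimator,
  ``m = E[I]^2 / Var[I]`` with ``I = A^2``.  ``m = 1`` corresponds to fully
  developed (Rayleigh) speckle; ``m < 1`` to pre-Rayleigh statistics.
* Homodyned-K clustering parameter ``alpha`` and coherent-to-diffuse ratio
  ``k`` via the X/U log-moment estimator: the scale-invariant statistics

      U = E[log I] - log E[I]
      X = E[I log I] / E[I] - E[log I]

  are inverted through the model's forward map (alpha, k) -> (U, X).
* Shannon entropy ``H`` (bits) of the amplitude histogram.

The homodyned-K convention used throughout the package (sampler and estimator
share it): the complex echo is ``eps + X + iY`` with ``z ~ Gamma(alpha, 1)``,
``X, Y | z ~ N(0, sigma^2 z)`` and ``eps = k * sigma * sqrt(2 * alpha)``, so
that ``k^2`` equals coherent power over total diffuse power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.interpolate import CubicSpline, RectBivariateSpline
from scipy.spatial import cKDTree as _cKDTree
from scipy.special import gammaln, psi, roots_legendre
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "EstimatorConfig",
    "HKEstimate",
    "nakagami_m",
    "hk_estimate_xu",
    "entropy_histogram",
    "hk_forward_ux",
    "hk_log_moments",
    "get_inverter",
]

_EG = np.euler_gamma

MIN_SAMPLES_NAKAGAMI = 10
MIN_SAMPLES_HK = 100


@dataclass(frozen=True)
class EstimatorConfig:
    """Configuration shared by the envelope-statistics estimators.

    Parameters
    ----------
    entropy_bins:
        Number of equal-width histogram bins for the entropy estimator.
    alpha_bounds, k_bounds:
        Extent of the precomputed (alpha, k) inversion grid.  Estimates
        falling outside are clipped and flagged.
    alpha_grid_size, k_grid_size:
        Resolution of the forward-map grid used to seed the inversion.
    """

    entropy_bins: int = 40
    alpha_bounds: tuple[float, float] = (0.1, 100.0)
    k_bounds: tuple[float, float] = (0.0, 3.0)
    alpha_grid_size: int = 60
    k_grid_size: int = 46
    newton_iterations: int = 12

    def __post_init__(self) -> None:
        if self.entropy_bins < 2:
            raise ValueError("entropy_bins must be >= 2")
        if not (self.alpha_bounds[0] > 0 and self.alpha_bounds[1] > self.alpha_bounds[0]):
            raise ValueError("invalid alpha bounds")
        if not (self.k_bounds[0] >= 0 and self.k_bounds[1] > self.k_bounds[0]):
            raise ValueError("invalid k bounds")


class HKEstimate(NamedTuple):
    alpha: float
    k: float
    boundary: bool  # True when the solution was clipped to the grid bounds


def _clean(samples) -> np.ndarray:
    a = np.asarray(samples, dtype=float).ravel()
    return a[np.isfinite(a)]


def nakagami_m(samples) -> tuple[float, float]:
    """Moment estimator of the Nakagami shape and scale.

    Returns ``(m, omega)`` where ``omega = E[A^2]`` and
    ``m = E[I]^2 / Var[I]`` with population (1/n) variance.

    Raises
    ------
    ValueError
        For fewer than 10 finite samples, negative amplitudes, or zero
        intensity variance (e.g. a constant input).
    """
    a = _clean(samples)
    if a.size < MIN_SAMPLES_NAKAGAMI:
        raise ValueError(f"need >= {MIN_SAMPLES_NAKAGAMI} finite samples, got {a.size}")
    if np.any(a < 0):
        raise ValueError("envelope samples must be nonnegative")
    intensity = a * a
    omega = float(np.mean(intensity))
    var = float(np.var(intensity))  # population variance
    if var <= 0.0:
        raise ValueError("zero intensity variance: Nakagami m undefined")
    return omega * omega / var, omega


def entropy_histogram(samples, bins: int = 40) -> float:
    """Shannon entropy (bits) of the equal-width amplitude histogram.

    Bin edges span [min, max] of the sample; ``H = -sum p_i log2 p_i`` over
    occupied bins, so ``0 <= H <= log2(bins)``.  An all-identical sample has
    zero entropy (returned, not an error).
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    a = _clean(samples)
    if a.size < 2:
        raise ValueError("need at least 2 finite samples")
    lo, hi = float(a.min()), float(a.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(a, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / a.size
    return float(-np.sum(p * np.log2(p)))


def hk_log_moments(samples) -> tuple[float, float]:
    """The scale-invariant (U, X) statistics of an intensity sample.

    ``U = mean(log I) - log(mean I)`` and
    ``X = mean(I log I)/mean(I) - mean(log I)`` with ``I = A^2``.
    Zero amplitudes are dropped (log-moment statistics require I > 0).
    """
    u, x, _ = hk_log_moments_with_cov(samples)
    return u, x


def hk_log_moments_with_cov(samples) -> tuple[float, float, np.ndarray]:
    """(U, X) statistics plus their delta-method sampling covariance.

    U and X are smooth functions of the moment triple
    (T1, T2, T3) = (mean I, mean log I, mean I log I); the plug-in
    covariance of the triple propagated through the gradients gives the
    2x2 covariance of (U, X) used by the k = 0 submodel test.
    """
    a = _clean(samples)
    a = a[a > 0]
    if a.size < MIN_SAMPLES_HK:
        raise ValueError(f"need >= {MIN_SAMPLES_HK} positive finite samples, got {a.size}")
    intensity = a * a
    if np.var(intensity) <= 0.0:
        raise ValueError("zero intensity variance: log-moment statistics undefined")
    log_i = np.log(intensity)
    il = intensity * log_i
    t1 = float(np.mean(intensity))
    t2 = float(np.mean(log_i))
    t3 = float(np.mean(il))
    u = t2 - np.log(t1)
    x = t3 / t1 - t2
    if not (np.isfinite(u) and np.isfinite(x)):
        raise ValueError("non-finite log-moment statistics")
    obs = np.column_stack([intensity, log_i, il])
    cov_t = np.cov(obs, rowvar=False) / a.size
    g = np.array(
        [
            [-1.0 / t1, 1.0, 0.0],
            [-t3 / (t1 * t1), -1.0, 1.0 / t1],
        ]
    )
    return float(u), float(x), g @ cov_t @ g.T


# ---------------------------------------------------------------------------
# Forward map (alpha, k) -> (U, X)
#
# Conditional on the gamma mixing variable z, the intensity is
# I = 2 sigma^2 z G with G ~ Gamma(1 + J, 1), J ~ Poisson(alpha k^2 / z)
# (Poisson mixture representation of the noncentral chi-square with 2 dof).
# The z-expectations of log z and z log z are digammas; the Poisson
# expectations E psi(1+J) and E (1+J) psi(2+J) are tabulated on a log-t grid
# once and splined.  U and X are independent of sigma.
# ---------------------------------------------------------------------------

_T_LO, _T_HI = 1e-8, 1e8


def _poisson_psi_tables() -> tuple[CubicSpline, CubicSpline]:
    log_t = np.linspace(np.log(_T_LO), np.log(_T_HI), 600)
    f1 = np.empty_like(log_t)
    g = np.empty_like(log_t)
    for i, t in enumerate(np.exp(log_t)):
        if t < 1e4:
            lo = max(0, int(t - 12 * np.sqrt(t) - 5))
            hi = int(t + 12 * np.sqrt(t) + 10)
            j = np.arange(lo, hi + 1)
            p = np.exp(-t + j * np.log(t) - gammaln(j + 1))
            f1[i] = np.sum(p * psi(1.0 + j))
            g[i] = np.sum(p * (1.0 + j) * psi(2.0 + j))
        else:  # asymptotics, relative error < 1e-9 here
            f1[i] = np.log(t)
            g[i] = (1 + t) * np.log1p(t) + t / (2 * (1 + t)) + 0.5
    return CubicSpline(log_t, f1), CubicSpline(log_t, g)


_F1_SPLINE: CubicSpline | None = None
_G_SPLINE: CubicSpline | None = None


def _f1(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t)
    small, big = t < _T_LO, t > _T_HI
    mid = ~(small | big)
    out[small] = -_EG + t[small]
    out[big] = np.log(t[big])
    out[mid] = _F1_SPLINE(np.log(t[mid]))
    return out


def _g(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t)
    small, big = t < _T_LO, t > _T_HI
    mid = ~(small | big)
    out[small] = (1 - _EG) + t[small] * (2 - _EG)
    tb = t[big]
    out[big] = (1 + tb) * np.log1p(tb) + tb / (2 * (1 + tb)) + 0.5
    out[mid] = _G_SPLINE(np.log(t[mid]))
    return out


_LEG_X, _LEG_W = roots_legendre(200)


def hk_forward_ux(alpha: float, k: float) -> tuple[float, float]:
    """Population (U, X) of the homodyned-K intensity for given (alpha, k)."""
    global _F1_SPLINE, _G_SPLINE
    if alpha <= 0 or k < 0:
        raise ValueError("alpha must be > 0 and k >= 0")
    mean_i = alpha * (1 + k * k)  # in units of 2 sigma^2
    if k == 0.0:
        e_log = psi(alpha) - _EG
        e_ilog = alpha * psi(alpha + 1) + (1 - _EG) * alpha
    else:
        if _F1_SPLINE is None:
            _F1_SPLINE, _G_SPLINE = _poisson_psi_tables()
        z_lo = max(_gamma_dist.ppf(1e-14, alpha), 1e-290)
        z_hi = _gamma_dist.isf(1e-14, alpha)
        u_lo, u_hi = np.log(z_lo), np.log(z_hi)
        u = 0.5 * (u_hi - u_lo) * _LEG_X + 0.5 * (u_hi + u_lo)
        z = np.exp(u)
        # z * pdf(z) du  (substitution z = e^u)
        w = _LEG_W * 0.5 * (u_hi - u_lo) * np.exp(alpha * u - z - gammaln(alpha))
        t = alpha * k * k / z
        c1 = float(np.sum(w * (_f1(t) + _EG)))
        c2 = float(np.sum(w * z * (_g(t) - (1 - _EG))))
        e_log = psi(alpha) - _EG + c1
        e_ilog = alpha * psi(alpha + 1) + alpha * k * k * psi(alpha) + (1 - _EG) * alpha + c2
    u_stat = e_log - np.log(mean_i)
    x_stat = e_ilog / mean_i - e_log
    return float(u_stat), float(x_stat)


@dataclass
class _HKInverter:
    """Grid-seeded Newton inversion of the (alpha, k) -> (U, X) map.

    The forward map is evaluated on a (log alpha, k) grid once and fitted with
    bicubic splines; inversion solves the splined system by damped Newton with
    analytic spline Jacobians, clipping to the grid bounds.
    """

    config: EstimatorConfig
    log_alpha: np.ndarray = field(init=False)
    k_vals: np.ndarray = field(init=False)
    u_spline: RectBivariateSpline = field(init=False)
    x_spline: RectBivariateSpline = field(init=False)
    u_grid: np.ndarray = field(init=False)
    x_grid: np.ndarray = field(init=False)
    _tree: object = field(init=False, default=None, repr=False)
    _tree_params: tuple = field(init=False, default=None, repr=False)

    def __post_init__(self) -> None:
        cfg = self.config
        self.log_alpha = np.linspace(
            np.log(cfg.alpha_bounds[0]), np.log(cfg.alpha_bounds[1]), cfg.alpha_grid_size
        )
        self.k_vals = np.linspace(cfg.k_bounds[0], cfg.k_bounds[1], cfg.k_grid_size)
        u = np.empty((cfg.alpha_grid_size, cfg.k_grid_size))
        x = np.empty_like(u)
        for i, la in enumerate(self.log_alpha):
            for j, kk in enumerate(self.k_vals):
                u[i, j], x[i, j] = hk_forward_ux(np.exp(la), kk)
        self.u_grid, self.x_grid = u, x
        self.u_spline = RectBivariateSpline(self.log_alpha, self.k_vals, u, kx=3, ky=3)
        self.x_spline = RectBivariateSpline(self.log_alpha, self.k_vals, x, kx=3, ky=3)

    def _fine_seed_tree(self):
        """KD-tree over a fine splined forward grid, for inversion seeding."""
        if self._tree is None:
            la = np.linspace(self.log_alpha[0], self.log_alpha[-1], 480)
            kk = np.linspace(self.k_vals[0], self.k_vals[-1], 300)
            u = self.u_spline(la, kk)
            x = self.x_spline(la, kk)
            su = max(np.ptp(self.u_grid), 1e-9)
            sx = max(np.ptp(self.x_grid), 1e-9)
            pts = np.column_stack([(u / su).ravel(), (x / sx).ravel()])
            self._tree = _cKDTree(pts)
            self._tree_params = (
                np.repeat(la, kk.size),
                np.tile(kk, la.size),
                su,
                sx,
            )
        return self._tree, self._tree_params

    def invert_batch(self, u, x, n_seeds: int = 3) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Invert arrays of (U, X) to (alpha, k); NaN inputs stay NaN.

        Seeds come from the nearest nodes of a fine splined forward grid
        (the map has a narrow, nearly flat valley at low k, so several seeds
        are tried); refinement is a vectorized damped Newton on the splined
        system with analytic Jacobians, clipped to the grid bounds.

        Returns ``(alpha, k, boundary_flag)`` arrays.
        """
        u = np.asarray(u, dtype=float).ravel()
        x = np.asarray(x, dtype=float).ravel()
        la_lo, la_hi = float(self.log_alpha[0]), float(self.log_alpha[-1])
        k_lo, k_hi = float(self.k_vals[0]), float(self.k_vals[-1])
        ok = np.isfinite(u) & np.isfinite(x)
        alpha = np.full(u.shape, np.nan)
        k_out = np.full(u.shape, np.nan)
        bflag = np.zeros(u.shape, dtype=bool)
        if not np.any(ok):
            return alpha, k_out, bflag
        uo, xo = u[ok], x[ok]
        tree, (la_nodes, k_nodes, su, sx) = self._fine_seed_tree()
        _, idx = tree.query(np.column_stack([uo / su, xo / sx]), k=n_seeds)
        idx = np.atleast_2d(idx.T).T if n_seeds == 1 else idx

        best_f = np.full(uo.shape, np.inf)
        best_la = np.empty_like(uo)
        best_k = np.empty_like(uo)
        for s in range(n_seeds):
            la = la_nodes[idx[:, s]].copy()
            kk = k_nodes[idx[:, s]].copy()
            ru = self.u_spline.ev(la, kk) - uo
            rx = self.x_spline.ev(la, kk) - xo
            f = (ru / su) ** 2 + (rx / sx) ** 2
            for _ in range(self.config.newton_iterations):
                j11 = self.u_spline.ev(la, kk, dx=1)
                j12 = self.u_spline.ev(la, kk, dy=1)
                j21 = self.x_spline.ev(la, kk, dx=1)
                j22 = self.x_spline.ev(la, kk, dy=1)
                det = j11 * j22 - j12 * j21
                det = np.where(np.abs(det) < 1e-13, np.sign(det + 1e-30) * 1e-13, det)
                dla = (-ru * j22 + rx * j12) / det
                dk = (-rx * j11 + ru * j21) / det
                step = np.ones_like(la)
                updated = np.zeros(la.shape, dtype=bool)
                for _bt in range(4):  # vectorized backtracking
                    trial_la = np.clip(la + step * dla, la_lo, la_hi)
                    trial_k = np.clip(kk + step * dk, k_lo, k_hi)
                    t_ru = self.u_spline.ev(trial_la, trial_k) - uo
                    t_rx = self.x_spline.ev(trial_la, trial_k) - xo
                    t_f = (t_ru / su) ** 2 + (t_rx / sx) ** 2
                    take = (~updated) & (t_f < f)
                    la = np.where(take, trial_la, la)
                    kk = np.where(take, trial_k, kk)
                    ru = np.where(take, t_ru, ru)
                    rx = np.where(take, t_rx, rx)
                    f = np.where(take, t_f, f)
                    updated |= take
                    step *= 0.5
                if not np.any(updated):
                    break
            better = f < best_f
            best_f = np.where(better, f, best_f)
            best_la = np.where(better, la, best_la)
            best_k = np.where(better, kk, best_k)

        eps = 1e-6
        alpha[ok] = np.exp(best_la)
        k_out[ok] = best_k
        bflag[ok] = (
            (best_la <= la_lo + eps)
            | (best_la >= la_hi - eps)
            | (best_k <= k_lo + eps)
            | (best_k >= k_hi - eps)
        )
        return alpha, k_out, bflag

    def invert(self, u: float, x: float) -> HKEstimate:
        a, kk, b = self.invert_batch(np.array([u]), np.array([x]))
        return HKEstimate(float(a[0]), float(kk[0]), bool(b[0]))


_INVERTERS: dict[EstimatorConfig, _HKInverter] = {}


def get_inverter(config: EstimatorConfig | None = None) -> _HKInverter:
    """Return (building and caching on first use) the inverter for a config."""
    cfg = config or EstimatorConfig()
    inv = _INVERTERS.get(cfg)
    if inv is None:
        inv = _HKInverter(cfg)
        _INVERTERS[cfg] = inv
    return inv


#: chi-square(1 dof) 0.99 quantile for the k = 0 submodel acceptance region
_CHI2_1_99 = 6.634896601021215


def _k0_curve(config: EstimatorConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense (alpha, U, X) samples of the K-distribution (k = 0) curve."""
    la = np.linspace(np.log(config.alpha_bounds[0]), np.log(config.alpha_bounds[1]), 2400)
    alpha = np.exp(la)
    return alpha, psi(alpha) - _EG - la, 1.0 + 1.0 / alpha


_K0_CACHE: dict[EstimatorConfig, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def hk_estimate_xu(samples, config: EstimatorConfig | None = None) -> HKEstimate:
    """X/U log-moment estimator of the homodyned-K (alpha, k).

    Computes the scale-invariant statistics (U, X) of the intensity and
    inverts the model forward map.  Because the map depends on k only
    through k^2, its Jacobian is singular along k = 0 and small sampling
    noise can otherwise spill into spurious k of order noise^(1/2); the
    estimator therefore first tests the K-distribution submodel: if the
    Mahalanobis distance (under the delta-method covariance of U and X)
    from the k = 0 curve is inside the chi-square(1) 99% region, the
    constrained (alpha, k = 0) fit is returned.  Estimates outside the
    covered (alpha, k) grid are clipped to its bounds and flagged via
    ``boundary``.
    """
    cfg = config or EstimatorConfig()
    u, x, cov = hk_log_moments_with_cov(samples)
    curve = _K0_CACHE.get(cfg)
    if curve is None:
        curve = _k0_curve(cfg)
        _K0_CACHE[cfg] = curve
    alpha_c, u_c, x_c = curve
    cov = cov + 1e-18 * np.eye(2)  # guard exact singularity
    ci = np.linalg.inv(cov)
    ru = u_c - u
    rx = x_c - x
    d2 = ci[0, 0] * ru * ru + 2 * ci[0, 1] * ru * rx + ci[1, 1] * rx * rx
    j = int(np.argmin(d2))
    if d2[j] <= _CHI2_1_99:
        at_edge = j == 0 or j == len(alpha_c) - 1
        return HKEstimate(float(alpha_c[j]), 0.0, bool(at_edge))
    return get_inverter(cfg).invert(u, x)
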