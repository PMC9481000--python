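"""Model classes for fitting DCS autocorrelation curves.

Follows the model/results pattern: a model object is built from a measured
(or synthetic) g1 curve plus the assumed medium and probe geometry, and its
``fit()`` returns a :class:`DCSFitResult` carrying the estimates, approximate
standard errors, residual diagnostics and a ``summary()`` table.

Three models are provided:

* :class:`ConventionalSemiInfiniteModel` — one parameter, the product
  alpha*D_B, fitted on lags where the measured g1 exceeds 0.7;
* :class:`HomogeneousFourierModel` — one parameter, D_B, using the
  Fourier-domain half-space Green's function on the standard lag window;
* :class:`TwoLayerModel` — two parameters, top-layer thickness d1 and
  bottom-layer Brownian coefficient D_B2, with optional SNR weighting,
  bounded coarse-grid + Nelder-Mead estimation, and an RSS-surface
  refinement fallback.

Helper functions (``estimate_beta``, ``g2_to_g1``, ``snr_curve``) implement
the standard preprocessing from measured intensity autocorrelations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from . import forward as fw
from .media import CorrelationCurve, LayeredMedium, OpticalLayer

__all__ = [
    "DCSFitResult",
    "RssSurface",
    "ConventionalSemiInfiniteModel",
    "HomogeneousFourierModel",
    "TwoLayerModel",
    "estimate_beta",
    "g2_to_g1",
    "snr_curve",
    "fit_single_layer_conventional",
    "fit_single_layer_fourier",
    "fit_two_layer",
    "rss_surface",
    "refine_with_surface",
]

#: default lag window for Fourier-domain fits, s
DEFAULT_TAU_RANGE = (1e-6, 3e-3)
#: default parameter bounds: d1 in cm, D_B2 in cm^2/s
DEFAULT_D1_BOUNDS = (0.0, 2.0)
DEFAULT_DB2_BOUNDS = (0.0, 1e-6)
#: default lag window for estimating the Siegert coherence factor, s
BETA_WINDOW = (0.5e-6, 0.8e-6)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class DCSFitResult:
    """Fit outcome for any of the DCS models.

    ``params`` maps parameter names to estimates in internal units
    (cm, cm^2/s); ``bse`` holds Gauss-Newton standard errors where the
    linearization is well conditioned, else NaN.
    """

    model: str
    params: dict[str, float]
    rss: float
    weighted_rss: float
    n_points: int
    converged: bool
    refined_by_surface: bool = False
    bse: dict[str, float] = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"DCS fit: {self.model}",
            f"  n_points: {self.n_points}",
            f"  converged: {self.converged}"
            + ("  (refined from RSS surface)" if self.refined_by_surface else ""),
            f"  RSS (unweighted): {self.rss:.6e}",
            f"  RSS (weighted):   {self.weighted_rss:.6e}",
            "  parameters:",
        ]
        units = {"alpha_db": "cm^2/s", "d_b": "cm^2/s", "d_b2": "cm^2/s", "d1": "cm"}
        for name, value in self.params.items():
            se = self.bse.get(name, math.nan)
            extra = f" +/- {se:.4g}" if math.isfinite(se) else ""
            lines.append(f"    {name} = {value:.6g}{extra} {units.get(name, '')}")
            if name == "d1":
                lines.append(f"      ({value * 10:.3f} mm)")
        for key, value in self.settings.items():
            lines.append(f"  {key}: {value}")
        return "\n".join(lines)


@dataclass
class RssSurface:
    """Unweighted residual-sum-of-squares landscape over (d1, D_B2)."""

    d1_grid: np.ndarray  # cm
    db2_grid: np.ndarray  # cm^2/s
    rss: np.ndarray  # shape (len(d1_grid), len(db2_grid))

    def __post_init__(self) -> None:
        self.d1_grid = np.asarray(self.d1_grid, float)
        self.db2_grid = np.asarray(self.db2_grid, float)
        self.rss = np.asarray(self.rss, float)
        if self.rss.shape != (self.d1_grid.size, self.db2_grid.size):
            raise ValueError("rss matrix shape does not match the grids")
        if not np.all(np.isfinite(self.rss)) or self.rss.min() < 0:
            raise ValueError("rss must be finite and non-negative")

    @property
    def argmin(self) -> tuple[float, float]:
        """(d1, D_B2) at the global grid minimum."""
        i, j = np.unravel_index(int(self.rss.argmin()), self.rss.shape)
        return float(self.d1_grid[i]), float(self.db2_grid[j])

    @property
    def min_rss(self) -> float:
        return float(self.rss.min())


# ---------------------------------------------------------------------------
# preprocessing helpers
# ---------------------------------------------------------------------------


def estimate_beta(
    g2: CorrelationCurve, window: tuple[float, float] = BETA_WINDOW
) -> float:
    """Siegert coherence factor from the earliest lags of an averaged g2.

    beta is the mean of g2(tau) - 1 over the early-lag window where g1 is
    still essentially 1. Values outside (0, 1] are clipped with a warning.
    """
    if g2.kind != "g2":
        raise ValueError("estimate_beta expects a g2 curve")
    mask = (g2.tau >= window[0]) & (g2.tau <= window[1])
    if not mask.any():
        raise ValueError(
            f"no lags inside the beta window [{window[0]:g}, {window[1]:g}] s"
        )
    beta = float(np.mean(g2.values[mask] - 1.0))
    if not (0 < beta <= 1):
        warnings.warn(
            f"estimated beta {beta:.4g} outside (0, 1]; clipping", RuntimeWarning,
            stacklevel=2,
        )
        beta = min(max(beta, 1e-6), 1.0)
    return beta


def g2_to_g1(g2: CorrelationCurve, beta: float) -> CorrelationCurve:
    """Invert the Siegert relation: g1 = sqrt(max(0, (g2 - 1)/beta)).

    Negative radicands (noise below the g2=1 baseline) are clipped to zero
    and counted in the returned curve's ``n_clipped``. Values slightly above
    1 (noise and beta-estimation error at the earliest lags) are kept as-is.
    """
    if not (0 < beta <= 1):
        raise ValueError("beta must lie in (0, 1]")
    if g2.kind != "g2":
        raise ValueError("g2_to_g1 expects a g2 curve")
    radicand = (g2.values - 1.0) / beta
    n_clipped = int(np.sum(radicand < 0))
    g1 = np.sqrt(np.clip(radicand, 0.0, None))
    return CorrelationCurve(
        g2.tau, g1, kind="g1", snr=g2.snr, n_snapshots=g2.n_snapshots,
        n_clipped=n_clipped,
    )


def snr_curve(snapshots: Sequence[CorrelationCurve]) -> np.ndarray:
    """Per-lag SNR = (mean g2 - 1) / std(g2) across an ensemble of snapshots.

    Lags with zero ensemble spread get an infinite SNR sentinel (excluded
    from fit weights downstream) and trigger a warning.
    """
    if len(snapshots) < 2:
        raise ValueError("need at least 2 snapshots")
    tau0 = snapshots[0].tau
    for snap in snapshots[1:]:
        if snap.tau.shape != tau0.shape or not np.allclose(snap.tau, tau0):
            raise ValueError("snapshots must share a common lag grid")
    stack = np.stack([s.values for s in snapshots])
    mean = stack.mean(axis=0)
    std = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = (mean - 1.0) / std
    degenerate = std == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} lags with zero ensemble spread; "
            "SNR set to +inf there",
            RuntimeWarning,
            stacklevel=2,
        )
        snr[degenerate] = np.inf
    return snr


# ---------------------------------------------------------------------------
# single-parameter models
# ---------------------------------------------------------------------------


def _scalar_fit(
    objective,
    grid: np.ndarray,
    refine_span: float = 30.0,
    lo: float = 1e-13,
    hi: float = 1e-6,
) -> tuple[float, bool]:
    """Deterministic 1-d bounded fit: coarse grid (including 0) then a
    bounded derivative-free refinement in log10 space around the grid best.

    Returns (estimate, converged); a boundary solution at zero flow is
    flagged as not converged.
    """
    candidates = np.concatenate([[0.0], grid])
    vals = np.array([objective(c) for c in candidates])
    best = candidates[int(vals.argmin())]
    if best == 0.0:
        return 0.0, False
    res = optimize.minimize_scalar(
        lambda u: objective(10.0**u),
        bounds=(
            math.log10(max(best / refine_span, lo)),
            math.log10(min(best * refine_span, hi)),
        ),
        method="bounded",
        options={"xatol": 1e-10},
    )
    est = float(10.0 ** res.x)
    return est, bool(res.success)


def _gauss_newton_bse(residual_fn, params: np.ndarray, rss: float, n: int) -> np.ndarray:
    """Approximate standard errors from a finite-difference Jacobian."""
    p = np.asarray(params, float)
    n_par = p.size
    if n <= n_par:
        return np.full(n_par, np.nan)
    r0 = residual_fn(p)
    jac = np.empty((r0.size, n_par))
    for i in range(n_par):
        h = 1e-6 * max(abs(p[i]), 1e-12)
        dp = p.copy()
        dp[i] += h
        jac[:, i] = (residual_fn(dp) - r0) / h
    try:
        cov = np.linalg.inv(jac.T @ jac) * rss / (n - n_par)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(n_par, np.nan)


class ConventionalSemiInfiniteModel:
    """Fit the closed-form homogeneous semi-infinite model for alpha*D_B.

    Only lags where the *measured* g1 strictly exceeds ``cutoff`` (default
    0.7) enter the unweighted least-squares objective.
    """

    name = "conventional_single"

    def __init__(
        self,
        curve: CorrelationCurve,
        layer: OpticalLayer,
        rho: float,
        wavelength_nm: float = 785.0,
        cutoff: float = 0.7,
    ):
        if curve.kind != "g1":
            raise ValueError("expected a g1 curve")
        self.curve = curve
        self.layer = layer
        self.rho = float(rho)
        self.wavelength_nm = float(wavelength_nm)
        self.cutoff = float(cutoff)
        self._mask = curve.values > cutoff
        if int(self._mask.sum()) < 5:
            raise ValueError(
                f"fewer than 5 lags with g1 > {cutoff}; cannot fit the "
                "conventional model"
            )
        self._tau = curve.tau[self._mask]
        self._meas = curve.values[self._mask]

    def predict(self, alpha_db: float, tau: Optional[np.ndarray] = None) -> np.ndarray:
        tau = self._tau if tau is None else np.asarray(tau, float)
        return fw.g1_semi_infinite_conventional_values(
            self.layer, alpha_db, self.rho, tau, self.wavelength_nm
        )

    def fit(self) -> DCSFitResult:
        meas = self._meas

        def objective(a_db: float) -> float:
            return float(np.sum((self.predict(a_db) - meas) ** 2))

        est, converged = _scalar_fit(objective, np.geomspace(1e-12, 1e-6, 61))
        rss = objective(est)
        bse = _gauss_newton_bse(
            lambda p: self.predict(p[0]) - meas, np.array([est]), rss, meas.size
        )
        return DCSFitResult(
            model=self.name,
            params={"alpha_db": est},
            rss=rss,
            weighted_rss=rss / meas.size,
            n_points=int(meas.size),
            converged=converged,
            bse={"alpha_db": float(bse[0])},
            settings={"cutoff": self.cutoff, "rho_cm": self.rho},
        )


class HomogeneousFourierModel:
    """Fit the Fourier-domain homogeneous half-space model for D_B."""

    name = "fourier_single"

    def __init__(
        self,
        curve: CorrelationCurve,
        layer: OpticalLayer,
        rho: float,
        wavelength_nm: float = 785.0,
        tau_range: tuple[float, float] = DEFAULT_TAU_RANGE,
        boundary_length_mode: str = "extrapolated",
        order: int = 20,
    ):
        if curve.kind != "g1":
            raise ValueError("expected a g1 curve")
        self.curve = curve
        self.layer = layer
        self.rho = float(rho)
        self.wavelength_nm = float(wavelength_nm)
        self.tau_range = tau_range
        self.mode = boundary_length_mode
        self.order = order
        self._mask = (curve.tau >= tau_range[0]) & (curve.tau <= tau_range[1])
        if int(self._mask.sum()) < 5:
            raise ValueError("fewer than 5 lags inside the fit window")
        self._tau = curve.tau[self._mask]
        self._meas = curve.values[self._mask]
        self._q_max = fw._auto_qmax(
            LayeredMedium.homogeneous(layer, self.mode), self.wavelength_nm
        )

    def predict(self, d_b: float, tau: Optional[np.ndarray] = None) -> np.ndarray:
        tau = self._tau if tau is None else np.asarray(tau, float)
        medium = LayeredMedium.homogeneous(self.layer.with_(d_b=d_b), self.mode)
        return fw.g1_layered_values(
            medium, self.rho, tau, self.wavelength_nm, self.order, self._q_max
        )

    def fit(self) -> DCSFitResult:
        meas = self._meas

        def objective(d_b: float) -> float:
            return float(np.sum((self.predict(d_b) - meas) ** 2))

        est, converged = _scalar_fit(objective, np.geomspace(1e-12, 1e-6, 61))
        rss = objective(est)
        bse = _gauss_newton_bse(
            lambda p: self.predict(p[0]) - meas, np.array([est]), rss, meas.size
        )
        return DCSFitResult(
            model=self.name,
            params={"d_b": est},
            rss=rss,
            weighted_rss=rss / meas.size,
            n_points=int(meas.size),
            converged=converged,
            bse={"d_b": float(bse[0])},
            settings={
                "tau_range_s": self.tau_range,
                "rho_cm": self.rho,
                "boundary_length_mode": self.mode,
            },
        )


# ---------------------------------------------------------------------------
# two-layer model
# ---------------------------------------------------------------------------


class TwoLayerModel:
    """Simultaneous bounded fit of top-layer thickness and bottom-layer flow.

    The medium's layer optical properties, refractive indices and top-layer
    D_B1 (zero for a static slab) are held fixed; d1 and D_B2 are free within
    d1 in [0, 20] mm and D_B2 in [0, 1e-6] cm^2/s by default. The objective is
    sum w(tau) * (g1_model - g1_meas)^2 with w the per-lag SNR normalized to
    unit sum (uniform without SNR); non-finite SNR lags are excluded from the
    weighted objective. Estimation is a deterministic coarse grid (d1 step
    0.5 mm, 30 log-spaced D_B2 values) followed by bounded Nelder-Mead
    refinement from the grid argmin, so identical inputs give bit-identical
    results.
    """

    name = "two_layer"

    def __init__(
        self,
        curve: CorrelationCurve,
        medium: LayeredMedium,
        rho: float,
        weights: Optional[np.ndarray] = None,
        wavelength_nm: float = 785.0,
        tau_range: tuple[float, float] = DEFAULT_TAU_RANGE,
        d1_bounds: tuple[float, float] = DEFAULT_D1_BOUNDS,
        db2_bounds: tuple[float, float] = DEFAULT_DB2_BOUNDS,
        order: int = 20,
    ):
        if curve.kind != "g1":
            raise ValueError("expected a g1 curve")
        if medium.n_layers != 2:
            raise ValueError("TwoLayerModel needs a two-layer medium")
        self.curve = curve
        self.medium = medium
        self.top = medium.top
        self.bottom = medium.bottom
        self.rho = float(rho)
        self.wavelength_nm = float(wavelength_nm)
        self.tau_range = tau_range
        self.d1_bounds = d1_bounds
        self.db2_bounds = db2_bounds
        self.order = order
        self.mode = medium.boundary_length_mode

        self._mask = (curve.tau >= tau_range[0]) & (curve.tau <= tau_range[1])
        if not self._mask.any():
            raise ValueError("empty fit window")
        self._tau = curve.tau[self._mask]
        self._meas = curve.values[self._mask]

        if weights is None and curve.snr is not None:
            weights = curve.snr[self._mask]
        elif weights is not None:
            weights = np.asarray(weights, float)
            if weights.shape == curve.tau.shape:
                weights = weights[self._mask]
            elif weights.shape != self._tau.shape:
                raise ValueError("weights must match the full or windowed lag grid")
        if weights is None:
            self._w = np.full(self._tau.size, 1.0 / self._tau.size)
            self._w_mask = np.ones(self._tau.size, bool)
        else:
            finite = np.isfinite(weights) & (weights > 0)
            if not finite.any():
                raise ValueError("no usable (finite, positive) weights")
            w = np.where(finite, weights, 0.0)
            self._w = w / w.sum()
            self._w_mask = finite
        self._q_max = fw._auto_qmax(
            LayeredMedium.two_layer(
                self.top.with_(thickness=0.5), self.bottom, self.mode
            ),
            self.wavelength_nm,
        )

    # -- forward evaluation -------------------------------------------------

    def _curves(self, d1: float, db2: np.ndarray | float,
                tau: Optional[np.ndarray] = None, order: Optional[int] = None
                ) -> np.ndarray:
        """Model g1 for one d1 and one or many D_B2 values; shape (M, Nt)."""
        tau = self._tau if tau is None else np.asarray(tau, float)
        ht = fw._cached_transform(self.rho, self._q_max, order or self.order)
        tau_full = np.concatenate([[0.0], tau])
        vals = fw._ghat0_two_layer_core(
            ht.q, tau_full, self.top, self.bottom, float(d1),
            np.atleast_1d(np.asarray(db2, float)), self.wavelength_nm, self.mode,
        )
        g0 = ht.integrate(vals)
        return np.clip(g0[..., 1:] / g0[..., :1], 0.0, None)

    def predict(
        self, d1: float, db2: float, tau: Optional[np.ndarray] = None
    ) -> np.ndarray:
        """Model g1 curve at parameters (d1 cm, D_B2 cm^2/s)."""
        return self._curves(d1, db2, tau)[0]

    # -- objectives ----------------------------------------------------------

    def _weighted_rss_many(self, model_curves: np.ndarray) -> np.ndarray:
        res = model_curves - self._meas
        return (res**2) @ self._w

    def weighted_rss(self, d1: float, db2: float) -> float:
        return float(self._weighted_rss_many(self._curves(d1, db2))[0])

    def unweighted_rss(self, d1: float, db2: float) -> float:
        res = self.predict(d1, db2) - self._meas
        return float(np.sum(res**2))

    # -- estimation ----------------------------------------------------------

    def fit(
        self,
        d1_step: float = 0.05,
        n_db2: int = 30,
        db2_grid_range: tuple[float, float] = (1e-11, 1e-6),
    ) -> DCSFitResult:
        """Coarse-grid start (d1 step in cm; log-spaced D_B2) plus bounded
        Nelder-Mead refinement in (d1, log10 D_B2)."""
        d1_lo, d1_hi = self.d1_bounds
        d1_grid = np.arange(d1_lo, d1_hi + 0.5 * d1_step, d1_step)
        db2_grid = np.geomspace(*db2_grid_range, n_db2)
        # coarse stage on a decimated lag grid with a low quadrature order:
        # it only has to place the start near the global basin
        stride = max(1, self._tau.size // 24)
        idx = np.arange(0, self._tau.size, stride)
        tau_c = self._tau[idx]
        meas_c = self._meas[idx]
        w_c = self._w[idx]
        w_c = w_c / w_c.sum() if w_c.sum() > 0 else np.full(idx.size, 1.0 / idx.size)
        best = (math.inf, d1_grid[0], db2_grid[0])
        for d1 in d1_grid:
            curves = self._curves(d1, db2_grid, tau=tau_c, order=8)
            obj = ((curves - meas_c) ** 2) @ w_c
            j = int(obj.argmin())
            if obj[j] < best[0]:
                best = (float(obj[j]), float(d1), float(db2_grid[j]))
        _, d1_0, db2_0 = best

        lv_lo = math.log10(db2_grid_range[0])
        lv_hi = math.log10(min(db2_grid_range[1], self.db2_bounds[1]))

        def objective(x: np.ndarray) -> float:
            return self.weighted_rss(x[0], 10.0 ** x[1])

        res = optimize.minimize(
            objective,
            x0=np.array([d1_0, math.log10(db2_0)]),
            method="Nelder-Mead",
            bounds=[(d1_lo, d1_hi), (lv_lo, lv_hi)],
            options={
                "xatol": 1e-6,
                "fatol": 1e-12,
                "maxiter": 500,
            },
        )
        d1_hat = float(res.x[0])
        db2_hat = float(10.0 ** res.x[1])
        at_bound = (
            d1_hat <= d1_lo + 1e-9
            or d1_hat >= d1_hi - 1e-9
            or abs(res.x[1] - lv_lo) <= 1e-6
            or abs(res.x[1] - lv_hi) <= 1e-6
        )
        converged = bool(res.success) and not at_bound
        w_rss = float(res.fun)
        rss = self.unweighted_rss(d1_hat, db2_hat)
        bse = _gauss_newton_bse(
            lambda p: (self.predict(p[0], p[1]) - self._meas) * np.sqrt(self._w),
            np.array([d1_hat, db2_hat]),
            w_rss,
            self._meas.size,
        )
        return DCSFitResult(
            model=self.name,
            params={"d1": d1_hat, "d_b2": db2_hat},
            rss=rss,
            weighted_rss=w_rss,
            n_points=int(self._meas.size),
            converged=converged,
            bse={"d1": float(bse[0]), "d_b2": float(bse[1])},
            settings={
                "tau_range_s": self.tau_range,
                "rho_cm": self.rho,
                "boundary_length_mode": self.mode,
                "d1_bounds_cm": self.d1_bounds,
                "db2_bounds": self.db2_bounds,
                "weighted": bool(self.curve.snr is not None),
            },
        )

    # -- RSS landscape --------------------------------------------------------

    def rss_surface(
        self,
        d1_range: tuple[float, float] = (0.1, 0.9),
        db2_range: tuple[float, float] = (0.5e-9, 7.5e-9),
        grid_sizes: tuple[int, int] = (33, 29),
    ) -> RssSurface:
        """Dense unweighted RSS matrix over a (d1, D_B2) grid (cm, cm^2/s)."""
        n_d1, n_db2 = grid_sizes
        if n_d1 < 2 or n_db2 < 2:
            raise ValueError("grids need at least 2 points per axis")
        if d1_range[0] <= 0 or db2_range[0] <= 0:
            raise ValueError("grid ranges must be positive")
        d1_grid = np.linspace(*d1_range, n_d1)
        db2_grid = np.linspace(*db2_range, n_db2)
        rss = np.empty((n_d1, n_db2))
        for i, d1 in enumerate(d1_grid):
            res = self._curves(d1, db2_grid) - self._meas
            rss[i] = np.sum(res**2, axis=-1)
        return RssSurface(d1_grid, db2_grid, rss)


# ---------------------------------------------------------------------------
# functional wrappers (spec operation surface)
# ---------------------------------------------------------------------------


def fit_single_layer_conventional(
    g1: CorrelationCurve, layer: OpticalLayer, rho: float, **kwargs
) -> DCSFitResult:
    """Fit alpha*D_B with the conventional semi-infinite model (g1 > 0.7)."""
    return ConventionalSemiInfiniteModel(g1, layer, rho, **kwargs).fit()


def fit_single_layer_fourier(
    g1: CorrelationCurve, layer: OpticalLayer, rho: float, **kwargs
) -> DCSFitResult:
    """Fit D_B with the Fourier-domain homogeneous model."""
    return HomogeneousFourierModel(g1, layer, rho, **kwargs).fit()


def fit_two_layer(
    g1: CorrelationCurve,
    medium: LayeredMedium,
    rho: float,
    snr: Optional[np.ndarray] = None,
    **kwargs,
) -> DCSFitResult:
    """Fit (d1, D_B2) with the two-layer model; SNR weights taken from the
    curve when present, or passed explicitly via ``snr``."""
    fit_kwargs = {}
    for key in ("d1_step", "n_db2", "db2_grid_range"):
        if key in kwargs:
            fit_kwargs[key] = kwargs.pop(key)
    return TwoLayerModel(g1, medium, rho, weights=snr, **kwargs).fit(**fit_kwargs)


def rss_surface(
    g1: CorrelationCurve,
    medium: LayeredMedium,
    rho: float,
    d1_range: tuple[float, float] = (0.1, 0.9),
    db2_range: tuple[float, float] = (0.5e-9, 7.5e-9),
    grid_sizes: tuple[int, int] = (33, 29),
    **kwargs,
) -> RssSurface:
    """Unweighted RSS landscape of the two-layer model over (d1, D_B2)."""
    model = TwoLayerModel(g1, medium, rho, **kwargs)
    return model.rss_surface(d1_range, db2_range, grid_sizes)


def refine_with_surface(
    fit: DCSFitResult, surface: RssSurface, rel_tol: float = 1e-3
) -> DCSFitResult:
    """Replace a local-optimizer solution by the RSS-surface global argmin.

    The surface argmin is adopted only when its RSS undercuts the fit's
    unweighted RSS by strictly more than ``rel_tol`` relative; otherwise the
    fit is returned unchanged. This mirrors the contour-plot fallback used
    when a local optimizer is not guaranteed to reach the global minimum.
    """
    if fit.model != "two_layer":
        raise ValueError("surface refinement applies to two-layer fits")
    if surface.min_rss < fit.rss * (1.0 - rel_tol):
        d1, db2 = surface.argmin
        return DCSFitResult(
            model=fit.model,
            params={"d1": d1, "d_b2": db2},
            rss=surface.min_rss,
            weighted_rss=fit.weighted_rss,
            n_points=fit.n_points,
            converged=fit.converged,
            refined_by_surface=True,
            bse={},
            settings=fit.settings,
        )
    return fit
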