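"""Forward solutions of the correlation diffusion equation.

Continuous-wave DCS measures the normalized electric-field autocorrelation
g1(rho, tau) of multiply scattered coherent light. Two forward models are
provided:

* the conventional closed-form solution for a homogeneous semi-infinite
  medium (image-source construction with the extrapolated boundary), and
* a Fourier-domain Green's function for a finite slab over a semi-infinite
  medium (the skull-over-cortex geometry), returned to real space by an
  inverse Hankel transform with a zero-order Bessel kernel.

All lengths are in cm, times in s; the source normalization constant s0 is
set to 1 since it cancels in the normalized g1.
"""

from __future__ import annotations

import math
import warnings
from typing import Callable, Optional

import numpy as np
from scipy.special import j0, jn_zeros, roots_legendre

from .media import CorrelationCurve, LayeredMedium, OpticalLayer

__all__ = [
    "effective_reflection",
    "boundary_lengths",
    "decay_alpha",
    "g1_semi_infinite_conventional",
    "ghat0_homogeneous",
    "ghat0_two_layer",
    "inverse_hankel",
    "HankelTransform",
    "g1_layered",
    "g1_layered_values",
    "siegert",
]


def effective_reflection(n_refr: float) -> float:
    """Effective reflection coefficient of the medium-air boundary.

    Polynomial fit in the refractive index n:
    Reff = -1.44 n^-2 + 0.71 n^-1 + 0.064 n + 0.668.
    """
    n = float(n_refr)
    if not math.isfinite(n) or n < 1:
        raise ValueError(f"refractive index must be finite and >= 1, got {n_refr}")
    return -1.44 * n**-2 + 0.71 * n**-1 + 0.064 * n + 0.668


def boundary_lengths(layer: OpticalLayer) -> tuple[float, float]:
    """Image-source depth z0 = 1/mu_s' and extrapolation length zb, both cm.

    zb = (2/(3 mu_s')) * (1+Reff)/(1-Reff) with Reff the effective reflection
    coefficient for the layer's refractive index.
    """
    reff = effective_reflection(layer.n_refr)
    if reff >= 1:
        raise ValueError(f"effective reflection {reff:.4f} >= 1; zb undefined")
    z0 = layer.l_star
    zb = (2.0 / (3.0 * layer.mu_s_prime)) * (1.0 + reff) / (1.0 - reff)
    return z0, zb


def _alpha_sq(layer: OpticalLayer, tau: np.ndarray, wavelength_nm: float) -> np.ndarray:
    """Squared decay coefficient alpha_n(tau)^2 = 3 mu_a mu_s' + 6 tau k^2 D_B mu_s'^2.

    Equivalent to 3/(l* l_a) + 6 tau / (tau0 l*^2) with tau0 = 1/(k^2 D_B).
    """
    k = layer.wavenumber(wavelength_nm)
    return (
        3.0 * layer.mu_a * layer.mu_s_prime
        + 6.0 * k * k * layer.d_b * layer.mu_s_prime**2 * tau
    )


def decay_alpha(
    layer: OpticalLayer, tau: np.ndarray | float, wavelength_nm: float = 785.0
) -> np.ndarray:
    """Per-layer decay coefficient alpha_n(tau) of the correlation diffusion
    equation, cm^-1. Reduces to sqrt(3 mu_a mu_s') for a static layer."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    return np.sqrt(_alpha_sq(layer, tau, wavelength_nm))


# ---------------------------------------------------------------------------
# conventional semi-infinite model
# ---------------------------------------------------------------------------


def g1_semi_infinite_conventional_values(
    layer: OpticalLayer,
    alpha_db: float,
    rho: float,
    tau: np.ndarray,
    wavelength_nm: float = 785.0,
) -> np.ndarray:
    """Normalized g1 of the conventional homogeneous semi-infinite model.

    K(tau)^2 = 3 mu_a mu_s' + mu_s'^2 k0^2 * 6 * (alpha_db) * tau, with
    alpha_db the product of the moving-scatterer fraction and the Brownian
    diffusion coefficient (the quantity the conventional model fits).
    """
    if alpha_db < 0 or not math.isfinite(alpha_db):
        raise ValueError("alpha_db must be finite and >= 0")
    if rho <= 0:
        raise ValueError("rho must be positive")
    tau = np.asarray(tau, dtype=float)
    k0 = layer.wavenumber(wavelength_nm)
    z0, zb = boundary_lengths(layer)
    r1 = math.hypot(rho, z0)
    r2 = math.hypot(rho, z0 + 2.0 * zb)

    def unnormalized(t: np.ndarray) -> np.ndarray:
        ksq = 3.0 * layer.mu_a * layer.mu_s_prime + 6.0 * layer.mu_s_prime**2 * k0**2 * alpha_db * t
        kk = np.sqrt(ksq)
        return np.exp(-kk * r1) / r1 - np.exp(-kk * r2) / r2

    g = unnormalized(tau) / unnormalized(np.asarray(0.0))
    return np.clip(g, 0.0, None)


def g1_semi_infinite_conventional(
    layer: OpticalLayer,
    alpha_db: float,
    rho: float,
    tau: np.ndarray,
    wavelength_nm: float = 785.0,
) -> CorrelationCurve:
    """As :func:`g1_semi_infinite_conventional_values`, packaged as a curve."""
    values = g1_semi_infinite_conventional_values(
        layer, alpha_db, rho, tau, wavelength_nm
    )
    return CorrelationCurve(np.asarray(tau, float), np.clip(values, 0.0, 1.0), kind="g1")


# ---------------------------------------------------------------------------
# Fourier-domain Green's functions
# ---------------------------------------------------------------------------


def _z0_for_mode(top: OpticalLayer, mode: str) -> float:
    if mode == "extrapolated":
        return boundary_lengths(top)[1]
    if mode == "mfp":
        return top.l_star
    raise ValueError(f"unknown boundary_length_mode {mode!r}")


def ghat0_homogeneous(
    q: np.ndarray | float,
    tau: np.ndarray | float,
    layer: OpticalLayer,
    wavelength_nm: float = 785.0,
    boundary_length_mode: str = "extrapolated",
) -> np.ndarray:
    """Surface Fourier-domain Green's function for a homogeneous half-space.

    ghat0(q, z=0, tau) = z0 * exp(-beta1 z') / (1 + beta1 z0), with
    beta1 = sqrt(alpha1(tau)^2 + q^2), z' = 1/mu_s' the source depth, and z0
    the surface boundary length (extrapolation length by default). Returned
    up to the source constant s0. Broadcasts q against tau: array q of shape
    (Nq,) with array tau of shape (Nt,) yields shape (Nq, Nt).
    """
    q = np.asarray(q, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    q2 = (q**2)[..., None] if tau.ndim else q**2
    beta1 = np.sqrt(_alpha_sq(layer, tau, wavelength_nm) + q2)
    z_src = layer.l_star
    z0 = _z0_for_mode(layer, boundary_length_mode)
    return z0 * np.exp(-beta1 * z_src) / (1.0 + beta1 * z0)


def _ghat0_two_layer_core(
    q: np.ndarray,
    tau: np.ndarray,
    top: OpticalLayer,
    bottom: OpticalLayer,
    d1: float,
    db2: np.ndarray | float,
    wavelength_nm: float,
    boundary_length_mode: str,
) -> np.ndarray:
    """Two-layer ghat0 with optional vectorization over bottom-layer D_B.

    Shapes: q (Nq,), tau (Nt,), db2 scalar or (M,); output (Nq, Nt) or
    (M, Nq, Nt). Hyperbolic functions are evaluated in tanh/ratio form so the
    result stays finite for arbitrarily large beta1*d1.
    """
    z_src = top.l_star
    z0 = _z0_for_mode(top, boundary_length_mode)
    d_top = top.photon_diffusion
    d_bot = bottom.photon_diffusion
    k2 = bottom.wavenumber(wavelength_nm)

    a1_sq = _alpha_sq(top, tau, wavelength_nm)  # (Nt,)
    db2_arr = np.asarray(db2, dtype=float)
    scalar_db2 = db2_arr.ndim == 0
    db2_col = np.atleast_1d(db2_arr)[:, None]  # (M, 1)
    a2_sq = (
        3.0 * bottom.mu_a * bottom.mu_s_prime
        + 6.0 * k2 * k2 * bottom.mu_s_prime**2 * db2_col * tau
    )  # (M, Nt)

    q_sq = (q**2)[None, :, None]  # (1, Nq, 1)
    beta1 = np.sqrt(a1_sq[None, None, :] + q_sq)  # (1, Nq, Nt)
    beta2 = np.sqrt(a2_sq[:, None, :] + q_sq)  # (M, Nq, Nt)

    # Ratios cosh(beta1 (d1-z'))/cosh(beta1 d1) and sinh(..)/cosh(..) written
    # with explicit exponentials: the naive cosh(x) - tanh(a) sinh(x) loses
    # all precision once x >~ 18 because tanh saturates to 1.
    a = beta1 * d1
    x = beta1 * z_src
    em2a = np.exp(-2.0 * a)
    t = (1.0 - em2a) / (1.0 + em2a)  # tanh(beta1 d1)
    e_up = np.exp(x - 2.0 * a)
    e_dn = np.exp(-x)
    ch_ratio = (e_up + e_dn) / (1.0 + em2a)
    sh_ratio = (e_dn - e_up) / (1.0 + em2a)
    num = z0 * (beta1 * d_top * ch_ratio + beta2 * d_bot * sh_ratio)
    den = beta1 * (d_top + beta2 * d_bot * z0) + (
        beta2 * d_bot + beta1**2 * d_top * z0
    ) * t
    out = num / den
    return out[0] if scalar_db2 else out


def ghat0_two_layer(
    q: np.ndarray | float,
    tau: np.ndarray | float,
    medium: LayeredMedium,
    wavelength_nm: float = 785.0,
) -> np.ndarray:
    """Surface Fourier-domain Green's function for a two-layer medium.

    Finite top slab of thickness d1 over a semi-infinite bottom layer; the
    isotropic source sits one transport mean free path below the surface,
    inside the top layer. Returned up to the source constant s0. For array
    q (Nq,) and tau (Nt,) the result has shape (Nq, Nt).
    """
    if medium.n_layers != 2:
        raise ValueError("ghat0_two_layer requires a two-layer medium")
    top, bottom = medium.layers
    d1 = top.thickness
    if d1 <= top.l_star:
        warnings.warn(
            f"top-layer thickness {d1:.4g} cm does not exceed the source depth "
            f"z' = {top.l_star:.4g} cm; the slab Green's function is evaluated "
            "anyway but the diffusion approximation is questionable",
            RuntimeWarning,
            stacklevel=2,
        )
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    tau_arr = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(q_arr < 0):
        raise ValueError("q must be >= 0")
    out = _ghat0_two_layer_core(
        q_arr, tau_arr, top, bottom, d1, bottom.d_b, wavelength_nm,
        medium.boundary_length_mode,
    )
    if np.ndim(tau) == 0:
        out = out[..., 0]
    if np.ndim(q) == 0 and out.ndim:
        out = out[0]
    return out


# ---------------------------------------------------------------------------
# inverse Hankel transform
# ---------------------------------------------------------------------------


class HankelTransform:
    """Fixed quadrature rule for (1/2pi) * int_0^inf ghat(q) q J0(rho q) dq.

    The integration interval [0, q_max] is split into panels at successive
    zeros of J0(rho q), each integrated with Gauss-Legendre of the given
    order, so the oscillatory kernel is resolved panel by panel. Nodes and
    the combined weights w_i * q_i * J0(rho q_i) / (2 pi) are precomputed;
    evaluating a transform is then a single contraction over the node axis.
    """

    def __init__(self, rho: float, q_max: float, order: int = 20):
        if rho <= 0 or q_max <= 0:
            raise ValueError("rho and q_max must be positive")
        n_zeros = max(1, int(math.ceil(q_max * rho / math.pi)) + 1)
        zeros = jn_zeros(0, n_zeros) / rho
        edges = np.concatenate([[0.0], zeros[zeros < q_max], [q_max]])
        x, w = roots_legendre(order)
        mid = 0.5 * (edges[1:] + edges[:-1])
        half = 0.5 * (edges[1:] - edges[:-1])
        q = (mid[:, None] + half[:, None] * x[None, :]).ravel()
        wq = (half[:, None] * w[None, :]).ravel()
        self.rho = float(rho)
        self.q_max = float(q_max)
        self.order = int(order)
        self.q = q
        self.weights = wq * q * j0(rho * q) / (2.0 * math.pi)

    def integrate(self, ghat_values: np.ndarray) -> np.ndarray:
        """Contract ghat values sampled at ``self.q`` (axis -2 for 2-d and
        higher input, axis -1 for 1-d input) against the quadrature weights."""
        vals = np.asarray(ghat_values, dtype=float)
        if vals.ndim == 1:
            return float(vals @ self.weights)
        return np.einsum("...qt,q->...t", vals, self.weights)


def _probe_qmax(
    ghat: Callable[[np.ndarray], np.ndarray],
    q_floor: float,
    q_cap: float,
    rel_cut: float = 1e-12,
) -> float:
    """Upper cutoff where the integrand envelope q*ghat(q) has fallen below
    ``rel_cut`` of its peak, probed on a coarse grid; never below q_floor."""
    qs = np.linspace(1e-6, q_cap, 512)
    env = np.abs(np.asarray(ghat(qs), dtype=float).reshape(len(qs), -1)).max(axis=1) * qs
    peak = env.max()
    if peak <= 0:
        return q_floor
    ipk = int(env.argmax())
    below = np.nonzero(env[ipk:] < rel_cut * peak)[0]
    if below.size == 0:
        return q_cap
    return max(q_floor, float(qs[ipk + below[0]]))


def inverse_hankel(
    ghat: Callable[[np.ndarray], np.ndarray],
    rho: float,
    q_max: Optional[float] = None,
    rtol: float = 1e-8,
    max_order: int = 128,
) -> float:
    """Zero-order inverse Hankel transform (1/2pi) int_0^inf ghat(q) q J0(rho q) dq.

    ``ghat`` is evaluated on vector q >= 0 at fixed tau. Panels are split at
    the zeros of J0(rho q); the Gauss-Legendre order per panel is doubled
    until two successive estimates agree to ``rtol`` relative. If ``q_max``
    is omitted it is chosen where the integrand falls below 1e-12 of its
    peak (capped at 8x the default search window).

    Raises
    ------
    RuntimeError
        If the estimates have not converged at ``max_order``.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    if q_max is None:
        q_max = _probe_qmax(ghat, q_floor=40.0 / rho, q_cap=4096.0 / rho)
    prev = None
    order = 16
    while order <= max_order:
        ht = HankelTransform(rho, q_max, order)
        samples = np.asarray(ghat(ht.q), dtype=float)
        val = float(samples @ ht.weights)
        # the oscillatory sum cannot be resolved below the roundoff of its
        # absolute terms, so the tolerance carries an absolute floor
        floor = 1e-13 * float(np.abs(samples) @ np.abs(ht.weights))
        if prev is not None and abs(val - prev) <= max(rtol * abs(val), floor):
            return val
        prev = val
        order *= 2
    raise RuntimeError(
        f"inverse Hankel transform did not converge to rtol={rtol:g} at "
        f"order {max_order} (last two estimates {prev:.6e}); "
        f"rho={rho:g} cm, q_max={q_max:g} cm^-1"
    )


# ---------------------------------------------------------------------------
# assembled layered g1
# ---------------------------------------------------------------------------

_TRANSFORM_CACHE: dict[tuple[float, float, int], HankelTransform] = {}


def _cached_transform(rho: float, q_max: float, order: int) -> HankelTransform:
    key = (round(rho, 10), round(q_max, 6), order)
    ht = _TRANSFORM_CACHE.get(key)
    if ht is None:
        ht = HankelTransform(rho, q_max, order)
        if len(_TRANSFORM_CACHE) > 256:
            _TRANSFORM_CACHE.clear()
        _TRANSFORM_CACHE[key] = ht
    return ht


def _medium_ghat(medium: LayeredMedium, wavelength_nm: float):
    """Return an evaluator ghat(q, tau)->(Nq,Nt) for a 1- or 2-layer medium."""
    if medium.n_layers == 1:
        layer = medium.layers[0]
        mode = medium.boundary_length_mode

        def ghat(q: np.ndarray, tau: np.ndarray) -> np.ndarray:
            return ghat0_homogeneous(q, tau, layer, wavelength_nm, mode)

        return ghat

    top, bottom = medium.layers

    def ghat(q: np.ndarray, tau: np.ndarray) -> np.ndarray:
        return _ghat0_two_layer_core(
            q, tau, top, bottom, top.thickness, bottom.d_b, wavelength_nm,
            medium.boundary_length_mode,
        )

    return ghat


def _auto_qmax(medium: LayeredMedium, wavelength_nm: float) -> float:
    """Cutoff for the q integration based on the tau=0 integrand envelope."""
    ghat = _medium_ghat(medium, wavelength_nm)
    mus1 = medium.top.mu_s_prime
    return _probe_qmax(
        lambda q: ghat(q, np.array([0.0]))[:, 0],
        q_floor=20.0 * mus1,
        q_cap=60.0 * mus1,
    )


def g1_layered_values(
    medium: LayeredMedium,
    rho: float,
    tau: np.ndarray,
    wavelength_nm: float = 785.0,
    order: int = 20,
    q_max: Optional[float] = None,
) -> np.ndarray:
    """Normalized g1(tau) = G0(rho, tau) / G0(rho, 0) for a layered medium."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    tau = np.asarray(tau, dtype=float)
    if q_max is None:
        q_max = _auto_qmax(medium, wavelength_nm)
    ht = _cached_transform(rho, q_max, order)
    ghat = _medium_ghat(medium, wavelength_nm)
    tau_full = np.concatenate([[0.0], tau])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = ghat(ht.q, tau_full)
    g0 = ht.integrate(vals)
    g = g0[..., 1:] / g0[..., :1]
    return np.clip(g, 0.0, None)


def g1_layered(
    medium: LayeredMedium,
    rho: float,
    tau: np.ndarray,
    wavelength_nm: float = 785.0,
    order: int = 20,
    q_max: Optional[float] = None,
) -> CorrelationCurve:
    """As :func:`g1_layered_values`, packaged as a :class:`CorrelationCurve`."""
    values = g1_layered_values(medium, rho, tau, wavelength_nm, order, q_max)
    return CorrelationCurve(np.asarray(tau, float), np.clip(values, 0.0, 1.0), kind="g1")


def siegert(curve: CorrelationCurve, beta: float) -> CorrelationCurve:
    """Siegert relation g2 = 1 + beta * |g1|^2 for 0 < beta <= 1."""
    if not (0 < beta <= 1):
        raise ValueError("beta must lie in (0, 1]")
    if curve.kind != "g1":
        raise ValueError("siegert expects a g1 curve")
    return CorrelationCurve(
        curve.tau,
        1.0 + beta * curve.values**2,
        kind="g2",
        n_snapshots=curve.n_snapshots,
    )
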