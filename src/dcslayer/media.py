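"""Optical media, probe geometry and correlation-curve containers.

Internal units are cm, s and cm^2/s throughout; wavelengths are carried in nm
(the conventional unit on the instrument side) and converted where needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "C_VACUUM_CM_S",
    "OpticalLayer",
    "LayeredMedium",
    "ProbeGeometry",
    "CorrelationCurve",
    "BoundaryLengthMode",
]

#: speed of light in vacuum, cm/s
C_VACUUM_CM_S = 2.99792458e10

BoundaryLengthMode = Literal["extrapolated", "mfp"]


@dataclass(frozen=True)
class OpticalLayer:
    """A homogeneous optical layer.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, cm^-1. Must be positive.
    mu_s_prime : float
        Reduced scattering coefficient, cm^-1. Must be positive.
    n_refr : float
        Refractive index (>= 1).
    d_b : float
        Brownian diffusion coefficient of the moving scatterers, cm^2/s.
        Zero for a static layer.
    thickness : float or None
        Layer thickness in cm. ``None`` is the explicit sentinel for a
        semi-infinite layer.
    """

    mu_a: float
    mu_s_prime: float
    n_refr: float = 1.33
    d_b: float = 0.0
    thickness: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu_a) and self.mu_a > 0):
            raise ValueError(f"mu_a must be positive and finite, got {self.mu_a}")
        if not (math.isfinite(self.mu_s_prime) and self.mu_s_prime > 0):
            raise ValueError(
                f"mu_s_prime must be positive and finite, got {self.mu_s_prime}"
            )
        if not (math.isfinite(self.n_refr) and self.n_refr >= 1):
            raise ValueError(f"n_refr must be >= 1, got {self.n_refr}")
        if not (math.isfinite(self.d_b) and self.d_b >= 0):
            raise ValueError(f"d_b must be >= 0, got {self.d_b}")
        if self.thickness is not None and not (
            math.isfinite(self.thickness) and self.thickness > 0
        ):
            raise ValueError(
                "thickness must be positive and finite, or None for semi-infinite"
            )

    # ---- derived transport quantities -------------------------------------

    @property
    def l_star(self) -> float:
        """Transport mean free path l* = 1/mu_s', cm."""
        return 1.0 / self.mu_s_prime

    @property
    def l_a(self) -> float:
        """Absorption mean free path l_a = 1/mu_a, cm."""
        return 1.0 / self.mu_a

    @property
    def photon_diffusion(self) -> float:
        """Photon diffusion coefficient D = c*l*/3 with c the in-medium speed, cm^2/s."""
        return (C_VACUUM_CM_S / self.n_refr) * self.l_star / 3.0

    def wavenumber(self, wavelength_nm: float) -> float:
        """In-medium optical wavenumber k = 2*pi*n/lambda, cm^-1."""
        if wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        return 2.0 * math.pi * self.n_refr / (wavelength_nm * 1e-7)

    def single_scattering_time(self, wavelength_nm: float) -> float:
        """Correlation time of a single scattering event, tau0 = 1/(k^2 * D_B), s.

        Infinite for a static layer (d_b == 0).
        """
        if self.d_b == 0:
            return math.inf
        return 1.0 / (self.wavenumber(wavelength_nm) ** 2 * self.d_b)

    @property
    def semi_infinite(self) -> bool:
        return self.thickness is None

    def with_(self, **kwargs) -> "OpticalLayer":
        """Return a copy with fields replaced (convenience for perturbations)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LayeredMedium:
    """An ordered stack of layers, top first; the last layer is semi-infinite.

    Supports one layer (homogeneous half-space) or two layers (finite static or
    dynamic slab over a semi-infinite medium, the skull-over-cortex geometry).
    """

    layers: tuple[OpticalLayer, ...]
    boundary_length_mode: BoundaryLengthMode = "extrapolated"

    def __init__(
        self,
        layers: Sequence[OpticalLayer],
        boundary_length_mode: BoundaryLengthMode = "extrapolated",
    ):
        layers = tuple(layers)
        if len(layers) not in (1, 2):
            raise ValueError("LayeredMedium supports 1 or 2 layers")
        for lyr in layers[:-1]:
            if lyr.semi_infinite:
                raise ValueError("only the last layer may be semi-infinite")
        if not layers[-1].semi_infinite:
            raise ValueError("the last layer must be semi-infinite (thickness=None)")
        if boundary_length_mode not in ("extrapolated", "mfp"):
            raise ValueError(f"unknown boundary_length_mode {boundary_length_mode!r}")
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "boundary_length_mode", boundary_length_mode)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def top(self) -> OpticalLayer:
        return self.layers[0]

    @property
    def bottom(self) -> OpticalLayer:
        return self.layers[-1]

    @property
    def d1(self) -> Optional[float]:
        """Top-layer thickness in cm (None for a homogeneous medium)."""
        return self.layers[0].thickness if self.n_layers == 2 else None

    @staticmethod
    def homogeneous(
        layer: OpticalLayer, boundary_length_mode: BoundaryLengthMode = "extrapolated"
    ) -> "LayeredMedium":
        if not layer.semi_infinite:
            layer = layer.with_(thickness=None)
        return LayeredMedium([layer], boundary_length_mode)

    @staticmethod
    def two_layer(
        top: OpticalLayer,
        bottom: OpticalLayer,
        boundary_length_mode: BoundaryLengthMode = "extrapolated",
    ) -> "LayeredMedium":
        if top.semi_infinite:
            raise ValueError("top layer needs a finite thickness")
        if not bottom.semi_infinite:
            bottom = bottom.with_(thickness=None)
        return LayeredMedium([top, bottom], boundary_length_mode)


@dataclass(frozen=True)
class ProbeGeometry:
    """Source-detector geometry and detection coherence.

    rho is the tuple of source-detector distances in cm; beta the Siegert
    coherence factor in (0, 1].
    """

    rho: tuple[float, ...]
    wavelength_nm: float = 785.0
    beta: float = 0.5

    def __init__(
        self,
        rho: Sequence[float],
        wavelength_nm: float = 785.0,
        beta: float = 0.5,
    ):
        rho = tuple(float(r) for r in rho)
        if not rho or any(not math.isfinite(r) or r <= 0 for r in rho):
            raise ValueError("all source-detector distances must be positive")
        if wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if not (0 < beta <= 1):
            raise ValueError("beta must lie in (0, 1]")
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "wavelength_nm", float(wavelength_nm))
        object.__setattr__(self, "beta", float(beta))

    @staticmethod
    def from_mm(
        sd_mm: Sequence[float], wavelength_nm: float = 785.0, beta: float = 0.5
    ) -> "ProbeGeometry":
        return ProbeGeometry([r / 10.0 for r in sd_mm], wavelength_nm, beta)


_KIND_TOL = 1e-9


@dataclass(frozen=True)
class CorrelationCurve:
    """A sampled autocorrelation curve on a strictly increasing lag grid.

    ``kind`` distinguishes the field autocorrelation g1 from the intensity
    autocorrelation g2. ``snr`` optionally carries the per-lag signal-to-noise
    ratio (g2-1 over its ensemble standard deviation); ``n_snapshots`` records
    how many snapshots were averaged into the values.
    """

    tau: np.ndarray
    values: np.ndarray
    kind: Literal["g1", "g2"] = "g1"
    snr: Optional[np.ndarray] = None
    n_snapshots: int = 1
    n_clipped: int = 0

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "values", values)
        if tau.ndim != 1 or values.shape != tau.shape:
            raise ValueError("tau and values must be 1-d arrays of equal length")
        if tau.size == 0:
            raise ValueError("empty lag grid")
        if np.any(tau <= 0) or np.any(np.diff(tau) <= 0):
            raise ValueError("tau must be positive and strictly increasing")
        if self.kind not in ("g1", "g2"):
            raise ValueError(f"kind must be 'g1' or 'g2', got {self.kind!r}")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite correlation values")
        # forward-model g1 obeys [0, 1] to numeric tolerance; g1 converted
        # from noisy g2 with an estimated beta may exceed 1 by a small margin
        if self.kind == "g1" and (
            values.min() < -1e-6 or values.max() > 1.05
        ):
            raise ValueError("g1 values must lie in [0, 1] (within tolerance)")
        if self.kind == "g2" and values.min() < 1 - 0.5:
            # allow noisy g2 to dip below 1 but reject obviously mislabeled data
            raise ValueError("g2 values must be >= 1 up to noise")
        if self.snr is not None:
            snr = np.asarray(self.snr, dtype=float)
            if snr.shape != tau.shape:
                raise ValueError("snr must match the lag grid")
            object.__setattr__(self, "snr", snr)
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")

    def restrict(self, tau_min: float, tau_max: float) -> "CorrelationCurve":
        """Slice the curve to tau_min <= tau <= tau_max (inclusive)."""
        mask = (self.tau >= tau_min) & (self.tau <= tau_max)
        if not mask.any():
            raise ValueError(
                f"no lags in [{tau_min:g}, {tau_max:g}] s on this grid"
            )
        return CorrelationCurve(
            self.tau[mask],
            self.values[mask],
            kind=self.kind,
            snr=None if self.snr is None else self.snr[mask],
            n_snapshots=self.n_snapshots,
            n_clipped=self.n_clipped,
        )

    def __len__(self) -> int:
        return int(self.tau.size)
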