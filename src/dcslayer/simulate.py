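"""Synthetic two-layer phantom series and noisy DCS acquisitions.

The preset series mirrors a skull-over-cortex phantom ladder: a static solid
slab (P1-P7, thicknesses 2.01-8.08 mm) resting on a semi-infinite dynamic
liquid, plus the homogeneous liquid-only reference P0. Acquisitions emulate a
hardware correlator streaming g2 snapshots at a fixed rate; the noise model
is a shot-noise-style Gaussian perturbation per lag (see ``noise_sigma``),
chosen to exercise SNR estimation and weighting rather than to reproduce any
particular correlator's statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import forward as fw
from .media import CorrelationCurve, LayeredMedium, OpticalLayer
from .models import snr_curve

__all__ = [
    "PhantomPreset",
    "AcquisitionSpec",
    "phantom_presets",
    "default_tau_grid",
    "noise_sigma",
    "simulate_acquisition",
    "average_curve",
]

#: printed phantom ladder: top-layer thicknesses in mm (P0 has no top layer)
PRESET_THICKNESS_MM: dict[str, Optional[float]] = {
    "P0": None,
    "P1": 2.01,
    "P2": 3.28,
    "P3": 3.87,
    "P4": 4.65,
    "P5": 4.99,
    "P6": 5.96,
    "P7": 8.08,
}

#: baseline optical properties of the solid top layer (skull surrogate)
TOP_BASELINE = {"mu_a": 0.11, "mu_s_prime": 8.50, "n_refr": 1.40, "d_b": 0.0}
#: baseline optical properties of the liquid bottom layer (cortex surrogate)
BOTTOM_BASELINE = {"mu_a": 0.12, "mu_s_prime": 10.46, "n_refr": 1.33}

#: default bottom-layer Brownian coefficient for presets, cm^2/s
DEFAULT_DB2 = 2e-9


@dataclass(frozen=True)
class PhantomPreset:
    """One rung of the phantom ladder: label, top thickness, layer properties."""

    label: str
    top_thickness_mm: Optional[float]
    top: Optional[OpticalLayer]
    bottom: OpticalLayer

    def medium(self, boundary_length_mode: str = "extrapolated") -> LayeredMedium:
        """Build the layered medium (homogeneous for P0)."""
        if self.top is None:
            return LayeredMedium.homogeneous(self.bottom, boundary_length_mode)
        return LayeredMedium.two_layer(self.top, self.bottom, boundary_length_mode)

    @property
    def homogeneous(self) -> bool:
        return self.top is None


def phantom_presets(d_b2: float = DEFAULT_DB2) -> list[PhantomPreset]:
    """The eight presets P0-P7 with the baseline optical properties.

    All presets share the bottom layer; ``d_b2`` sets its Brownian
    coefficient (the liquid's true flow index is a configurable stand-in).
    """
    bottom = OpticalLayer(d_b=d_b2, thickness=None, **BOTTOM_BASELINE)
    presets = []
    for label, d1_mm in PRESET_THICKNESS_MM.items():
        top = (
            None
            if d1_mm is None
            else OpticalLayer(thickness=d1_mm / 10.0, **TOP_BASELINE)
        )
        presets.append(PhantomPreset(label, d1_mm, top, bottom))
    return presets


def default_tau_grid(
    tau_min: float = 1.5e-7, tau_max: float = 0.1, n: int = 128
) -> np.ndarray:
    """Quasi-logarithmic correlator lag grid, s.

    Spans the coherence-factor window (0.5-0.8 us) and the fit window
    (1e-6 to 3e-3 s) with room on both sides.
    """
    return np.geomspace(tau_min, tau_max, n)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition protocol: snapshot timing, probe distances, detection.

    Defaults follow the standard protocol: 2 Hz snapshots over 100 s at
    SD = 10/15/20/25 mm. ``count_rate`` is the per-detector photon rate
    (Hz) entering the noise model; ``attenuation_mm`` is the phenomenological
    e-folding thickness by which a static top layer reduces the count rate.
    """

    duration_s: float = 100.0
    rate_hz: float = 2.0
    sd_mm: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0)
    beta: float = 0.5
    count_rate: float = 5e4
    seed: int = 0
    tau_min_s: float = 1.5e-7
    tau_max_s: float = 0.1
    n_tau: int = 128
    attenuation_mm: float = 5.0

    def __post_init__(self) -> None:
        n_snap = self.duration_s * self.rate_hz
        if n_snap <= 0 or abs(n_snap - round(n_snap)) > 1e-9:
            raise ValueError("duration_s * rate_hz must be a positive integer")
        if self.beta <= 0 or self.beta > 1:
            raise ValueError("beta must lie in (0, 1]")
        if self.count_rate <= 0 or self.tau_min_s <= 0 or self.n_tau < 2:
            raise ValueError("invalid acquisition spec")

    @property
    def n_snapshots(self) -> int:
        return int(round(self.duration_s * self.rate_hz))

    @property
    def bin_time_s(self) -> float:
        return 1.0 / self.rate_hz

    def tau_grid(self) -> np.ndarray:
        return default_tau_grid(self.tau_min_s, self.tau_max_s, self.n_tau)


def noise_sigma(
    tau: np.ndarray,
    mean_g2: np.ndarray,
    count_rate: float,
    bin_time: float,
    beta: float = 0.5,
    scale: float = 1.0,
) -> np.ndarray:
    """Per-lag standard deviation of a single g2 snapshot.

    A shot-noise-dominated approximation: sigma(tau) =
    scale * sqrt(mean_g2 / (count_rate * bin_time)), with
    mean_g2 = 1 + beta*g1(tau)^2 carrying the lag dependence. This is a
    modeling choice for exercising the SNR-weighted pipeline, not a
    hardware-validated correlator noise model.
    """
    if count_rate <= 0 or bin_time <= 0:
        raise ValueError("count_rate and bin_time must be positive")
    tau = np.asarray(tau, float)
    mean_g2 = np.broadcast_to(np.asarray(mean_g2, float), tau.shape)
    return scale * np.sqrt(mean_g2 / (count_rate * bin_time))


def simulate_acquisition(
    medium: LayeredMedium,
    spec: AcquisitionSpec,
    wavelength_nm: float = 785.0,
    noise: bool = True,
) -> dict[float, list[CorrelationCurve]]:
    """Simulate per-SD ensembles of g2 snapshot curves.

    For each source-detector distance the forward g1 is computed once, the
    noise-free g2 follows from the Siegert relation, and each snapshot adds
    an independent Gaussian perturbation with ``noise_sigma``. A static top
    layer attenuates the effective count rate as exp(-d1/attenuation_mm).
    Fully reproducible for a fixed ``spec.seed``; set ``noise=False`` for the
    exact forward curves.
    """
    tau = spec.tau_grid()
    count_rate = spec.count_rate
    if medium.n_layers == 2:
        d1_mm = medium.d1 * 10.0
        count_rate = count_rate * math.exp(-d1_mm / spec.attenuation_mm)
    streams = np.random.SeedSequence(spec.seed).spawn(len(spec.sd_mm))
    out: dict[float, list[CorrelationCurve]] = {}
    for sd, stream in zip(spec.sd_mm, streams):
        rho = sd / 10.0
        g1 = fw.g1_layered_values(medium, rho, tau, wavelength_nm)
        g2_clean = 1.0 + spec.beta * g1**2
        sigma = noise_sigma(
            tau, g2_clean, count_rate, spec.bin_time_s, spec.beta
        )
        rng = np.random.default_rng(stream)
        snapshots = []
        for _ in range(spec.n_snapshots):
            values = g2_clean + (rng.normal(0.0, sigma) if noise else 0.0)
            snapshots.append(CorrelationCurve(tau, values, kind="g2"))
        out[sd] = snapshots
    return out


def average_curve(ensemble: Sequence[CorrelationCurve]) -> CorrelationCurve:
    """Average an ensemble of g2 snapshots and attach the per-lag SNR.

    With fewer than 2 snapshots, or an ensemble with zero spread everywhere
    (noise-free simulation), no SNR is attached.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    tau0 = ensemble[0].tau
    for c in ensemble[1:]:
        if c.tau.shape != tau0.shape or not np.allclose(c.tau, tau0):
            raise ValueError("snapshots must share a common lag grid")
        if c.kind != ensemble[0].kind:
            raise ValueError("mixed curve kinds in ensemble")
    mean = np.mean([c.values for c in ensemble], axis=0)
    snr = None
    if len(ensemble) >= 2:
        stack = np.stack([c.values for c in ensemble])
        # spread at rounding level (e.g. a noise-free ensemble) carries no
        # usable SNR information
        if stack.std(axis=0).max() > 1e-12:
            snr = snr_curve(list(ensemble))
    return CorrelationCurve(
        tau0, mean, kind=ensemble[0].kind, snr=snr, n_snapshots=len(ensemble)
    )
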