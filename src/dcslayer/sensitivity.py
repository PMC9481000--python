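"""Model-comparison and robustness sweeps.

Three analyses, each emitting a tidy table (one record per row):

* ``flow_comparison_sweep`` — how far the conventional single-layer flow
  index (alpha*D_B) and the two-layer bottom-layer flow (D_B2) deviate from
  the homogeneous-reference values as the static top layer thickens;
* ``perturbation_sweep`` — percent changes of the fitted (d1, D_B2) when a
  single optical coefficient assumed during fitting is off by a factor
  (one coefficient at a time, the others held at truth);
* ``thickness_trend`` — ordinary least-squares line (with the slope's
  two-sided t-test p-value) through fitted-vs-true top-layer thickness.

By default the sweeps run on noise-free forward curves at the preset
parameters, isolating model-induced bias from measurement noise; a noisy
mode runs the full snapshot pipeline instead.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import forward as fw
from .media import LayeredMedium, OpticalLayer
from .models import (
    estimate_beta,
    fit_single_layer_conventional,
    fit_single_layer_fourier,
    fit_two_layer,
    g2_to_g1,
)
from .simulate import (
    AcquisitionSpec,
    PhantomPreset,
    average_curve,
    default_tau_grid,
    simulate_acquisition,
)

__all__ = [
    "percent_difference",
    "flow_comparison_sweep",
    "perturbation_sweep",
    "thickness_trend",
]


def percent_difference(fitted: float, reference: float) -> float:
    """100 * (fitted - reference) / reference; reference must be nonzero."""
    if reference == 0 or not math.isfinite(reference):
        raise ValueError("reference must be finite and nonzero")
    return 100.0 * (fitted - reference) / reference


def _noise_free_g1(
    medium: LayeredMedium, rho: float, tau: np.ndarray, wavelength_nm: float
):
    return fw.g1_layered(medium, rho, tau, wavelength_nm)


def _pipeline_g1(
    medium: LayeredMedium, sd_mm: float, spec: AcquisitionSpec, wavelength_nm: float
):
    """Full measured-data emulation: simulate, average, estimate beta, invert."""
    ensemble = simulate_acquisition(
        medium, AcquisitionSpec(**{**spec.__dict__, "sd_mm": (sd_mm,)}),
        wavelength_nm,
    )[sd_mm]
    avg = average_curve(ensemble)
    beta = estimate_beta(avg)
    return g2_to_g1(avg, beta)


def _reference_flows(
    bottom: OpticalLayer,
    sd_mm: Sequence[float],
    tau: np.ndarray,
    wavelength_nm: float,
    mode: str,
    noise_spec: Optional[AcquisitionSpec],
) -> dict[float, tuple[float, float]]:
    """Per-SD (alpha_db_ref, db2_ref) from the homogeneous reference medium."""
    medium = LayeredMedium.homogeneous(bottom, mode)
    refs = {}
    for sd in sd_mm:
        rho = sd / 10.0
        if noise_spec is None:
            g1 = _noise_free_g1(medium, rho, tau, wavelength_nm)
        else:
            g1 = _pipeline_g1(medium, sd, noise_spec, wavelength_nm)
        a_ref = fit_single_layer_conventional(g1, bottom, rho).params["alpha_db"]
        db_ref = fit_single_layer_fourier(
            g1, bottom, rho, boundary_length_mode=mode
        ).params["d_b"]
        refs[sd] = (a_ref, db_ref)
    return refs


def flow_comparison_sweep(
    presets: Sequence[PhantomPreset],
    sd_mm: Sequence[float] = (10.0, 15.0, 20.0, 25.0),
    noise_spec: Optional[AcquisitionSpec] = None,
    boundary_length_mode: str = "extrapolated",
    wavelength_nm: float = 785.0,
    tau: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Percent flow deviation from the homogeneous reference, per preset/SD/model.

    The homogeneous preset (no top layer) must be present: it provides the
    per-SD reference alpha*D_B (conventional model) and D_B2 (Fourier-domain
    homogeneous model) every other row is compared against.

    Columns: preset, sd_mm, true_d1_mm, model, flow_cm2_s, pct_diff.
    """
    if tau is None:
        tau = default_tau_grid()
    p0 = [p for p in presets if p.homogeneous]
    if not p0:
        raise ValueError("the homogeneous reference preset (no top layer) is required")
    bottom = p0[0].bottom
    refs = _reference_flows(
        bottom, sd_mm, tau, wavelength_nm, boundary_length_mode, noise_spec
    )
    rows = []
    for preset in presets:
        medium = preset.medium(boundary_length_mode)
        for sd in sd_mm:
            rho = sd / 10.0
            a_ref, db_ref = refs[sd]
            if preset.homogeneous:
                rows.append((preset.label, sd, 0.0, "single_conventional", a_ref, 0.0))
                rows.append((preset.label, sd, 0.0, "two_layer", db_ref, 0.0))
                continue
            if noise_spec is None:
                g1 = _noise_free_g1(medium, rho, tau, wavelength_nm)
            else:
                g1 = _pipeline_g1(medium, sd, noise_spec, wavelength_nm)
            a_fit = fit_single_layer_conventional(g1, bottom, rho).params["alpha_db"]
            two = fit_two_layer(g1, medium, rho)
            rows.append(
                (
                    preset.label, sd, preset.top_thickness_mm,
                    "single_conventional", a_fit,
                    percent_difference(a_fit, a_ref),
                )
            )
            rows.append(
                (
                    preset.label, sd, preset.top_thickness_mm,
                    "two_layer", two.params["d_b2"],
                    percent_difference(two.params["d_b2"], db_ref),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["preset", "sd_mm", "true_d1_mm", "model", "flow_cm2_s", "pct_diff"],
    )


_COEFFICIENTS = ("mu_a", "mu_s_prime")


def _perturbed(layer: OpticalLayer, coefficient: str, factor: float) -> OpticalLayer:
    if coefficient not in _COEFFICIENTS:
        raise ValueError(f"coefficient must be one of {_COEFFICIENTS}")
    return layer.with_(**{coefficient: getattr(layer, coefficient) * factor})


def perturbation_sweep(
    presets: Sequence[PhantomPreset],
    sd_mm: Sequence[float] = (10.0, 15.0, 20.0, 25.0),
    factors: Sequence[float] = (0.8, 1.2),
    coefficients: Sequence[str] = _COEFFICIENTS,
    layers: Sequence[int] = (1, 2),
    boundary_length_mode: str = "extrapolated",
    wavelength_nm: float = 785.0,
    tau: Optional[np.ndarray] = None,
    db2_reference: Optional[float] = None,
) -> pd.DataFrame:
    """Refit noise-free curves with single perturbed optical coefficients.

    For every (two-layer preset, SD, layer, coefficient, factor) cell, the
    forward curve generated at the true parameters is refitted with that one
    coefficient scaled by ``factor`` in the assumed medium (everything else at
    truth), and the percent changes of the fitted d1 and D_B2 relative to
    their true values are recorded. ``db2_reference`` defaults to the per-SD
    homogeneous Fourier-domain fit of the no-top-layer reference, the
    standard ground-truth protocol.

    Columns: preset, sd_mm, true_d1_mm, layer, coefficient, factor,
    pct_change_d1, pct_change_db2.
    """
    if tau is None:
        tau = default_tau_grid()
    two_layer_presets = [p for p in presets if not p.homogeneous]
    if not two_layer_presets:
        raise ValueError("need at least one two-layer preset")
    bottom = two_layer_presets[0].bottom
    if db2_reference is None:
        refs = _reference_flows(
            bottom, sd_mm, tau, wavelength_nm, boundary_length_mode, None
        )
        db2_ref_by_sd = {sd: refs[sd][1] for sd in sd_mm}
    else:
        db2_ref_by_sd = {sd: db2_reference for sd in sd_mm}

    rows = []
    for preset in two_layer_presets:
        true_medium = preset.medium(boundary_length_mode)
        d1_true = preset.top_thickness_mm / 10.0
        for sd in sd_mm:
            rho = sd / 10.0
            g1 = _noise_free_g1(true_medium, rho, tau, wavelength_nm)
            for layer_idx in layers:
                for coeff in coefficients:
                    for factor in factors:
                        top, bot = preset.top, preset.bottom
                        if layer_idx == 1:
                            top = _perturbed(top, coeff, factor)
                        elif layer_idx == 2:
                            bot = _perturbed(bot, coeff, factor)
                        else:
                            raise ValueError("layer index must be 1 or 2")
                        assumed = LayeredMedium.two_layer(
                            top, bot, boundary_length_mode
                        )
                        fit = fit_two_layer(g1, assumed, rho)
                        rows.append(
                            (
                                preset.label, sd, preset.top_thickness_mm,
                                layer_idx, coeff, factor,
                                percent_difference(fit.params["d1"], d1_true),
                                percent_difference(
                                    fit.params["d_b2"], db2_ref_by_sd[sd]
                                ),
                            )
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "preset", "sd_mm", "true_d1_mm", "layer", "coefficient", "factor",
            "pct_change_d1", "pct_change_db2",
        ],
    )


def thickness_trend(
    true_d1_mm: Sequence[float],
    fitted_d1_mm: Sequence[float],
    max_true_mm: Optional[float] = None,
) -> dict[str, float]:
    """OLS line through fitted-vs-true thickness with the slope's p-value.

    ``max_true_mm`` restricts the regression to thin tops (the regime where
    the fitted thickness tracks the true one linearly).
    """
    x = np.asarray(true_d1_mm, float)
    y = np.asarray(fitted_d1_mm, float)
    if x.shape != y.shape:
        raise ValueError("true and fitted arrays must have the same length")
    if max_true_mm is not None:
        keep = x <= max_true_mm
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 (true, fitted) pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all true thicknesses equal")
    if np.ptp(y) == 0:
        # exactly constant fit values: zero slope, no evidence of a trend
        return {
            "slope": 0.0, "intercept": float(y[0]), "p_value": 1.0,
            "r_value": 0.0, "stderr": 0.0, "n": int(x.size),
        }
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "p_value": float(res.pvalue),
        "r_value": float(res.rvalue),
        "stderr": float(res.stderr),
        "n": int(x.size),
    }
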