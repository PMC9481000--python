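"""Forward-model correctness: closed forms, Green's functions, invariants."""

import math
import warnings

import numpy as np
import pytest

from dcslayer import (
    LayeredMedium,
    OpticalLayer,
    boundary_lengths,
    decay_alpha,
    effective_reflection,
    g1_layered,
    g1_layered_values,
    g1_semi_infinite_conventional,
    ghat0_homogeneous,
    ghat0_two_layer,
    siegert,
)
from dcslayer.forward import _z0_for_mode, g1_semi_infinite_conventional_values


class TestEffectiveReflection:
    def test_printed_polynomial_values(self):
        # direct evaluation of -1.44 n^-2 + 0.71 n^-1 + 0.064 n + 0.668
        assert effective_reflection(1.0) == pytest.approx(0.002, abs=1e-12)
        assert effective_reflection(1.4) == pytest.approx(0.53004898, abs=1e-6)

    def test_monotone_increasing_on_tissue_range(self):
        n = np.linspace(1.2, 1.6, 200)
        vals = np.array([effective_reflection(x) for x in n])
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals > 0) & (vals < 1))

    def test_domain_errors(self):
        for bad in (0.5, float("nan"), float("inf")):
            with pytest.raises(ValueError):
                effective_reflection(bad)


class TestBoundaryLengths:
    def test_z0_is_transport_mean_free_path(self, top_layer, bottom_layer):
        assert boundary_lengths(top_layer)[0] == pytest.approx(1 / 8.50)
        assert boundary_lengths(bottom_layer)[0] == pytest.approx(1 / 10.46)

    def test_zb_formula(self, bottom_layer):
        reff = effective_reflection(1.33)
        expected = (2 / (3 * 10.46)) * (1 + reff) / (1 - reff)
        assert boundary_lengths(bottom_layer)[1] == pytest.approx(expected)

    def test_index_matched_limit(self):
        # n = 1 gives Reff ~ 0.002, so zb ~ (2/3) z0
        layer = OpticalLayer(mu_a=0.1, mu_s_prime=10.0, n_refr=1.0)
        z0, zb = boundary_lengths(layer)
        assert zb == pytest.approx(2 * z0 / 3, rel=0.01)


class TestDecayAlpha:
    def test_static_layer_is_tau_independent(self, top_layer):
        tau = np.geomspace(1e-7, 1e-1, 20)
        alpha = decay_alpha(top_layer, tau)
        assert np.allclose(alpha, math.sqrt(3 * 0.11 * 8.50), rtol=1e-12)

    def test_scalar_oracle(self, bottom_layer):
        # independent scalar evaluation of sqrt(3/(l* l_a) + 6 tau/(tau0 l*^2))
        tau = 1e-4
        l_star, l_a = 1 / 10.46, 1 / 0.12
        k = 2 * math.pi * 1.33 / 785e-7
        tau0 = 1 / (k**2 * 2e-9)
        expected = math.sqrt(3 / (l_star * l_a) + 6 * tau / (tau0 * l_star**2))
        assert float(decay_alpha(bottom_layer, tau)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_monotone_and_floor(self, bottom_layer):
        tau = np.geomspace(1e-7, 1e-1, 50)
        alpha = decay_alpha(bottom_layer, tau)
        assert np.all(np.diff(alpha) > 0)
        assert alpha[0] > math.sqrt(3 * 0.12 * 10.46)
        assert float(decay_alpha(bottom_layer, 0.0)) == pytest.approx(
            math.sqrt(3 * 0.12 * 10.46)
        )


class TestConventionalModel:
    def test_static_medium_has_no_decay(self, bottom_layer, tau_grid):
        g = g1_semi_infinite_conventional(bottom_layer, 0.0, 2.0, tau_grid)
        assert np.allclose(g.values, 1.0, atol=1e-12)

    def test_k0_closed_form(self, bottom_layer):
        # K(0) = sqrt(3 mu_a mu_s') for the bottom-layer properties
        assert math.sqrt(3 * 0.12 * 10.46) == pytest.approx(1.9405, abs=2e-4)

    def test_alpha_db_tau_rescaling_identity(self, bottom_layer, tau_grid):
        # g1 depends on alpha_db * tau only
        a = g1_semi_infinite_conventional_values(bottom_layer, 2e-9, 2.0, tau_grid)
        b = g1_semi_infinite_conventional_values(
            bottom_layer, 4e-9, 2.0, tau_grid / 2
        )
        assert np.allclose(a, b, atol=1e-13)

    def test_normalized_and_monotone(self, bottom_layer, tau_grid):
        g = g1_semi_infinite_conventional(bottom_layer, 2e-9, 2.0, tau_grid)
        assert g.values[0] <= 1.0
        assert np.all(np.diff(g.values) <= 1e-12)
        tiny = g1_semi_infinite_conventional_values(
            bottom_layer, 2e-9, 2.0, np.array([1e-12])
        )
        assert tiny[0] == pytest.approx(1.0, abs=1e-6)

    def test_rejects_negative_flow(self, bottom_layer, tau_grid):
        with pytest.raises(ValueError):
            g1_semi_infinite_conventional(bottom_layer, -1e-9, 2.0, tau_grid)


def _two_layer_oracle(q, tau, top, bottom, mode="extrapolated", wavelength=785.0):
    """Independent depth-ODE solution: piecewise exponentials with continuity
    of G and D*G' at the interface, a source-strength jump at z', and the
    Robin condition G = z0 G' at the surface. Returns G(z=0) for s0 = 1."""
    z0 = _z0_for_mode(top, mode)
    zs = top.l_star
    d1 = top.thickness
    b1 = math.hypot(float(decay_alpha(top, tau, wavelength)), q)
    b2 = math.hypot(float(decay_alpha(bottom, tau, wavelength)), q)
    d_top, d_bot = top.photon_diffusion, bottom.photon_diffusion
    e = math.exp
    m = np.zeros((5, 5))
    rhs = np.zeros(5)
    m[0, 0], m[0, 1] = 1 - z0 * b1, 1 + z0 * b1
    m[1, 0], m[1, 1] = e(b1 * zs), e(-b1 * zs)
    m[1, 2], m[1, 3] = -e(b1 * zs), -e(-b1 * zs)
    m[2, 0], m[2, 1] = -d_top * b1 * e(b1 * zs), d_top * b1 * e(-b1 * zs)
    m[2, 2], m[2, 3] = d_top * b1 * e(b1 * zs), -d_top * b1 * e(-b1 * zs)
    rhs[2] = -1.0
    m[3, 2], m[3, 3], m[3, 4] = e(b1 * d1), e(-b1 * d1), -1.0
    m[4, 2], m[4, 3] = d_top * b1 * e(b1 * d1), -d_top * b1 * e(-b1 * d1)
    m[4, 4] = d_bot * b2
    sol = np.linalg.solve(m, rhs)
    return sol[0] + sol[1]


class TestFourierDomainGreens:
    def test_two_layer_matches_depth_ode_oracle(self, top_layer, bottom_layer):
        """The closed-form slab Green's function equals an independently
        assembled piecewise-exponential solution up to the constant D1
        (absorbed into the source constant, cancels in normalized g1)."""
        medium = LayeredMedium.two_layer(top_layer, bottom_layer)
        d1_const = top_layer.photon_diffusion
        for q in (0.5, 5.0, 30.0, 120.0):
            for tau in (0.0, 1e-5, 1e-3):
                ours = float(ghat0_two_layer(q, tau, medium))
                oracle = _two_layer_oracle(q, tau, top_layer, bottom_layer)
                assert ours == pytest.approx(d1_const * oracle, rel=1e-9)

    def test_identical_layers_collapse_to_homogeneous(self, bottom_layer):
        top = bottom_layer.with_(thickness=0.4)
        medium = LayeredMedium.two_layer(top, bottom_layer)
        q = np.geomspace(1e-3, 400, 80)
        tau = np.array([0.0, 1e-5, 1e-3])
        two = ghat0_two_layer(q, tau, medium)
        one = ghat0_homogeneous(q, tau, bottom_layer)
        assert np.allclose(two, one, rtol=1e-12)

    def test_decays_in_q_and_vanishes(self, two_layer_medium, bottom_layer):
        q = np.geomspace(0.1, 500, 60)
        two = ghat0_two_layer(q, 1e-5, two_layer_medium)
        one = ghat0_homogeneous(q, np.array(1e-5), bottom_layer)
        assert np.all(np.diff(two) < 0) and np.all(np.diff(one) < 0)
        assert two[-1] < 1e-12 * two[0]

    def test_static_top_tau_independent_in_thick_limit(self, top_layer, bottom_layer):
        thick = top_layer.with_(thickness=5.0)
        medium = LayeredMedium.two_layer(thick, bottom_layer)
        vals = ghat0_two_layer(np.array([1.0, 10.0]), np.array([0.0, 1e-3]), medium)
        assert np.allclose(vals[:, 0], vals[:, 1], rtol=1e-10)

    def test_warns_when_source_below_interface(self, top_layer, bottom_layer):
        shallow = top_layer.with_(thickness=0.05)  # z' = 1.18 mm > 0.5 mm
        medium = LayeredMedium.two_layer(shallow, bottom_layer)
        with pytest.warns(RuntimeWarning):
            ghat0_two_layer(1.0, 1e-5, medium)


class TestLayeredG1:
    SD_CM = (1.0, 1.5, 2.0, 2.5)

    def test_normalization_and_monotonicity(self, two_layer_medium, tau_grid):
        for rho in self.SD_CM:
            g = g1_layered_values(two_layer_medium, rho, tau_grid)
            early = g1_layered_values(two_layer_medium, rho, np.array([1e-10]))
            assert early[0] == pytest.approx(1.0, abs=1e-6)
            assert np.all(np.diff(g) <= 1e-10)
            assert g.min() >= 0.0

    def test_homogeneous_collapse(self, bottom_layer, homogeneous_medium):
        """Two identical layers reproduce the homogeneous solution."""
        top = bottom_layer.with_(thickness=0.4)
        stacked = LayeredMedium.two_layer(top, bottom_layer)
        tau = np.geomspace(1e-6, 3e-3, 40)
        for rho in self.SD_CM:
            two = g1_layered_values(stacked, rho, tau)
            one = g1_layered_values(homogeneous_medium, rho, tau)
            assert np.max(np.abs(two - one)) < 1e-8

    def test_static_limit_is_flat(self, top_layer, bottom_layer, tau_grid):
        static = LayeredMedium.two_layer(
            top_layer, bottom_layer.with_(d_b=0.0)
        )
        g = g1_layered_values(static, 2.0, tau_grid)
        assert np.allclose(g, 1.0, atol=1e-9)

    def test_db2_tau_scale_invariance(self, top_layer, bottom_layer, tau_grid):
        base = LayeredMedium.two_layer(top_layer, bottom_layer)
        scaled = LayeredMedium.two_layer(top_layer, bottom_layer.with_(d_b=8e-9))
        a = g1_layered_values(base, 2.0, tau_grid)
        b = g1_layered_values(scaled, 2.0, tau_grid / 4)
        assert np.max(np.abs(a - b)) < 1e-8

    def test_thick_static_top_blinds_short_sd(self, top_layer, bottom_layer):
        deep = LayeredMedium.two_layer(top_layer.with_(thickness=2.0), bottom_layer)
        tau = np.geomspace(1e-6, 3e-3, 30)
        g = g1_layered_values(deep, 1.0, tau)
        assert np.all(g > 0.995)

    def test_close_to_conventional_model(self, homogeneous_medium, bottom_layer):
        tau = np.geomspace(1e-6, 3e-3, 40)
        fourier = g1_layered_values(homogeneous_medium, 2.0, tau)
        conv = g1_semi_infinite_conventional_values(bottom_layer, 2e-9, 2.0, tau)
        assert np.max(np.abs(fourier - conv)) < 0.01


class TestSiegert:
    def test_values_and_round_trip(self, tau_grid):
        from dcslayer.media import CorrelationCurve
        from dcslayer.models import g2_to_g1

        values = np.linspace(1, 0, tau_grid.size)
        values[1] = 0.8
        values = np.sort(values)[::-1]
        g1 = CorrelationCurve(tau_grid, values, kind="g1")
        g2 = siegert(g1, 0.5)
        assert g2.values[0] == pytest.approx(1.5)
        idx = int(np.argmin(np.abs(g1.values - 0.8)))
        assert g2.values[idx] == pytest.approx(1.32, abs=1e-12)  # 1 + 0.5*0.64
        back = g2_to_g1(g2, 0.5)
        assert np.allclose(back.values, g1.values, atol=1e-12)

    def test_beta_domain(self, tau_grid):
        from dcslayer.media import CorrelationCurve

        g1 = CorrelationCurve(tau_grid, np.ones(tau_grid.size), kind="g1")
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                siegert(g1, bad)
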