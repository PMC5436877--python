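import numpy as np
import pytest

from lamellosc.models import (build_system, conserved_toggle_system,
                              ecm_competition_system, gtpase_toggle_system,
                              mirror_state, reduced_system,
                              rho_activation_input, rhs, state_labels)
from lamellosc.params import ModelTag, ModelVariant, ParameterSet

from conftest import random_params, random_state

ALL_VARIANTS = [ModelVariant(t) for t in ModelTag] + \
               [ModelVariant(ModelTag.M3, ecm_to_rac=True)]


M2 = ModelVariant(ModelTag.M2)
P_M2 = ParameterSet(n=3, delta=1.0, b_R=2.0, k_E=1.2, gamma_E=3.0, E0=0.25,
                    k_R=0.05, gamma_R=0.5, R0=1.0, k_rho=0.05,
                    gamma_rho=0.5, rho0=1.0, eps=0.05, l_c=0.1)


class TestRhoActivationInput:
    def test_hill_identities(self):
        # vanishes at zero, half-saturates at E0, saturates at large E
        assert rho_activation_input(P_M2, M2, 0.0) == pytest.approx(P_M2.k_E)
        assert rho_activation_input(P_M2, M2, P_M2.E0) == pytest.approx(
            P_M2.k_E + P_M2.gamma_E / 2)
        assert rho_activation_input(P_M2, M2, 1e9) == pytest.approx(
            P_M2.k_E + P_M2.gamma_E, rel=1e-6)

    def test_linear_form_for_m1(self):
        p = ParameterSet(n=1, k_E=0.1, gamma_E=2.0)
        v = ModelVariant(ModelTag.M1A)
        assert rho_activation_input(p, v, 1.5) == pytest.approx(0.1 + 3.0)

    def test_monotone_and_bounded(self):
        E = np.linspace(0, 50, 500)
        b = rho_activation_input(P_M2, M2, E)
        assert np.all(np.diff(b) >= 0)
        assert b.max() <= P_M2.k_E + P_M2.gamma_E + 1e-12

    def test_negative_ecm_rejected(self):
        with pytest.raises(ValueError):
            rho_activation_input(P_M2, M2, -0.1)


class TestRhs:
    def test_origin_rates_m2(self):
        # all Hill terms vanish at the origin
        d = rhs(P_M2, M2, np.zeros(6))
        np.testing.assert_allclose(
            d, [P_M2.b_R, P_M2.k_E, P_M2.eps * P_M2.k_R] * 2)

    @pytest.mark.parametrize("variant", ALL_VARIANTS, ids=lambda v: str(v.tag.value) + ("+ER" if v.ecm_to_rac else ""))
    def test_exchange_symmetry(self, variant):
        """Relabeling lamellipods commutes with the right-hand side."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            p = random_params(rng, variant)
            if variant.ecm_to_rac:
                p = p.with_(gamma_ER=float(rng.uniform(0, 1)))
            y = random_state(rng, variant, p)
            labels = state_labels(variant)
            d = rhs(p, variant, y)
            d_mirror = rhs(p, variant, mirror_state(y, labels))
            np.testing.assert_allclose(mirror_state(d, labels), d_mirror,
                                       rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("tag", [ModelTag.M1B, ModelTag.M1C, ModelTag.M3])
    def test_explicit_pools_conserve_totals(self, tag):
        """The GTPase totals are first integrals of the explicit-pool form."""
        variant = ModelVariant(tag)
        rng = np.random.default_rng(7)
        labels = state_labels(variant)
        iR = [labels.index(k) for k in ("R1", "R2", "RI")]
        irho = [labels.index(k) for k in ("rho1", "rho2", "rhoI")]
        for _ in range(20):
            p = random_params(rng, variant)
            y = random_state(rng, variant, p)
            d = rhs(p, variant, y)
            assert abs(d[iR].sum()) < 1e-12
            assert abs(d[irho].sum()) < 1e-12

    @pytest.mark.parametrize("variant", ALL_VARIANTS, ids=lambda v: str(v.tag.value) + ("+ER" if v.ecm_to_rac else ""))
    def test_positive_orthant_invariance(self, variant):
        """Derivatives are non-negative on the boundary faces."""
        rng = np.random.default_rng(3)
        labels = state_labels(variant)
        for _ in range(20):
            p = random_params(rng, variant)
            if variant.ecm_to_rac:
                p = p.with_(gamma_ER=float(rng.uniform(0, 1)))
            y = random_state(rng, variant, p)
            for i in range(len(labels)):
                z = y.copy()
                z[i] = 0.0
                d = rhs(p, variant, z)
                assert d[i] >= -1e-13, f"{labels[i]} leaves the orthant"

    def test_qssa_effectors_reduce_to_m1b(self):
        """With w = R and c = rho, the M1C equations restrict to M1B."""
        rng = np.random.default_rng(11)
        v1b, v1c = ModelVariant(ModelTag.M1B), ModelVariant(ModelTag.M1C)
        for _ in range(10):
            p = random_params(rng, v1c)
            y_b = random_state(rng, v1b, p)
            y_c = np.concatenate([y_b, [y_b[0], y_b[1], y_b[3], y_b[4]]])
            d_c = rhs(p, v1c, y_c)
            d_b = rhs(p.with_(eps2=None), v1b, y_b)
            np.testing.assert_allclose(d_c[:8], d_b, rtol=1e-12, atol=1e-12)
            # effector derivatives vanish on the quasi-steady manifold
            np.testing.assert_allclose(d_c[8:], 0.0, atol=1e-12)

    def test_variant_parameter_mismatch_is_configuration_error(self):
        with pytest.raises(ValueError):
            rhs(P_M2, ModelVariant(ModelTag.M3), np.zeros(8), check=True)

    def test_negative_state_rejected_when_checked(self):
        with pytest.raises(ValueError):
            rhs(P_M2, M2, np.full(6, -0.1), check=True)


class TestSubmodels:
    def test_ecm_competition_exclusion_states(self):
        sys = ecm_competition_system(1.0, 1.0, 0.5, 0.5, 1.0, eps=1.0)
        # exclusion equilibria at E_k* = eps*A/L
        np.testing.assert_allclose(sys.f(np.array([2.0, 0.0])), 0.0, atol=1e-14)
        np.testing.assert_allclose(sys.f(np.array([0.0, 2.0])), 0.0, atol=1e-14)

    def test_analytic_jacobians_match_finite_differences(self):
        from lamellosc.equilibria import fd_jacobian
        rng = np.random.default_rng(0)
        for sys in (ecm_competition_system(1.2, 0.8, 0.5, 0.7, 0.9, 1.1),
                    gtpase_toggle_system(2.0, 3.0, 3, 1.0)):
            y = rng.uniform(0.1, 2.0, size=sys.dim)
            np.testing.assert_allclose(sys.jac(y), fd_jacobian(sys.f, y),
                                       rtol=1e-5, atol=1e-7)

    def test_conserved_toggle_matches_reduced_m3_without_ecm(self):
        """Freezing b_rho reproduces the M3 GTPase block."""
        p = ParameterSet(n=3, delta=1.0, b_R=6.0, k_E=2.0, gamma_E=0.0,
                         E0=0.15, k_R=0.05, gamma_R=0.0, R0=1.0, k_rho=0.05,
                         gamma_rho=0.0, rho0=1.0, eps=0.02, l_c=0.0,
                         R_T=2.0, rho_T=2.0)
        v = ModelVariant(ModelTag.M3)
        full = reduced_system(p, v)
        frozen = conserved_toggle_system(6.0, 2.0, 2.0, 3, 1.0, 2.0, 2.0)
        y6 = np.array([0.5, 0.4, 0.3, 0.6, 0.2, 0.1])
        d6 = full.f(y6)
        d4 = frozen.f(y6[[0, 1, 3, 4]])
        np.testing.assert_allclose(d6[[0, 1, 3, 4]], d4, rtol=1e-12)
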