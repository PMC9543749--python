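"""Closed-form invasion formulae: frozen examples, independent oracles,
limits and structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from invasibility import (
    InvasionQuery,
    NSpaceParams,
    WKBIntermediates,
    ZSpaceParams,
    extinction_threshold,
    natural_target_abundance,
    pi_diffusion,
    pi_fixed_env,
    pi_quenched,
    pi_wkb,
    q_interpolated,
    wkb_outer,
)

# Strategies for valid, well-conditioned parameters.
growths = st.floats(-0.3, 0.3)
variances = st.floats(1e-4, 2.0)
abundances = st.floats(0.0, 1.0)  # as a fraction of nf


def _da_oracle(n, nf, eps, vd, ve):
    """Quadrature solution of the backward diffusion boundary-value problem.

    With E[Δn]=ℰn and Var[Δn]=Vd n+Ve n², Π''/Π' = −2ℰ/(Vd+Ve n), so
    Π(n) ∝ ∫₀ⁿ (Vd+Ve m)^{−2ℰ/Ve} dm; independent of the closed-form
    algebra being checked.
    """
    integrand = lambda m: (vd + ve * m) ** (-2.0 * eps / ve)
    num, _ = quad(integrand, 0.0, n)
    den, _ = quad(integrand, 0.0, nf)
    return num / den


class TestDiffusion:
    def test_neutral_is_exact_ratio(self):
        q = InvasionQuery(10, 200)
        assert pi_diffusion(q, NSpaceParams(0.0, 1.0, 0.3)) == pytest.approx(
            0.05, abs=1e-15
        )

    def test_boundary_at_target(self):
        q = InvasionQuery(200, 200)
        assert pi_diffusion(q, NSpaceParams(0.5, 2.0, 0.7)) == 1.0

    def test_matches_quadrature_oracle(self):
        q = InvasionQuery(1, 200)
        p = NSpaceParams(0.02, 1.0, 0.1)
        expected = _da_oracle(1, 200, 0.02, 1.0, 0.1)
        assert expected == pytest.approx(0.01129, abs=5e-6)  # frozen
        assert pi_diffusion(q, p) == pytest.approx(expected, rel=1e-9)

    def test_weak_environment_reduces_to_fixed(self):
        q = InvasionQuery(1, 200)
        got = pi_diffusion(q, NSpaceParams(0.05, 1.0, 1e-10))
        assert got == pytest.approx(pi_fixed_env(q, 0.05, 1.0), rel=1e-6)
        assert got == pytest.approx(0.09516, abs=5e-6)

    def test_rejects_no_demographic_noise_below_one_individual(self):
        with pytest.raises(ValueError):
            pi_diffusion(InvasionQuery(0.5, 200), NSpaceParams(0.1, 0.0, 0.5))

    def test_no_demographic_noise_limits(self):
        # Vd -> 0 continuum: negative drift gives (n/nf)^Q, positive gives 1.
        q = InvasionQuery(10, 1000)
        decl = pi_diffusion(q, NSpaceParams(-0.05, 0.0, 0.2))
        assert decl == pytest.approx((10 / 1000) ** (1 + 2 * 0.05 / 0.2), rel=1e-9)
        assert pi_diffusion(q, NSpaceParams(0.2, 0.0, 0.2)) == 1.0
        # continuity against a tiny but nonzero Vd
        near = pi_diffusion(q, NSpaceParams(-0.05, 1e-9, 0.2))
        assert near == pytest.approx(decl, rel=1e-3)

    @given(frac=abundances, eps=growths, vd=variances, ve=variances)
    def test_bounds_and_boundaries(self, frac, eps, vd, ve):
        nf = 200.0
        p = NSpaceParams(eps, vd, ve)
        assert pi_diffusion(InvasionQuery(0, nf), p) == 0.0
        assert pi_diffusion(InvasionQuery(nf, nf), p) == 1.0
        val = pi_diffusion(InvasionQuery(frac * nf, nf), p)
        assert 0.0 <= val <= 1.0

    @given(vd=variances, ve=variances, frac=st.floats(0.01, 0.99))
    def test_neutral_collapses_to_ratio(self, vd, ve, frac):
        nf = 321.0
        got = pi_diffusion(InvasionQuery(frac * nf, nf), NSpaceParams(0.0, vd, ve))
        assert got == pytest.approx(frac, abs=1e-12)

    @given(eps=growths, vd=variances, ve=variances)
    def test_monotone_in_initial_and_target(self, eps, vd, ve):
        p = NSpaceParams(eps, vd, ve)
        ns = [1.0, 5.0, 25.0, 100.0]
        vals = [pi_diffusion(InvasionQuery(n, 200.0), p) for n in ns]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
        nfs = [200.0, 400.0, 800.0]
        tvals = [pi_diffusion(InvasionQuery(10.0, nf), p) for nf in nfs]
        assert all(a >= b - 1e-12 for a, b in zip(tvals, tvals[1:]))

    @given(vd=variances, ve=variances)
    def test_monotone_in_growth(self, vd, ve):
        grid = np.linspace(-0.2, 0.2, 9)
        vals = [
            pi_diffusion(InvasionQuery(10.0, 200.0), NSpaceParams(e, vd, ve))
            for e in grid
        ]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


class TestWKBOuter:
    def test_symmetric_jumps(self):
        w = wkb_outer(ZSpaceParams(0.0, 1.0, 0.04))
        assert (w.beta, w.alpha, w.q_bar) == (0.2, 0.5, 0.0)
        assert w.R == pytest.approx(0.04)

    def test_example_against_root_solver(self):
        w = wkb_outer(ZSpaceParams(0.1, 1.0, 0.09))
        assert w.beta == pytest.approx(0.31623, abs=1e-5)
        assert w.alpha == pytest.approx(0.65811, abs=1e-5)
        assert w.q_bar == pytest.approx(-2.0710, abs=1e-4)
        assert w.R == pytest.approx(0.09657, abs=1e-5)
        # independent oracle: q must solve 1 = 2α sinh(qβ) + e^{−qβ}
        f = lambda qv: 2 * w.alpha * math.sinh(qv * w.beta) + math.exp(-qv * w.beta) - 1
        root = brentq(f, -50.0, -1e-9, xtol=1e-14)
        assert w.q_bar == pytest.approx(root, abs=1e-10)
        assert abs(f(w.q_bar)) < 1e-12

    def test_antisymmetry_under_sign_flip(self):
        plus = wkb_outer(ZSpaceParams(0.1, 1.0, 0.09))
        minus = wkb_outer(ZSpaceParams(-0.1, 1.0, 0.09))
        assert minus.q_bar == pytest.approx(-plus.q_bar, rel=1e-12)
        assert minus.beta == plus.beta
        assert minus.alpha == pytest.approx(1.0 - plus.alpha, rel=1e-12)

    @given(e0=st.floats(-0.5, 0.5), ve=variances)
    def test_moment_preservation_and_consistency(self, e0, ve):
        w = wkb_outer(ZSpaceParams(e0, 1.0, ve))
        # two-destination construction preserves the first two moments
        assert 2 * (w.alpha - 0.5) * w.beta == pytest.approx(e0, abs=1e-12)
        assert w.beta**2 == pytest.approx(ve + e0 * e0, rel=1e-12)
        assert 0.0 <= w.alpha <= 1.0
        # self-consistency residual of the WKB characteristic equation
        resid = 2 * w.alpha * math.sinh(w.q_bar * w.beta) + math.exp(
            -w.q_bar * w.beta
        ) - 1.0
        assert abs(resid) < 1e-12
        if e0 != 0.0:
            assert math.copysign(1, w.q_bar) == -math.copysign(1, e0)
            assert w.R >= 0.0

    def test_degenerate_environment_flag(self):
        w = wkb_outer(ZSpaceParams(0.05, 1.0, 0.0))
        assert w.degenerate and w.alpha == 1.0 and w.q_bar == -math.inf

    def test_rejects_zero_demographic_coefficient(self):
        with pytest.raises(ValueError):
            wkb_outer(ZSpaceParams(0.1, 0.0, 0.09))


class TestWKBFormula:
    def test_boundaries(self):
        p = ZSpaceParams(0.07, 1.0, 0.2)
        assert pi_wkb(InvasionQuery(0, 200), p) == 0.0
        assert pi_wkb(InvasionQuery(200, 200), p) == 1.0

    def test_neutral_log_limit_two_sided(self):
        q = InvasionQuery(1, 200)
        got = pi_wkb(q, ZSpaceParams(0.0, 1.0, 1.0))
        expected = math.log(2) / math.log(201)
        assert got == pytest.approx(expected, rel=1e-12)
        # two-sided convergence of the general expression to the limit
        hi = pi_wkb(q, ZSpaceParams(1e-8, 1.0, 1.0))
        lo = pi_wkb(q, ZSpaceParams(-1e-8, 1.0, 1.0))
        assert lo < got < hi
        assert hi == pytest.approx(expected, rel=1e-6)
        assert lo == pytest.approx(expected, rel=1e-6)

    def test_example_against_interpolation_quadrature(self):
        # Independent route: Π_II(n) = exp ∫ q_inter(m)/m dm, combined with
        # the constant solution to meet the boundary conditions.
        p = ZSpaceParams(0.1, 1.0, 0.09)
        w = wkb_outer(p)
        integrand = lambda m: q_interpolated(m, p.E0, p.Vd_z, w.q_bar) / m
        def pi_ii(x):
            val, _ = quad(integrand, 0.0, x, limit=200)
            return math.exp(val)
        expected = (pi_ii(1) - 1.0) / (pi_ii(200) - 1.0)
        got = pi_wkb(InvasionQuery(1, 200), p)
        assert got == pytest.approx(expected, rel=1e-7)
        assert got == pytest.approx(0.17416, abs=2e-5)  # frozen

    def test_certain_establishment_at_large_scaled_abundance(self):
        p = ZSpaceParams(0.1, 1.0, 0.09)
        w = wkb_outer(p)
        assert w.q_bar < 0
        n = 1e4 / w.R
        assert pi_wkb(InvasionQuery(n, 2 * n), p) == pytest.approx(1.0, abs=1e-3)

    def test_weak_environment_reduces_to_fixed(self):
        q = InvasionQuery(1, 200)
        got = pi_wkb(q, ZSpaceParams(0.05, 1.0, 1e-10))
        assert got == pytest.approx(pi_fixed_env(q, 0.05, 1.0), rel=1e-6)

    @given(frac=abundances, e0=growths, vd=variances, ve=variances)
    def test_bounds_and_boundaries(self, frac, e0, vd, ve):
        nf = 200.0
        p = ZSpaceParams(e0, vd, ve)
        assert pi_wkb(InvasionQuery(0, nf), p) == 0.0
        assert pi_wkb(InvasionQuery(nf, nf), p) == 1.0
        assert 0.0 <= pi_wkb(InvasionQuery(frac * nf, nf), p) <= 1.0

    @given(e0=growths, vd=variances, ve=variances)
    def test_monotone_in_initial_abundance(self, e0, vd, ve):
        p = ZSpaceParams(e0, vd, ve)
        ns = [1.0, 5.0, 25.0, 100.0, 200.0]
        vals = [pi_wkb(InvasionQuery(n, 200.0), p) for n in ns]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    @given(e0=st.floats(-0.25, 0.25), vd=variances)
    def test_monotone_in_mean_growth(self, e0, vd):
        lo = pi_wkb(InvasionQuery(10, 200), ZSpaceParams(e0 - 0.01, vd, 0.05))
        hi = pi_wkb(InvasionQuery(10, 200), ZSpaceParams(e0 + 0.01, vd, 0.05))
        assert lo <= hi + 1e-12

    def test_interpolated_exponent_limits(self):
        e0, vd = 0.08, 1.3
        q_bar = wkb_outer(ZSpaceParams(e0, vd, 0.2)).q_bar
        n_small = 1e-6 * vd / abs(e0)
        n_large = 1e6 * vd / abs(e0)
        assert q_interpolated(n_small, e0, vd, q_bar) == pytest.approx(
            -2 * e0 * n_small / vd, rel=1e-5
        )
        assert q_interpolated(n_large, e0, vd, q_bar) == pytest.approx(
            q_bar, rel=1e-5
        )

    def test_agrees_with_diffusion_when_weak(self):
        # Weak selection and weak noise: the two approximations coincide,
        # provided the parameters describe the same process. The n-space
        # mean carries the Ito correction relative to the log-space mean:
        # ℰ = E[e^{Δz}] − 1 ≈ E0 + (Ve + E0²)/2.
        for e0 in (-0.01, -0.003, 0.003, 0.01):
            for ve in (0.001, 0.01):
                eps = e0 + (ve + e0 * e0) / 2.0
                da = pi_diffusion(InvasionQuery(5, 200), NSpaceParams(eps, 1.0, ve))
                wkb = pi_wkb(InvasionQuery(5, 200), ZSpaceParams(e0, 1.0, ve))
                assert wkb == pytest.approx(da, rel=0.02)


class TestFixedEnvAndQuenched:
    def test_neutral_ratio(self):
        assert pi_fixed_env(InvasionQuery(5, 50), 0.0, 1.0) == pytest.approx(0.1)

    def test_hand_checkable_value(self):
        got = pi_fixed_env(InvasionQuery(1, 200), 0.05, 1.0)
        expected = math.expm1(-0.1) / math.expm1(-20.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.09516, abs=5e-6)

    def test_boundary(self):
        assert pi_fixed_env(InvasionQuery(7, 7), -0.3, 0.5) == 1.0

    def test_deleterious_large_target_underflow_safe(self):
        val = pi_fixed_env(InvasionQuery(1, 1e6), -0.05, 1.0)
        assert 0.0 <= val <= 1.0

    def test_quenched_degenerate_equals_fixed(self):
        q = InvasionQuery(3, 90)
        assert pi_quenched(q, [(0.05, 1.0)], 1.0) == pi_fixed_env(q, 0.05, 1.0)

    def test_quenched_two_state_average(self):
        q = InvasionQuery(1, 200)
        expected = 0.5 * (
            pi_fixed_env(q, 0.05, 1.0) + pi_fixed_env(q, -0.05, 1.0)
        )
        got = pi_quenched(q, [(0.05, 0.5), (-0.05, 0.5)], 1.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_quenched_neutral_limit(self):
        q = InvasionQuery(2, 40)
        got = pi_quenched(q, [(1e-9, 0.5), (-1e-9, 0.5)], 1.0)
        assert got == pytest.approx(2 / 40, rel=1e-6)

    def test_quenched_validation(self):
        q = InvasionQuery(1, 10)
        with pytest.raises(ValueError):
            pi_quenched(q, [], 1.0)
        with pytest.raises(ValueError):
            pi_quenched(q, [(0.1, 0.7)], 1.0)


class TestThresholdAndTarget:
    @pytest.mark.parametrize(
        "vd,ve,expected", [(1.0, 1.0, 1.0), (1.0, 0.04, 25.0), (0.0, 0.1, 0.0)]
    )
    def test_extinction_threshold(self, vd, ve, expected):
        assert extinction_threshold(NSpaceParams(0.0, vd, ve)) == pytest.approx(
            expected
        )

    def test_threshold_requires_environmental_noise(self):
        with pytest.raises(ValueError):
            extinction_threshold(NSpaceParams(0.0, 1.0, 0.0))

    def test_natural_target_values(self):
        w = WKBIntermediates(beta=1.0, alpha=0.7, q_bar=-1.0, R=1.0)
        assert natural_target_abundance(w) == pytest.approx(math.e, rel=1e-12)
        w2 = wkb_outer(ZSpaceParams(0.1, 1.0, 0.09))
        # e^{1/2.070977}/0.0965728, from the outer-regime example values
        assert natural_target_abundance(w2) == pytest.approx(16.782, abs=0.01)

    def test_natural_target_strong_selection_limit(self):
        w = WKBIntermediates(beta=1.0, alpha=0.99, q_bar=-1e6, R=0.5)
        assert natural_target_abundance(w) == pytest.approx(1 / 0.5, rel=1e-5)

    def test_natural_target_requires_positive_growth(self):
        with pytest.raises(ValueError):
            natural_target_abundance(
                WKBIntermediates(beta=1.0, alpha=0.3, q_bar=0.8, R=1.0)
            )


class TestQueryValidation:
    def test_rejects_target_below_initial(self):
        with pytest.raises(ValueError):
            InvasionQuery(300, 200)

    def test_rejects_negative_initial(self):
        with pytest.raises(ValueError):
            InvasionQuery(-1, 200)
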