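"""Diffusion and branching fixation probabilities and the contour analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introfix.core import HFEParams, SelectionModel, alpha, fitness_at
from introfix.fixation import (
    HFE_HORIZON,
    branching_fixation_prob,
    branching_survival_by_t,
    diffusion_fixation_prob,
    iso_probability_contour,
)


def kimura_semidominant(s, ne, x):
    """Independent textbook diffusion fixation probability (no HFEs)."""
    if s == 0:
        return x
    return math.expm1(-4 * ne * s * x) / math.expm1(-4 * ne * s)


class TestDiffusion:
    @pytest.mark.parametrize("s", [0.001, 0.01, -0.0005, 0.1])
    def test_reduces_to_kimura_without_hfes(self, s):
        sel = SelectionModel(s=s, Ne=5_000)
        est = diffusion_fixation_prob(HFEParams(0, 0), sel)
        assert est.probability == pytest.approx(
            kimura_semidominant(s, sel.Ne, sel.q0), rel=1e-12
        )
        assert est.method == "diffusion" and est.std_error == 0.0

    def test_neutral_single_copy_fixes_with_alpha_over_2ne(self):
        hfe = HFEParams(0.6, -0.3)
        sel = SelectionModel(s=0.0, Ne=2_000)
        est = diffusion_fixation_prob(hfe, sel)
        assert est.probability == pytest.approx(alpha(hfe) / (2 * sel.Ne))

    def test_lethal_hybrids_never_fix(self):
        est = diffusion_fixation_prob(HFEParams(0, -1.0), SelectionModel(s=0.1))
        assert est.probability == 0.0

    def test_strongly_deleterious_is_finite_and_tiny(self):
        # exponents overflow naive expm1 evaluation; the log-space fallback
        # must return a probability in [0, 1] far below the neutral one
        est = diffusion_fixation_prob(HFEParams(0, 0), SelectionModel(s=-0.05))
        assert 0.0 <= est.probability < 1.0 / (2 * 10_000)


class TestBranching:
    def test_matches_homogeneous_fixed_point(self):
        # independent oracle: iterate u = 1 - exp(-lam*u) to convergence
        s = 0.02
        lam, u = 1 + s, 1.0
        for _ in range(100_000):
            u_new = -math.expm1(-lam * u)
            if abs(u_new - u) < 1e-15:
                break
            u = u_new
        est = branching_fixation_prob(HFEParams(0, 0), SelectionModel(s=s))
        assert est.probability == pytest.approx(u, abs=1e-12)
        # Haldane: ~2s with an O(s^2) correction (exact value 0.0389577...)
        assert abs(est.probability - 2 * s) < 3 * s**2

    def test_lethal_dmi_goes_extinct_in_one_generation(self):
        hfe, sel = HFEParams(0, -1.0), SelectionModel(s=0.1)
        assert branching_survival_by_t(hfe, sel, 1) == 0.0
        assert branching_fixation_prob(hfe, sel).probability == 0.0

    def test_critical_process_survival_decreases_to_zero(self):
        hfe, sel = HFEParams(0, 0), SelectionModel(s=0.0)
        u = [branching_survival_by_t(hfe, sel, t) for t in (1, 2, 5, 20, 200)]
        assert all(a > b for a, b in zip(u, u[1:]))
        assert u[-1] < 0.02

    def test_non_beneficial_flagged_outside_regime(self):
        for s in (0.0, -0.01):
            est = branching_fixation_prob(HFEParams(0.5, 0), SelectionModel(s=s))
            assert est.probability == 0.0
            assert not est.in_regime and est.note

    @settings(max_examples=40, derandomize=True)
    @given(
        eta1=st.floats(0.0, 1.0),
        delta1=st.floats(-0.9, 0.0),
        s=st.floats(0.001, 0.2),
        t=st.integers(1, 120),
    )
    def test_survival_in_unit_interval_and_extinction_monotone(
        self, eta1, delta1, s, t
    ):
        hfe, sel = HFEParams(eta1, delta1), SelectionModel(s=s)
        u_t = branching_survival_by_t(hfe, sel, t)
        u_next = branching_survival_by_t(hfe, sel, t + 1)
        assert 0.0 <= u_t <= 1.0
        assert u_next <= u_t + 1e-12  # extinction prob non-decreasing in t

    def test_infinite_horizon_bounds_finite_horizons(self):
        hfe, sel = HFEParams(0.8, -0.4), SelectionModel(s=0.01)
        u_inf = branching_fixation_prob(hfe, sel).probability
        assert u_inf <= branching_survival_by_t(hfe, sel, 500) + 1e-9
        assert u_inf == pytest.approx(
            branching_survival_by_t(hfe, sel, 5_000), abs=1e-6
        )

    def test_weak_selection_scaling_by_alpha(self):
        # for weak s the fixation probability is ~ 2*alpha*s
        s = 1e-3
        base = branching_fixation_prob(HFEParams(0, 0), SelectionModel(s=s))
        for eta1, delta1 in [(0.3, 0.0), (0.0, -0.3), (0.8, -0.5), (0.5, -0.45)]:
            hfe = HFEParams(eta1, delta1)
            ratio = (
                branching_fixation_prob(hfe, SelectionModel(s=s)).probability
                / base.probability
            )
            assert ratio == pytest.approx(alpha(hfe), rel=0.05)

    def test_equal_initial_strengths_reduce_fixation(self):
        # heterosis decays faster, so eta1 = |delta1| leaves net breakdown
        s = 0.01
        u = branching_fixation_prob(HFEParams(0.8, -0.8), SelectionModel(s=s))
        assert u.probability < 2 * s

    @pytest.mark.parametrize(
        "worse, better",
        [
            ((0.2, -0.3, 0.01), (0.4, -0.3, 0.01)),  # more heterosis
            ((0.4, -0.5, 0.01), (0.4, -0.3, 0.01)),  # weaker DMIs
            ((0.4, -0.3, 0.01), (0.4, -0.3, 0.02)),  # stronger selection
        ],
    )
    def test_monotonicity(self, worse, better):
        def u(args):
            eta1, delta1, s = args
            return branching_fixation_prob(
                HFEParams(eta1, delta1), SelectionModel(s=s)
            ).probability

        assert u(worse) < u(better)

    @pytest.mark.parametrize(
        "eta1, delta1, s",
        [
            (0.0, 0.0, 0.02),
            (0.8, 0.0, 0.01),
            (0.0, -0.8, 0.05),
            (0.8, -0.8, 0.02),
            (0.5, -0.45, 0.05),
        ],
    )
    def test_against_monte_carlo_galton_watson(self, eta1, delta1, s):
        """Direct Poisson-offspring simulation reproduces the recursion."""
        hfe, sel = HFEParams(eta1, delta1), SelectionModel(s=s)
        horizon, reps, cap = 30, 100_000, 2_000
        lam = [fitness_at(hfe, sel, t).w_AB if t <= HFE_HORIZON else 1 + s
               for t in range(1, horizon + 1)]
        rng = np.random.default_rng(12345)
        n = np.ones(reps, dtype=np.int64)
        for lam_t in lam:
            alive = n > 0
            n[alive] = rng.poisson(lam_t * np.minimum(n[alive], cap))
        p_mc = np.mean(n > 0)
        se = math.sqrt(p_mc * (1 - p_mc) / reps)
        u = branching_survival_by_t(hfe, sel, horizon)
        assert abs(p_mc - u) <= 3 * se + 1e-9


class TestDiffusionBranchingAgreement:
    def test_moderate_hfes_agree_within_ten_percent(self):
        # alpha in [0.5, 2], s in [0.001, 0.05]
        cases = [(0.0, 0.0), (0.3, 0.0), (0.0, -0.2), (0.3, -0.3), (0.1, -0.15)]
        for eta1, delta1 in cases:
            a = alpha(HFEParams(eta1, delta1))
            assert 0.5 <= a <= 2.0
            for s in (0.001, 0.01, 0.05):
                sel = SelectionModel(s=s, Ne=10_000)
                d = diffusion_fixation_prob(HFEParams(eta1, delta1), sel)
                b = branching_fixation_prob(HFEParams(eta1, delta1), sel)
                assert d.probability == pytest.approx(b.probability, rel=0.10)


class TestContour:
    def test_requires_positive_selection(self):
        with pytest.raises(ValueError):
            iso_probability_contour(0.0)
        with pytest.raises(ValueError):
            iso_probability_contour(0.01, eta_grid=np.array([]))

    def test_origin_is_on_the_contour(self):
        res = iso_probability_contour(0.01, eta_grid=np.linspace(0, 0.5, 6))
        eta0 = res.points[res.points[:, 0] == 0.0]
        assert eta0.shape == (1, 2) and eta0[0, 1] == 0.0

    def test_weak_effect_slope_approaches_four_thirds(self):
        res = iso_probability_contour(0.01, eta_grid=np.linspace(0, 0.02, 21))
        assert res.slope == pytest.approx(4 / 3, abs=0.02)
        assert res.r_squared > 0.999

    def test_contour_points_cancel_the_hfes(self):
        res = iso_probability_contour(0.01, eta_grid=np.linspace(0, 1, 6))
        sel = SelectionModel(s=0.01)
        target = branching_fixation_prob(HFEParams(0, 0), sel).probability
        for eta1, d in res.points:
            u = branching_fixation_prob(HFEParams(eta1, -d), sel).probability
            assert abs(u - target) <= 1e-9
        assert res.slope > 0 and res.omitted == ()
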