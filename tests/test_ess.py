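"""Evolutionarily stable inactivation ratios and mean-fitness accounting."""

import numpy as np
import pytest

from xinact import (
    SelectionScheme,
    UnsupportedRegimeError,
    ess_convergence_walk,
    ess_msb,
    ess_numeric,
    ess_sa,
    mean_fitness_change_msb,
    mean_fitness_change_sa,
    mutation_bias_condition,
    sa_region_classification,
    selection_gradient,
)


def del_scheme(s_f=0.2, s_m=0.2, h=0.25, u_f=1e-5, u_m=1e-5):
    return SelectionScheme(
        mode="deleterious", s_f=s_f, s_m=s_m, h=h, u_f=u_f, u_m=u_m
    )


def sa(s_f=0.2, t_m=0.2, h=0.25):
    return SelectionScheme(mode="sexually_antagonistic", s_f=s_f, t_m=t_m, h=h)


class TestClosedForms:
    def test_sa_ess_value_and_paternal_bias(self):
        # e = -ln2/ln(2h) = 1 for h = 1/4
        res = ess_sa(sa(t_m=0.2, h=0.25))
        assert res.xi_star == pytest.approx(1.0 / 1.8, abs=1e-14)
        assert res.bias_direction == "paternal"

    @pytest.mark.parametrize("t_m", [0.05, 0.3, 0.7])
    @pytest.mark.parametrize("h", [0.1, 0.25, 0.45])
    def test_sa_ess_always_exceeds_half(self, t_m, h):
        assert ess_sa(sa(s_f=0.3, t_m=t_m, h=h)).xi_star > 0.5

    def test_sa_ess_increases_with_tm_and_h(self):
        assert ess_sa(sa(t_m=0.4)).xi_star > ess_sa(sa(t_m=0.1)).xi_star
        assert ess_sa(sa(h=0.4)).xi_star > ess_sa(sa(h=0.1)).xi_star

    def test_msb_bias_sign_rule(self):
        # maternal silencing favored iff s_m > s_f h
        maternal = ess_msb(del_scheme(s_f=0.1, s_m=0.2))
        paternal = ess_msb(del_scheme(s_f=0.4, s_m=0.01, h=0.3))
        assert maternal.xi_star < 0.5 and maternal.bias_direction == "maternal"
        assert paternal.xi_star > 0.5 and paternal.bias_direction == "paternal"

    def test_msb_unbiased_on_the_knife_edge(self):
        # s_m == s_f h makes eggs and sperm equally loaded; exact in the
        # weak-selection form, and close for the full self-consistent solve
        scheme = del_scheme(s_f=0.4, s_m=0.1, h=0.25)
        assert ess_msb(scheme, approx=True).xi_star == pytest.approx(0.5, abs=1e-14)
        assert ess_msb(scheme).xi_star == pytest.approx(0.5, abs=1e-3)

    def test_msb_exact_vs_weak_selection_approximation(self):
        scheme = del_scheme(s_f=0.02, s_m=0.02, h=0.25)
        exact = ess_msb(scheme).xi_star
        approx = ess_msb(scheme, approx=True).xi_star
        assert exact == pytest.approx(approx, abs=1e-4)

    def test_dominant_variation_unsupported(self):
        with pytest.raises(UnsupportedRegimeError):
            ess_sa(sa(h=0.6))

    def test_mode_guards(self):
        with pytest.raises(ValueError):
            ess_sa(del_scheme())
        with pytest.raises(ValueError):
            ess_msb(sa())


class TestNumericAgreement:
    def test_sa_numeric_matches_analytic(self):
        scheme = sa(s_f=0.25, t_m=0.2, h=0.2)
        num = ess_numeric(scheme)
        assert num.xi_star == pytest.approx(ess_sa(scheme).xi_star, abs=1e-6)
        assert num.gradient_residual < 1e-10

    def test_msb_numeric_matches_analytic(self):
        scheme = del_scheme(s_f=0.1, s_m=0.15, h=0.3)
        num = ess_numeric(scheme)
        assert num.xi_star == pytest.approx(ess_msb(scheme).xi_star, abs=1e-5)

    def test_ess_invariant_to_linkage(self):
        scheme = sa(s_f=0.25, t_m=0.2, h=0.2)
        auto = ess_numeric(scheme, linkage="autosome")
        assert auto.xi_star == pytest.approx(ess_sa(scheme).xi_star, abs=1e-6)

    def test_gradient_sign_flips_across_ess(self):
        scheme = sa(t_m=0.3, h=0.25)
        xi_star = ess_sa(scheme).xi_star
        g_below = selection_gradient(scheme, xi_star - 0.05, symmetric=True)
        g_above = selection_gradient(scheme, xi_star + 0.05, symmetric=True)
        assert g_below > 0 > g_above


class TestUninvadabilityAndConvergence:
    @pytest.mark.parametrize("delta", [1e-2, 1e-3])
    def test_ess_is_uninvadable(self, delta):
        scheme = sa(s_f=0.25, t_m=0.2, h=0.2)
        xi_star = ess_sa(scheme).xi_star
        for sign in (+1.0, -1.0):
            g = selection_gradient(scheme, xi_star, delta=sign * delta)
            # a mutant on either side of the ESS must not invade
            assert g <= 1e-9

    @pytest.mark.parametrize("xi0", [0.01, 0.99])
    def test_substitution_walk_converges_msb(self, xi0):
        # the balance polymorphism exists for every resident strategy, so
        # the walk can start from the extremes
        scheme = del_scheme(s_f=0.1, s_m=0.15, h=0.3)
        xi_final, subs = ess_convergence_walk(scheme, xi0)
        assert xi_final == pytest.approx(ess_msb(scheme).xi_star, abs=5e-3)
        assert subs > 0

    @pytest.mark.parametrize("xi0", [0.2, 0.95])
    def test_substitution_walk_converges_sa(self, xi0):
        # start inside the strategy range that keeps the polymorphism protected
        scheme = sa(s_f=0.25, t_m=0.2, h=0.2)
        xi_final, subs = ess_convergence_walk(scheme, xi0)
        assert xi_final == pytest.approx(ess_sa(scheme).xi_star, abs=5e-3)
        assert subs > 0


class TestMeanFitnessChange:
    def test_msb_female_up_male_down(self):
        # inside the RXI-evolvable region with s_m > 0
        fc = mean_fitness_change_msb(del_scheme(h=0.25))
        assert fc.female_up
        assert not fc.male_up and not fc.male_unchanged

    def test_msb_male_unchanged_without_male_selection(self):
        fc = mean_fitness_change_msb(del_scheme(s_m=1e-12))
        assert abs(fc.mean_w_m_after - fc.mean_w_m_before) < 1e-12

    def test_msb_closed_form_matches_full_table(self):
        scheme = del_scheme(h=0.25)
        closed = mean_fitness_change_msb(scheme, closed_form=True)
        full = mean_fitness_change_msb(scheme, closed_form=False)
        for attr in ("mean_w_f_before", "mean_w_m_before", "mean_w_f_after", "mean_w_m_after"):
            assert getattr(closed, attr) == pytest.approx(getattr(full, attr), abs=1e-8)

    def test_sa_male_up_iff_female_selection_dominates(self):
        # s_f > t_m: RXI makes the female-deleterious allele rarer in eggs
        up = mean_fitness_change_sa(sa(s_f=0.3, t_m=0.2, h=0.2))
        down = mean_fitness_change_sa(sa(s_f=0.2, t_m=0.3, h=0.2))
        assert up.male_up
        assert not down.male_up

    def test_sa_interior_means_match_iterated_recursion(self):
        from xinact import (
            GametePool,
            InactivationPolicy,
            build_fitness_tables,
            iterate,
        )

        scheme = sa(s_f=0.3, t_m=0.25, h=0.2)
        fc = mean_fitness_change_sa(scheme)
        assert fc.region_label == "interior"
        for xi, wf_expect, wm_expect in (
            (1.0, fc.mean_w_f_before, fc.mean_w_m_before),
            (0.5, fc.mean_w_f_after, fc.mean_w_m_after),
        ):
            pol = InactivationPolicy.from_scheme(scheme, xi_11=xi)
            t = build_fitness_tables(scheme, pol)
            res = iterate(GametePool.monomorphic_b1(0.4, 0.4), t, scheme, tol=1e-14)
            wf, wm = res.pool.mean_fitness(t)
            assert wf == pytest.approx(wf_expect, abs=1e-9)
            assert wm == pytest.approx(wm_expect, abs=1e-9)

    def test_sa_boundary_cases_labeled(self):
        fc = mean_fitness_change_sa(sa(s_f=0.6, t_m=0.05, h=0.2))
        assert "A2_fixes" in fc.region_label


class TestMutationBias:
    def test_condition_and_margin(self):
        holds, margin = mutation_bias_condition(del_scheme(s_f=0.1, s_m=0.2, h=0.25))
        assert holds and margin == pytest.approx(0.2 - 0.1 * 0.25, abs=1e-14)
        # male-biased mutation flips the verdict
        holds_biased, _ = mutation_bias_condition(
            del_scheme(s_f=0.1, s_m=0.02, h=0.25, u_f=1e-6, u_m=1e-5)
        )
        assert not holds_biased


class TestRegionClassification:
    def test_small_grid_structure(self):
        df = sa_region_classification(n_grid=15)
        assert len(df) == 225
        assert set(df.columns) >= {"t_m", "s_f", "region_label", "male_up", "d_w_m"}
        interior = df[df.region_label == "interior"]
        assert len(interior) > 0
        # flags must agree with the signed changes they summarize
        assert (interior.female_up == (interior.d_w_f > 1e-12)).all()
        # male gains iff s_f > t_m, so strictly-changed points split evenly
        changed = interior[~interior.male_unchanged]
        assert np.isclose(changed.male_up.mean(), 0.5)
        assert ((changed.male_up) == (changed.s_f > changed.t_m)).all()
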