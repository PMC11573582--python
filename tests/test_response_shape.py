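import math

import numpy as np
import pytest

import squarecycle as sq
from squarecycle.steady_state import RationalResponse

from conftest import grid_concavity_oracle


def hill_family(beta):
    """x/(1+x) times the common factor (1+beta*x) in numerator and denominator."""
    return RationalResponse(A=0.0, B=1.0, C=beta, D=1.0, E=1.0 + beta, F=beta)


class TestEvaluateAndLimits:
    def test_endpoints(self):
        c = hill_family(4.0)
        assert c.evaluate(0.0) == c.r0 == 0.0
        assert c.evaluate(np.inf) == c.r_inf == 1.0
        assert math.isclose(c.evaluate(1.0), 0.5)

    def test_response_stays_within_potency_hull(self):
        rng = np.random.default_rng(2)
        pot = sq.Potencies(0.1, 0.0, 1.0, 2.0)
        lo, hi = min(pot.as_tuple()), max(pot.as_tuple())
        for rs in sq.sample_rate_sets(1000, seed=23):
            c = sq.square_response_coefficients(rs, pot)
            x = 10.0 ** rng.uniform(-4, 4)
            v = c.evaluate(x)
            assert lo - 1e-12 <= v <= hi + 1e-12


class TestLeakinessSaturation:
    def test_two_state_balance_gives_half(self, unit_rates):
        assert sq.leakiness(unit_rates) == 0.5

    def test_match_curve_limits(self):
        pot = sq.Potencies(0.3, 0.1, 1.0, 0.8)
        for rs in sq.sample_rate_sets(100, seed=29):
            c = sq.square_response_coefficients(rs, pot)
            assert math.isclose(sq.leakiness(rs, pot), c.r0, rel_tol=1e-12)
            assert math.isclose(sq.saturation(rs, pot), c.r_inf, rel_tol=1e-12)

    def test_leakiness_depends_only_on_s_p_exchange(self, plausible):
        rng = np.random.default_rng(31)
        base = sq.leakiness(plausible)
        tweaked = plausible
        for edge in ("k_sx", "k_xs", "k_x_xp", "k_xp_x", "k_p_xp", "k_xp_p"):
            tweaked = tweaked.scaled(edge, float(rng.uniform(0.1, 10.0)))
        assert sq.leakiness(tweaked) == base
        # saturation likewise only sees the X<->XP exchange
        sat = sq.saturation(plausible)
        tweaked2 = plausible
        for edge in ("k_sx", "k_xs", "k_sp", "k_ps", "k_p_xp", "k_xp_p"):
            tweaked2 = tweaked2.scaled(edge, float(rng.uniform(0.1, 10.0)))
        assert sq.saturation(tweaked2) == sat


class TestShapeCollapse:
    @pytest.mark.parametrize("beta", [0.2, 1.0, 3.7, 40.0])
    def test_hill_family_parameters(self, beta):
        sp = sq.collapse_shape(hill_family(beta))
        rb = math.sqrt(beta)
        assert math.isclose(sp.a, 1.0 / rb, rel_tol=1e-12)
        assert math.isclose(sp.b, rb + 1.0 / rb, rel_tol=1e-12)
        # normalized curve collapses back to x/(1+x) at y = x/x_scale
        x = np.logspace(-3, 3, 25)
        assert np.allclose(
            sp.normalized_curve(x / sp.x_scale) , x / (1.0 + x), rtol=1e-10
        )

    def test_normalized_identity_pointwise(self):
        x = np.logspace(-5, 5, 41)
        for rs in sq.sample_rate_sets(200, seed=37):
            c = sq.square_response_coefficients(rs)
            sp = sq.collapse_shape(c)
            if sp.degenerate:
                continue
            lhs = (c.evaluate(x) - sp.r0) / (sp.r_inf - sp.r0)
            assert np.allclose(lhs, sp.normalized_curve(x / sp.x_scale), atol=1e-9)

    def test_normalized_curve_runs_zero_to_one(self, plausible):
        sp = sq.collapse_shape(sq.square_response_coefficients(plausible))
        assert abs(sp.normalized_curve(1e-12)) < 1e-9
        assert abs(sp.normalized_curve(1e12) - 1.0) < 1e-9

    def test_equilibrium_b_equals_a_plus_inverse(self):
        for rs in sq.sample_equilibrium_rate_sets(200, seed=41):
            sp = sq.collapse_shape(sq.square_response_coefficients(rs))
            if sp.degenerate:
                continue
            assert math.isclose(sp.b, sp.a + 1.0 / sp.a, rel_tol=1e-6)

    def test_degenerate_flagged_not_divided(self, unit_rates):
        sp = sq.collapse_shape(sq.square_response_coefficients(unit_rates))
        assert sp.degenerate and math.isnan(sp.a)
        with pytest.raises(sq.DegenerateResponseError):
            sp.normalized_curve(1.0)


class TestEquilibriumLinearForm:
    def test_pointwise_match(self):
        x = np.logspace(-6, 6, 20)
        for rs in sq.sample_equilibrium_rate_sets(100, seed=43):
            lf = sq.equilibrium_linear_form(rs)
            c = sq.square_response_coefficients(rs)
            assert np.allclose(lf(x), c.evaluate(x), rtol=1e-9)

    def test_unit_rates_value_half(self, unit_rates):
        lf = sq.equilibrium_linear_form(unit_rates)
        assert math.isclose(lf(1.0), 0.5, rel_tol=1e-14)

    def test_driven_set_rejected_with_measured_drive(self, plausible):
        driven = plausible.scaled("k_sx", math.exp(10.0))
        with pytest.raises(sq.NotDetailedBalancedError, match="10") as exc:
            sq.equilibrium_linear_form(driven)
        assert math.isclose(exc.value.drive, 10.0, rel_tol=1e-9)


class TestInflectionCounting:
    def test_equilibrium_curves_have_one_inflection(self):
        for rs in sq.sample_equilibrium_rate_sets(300, seed=47):
            c = sq.square_response_coefficients(rs)
            try:
                assert sq.count_inflections(c) == 1
            except sq.DegenerateResponseError:
                pass

    def test_universal_count_set(self):
        from squarecycle import analyze_rate_array

        from conftest import rates_matrix

        df = analyze_rate_array(rates_matrix(sq.sample_rate_sets(2000, seed=53)))
        counts = set(df["n_inflections"].unique())
        assert counts <= {1, 2, 3}

    def test_agrees_with_dense_grid_oracle(self):
        mismatches = 0
        for rs in sq.sample_rate_sets(300, seed=59):
            c = sq.square_response_coefficients(rs)
            try:
                ours = sq.count_inflections(c)
            except sq.DegenerateResponseError:
                continue
            oracle = grid_concavity_oracle(c)
            if ours != oracle:
                # only marginal curves (features below the oracle's
                # double-differencing resolution) may disagree
                rep = sq.classify_phenotype(c)
                rel = np.abs(rep.inflection_slopes) / (rep.r_max - rep.r_min)
                assert rel.min() < 1e-6
                mismatches += 1
        assert mismatches <= 6

    def test_degenerate_response_raises(self, unit_rates):
        with pytest.raises(sq.DegenerateResponseError):
            sq.count_inflections(sq.square_response_coefficients(unit_rates))

    def test_driven_default_turns_nonmonotonic(self, plausible):
        # beyond the scanned phenotype boundary the response develops an
        # interior extremum; confirm by dense evaluation
        driven = plausible.scaled("k_sx", math.exp(10.0))
        c = sq.square_response_coefficients(driven)
        assert sq.count_inflections(c) == 2
        rep = sq.classify_phenotype(c)
        assert not rep.monotonic
        x = np.logspace(-8, 8, 20001) * rep.x_scale
        r = c.evaluate(x)
        assert r.max() > max(rep.r0, rep.r_inf) + 1e-9 or r.min() < min(
            rep.r0, rep.r_inf
        ) - 1e-9


class TestPhenotypeReports:
    def test_monotonic_extremes_are_endpoints(self):
        for rs in sq.sample_equilibrium_rate_sets(100, seed=61):
            c = sq.square_response_coefficients(rs)
            try:
                rep = sq.classify_phenotype(c)
            except sq.DegenerateResponseError:
                continue
            assert rep.monotonic
            assert {rep.r_min, rep.r_max} == {rep.r0, rep.r_inf}
            assert {rep.argmin_x, rep.argmax_x} == {0.0, math.inf}

    def test_three_inflection_slope_pattern(self):
        from squarecycle import analyze_rate_array

        from conftest import rates_matrix

        sets = sq.sample_rate_sets(2000, seed=67)
        df = analyze_rate_array(rates_matrix(sets))
        idx = df.index[df["n_inflections"] == 3][:50]
        assert len(idx) > 0
        for i in idx:
            rep = sq.classify_phenotype(sq.square_response_coefficients(sets[i]))
            s1, s2, s3 = np.abs(rep.inflection_slopes)
            # steep-shallow-steep: the middle inflection is the plateau
            assert s2 < s1 and s2 < s3
            assert rep.r_star is not None
            lo, hi = sorted((rep.r0, rep.r_inf))
            assert lo - 1e-9 <= rep.r_star <= hi + 1e-9

    def test_two_inflection_has_interior_extremum(self):
        from squarecycle import analyze_rate_array

        from conftest import rates_matrix

        sets = sq.sample_rate_sets(1000, seed=71)
        df = analyze_rate_array(rates_matrix(sets))
        idx = df.index[df["n_inflections"] == 2][:50]
        assert len(idx) > 0
        for i in idx:
            rep = sq.classify_phenotype(sq.square_response_coefficients(sets[i]))
            assert not rep.monotonic
            assert math.isfinite(rep.argmin_x) and rep.argmin_x > 0 or (
                math.isfinite(rep.argmax_x) and rep.argmax_x > 0
            )

    def test_unit_equilibrium_single_finite_inflection(self, unit_rates, asym_potencies):
        rep = sq.classify_phenotype(
            sq.square_response_coefficients(unit_rates, asym_potencies)
        )
        assert rep.n_inflections == 1 and rep.monotonic
        assert math.isfinite(rep.inflection_positions[0])
        assert rep.inflection_slopes[0] > 0

    def test_serialization(self, plausible):
        rep = sq.classify_phenotype(sq.square_response_coefficients(plausible))
        row = rep.to_csv_row()
        assert set(row) == {
            "n_inflections", "u1", "u2", "u3", "s1", "s2", "s3",
            "monotonic", "r0", "r_inf", "r_min", "r_max", "r_star",
        }
        import json

        json.dumps(rep.to_dict())  # must be JSON-serializable


class TestShapeInvariances:
    def test_potency_affine_invariance(self, plausible):
        driven = plausible.scaled("k_sx", math.exp(6.0))
        p1 = sq.Potencies(0.0, 0.0, 1.0, 1.0)
        p2 = sq.Potencies(0.5, 0.5, 2.0, 2.0)  # r -> 1.5*r + 0.5
        c1 = sq.square_response_coefficients(driven, p1)
        c2 = sq.square_response_coefficients(driven, p2)
        assert sq.count_inflections(c1) == sq.count_inflections(c2)
        s1 = sq.max_normalized_sensitivity(c1)
        s2 = sq.max_normalized_sensitivity(c2)
        assert math.isclose(s1.s_max, s2.s_max, rel_tol=1e-9)
        assert math.isclose(s1.x_at_max, s2.x_at_max, rel_tol=1e-6)

    def test_concentration_rescaling_invariance(self, plausible):
        driven = plausible.scaled("k_ps", math.exp(8.0))
        c = 13.7  # x -> x/c: scale both TF-binding rates together
        rescaled = driven.scaled("k_sx", c).scaled("k_p_xp", c)
        c1 = sq.square_response_coefficients(driven)
        c2 = sq.square_response_coefficients(rescaled)
        assert sq.count_inflections(c1) == sq.count_inflections(c2)
        assert math.isclose(
            sq.max_normalized_sensitivity(c1).s_max,
            sq.max_normalized_sensitivity(c2).s_max,
            rel_tol=1e-9,
        )


class TestMonotonicityCriterion:
    def test_equality_cases_are_monotone_safe(self, plausible):
        import dataclasses

        equal_binding = dataclasses.replace(plausible, k_x_xp=plausible.k_sp)
        assert sq.monotonicity_criterion(equal_binding)
        equal_unbinding = dataclasses.replace(plausible, k_xp_x=plausible.k_ps)
        assert sq.monotonicity_criterion(equal_unbinding)

    def test_coherent_change_violates(self):
        rs = sq.RateSet(1, 1, 0.1, 0.01, 1.0, 0.1, 1, 1)
        assert rs.k_x_xp > rs.k_sp and rs.k_xp_x > rs.k_ps
        assert not sq.monotonicity_criterion(rs)

    def test_criterion_true_implies_monotonic(self):
        from squarecycle import analyze_rate_array

        from conftest import rates_matrix

        sets = sq.sample_rate_sets(2000, seed=73)
        sat = [rs for rs in sets if sq.monotonicity_criterion(rs)]
        assert len(sat) > 300
        df = analyze_rate_array(rates_matrix(sat))
        assert set(df["n_inflections"].unique()) <= {0, 1, 3}
        assert df["monotonic"].all()
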