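"""Interval estimators, reliability, and correlation-comparison statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ciberlite as cl


class TestMeanCI:
    def test_constant_vector_gives_flagged_zero_width(self):
        ci = cl.mean_ci([3, 3, 3, 3])
        assert (ci.point, ci.lower, ci.upper) == (3.0, 3.0, 3.0)
        assert ci.degenerate

    def test_one_to_five_against_t_table(self):
        # mean 3, sd sqrt(2.5); t_{.975,4} = 2.776445 -> half-width 1.963243
        ci = cl.mean_ci([1, 2, 3, 4, 5], level=0.95)
        assert ci.point == pytest.approx(3.0)
        assert ci.lower == pytest.approx(1.0367568, abs=1e-6)
        assert ci.upper == pytest.approx(4.9632432, abs=1e-6)

    def test_higher_level_strictly_wider(self, rng):
        x = rng.normal(size=30)
        assert cl.mean_ci(x, 0.99).width > cl.mean_ci(x, 0.95).width

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            cl.mean_ci([1.0])


class TestFisherZ:
    @pytest.mark.parametrize("r,z", [(0.0, 0.0), (0.5, 0.5493061)])
    def test_known_values(self, r, z):
        assert cl.fisher_z(r) == pytest.approx(z, abs=1e-6)

    @given(st.floats(-0.999, 0.999))
    @settings(deadline=None)
    def test_round_trip(self, r):
        assert cl.inverse_fisher(cl.fisher_z(r)) == pytest.approx(r, abs=1e-12)

    @pytest.mark.parametrize("bad", [1.0, -1.0, 1.5])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            cl.fisher_z(bad)


class TestCorrelationCI:
    def test_perfect_correlation_is_degenerate_and_flagged(self, rng):
        x = rng.normal(size=20)
        res = cl.correlation_ci(x, 2 * x + 1)
        assert res.r == 1.0
        assert res.ci.degenerate
        assert res.ci.lower == res.ci.upper == 1.0

    def test_halfwidth_matches_closed_form(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = 0.3 * x + np.sqrt(1 - 0.09) * rng.normal(size=n)
        res = cl.correlation_ci(x, y, level=0.95)
        c = 0.1396417  # 1.959964 / sqrt(197)
        assert res.ci.lower == pytest.approx(np.tanh(np.arctanh(res.r) - c), abs=1e-6)
        assert res.ci.upper == pytest.approx(np.tanh(np.arctanh(res.r) + c), abs=1e-6)
        assert res.ci.contains(res.r)
        assert res.z == pytest.approx(np.arctanh(res.r))

    def test_width_decreases_with_n_and_increases_with_level(self):
        def width(n, level):
            z = np.arctanh(0.4)
            x = np.linspace(-2, 2, n)
            y = np.tanh(z) * x + np.sin(np.arange(n))  # fixed non-random data
            return cl.correlation_ci(x, y, level=level).ci.width

        assert width(400, 0.95) < width(100, 0.95)
        assert width(100, 0.99) > width(100, 0.95)

    def test_errors(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="constant"):
            cl.correlation_ci(x, np.ones(10))
        with pytest.raises(ValueError, match="n >= 4"):
            cl.correlation_ci([1, 2, 3], [3, 2, 1])


class TestSpearmanBrown:
    # tolerance follows the delta method: d/dr [2r/(1+r)] = 2/(1+r)^2 is
    # steep near r = -1, so the band widens there
    @pytest.mark.parametrize(
        "r,expected,tol", [(1.0, 1.0, 1e-9), (0.0, 0.0, 0.1), (0.5, 2 / 3, 0.05), (-0.5, -2.0, 0.4)]
    )
    def test_step_up_formula(self, r, expected, tol, rng):
        n = 4000
        x = rng.normal(size=n)
        y = r * x + np.sqrt(1 - r**2) * rng.normal(size=n)
        res = cl.spearman_brown(x, y)
        # sampling error in r propagates; formula is exact in the sample r
        robs = np.corrcoef(x, y)[0, 1]
        assert res.estimate == pytest.approx(2 * robs / (1 + robs))
        assert res.estimate == pytest.approx(expected, abs=tol)
        assert res.k == 2

    @given(st.floats(-0.99, 0.999))
    @settings(deadline=None)
    def test_monotone_in_r_and_bounded_by_one(self, r):
        sb = 2 * r / (1 + r)
        sb_up = 2 * (r + 1e-3) / (1 + r + 1e-3)
        assert sb_up > sb
        assert sb <= 1.0

    def test_constant_item_rejected(self):
        with pytest.raises(ValueError):
            cl.spearman_brown([1, 1, 1], [1, 2, 3])


class TestMcdonaldOmega:
    def test_one_factor_equal_loadings_matches_closed_form(self, rng):
        n, k, lam = 20_000, 4, 0.7
        f = rng.standard_normal(n)
        items = lam * f[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((n, k))
        res = cl.mcdonald_omega(items, bootstrap_reps=0)
        expected = (k * lam) ** 2 / ((k * lam) ** 2 + k * (1 - lam**2))
        assert res.estimate == pytest.approx(expected, abs=0.01)
        assert res.extraction == "ml"

    def test_independent_items_give_near_zero(self, rng):
        items = rng.standard_normal((20_000, 4))
        res = cl.mcdonald_omega(items, bootstrap_reps=0)
        assert abs(res.estimate) < 0.05

    def test_bootstrap_ci_contains_point(self, rng):
        n, lam = 300, 0.7
        f = rng.standard_normal(n)
        items = lam * f[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((n, 4))
        res = cl.mcdonald_omega(items, bootstrap_reps=200, seed=1)
        assert res.ci is not None
        assert res.ci.contains(res.estimate)

    def test_bootstrap_is_seed_deterministic(self, rng):
        f = rng.standard_normal(200)
        items = 0.6 * f[:, None] + 0.8 * rng.standard_normal((200, 3))
        a = cl.mcdonald_omega(items, bootstrap_reps=100, seed=5)
        b = cl.mcdonald_omega(items, bootstrap_reps=100, seed=5)
        assert a.ci == b.ci

    def test_needs_three_items(self, rng):
        with pytest.raises(ValueError):
            cl.mcdonald_omega(rng.standard_normal((100, 2)))


class TestEigenScreen:
    def test_independent_items_have_no_kaiser_factors_in_population(self, rng):
        # at large n all eigenvalues hug 1; about half dip below
        screen = cl.eigen_screen(rng.standard_normal((100_000, 4)))
        assert np.allclose(screen.eigenvalues, 1.0, atol=0.02)

    def test_compound_symmetry_closed_form(self, rng):
        k, rho = 4, 0.5
        m = np.full((k, k), rho)
        np.fill_diagonal(m, 1.0)
        x = rng.standard_normal((200_000, k)) @ np.linalg.cholesky(m).T
        screen = cl.eigen_screen(x)
        np.testing.assert_allclose(
            screen.eigenvalues, [1 + (k - 1) * rho, 1 - rho, 1 - rho, 1 - rho], atol=0.02
        )
        assert screen.n_factors_kaiser == 1

    def test_trace_conservation(self, small_dataset):
        items = small_dataset.scores[:, :6].astype(float)
        screen = cl.eigen_screen(items)
        assert sum(screen.eigenvalues) == pytest.approx(6.0, abs=1e-9)
        assert list(screen.eigenvalues) == sorted(screen.eigenvalues, reverse=True)


class TestCohensQ:
    def test_equal_correlations_give_zero_symmetric(self):
        res = cl.cohens_q(0.4, 100, 0.4, 150, level=0.99)
        assert res.q == 0.0
        assert res.ci.lower == pytest.approx(-res.ci.upper)
        assert res.includes_zero

    def test_known_difference(self):
        res = cl.cohens_q(0.5, 100, 0.3, 100)
        assert res.q == pytest.approx(0.2397865, abs=1e-6)

    def test_antisymmetry(self):
        a = cl.cohens_q(0.6, 80, 0.2, 120)
        b = cl.cohens_q(0.2, 120, 0.6, 80)
        assert a.q == pytest.approx(-b.q)

    def test_ci_matches_normal_theory(self):
        res = cl.cohens_q(0.5, 103, 0.3, 103, level=0.95)
        half = 1.959964 * np.sqrt(2 / 100)
        assert res.ci.upper - res.q == pytest.approx(half, abs=1e-5)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            cl.cohens_q(0.5, 3, 0.3, 100)


class TestSdCI:
    def test_zero_sd_degenerate(self):
        ci = cl.sd_ci(0.0, 10)
        assert ci.degenerate and ci.width == 0.0

    def test_chi_square_table_values(self):
        # s=0.7, n=14: bounds from chi2 quantiles at df=13
        ci = cl.sd_ci(0.7, 14, level=0.95)
        assert ci.lower == pytest.approx(0.5074678, abs=1e-6)
        assert ci.upper == pytest.approx(1.1277297, abs=1e-6)

    def test_needs_n_two(self):
        with pytest.raises(ValueError):
            cl.sd_ci(1.0, 1)


class TestSummaries:
    def test_summary_means_and_structure(self, small_dataset, instrument):
        s = cl.summarize_determinants(small_dataset, instrument)
        assert len(s.blocks) == 3
        assert s.n == small_dataset.n
        for block in s.blocks:
            item_mean_avg = np.mean([m for _, m in block.item_means])
            assert block.generic_mean == pytest.approx(item_mean_avg)
            assert -1 <= block.correlation.ci.lower <= block.correlation.r <= block.correlation.ci.upper <= 1

    def test_correlation_ordering_reflects_generating_model(self, small_dataset, instrument):
        # generating det-target correlations: attitude .5 > norm .3 > pbc .15
        s = cl.summarize_determinants(small_dataset, instrument)
        rs = {b.label: b.correlation.r for b in s.blocks}
        assert rs["attitude"] > rs["perceived_norm"] > rs["pbc"]


class TestCompareCorrelationMatrices:
    def test_four_constructs_give_six_comparisons(self, instrument):
        corr = cl.raa_latent_corr(instrument)
        cond = cl.BehaviorCondition("b", {i: 3.0 for i in instrument.item_ids}, corr)
        ds1 = cl.simulate_responses(
            cl.SyntheticResponseSpec(300, instrument, (cond,), seed=1)
        )
        ds2 = cl.simulate_responses(
            cl.SyntheticResponseSpec(300, instrument, (cond,), seed=2)
        )
        comps = cl.compare_correlation_matrices(ds1, ds2, instrument, level=0.99)
        assert len(comps) == 6  # C(4,2): target + 3 determinants
        labels = {frozenset(c.labels) for c in comps}
        assert len(labels) == 6
        # same generating population: zero difference should be plausible overall
        assert sum(c.includes_zero for c in comps) >= 5

    def test_identical_datasets_warn_and_give_zero_q(self, small_dataset, instrument):
        with pytest.warns(UserWarning, match="independent"):
            comps = cl.compare_correlation_matrices(
                small_dataset, small_dataset, instrument
            )
        assert all(c.q == 0.0 for c in comps)


class TestExpertAggregation:
    def test_24_parameter_cells(self, expert_set):
        agg = cl.aggregate_expert_estimates(expert_set)
        assert agg.n_cells == 24
        assert set(agg.table["n"]) == {45}

    def test_identical_experts_degenerate(self):
        cells = [("b", "attitude"), ("b", "pbc")]
        est = cl.ExpertEstimateSet(
            expert_ids=["e1", "e2", "e3"],
            cells=cells,
            values=np.tile([4, 2], (3, 1)),
        )
        agg = cl.aggregate_expert_estimates(est)
        assert (agg.table["sd"] == 0).all()
        assert (agg.table["mean_lower"] == agg.table["mean_upper"]).all()
        assert agg.mean_of_sds == 0.0

    def test_sd_recovery_near_unit(self, expert_set):
        agg = cl.aggregate_expert_estimates(expert_set)
        # truth: sd of round(clip(N(3,1))) is 1.009
        assert agg.mean_of_sds == pytest.approx(1.01, abs=0.08)

    def test_needs_two_experts(self):
        est = cl.ExpertEstimateSet(expert_ids=["e1"], cells=[("b", "d")], values=[[3]])
        with pytest.raises(ValueError):
            cl.aggregate_expert_estimates(est)


def test_results_table_flattens_mixed_results(small_dataset, instrument, rng):
    s = cl.summarize_determinants(small_dataset, instrument)
    x = rng.normal(size=50)
    rows = cl.results_table(
        [s.blocks[0].correlation, cl.cohens_q(0.5, 100, 0.3, 100), cl.mean_ci(x)]
    )
    assert list(rows.columns) == ["statistic", "point", "lower", "upper", "level", "n"]
    assert len(rows) == 3
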