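"""Likelihood, EM fitting, goodness of fit and standard errors."""

import numpy as np
import pytest

from lineup2ht import (
    Fix,
    FitOptions,
    LineupDesign,
    ModelSpec,
    RestrictionMap,
    base_model_spec,
    category_probabilities,
    expected_counts,
    fit,
    log_likelihood,
    saturated_log_likelihood,
    standard_errors,
)

from conftest import FAST_FIT, make_table


class TestLogLikelihood:
    def test_all_mass_on_observed_categories_gives_zero(self, single_condition_spec):
        # dP=dA=b=g=0 puts probability 1 on rejection in both trees
        table = make_table([[[0, 0, 7], [0, 0, 5]]], conditions=("only",))
        ll = log_likelihood(np.zeros(4), single_condition_spec, table)
        assert ll == 0.0

    def test_unsupported_positive_count_gives_minus_infinity(self, single_condition_spec):
        table = make_table([[[3, 0, 7], [0, 0, 5]]], conditions=("only",))
        # dP=g=b=0 assigns probability 0 to culprit identifications
        assert log_likelihood(np.zeros(4), single_condition_spec, table) == -np.inf

    def test_additive_over_conditions(self, base_spec, table1):
        free = np.array([0.4, 0.5, 0.35, 0.45, 0.1, 0.1])
        total = log_likelihood(free, base_spec, table1)
        parts = 0.0
        for cond in ("FYC", "noFYC"):
            sub_spec = ModelSpec(base_spec.design, (cond,))
            idx = list(base_spec.condition_names).index(cond)
            sub = make_table(table1.counts[[idx]], conditions=(cond,))
            theta = base_spec.expand(free)[idx]
            parts += log_likelihood(theta, sub_spec, sub)
        assert total == pytest.approx(parts, abs=1e-9)

    def test_condition_mismatch_raises(self, base_spec):
        table = make_table([[[1, 1, 1], [1, 1, 1]]], conditions=("other",))
        with pytest.raises(ValueError, match="conditions"):
            log_likelihood(np.zeros(6), base_spec, table)


class TestFit:
    def test_reanalysis_base_model_reproduces_published_fit(self, base_spec, table1):
        res = fit(base_spec, table1)
        assert res.converged
        assert round(res.g_squared, 2) == 2.42
        assert res.df == 2
        est = res.rounded()
        assert est["b[FYC,noFYC]"] == 0.00
        assert est["dA[FYC,noFYC]"] == 0.13
        assert "b[FYC,noFYC]" in res.boundary_flags

    def test_replication_base_model_reproduces_published_fit(self, base_spec, table2):
        res = fit(base_spec, table2)
        est = res.rounded()
        assert round(res.g_squared, 2) == 3.09
        assert est["b[FYC,noFYC]"] == 0.01
        assert est["dA[FYC,noFYC]"] == 0.06

    def test_recovers_generating_parameters_from_expected_counts(self, base_spec):
        # self-consistency: data = rounded expected counts at large N
        truth = np.array([0.45, 0.55, 0.35, 0.5, 0.08, 0.2])
        probs = category_probabilities(base_spec.expand(truth), base_spec.design)
        n = 200_000
        counts = np.rint(probs.reshape(2, 2, 3) * n).astype(int)
        res = fit(base_spec, make_table(counts), FAST_FIT)
        assert np.abs(res.free_estimates - truth).max() < 0.01
        assert res.g_squared == pytest.approx(0.0, abs=1e-3)

    def test_g_squared_equals_twice_saturated_loglik_gap(self, base_spec, table1):
        res = fit(base_spec, table1)
        lr = 2.0 * (saturated_log_likelihood(table1) - res.log_likelihood)
        assert res.g_squared == pytest.approx(lr, abs=1e-8)

    def test_fit_invariant_to_condition_order(self, base_spec, table1):
        flipped_spec = base_model_spec(("noFYC", "FYC"))
        res = fit(base_spec, table1, FAST_FIT)
        res_flipped = fit(flipped_spec, table1.reordered(("noFYC", "FYC")), FAST_FIT)
        assert res_flipped.g_squared == pytest.approx(res.g_squared, abs=1e-8)
        a = res.estimates
        b = res_flipped.estimates
        for cond in ("FYC", "noFYC"):
            for p in ("dP", "g", "b", "dA"):
                assert b[cond][p] == pytest.approx(a[cond][p], abs=1e-6)

    def test_fit_invariant_to_scaling_counts(self, base_spec, table1):
        res = fit(base_spec, table1, FAST_FIT)
        scaled = make_table(table1.counts * 3)
        res3 = fit(base_spec, scaled, FAST_FIT)
        # estimate agreement is limited by the optimizer's stopping rule
        assert np.abs(res3.free_estimates - res.free_estimates).max() < 1e-4
        assert res3.g_squared == pytest.approx(3 * res.g_squared, rel=1e-6)

    def test_deterministic_given_seed(self, base_spec, table1):
        r1 = fit(base_spec, table1, FitOptions(seed=42), compute_se=False)
        r2 = fit(base_spec, table1, FitOptions(seed=42), compute_se=False)
        assert np.array_equal(r1.free_estimates, r2.free_estimates)
        assert r1.log_likelihood == r2.log_likelihood

    def test_nonconvergence_is_reported_not_raised(self, base_spec, table1):
        res = fit(base_spec, table1, FitOptions(max_iter=2, n_restarts=1), compute_se=False)
        assert not res.converged

    @pytest.mark.parametrize("which", ["table1", "table2"])
    def test_em_and_quasi_newton_agree_on_the_fixtures(self, which, request):
        table = request.getfixturevalue(which)
        spec = base_model_spec()
        em = fit(spec, table, FitOptions(n_restarts=2), compute_se=False)
        qn = fit(spec, table, FitOptions(n_restarts=2, method="lbfgs"), compute_se=False)
        assert abs(em.log_likelihood - qn.log_likelihood) < 1e-6

    def test_saturated_model_fits_model_compatible_data_perfectly(self, feasible_table):
        # df = 0 and an interior solution exists, so the fit is exact; note
        # that on real data the unrestricted 2-HT model need not be saturated
        # (an interior solution may not exist and b can hit the 0 boundary)
        spec = ModelSpec(LineupDesign(), ("FYC", "noFYC"))
        res = fit(spec, feasible_table, compute_se=False)
        assert res.df == 0
        assert res.g_squared == pytest.approx(0.0, abs=1e-6)


class TestExpectedCounts:
    def test_saturated_expected_counts_equal_observed(self, feasible_table):
        spec = ModelSpec(LineupDesign(), ("FYC", "noFYC"))
        res = fit(spec, feasible_table, compute_se=False)
        exp = expected_counts(res, feasible_table)
        # agreement limited by the optimizer's stopping rule, not the model
        assert np.abs(exp - feasible_table.counts).max() < 0.01

    def test_tree_totals_are_conserved(self, base_spec, table1):
        res = fit(base_spec, table1, FAST_FIT)
        exp = expected_counts(res, table1)
        assert np.abs(exp.sum(axis=2) - table1.tree_totals).max() < 1e-9
        # FYC culprit-present total is 71 + 26 + 61
        assert exp[0, 0].sum() == pytest.approx(158.0, abs=1e-9)

    def test_certain_detection_zeroes_other_culprit_present_cells(self):
        spec = ModelSpec(
            LineupDesign(),
            ("only",),
            RestrictionMap((Fix("dP", "only", 1.0),)),
        )
        table = make_table([[[50, 0, 0], [5, 10, 30]]], conditions=("only",))
        res = fit(spec, table, FAST_FIT, compute_se=False)
        exp = expected_counts(res, table)
        assert exp[0, 0, 1] == 0.0 and exp[0, 0, 2] == 0.0


class TestStandardErrors:
    def test_binomial_subcase_matches_closed_form(self):
        # dA=0, g=0 fixed, dP=1 fixed: the culprit-absent tree is a pure
        # binomial in b with P(suspect) = b, so SE = sqrt(b(1-b)/n)
        spec = ModelSpec(
            LineupDesign(),
            ("only",),
            RestrictionMap(
                (Fix("dP", "only", 1.0), Fix("g", "only", 0.0), Fix("dA", "only", 0.0))
            ),
        )
        k, n = 30, 120
        table = make_table([[[40, 0, 0], [k, 0, n - k]]], conditions=("only",))
        res = fit(spec, table, FAST_FIT)
        b_hat = res.free_estimates[0]
        assert b_hat == pytest.approx(k / n, abs=1e-8)
        assert res.standard_errors[0] == pytest.approx(
            np.sqrt(b_hat * (1 - b_hat) / n), rel=1e-4
        )

    def test_reanalysis_ses_close_to_published(self, base_spec, table1):
        # soft check: the exact SE convention of the original tool is unknown
        res = fit(base_spec, table1)
        ses = dict(zip(res.free_names, res.standard_errors))
        assert ses["b[FYC,noFYC]"] == pytest.approx(0.02, abs=0.01)
        assert ses["dA[FYC,noFYC]"] == pytest.approx(0.12, abs=0.05)
        assert any("boundary" in f for f in res.se_flags)

    def test_doubling_counts_shrinks_ses_by_sqrt2(self, base_spec, table2):
        res = fit(base_spec, table2)
        doubled = make_table(table2.counts * 2)
        res2 = fit(base_spec, doubled)
        ratio = res2.standard_errors / res.standard_errors
        assert np.abs(ratio - 1 / np.sqrt(2)).max() < 1e-6

    def test_standard_errors_function_matches_fit_output(self, base_spec, table2):
        res = fit(base_spec, table2)
        assert np.allclose(
            standard_errors(res, table2), res.standard_errors, equal_nan=True
        )
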