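import warnings
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from laneseq.count_data import CountMatrix, LaneInfo
from laneseq.errors import ValidationError
from laneseq.de_testing import (
    benjamini_hochberg,
    design_matrix,
    fisher_exact_de,
    fisher_pvalues_for_margins,
    filter_low_count,
    fit_poisson_glm,
    lr_test,
    mantel_haenszel_de,
    run_de,
    t_statistic_delta,
    t_statistic_glm,
    weight_by_length,
)
from laneseq.normalization import NormalizationFactors
from laneseq import simgen


def _lanes(conds, fcs=None, preps=None, totals=None):
    n = len(conds)
    fcs = fcs or ["F1"] * n
    preps = preps or ["p1"] * n
    totals = totals if totals is not None else [0] * n
    return LaneInfo.from_records(
        [(f"L{i}", conds[i], fcs[i], preps[i], int(totals[i])) for i in range(n)])


def _factors(lanes, d):
    return NormalizationFactors(lanes.lane_ids, np.asarray(d, dtype=float), "custom")


class TestDesignMatrix:
    LANES = _lanes(["A", "A", "B", "B"], ["F1", "F2", "F1", "F2"],
                   ["p1", "p2", "p3", "p4"])

    @pytest.mark.parametrize("spec,ncols", [
        ("null", 1), ("condition", 2), ("condition+flowcell", 3),
        ("libprep_within_flowcell", 4),
    ])
    def test_shapes_and_full_rank(self, spec, ncols):
        X, labels, _, _ = design_matrix(self.LANES, spec)
        assert X.shape == (4, ncols)
        assert len(labels) == ncols
        assert np.linalg.matrix_rank(X) == ncols

    def test_unknown_spec_rejected(self):
        with pytest.raises(ValidationError):
            design_matrix(self.LANES, "bogus")


class TestPoissonGLM:
    def test_null_design_closed_form(self):
        lanes = _lanes(["A", "A"])
        fit = fit_poisson_glm(np.array([2, 4]), lanes, _factors(lanes, [1, 1]),
                              "null")
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(np.log(3.0), abs=1e-9)

    def test_two_group_matches_closed_form_mle(self):
        rng = np.random.default_rng(5)
        lanes = _lanes(["A"] * 3 + ["B"] * 3)
        d = rng.uniform(0.5, 2.0, 6)
        factors = _factors(lanes, d)
        for _ in range(20):
            y = rng.poisson(rng.uniform(5, 50), 6)
            if y[:3].sum() == 0 or y[3:].sum() == 0:
                continue
            fit = fit_poisson_glm(y, lanes, factors, "condition")
            lamA = y[:3].sum() / d[:3].sum()
            lamB = y[3:].sum() / d[3:].sum()
            assert fit.coefficients[0] == pytest.approx(np.log(lamA), rel=1e-8)
            assert fit.coefficients[1] == pytest.approx(np.log(lamB), rel=1e-8)

    def test_scaling_offsets_and_counts_leaves_rate_unchanged(self):
        lanes = _lanes(["A", "A", "B", "B"])
        f1 = _factors(lanes, [1, 1, 1, 1])
        f2 = _factors(lanes, [2, 2, 2, 2])
        y = np.array([3, 5, 10, 12])
        fit1 = fit_poisson_glm(y, lanes, f1, "condition")
        fit2 = fit_poisson_glm(2 * y, lanes, f2, "condition")
        assert np.allclose(fit1.coefficients, fit2.coefficients, atol=1e-8)

    def test_zero_count_group_flagged_not_raised(self):
        lanes = _lanes(["A", "A", "B", "B"])
        fit = fit_poisson_glm(np.array([0, 0, 10, 12]), lanes,
                              _factors(lanes, [1, 1, 1, 1]), "condition")
        assert not fit.converged

    def test_agrees_with_statsmodels_on_nuisance_design(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        lanes = _lanes(["A", "A", "B", "B", "A", "B"],
                       ["F1", "F1", "F1", "F2", "F2", "F2"])
        d = rng.uniform(0.5, 2.0, 6)
        y = rng.poisson(20, 6)
        fit = fit_poisson_glm(y, lanes, _factors(lanes, d), "condition+flowcell")
        X, _, _, _ = design_matrix(lanes, "condition+flowcell")
        ref = sm.GLM(y, X, family=sm.families.Poisson(),
                     offset=np.log(d)).fit()
        assert np.allclose(fit.coefficients, ref.params, rtol=1e-6)
        assert fit.log_likelihood == pytest.approx(ref.llf, rel=1e-8)
        assert np.allclose(fit.covariance, ref.cov_params(), rtol=1e-5)


class TestLikelihoodRatio:
    def _fits(self, y, d, conds):
        lanes = _lanes(conds)
        factors = _factors(lanes, d)
        return (fit_poisson_glm(y, lanes, factors, "condition", gene_id="g"),
                fit_poisson_glm(y, lanes, factors, "null", gene_id="g"))

    def test_identical_groups_give_zero(self):
        full, null = self._fits(np.array([5, 5, 5, 5]), [1, 1, 1, 1],
                                ["A", "A", "B", "B"])
        res = lr_test(full, null)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_equal_group_rates_give_zero(self):
        # groups (sum 10, offsets 2) vs (sum 5, offsets 1): same rate
        full, null = self._fits(np.array([5, 5, 5]), [1, 1, 1],
                                ["A", "A", "B"])
        res = lr_test(full, null)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)

    def test_zero_count_group_gives_small_p(self):
        full, null = self._fits(np.array([0, 0, 10, 12]), [1, 1, 1, 1],
                                ["A", "A", "B", "B"])
        res = lr_test(full, null)
        assert np.isfinite(res.statistic) and res.statistic > 0
        assert res.p_value < 1e-3

    def test_matches_brute_force_likelihood_oracle(self):
        rng = np.random.default_rng(7)
        conds = ["A"] * 4 + ["B"] * 3
        lanes = _lanes(conds)
        d = rng.uniform(0.5, 2.0, 7)
        factors = _factors(lanes, d)
        for _ in range(20):
            y = rng.poisson(rng.uniform(2, 40), 7)
            if y[:4].sum() == 0 or y[4:].sum() == 0:
                continue
            full = fit_poisson_glm(y, lanes, factors, "condition", gene_id="g")
            null = fit_poisson_glm(y, lanes, factors, "null", gene_id="g")
            res = lr_test(full, null)
            # oracle: direct Poisson log-mass sums at the closed-form MLEs
            lamA = y[:4].sum() / d[:4].sum()
            lamB = y[4:].sum() / d[4:].sum()
            lam0 = y.sum() / d.sum()
            mu_full = d * np.where(np.arange(7) < 4, lamA, lamB)
            expected = 2 * (stats.poisson.logpmf(y, mu_full).sum()
                            - stats.poisson.logpmf(y, d * lam0).sum())
            assert res.statistic == pytest.approx(expected, rel=1e-7, abs=1e-9)

    def test_invariant_to_common_offset_scaling(self):
        y = np.array([3, 8, 20, 11])
        conds = ["A", "A", "B", "B"]
        r1 = self._fits(y, [1, 2, 1, 2], conds)
        r2 = self._fits(y, [5, 10, 5, 10], conds)
        assert lr_test(*r1).statistic == pytest.approx(lr_test(*r2).statistic,
                                                       rel=1e-9)

    def test_non_nested_designs_rejected(self):
        lanes = _lanes(["A", "A", "B", "B"], ["F1", "F2", "F1", "F2"])
        factors = _factors(lanes, [1, 1, 1, 1])
        y = np.array([1, 2, 3, 4])
        cond = fit_poisson_glm(y, lanes, factors, "condition", gene_id="g")
        fcell = fit_poisson_glm(y, lanes, factors, "libprep_within_flowcell",
                                gene_id="g")
        with pytest.raises(ValidationError, match="nested"):
            lr_test(cond, fcell)


class TestTStatistics:
    def test_glm_t_zero_for_equal_rates(self):
        lanes = _lanes(["A", "A", "B", "B"])
        fit = fit_poisson_glm(np.array([5, 5, 5, 5]), lanes,
                              _factors(lanes, [1, 1, 1, 1]), "condition")
        res = t_statistic_glm(fit)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0)

    def test_glm_t_p_near_one_for_zero_count_group(self):
        lanes = _lanes(["A", "A", "B", "B"])
        for other in (5, 20, 50):
            fit = fit_poisson_glm(np.array([0, 0, other, other]), lanes,
                                  _factors(lanes, [1, 1, 1, 1]), "condition")
            res = t_statistic_glm(fit)
            assert res.p_value > 0.9
            assert res.flag == "zero_count"

    def test_glm_t_squared_tracks_lr_for_high_counts(self):
        rng = np.random.default_rng(8)
        lanes = _lanes(["A"] * 3 + ["B"] * 3)
        factors = _factors(lanes, np.ones(6))
        for _ in range(10):
            y = rng.poisson(500, 6)
            full = fit_poisson_glm(y, lanes, factors, "condition", gene_id="g")
            null = fit_poisson_glm(y, lanes, factors, "null", gene_id="g")
            t = t_statistic_glm(full).statistic
            lr = lr_test(full, null).statistic
            assert t ** 2 == pytest.approx(lr, rel=0.1, abs=1e-3)

    def test_delta_zero_when_rates_match(self):
        res = t_statistic_delta(10, 20, 1.0, 2.0)
        assert res.statistic == 0.0

    def test_delta_zero_count_flagged_with_p_one(self):
        res = t_statistic_delta(10, 0, 1.0, 1.0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.flag == "zero_count"

    def test_delta_hand_computed_value(self):
        res = t_statistic_delta(100, 50, 1.0, 1.0)
        assert res.statistic == pytest.approx(np.log(2) / np.sqrt(0.03))
        assert res.direction == 1


class TestFisher:
    def test_symmetric_table_gives_p_one(self):
        res = fisher_exact_de(5, 5, 100, 100)
        assert res.p_value == pytest.approx(1.0)

    def test_column_swap_symmetry(self):
        a = fisher_exact_de(3, 11, 500, 400)
        b = fisher_exact_de(11, 3, 400, 500)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.direction == -b.direction

    def test_matches_exact_rational_enumeration(self):
        # oracle: exact hypergeometric arithmetic with Fractions
        for (xA, xB, dA, dB) in [(0, 10, 50, 50), (3, 1, 20, 30), (7, 2, 40, 15)]:
            res = fisher_exact_de(xA, xB, dA, dB)
            N, K, n = dA + dB, xA + xB, dA
            probs = {}
            for k in range(max(0, n + K - N), min(n, K) + 1):
                probs[k] = Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))
            obs = probs[xA]
            expected = float(sum(p for p in probs.values() if p <= obs))
            assert res.p_value == pytest.approx(expected, rel=1e-10)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            xA, xB = rng.integers(0, 40, 2)
            dA, dB = rng.integers(50, 200, 2)
            res = fisher_exact_de(int(xA), int(xB), int(dA), int(dB))
            tab = [[xA, xB], [dA - xA, dB - xB]]
            assert res.p_value == pytest.approx(
                stats.fisher_exact(tab).pvalue, rel=1e-9)

    def test_inconsistent_factors_rejected(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            fisher_exact_de(10, 0, 5, 100)

    def test_margin_grid_pvalues_are_valid(self):
        k, p = fisher_pvalues_for_margins(40, 12, 17)
        assert np.all((p > 0) & (p <= 1))
        assert p.max() == pytest.approx(1.0)


class TestMantelHaenszel:
    def test_single_stratum_reduces_to_chi_square(self):
        tab = np.array([[12, 5], [88, 95]])
        res = mantel_haenszel_de([tab])
        chi2 = stats.chi2_contingency(tab, correction=False).statistic
        n = tab.sum()
        assert res.statistic == pytest.approx((n - 1) / n * chi2, rel=1e-9)

    def test_identical_balanced_null_tables_give_zero(self):
        tab = [[10, 10], [90, 90]]
        res = mantel_haenszel_de([tab, tab])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_on_heterogeneous_strata(self):
        from statsmodels.stats.contingency_tables import StratifiedTable

        tables = [np.array([[12, 4], [60, 70]]), np.array([[3, 9], [40, 35]])]
        res = mantel_haenszel_de(tables)
        ref = StratifiedTable([t for t in tables]).test_null_odds(correction=False)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_margin_stratum_dropped_with_warning(self):
        good = [[5, 1], [45, 49]]
        empty = [[0, 0], [50, 50]]
        with pytest.warns(UserWarning, match="dropped"):
            res = mantel_haenszel_de([good, empty])
        assert res.statistic == pytest.approx(mantel_haenszel_de([good]).statistic)

    def test_all_strata_dropped_is_error(self):
        with pytest.raises(ValidationError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mantel_haenszel_de([[[0, 0], [5, 5]]])


class TestLengthWeighting:
    def test_length_one_is_identity(self):
        res = t_statistic_delta(100, 50, 1.0, 1.0)
        assert weight_by_length(res, 1).statistic == res.statistic

    def test_arithmetic(self):
        res = t_statistic_delta(100, 50, 1.0, 1.0)
        res = weight_by_length(res, 400)
        base = t_statistic_delta(100, 50, 1.0, 1.0).statistic
        assert res.statistic == pytest.approx(base / 20)
        assert res.method.endswith("_lw")

    def test_missing_length_rejected(self):
        res = t_statistic_delta(100, 50, 1.0, 1.0)
        with pytest.raises(ValidationError):
            weight_by_length(res, None)


class TestFilterLowCount:
    @pytest.mark.parametrize("pooled,kept", [
        ((19, 100), False),  # fewer than 20 in one condition
        ((20, 20), True),    # boundary: "fewer than" is strict
        ((0, 1000), False),
    ])
    def test_threshold_rule(self, pooled, kept):
        counts = np.array([[pooled[0], pooled[1]]])
        m = CountMatrix(["g0"], ["L0", "L1"], counts)
        lanes = _lanes(["A", "B"], totals=m.lane_totals())
        assert filter_low_count(m, lanes, 20)[0] == kept

    def test_requires_two_conditions(self):
        m = CountMatrix(["g0"], ["L0", "L1"], np.array([[5, 5]]))
        lanes = _lanes(["A", "A"], totals=m.lane_totals())
        with pytest.raises(ValidationError):
            filter_low_count(m, lanes)


class TestRunDe:
    @pytest.fixture
    def bundle(self):
        b = simgen.scenario_basic_de(21, n_genes=200)
        d = np.sqrt(b["counts"].lane_totals().astype(float))  # arbitrary positive
        factors = NormalizationFactors(
            b["counts"].lane_ids, d * b["counts"].counts.sum() / d.sum(), "custom")
        return b["counts"], b["lanes"], factors

    def test_single_gene_matrix(self):
        m = CountMatrix(["g0"], ["L0", "L1"], np.array([[30, 5]]))
        lanes = _lanes(["A", "B"], totals=m.lane_totals())
        res = run_de(m, lanes, _factors(lanes, [1.0, 1.0]), "lr")
        assert len(res) == 1
        assert res["p_value"][0] < 0.01

    @pytest.mark.parametrize("method", ["lr", "t_delta", "fisher", "mh"])
    def test_permuting_genes_permutes_results(self, bundle, method):
        m, lanes, factors = bundle
        perm = np.random.default_rng(0).permutation(m.n_genes)
        m2 = CountMatrix([m.gene_ids[i] for i in perm], m.lane_ids,
                         m.counts[perm], gene_lengths=m.gene_lengths[perm])
        r1 = run_de(m, lanes, factors, method).set_index("gene_id")
        r2 = run_de(m2, lanes, factors, method).set_index("gene_id")
        assert np.allclose(r1.loc[r2.index, "p_value"], r2["p_value"],
                           equal_nan=True)

    def test_methods_agree_on_direction_of_clear_de(self):
        counts = np.column_stack([np.full(30, 10), np.full(30, 10),
                                  np.full(30, 40), np.full(30, 40)])
        counts[0] = [200, 200, 10, 10]
        m = CountMatrix([f"g{i}" for i in range(30)], ["L0", "L1", "L2", "L3"],
                        counts)
        lanes = _lanes(["A", "A", "B", "B"], ["F1", "F2", "F1", "F2"],
                       totals=m.lane_totals())
        factors = _factors(lanes, m.lane_totals().astype(float))
        for method in ("lr", "t_glm", "t_delta", "fisher", "mh"):
            res = run_de(m, lanes, factors, method)
            assert res["direction"][0] == -1, method

    def test_glm_route_agrees_with_vectorized_two_group_path(self, bundle):
        m, lanes, factors = bundle
        fast = run_de(m, lanes, factors, "lr")
        for g in (0, 7, 42):
            full = fit_poisson_glm(m.counts[g], lanes, factors, "condition",
                                   gene_id=m.gene_ids[g])
            null = fit_poisson_glm(m.counts[g], lanes, factors, "null",
                                   gene_id=m.gene_ids[g])
            res = lr_test(full, null)
            assert fast["statistic"][g] == pytest.approx(res.statistic,
                                                         rel=1e-6, abs=1e-8)

    def test_filtered_genes_are_flagged(self, bundle):
        m, lanes, factors = bundle
        res = run_de(m, lanes, factors, "lr", filter_min=20)
        mask = filter_low_count(m, lanes, 20)
        assert (res.loc[~mask, "flag"] == "filtered").all()
        assert res.loc[~mask, "p_value"].isna().all()

    def test_bh_step_up_oracle(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 1.0]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 1.0])
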