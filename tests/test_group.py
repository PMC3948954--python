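import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpgc.group import (GroupAnalysisError, _group_lm, ancova_path,
                        behavior_correlation, behavior_correlations,
                        contingency_chi2, demographics_table,
                        masked_group_difference, qc_motion_correlation,
                        summary_stat_ttest)
from cpgc.surrogate import classify_paths

GROUPS_16_16 = np.r_[np.ones(16), np.zeros(16)]


class TestAncova:
    def test_matches_statsmodels(self, rng):
        """Independent oracle: statsmodels OLS on the same design."""
        import statsmodels.api as sm

        y = rng.normal(size=32)
        cov = rng.normal(size=32)
        res = ancova_path(y, GROUPS_16_16, cov)
        X = sm.add_constant(np.c_[GROUPS_16_16, cov])
        fit = sm.OLS(y, X).fit()
        assert res.p == pytest.approx(fit.pvalues[1], abs=1e-10)
        assert res.f == pytest.approx(fit.tvalues[1] ** 2, abs=1e-8)
        assert res.coef == pytest.approx(fit.params[1], abs=1e-10)

    def test_null_pvalues_uniform(self, rng):
        Y = rng.normal(size=(32, 2000))
        cov = rng.normal(size=32)
        _, _, p = _group_lm(Y, GROUPS_16_16, cov)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_power_matches_t_test_oracle(self, rng):
        """delta = 1 SD at n=16+16: empirical power at alpha=0.01 equals the
        closed-form noncentral-t power of the two-sample test."""
        delta = 1.0
        Y = rng.normal(size=(32, 2000))
        Y[:16] += delta
        _, _, p = _group_lm(Y, GROUPS_16_16, None)
        power = (p < 0.01).mean()
        nc = delta / np.sqrt(2 / 16)
        tcrit = stats.t.ppf(1 - 0.005, 30)
        theory = stats.nct.sf(tcrit, 30, nc) + stats.nct.cdf(-tcrit, 30, nc)
        assert abs(power - theory) < 0.04

    def test_covariate_explains_group_difference(self, rng):
        """When the covariate carries the whole group effect, the adjusted
        group p-values stay near-uniform."""
        sig = 0
        n_sim = 1000
        cov = GROUPS_16_16 * 2.0 + rng.normal(size=32) * 0.3
        Y = cov[:, None] + rng.normal(size=(32, n_sim))
        _, _, p = _group_lm(Y, GROUPS_16_16, cov)
        sig = (p < 0.05).mean()
        assert sig < 0.15     # no systematic group effect once adjusted

    def test_zero_variance_covariate_equals_plain_anova(self, rng):
        y = rng.normal(size=32)
        with_cov = ancova_path(y, GROUPS_16_16, np.full(32, 3.0))
        f, p = stats.f_oneway(y[:16], y[16:])
        assert with_cov.f == pytest.approx(f, abs=1e-8)
        assert with_cov.p == pytest.approx(p, abs=1e-8)

    def test_direction_sign(self, rng):
        y = rng.normal(size=32)
        y[:16] += 5.0
        assert ancova_path(y, GROUPS_16_16, None).direction == 1

    def test_degenerate_inputs(self, rng):
        with pytest.raises(GroupAnalysisError, match="two groups"):
            ancova_path(rng.normal(size=5), np.ones(5), None)
        with pytest.raises(GroupAnalysisError, match="degenerate"):
            ancova_path(np.ones(32), GROUPS_16_16, None)


def make_inference(k, sig_paths, alpha=0.01):
    p = np.ones((k, k))
    for (i, j) in sig_paths:
        p[i, j] = alpha / 10
    return classify_paths(p, alpha)


class TestMaskedGroupDifference:
    k = 4

    def stacks(self, rng, delta_path=None, delta=0.0):
        pat = rng.normal(size=(16, self.k, self.k)) * 0.1 + 1.0
        con = rng.normal(size=(16, self.k, self.k)) * 0.1 + 1.0
        if delta_path is not None:
            pat[:, delta_path[0], delta_path[1]] += delta
        return pat, con

    def test_between_significant_but_unmasked_excluded(self, rng):
        pat, con = self.stacks(rng, (1, 0), 2.0)
        empty = make_inference(self.k, [])
        res = masked_group_difference(pat, con, empty, empty, alpha=0.01)
        assert res.p[1, 0] < 0.01          # strongly significant between groups
        assert res.increased == [] and res.decreased == []

    def test_masked_detection_and_direction(self, rng):
        pat, con = self.stacks(rng, (1, 0), 2.0)
        wp = make_inference(self.k, [(1, 0)])
        wc = make_inference(self.k, [])
        res = masked_group_difference(pat, con, wp, wc, alpha=0.01)
        assert (1, 0) in res.increased
        assert res.decreased == []

    def test_decreased_requires_control_mask(self, rng):
        pat, con = self.stacks(rng)
        con[:, 2, 3] += 2.0
        wc = make_inference(self.k, [(2, 3)])
        res = masked_group_difference(pat, con, make_inference(self.k, []),
                                      wc, alpha=0.01)
        assert (2, 3) in res.decreased

    def test_monotone_in_alpha(self, rng):
        pat, con = self.stacks(rng, (1, 0), 0.8)
        full = make_inference(self.k, [(i, j) for i in range(self.k)
                                       for j in range(self.k) if i != j])
        strict = masked_group_difference(pat, con, full, full, alpha=0.005)
        loose = masked_group_difference(pat, con, full, full, alpha=0.01)
        assert set(strict.increased) <= set(loose.increased)
        assert set(strict.decreased) <= set(loose.decreased)

    def test_disjoint_sets(self, rng):
        pat, con = self.stacks(rng, (1, 0), 2.0)
        con[:, 3, 1] += 2.0
        full = make_inference(self.k, [(i, j) for i in range(self.k)
                                       for j in range(self.k) if i != j])
        res = masked_group_difference(pat, con, full, full, alpha=0.01)
        assert not (set(res.increased) & set(res.decreased))

    def test_misaligned_shapes_rejected(self, rng):
        pat = rng.normal(size=(16, 4, 4))
        con = rng.normal(size=(16, 5, 5))
        inf4 = make_inference(4, [])
        with pytest.raises(GroupAnalysisError, match="misaligned"):
            masked_group_difference(pat, con, inf4, inf4)


class TestBehaviorCorrelation:
    def test_exact_linear_relation(self):
        v = np.arange(16.0)
        bc = behavior_correlation(v, 2.0 * v + 1.0)
        assert bc.r == pytest.approx(1.0)
        assert bc.p < 1e-10

    def test_matches_direct_covariance_formula(self, rng):
        v, s = rng.normal(size=16), rng.normal(size=16)
        bc = behavior_correlation(v, s)
        direct = (np.cov(v, s)[0, 1] / (np.std(v, ddof=1) * np.std(s, ddof=1)))
        assert bc.r == pytest.approx(direct, abs=1e-12)

    def test_type_one_error_rate(self, rng):
        hits = sum(behavior_correlation(rng.normal(size=16),
                                        rng.normal(size=16)).p < 0.05
                   for _ in range(2000))
        lo, hi = stats.binom.ppf([0.025, 0.975], 2000, 0.05)
        assert lo <= hits <= hi

    def test_input_validation(self, rng):
        with pytest.raises(GroupAnalysisError, match="3 subjects"):
            behavior_correlation(np.ones(2), np.ones(2))
        with pytest.raises(GroupAnalysisError, match="non-finite"):
            behavior_correlation(rng.normal(size=5), np.r_[np.nan, np.ones(4)])

    def test_table_over_paths_and_measures(self, rng):
        cpgc = rng.normal(size=(16, 3, 3))
        scores = pd.DataFrame({"MMSE": rng.normal(size=16),
                               "CDT": rng.normal(size=16)})
        tbl = behavior_correlations(cpgc, [(1, 0), (2, 1)], scores)
        assert len(tbl) == 4
        assert set(tbl["measure"]) == {"MMSE", "CDT"}
        assert np.all(np.abs(tbl["r"]) <= 1.0)


class TestMotionQc:
    def test_constant_fd_flagged(self, rng):
        tbl = qc_motion_correlation(np.ones(10), rng.normal(size=(10, 3, 3)))
        assert not tbl["defined"].any()

    def test_fd_equal_to_path_gives_r_one(self, rng):
        V = rng.normal(size=(12, 3, 3))
        fd = V[:, 1, 0].copy()
        tbl = qc_motion_correlation(fd, V)
        row = tbl[(tbl.target == 1) & (tbl.source == 0)].iloc[0]
        assert row.r == pytest.approx(1.0)

    def test_independent_fd_false_positive_rate(self, rng):
        flagged = total = 0
        for _ in range(40):
            tbl = qc_motion_correlation(rng.normal(size=16),
                                        rng.normal(size=(16, 8, 8)))
            flagged += (tbl["p"] < 0.05).sum()
            total += len(tbl)
        lo, hi = stats.binom.ppf([0.005, 0.995], total, 0.05)
        assert lo <= flagged <= hi


class TestSummaryStatTests:
    def test_identical_groups(self):
        t, p = summary_stat_ttest(5.0, 1.0, 16, 5.0, 1.0, 16)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_cohort_score_rows_significant(self):
        """MMSE and long-delay recall summaries (n=16/16) differ at p<0.05."""
        _, p_mmse = summary_stat_ttest(25.94, 1.65, 16, 28.56, 0.63, 16)
        _, p_cvlt = summary_stat_ttest(7.31, 1.43, 16, 12.62, 1.36, 16)
        assert p_mmse < 0.05
        assert p_cvlt < 0.05

    def test_welch_flag_changes_result(self):
        p_pooled = summary_stat_ttest(1.0, 0.5, 10, 1.4, 2.5, 30)[1]
        p_welch = summary_stat_ttest(1.0, 0.5, 10, 1.4, 2.5, 30,
                                     equal_var=False)[1]
        assert p_pooled != p_welch

    def test_invalid_summaries(self):
        with pytest.raises(GroupAnalysisError):
            summary_stat_ttest(1.0, 0.0, 16, 1.0, 1.0, 16)
        with pytest.raises(GroupAnalysisError):
            summary_stat_ttest(1.0, 1.0, 1, 1.0, 1.0, 16)


class TestContingencyChi2:
    def test_balanced_sex_table(self):
        chi2, p = contingency_chi2([[10, 6], [10, 6]])
        assert chi2 == pytest.approx(0.0)
        assert p >= 0.99

    def test_perfect_association(self):
        _, p = contingency_chi2([[10, 0], [0, 10]])
        assert p < 0.01

    def test_zero_margin_rejected(self):
        with pytest.raises(GroupAnalysisError, match="zero margin"):
            contingency_chi2([[5, 0], [7, 0]])

    def test_continuity_auto_for_small_expected(self):
        # expected counts < 5 -> Yates applied automatically; forcing it off
        # must give a smaller p for this table
        table = [[4, 1], [1, 4]]
        _, p_auto = contingency_chi2(table)
        _, p_raw = contingency_chi2(table, continuity=False)
        assert p_raw < p_auto

    def test_non_integer_rejected(self):
        with pytest.raises(GroupAnalysisError):
            contingency_chi2([[1.5, 2], [3, 4]])


def test_demographics_table_structure(rng):
    meta = pd.DataFrame({
        "group": ["patient"] * 16 + ["control"] * 16,
        "sex": (["F"] * 10 + ["M"] * 6) * 2,
        "age": rng.normal(68, 8, size=32),
        "MMSE": np.r_[rng.normal(26, 1.6, 16), rng.normal(28.6, 0.6, 16)],
    })
    tbl = demographics_table(meta)
    sex_row = tbl[tbl.measure == "sex F/M"].iloc[0]
    assert sex_row.p >= 0.99
    assert (tbl[tbl.measure == "MMSE"].iloc[0].p
            == pytest.approx(stats.ttest_ind(meta.MMSE[:16], meta.MMSE[16:]).pvalue))
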