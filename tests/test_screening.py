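"""Decision layer: ROC/AUC, threshold rule, and statistical kernels."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from uriscreen.errors import (
    InsufficientDataError,
    NormalizationError,
    UndefinedStatisticError,
)
from uriscreen.panels import ClonePanel, generate_panel, table1_models
from uriscreen.screening import (
    PairDesign,
    apply_threshold_rule,
    binormal_auc,
    empirical_auc,
    mean_difference_test,
    normality_test,
    pearson_r,
    replicate_pair_auc,
    replicate_threshold_rule,
    roc_curve,
    screen_report,
    summarize,
    variance_homogeneity_test,
)


def panel_from_sa(name, sa, protein=None):
    sa = np.asarray(sa, dtype=float)
    protein = np.ones_like(sa) if protein is None else np.asarray(protein, dtype=float)
    return ClonePanel(candidate=name, n=sa.size, protein_mg_per_mL=protein,
                      ac_U_per_mL=sa * protein, sa_U_per_mg=sa)


class TestSummarize:
    def test_constant_values(self):
        assert summarize([1.0, 1.0, 1.0]) == (1.0, 0.0, 0.0)

    def test_cv_matches_population_ratio(self, rng):
        x = rng.normal(0.28, 0.05, 100_000)
        s = summarize(x)
        assert s.cv == pytest.approx(0.05 / 0.28, rel=0.02)

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize([1.0])

    def test_zero_mean_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            summarize([-1.0, 1.0])


class TestEmpiricalAuc:
    def test_perfect_separation(self):
        assert empirical_auc([3, 4, 5], [0, 1, 2]) == 1.0

    def test_pure_ties(self):
        assert empirical_auc([1.0], [1.0]) == 0.5

    @given(
        pos=st.lists(st.integers(0, 9), min_size=1, max_size=8),
        neg=st.lists(st.integers(0, 9), min_size=1, max_size=8),
    )
    def test_matches_exhaustive_pair_count(self, pos, neg):
        brute = sum(
            1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
        ) / (len(pos) * len(neg))
        assert empirical_auc(pos, neg) == pytest.approx(brute, abs=1e-12)

    def test_label_swap_symmetry(self, rng):
        a = rng.normal(0.3, 0.1, 25)
        b = rng.normal(0.2, 0.1, 30)
        assert empirical_auc(a, b) == pytest.approx(1.0 - empirical_auc(b, a), abs=1e-12)


class TestRocCurve:
    def test_perfect_pair_hits_corner(self):
        design = PairDesign(panel_from_sa("SM", [1, 2, 3]), panel_from_sa("P", [4, 5, 6]))
        report = roc_curve(design)
        assert report.auc == 1.0
        corner = (report.sensitivity == 1.0) & (report.specificity == 1.0)
        assert np.any(corner)

    def test_monotone_sensitivity_specificity(self, rng):
        sm = panel_from_sa("SM", rng.normal(0.28, 0.05, 30))
        pos = panel_from_sa("P", rng.normal(0.49, 0.09, 30))
        report = roc_curve(PairDesign(sm, pos))
        assert np.all(np.diff(report.sensitivity) <= 1e-12)
        assert np.all(np.diff(report.specificity) >= -1e-12)

    def test_trapezoid_equals_mann_whitney(self, rng):
        for _ in range(20):
            sm = panel_from_sa("SM", rng.integers(0, 6, 15).astype(float))
            pos = panel_from_sa("P", rng.integers(0, 6, 12).astype(float))
            report = roc_curve(PairDesign(sm, pos))
            assert report.auc == pytest.approx(
                empirical_auc(pos.sa_U_per_mg, sm.sa_U_per_mg), abs=1e-12
            )

    def test_normalized_cutoffs_centered_on_starting_material(self, rng):
        sm_values = rng.normal(0.28, 0.05, 30)
        sm = panel_from_sa("SM", sm_values)
        pos = panel_from_sa("P", rng.normal(0.49, 0.09, 30))
        report = roc_curve(PairDesign(sm, pos))
        mean, sd, _ = summarize(sm_values)
        finite = np.isfinite(report.cutoffs)
        expected = (report.cutoffs[finite] - mean) / sd
        assert np.allclose(report.normalized_cutoffs[finite], expected)

    def test_zero_spread_starting_material_rejected(self):
        design = PairDesign(panel_from_sa("SM", [1, 1, 1]), panel_from_sa("P", [2, 3, 4]))
        with pytest.raises(NormalizationError):
            roc_curve(design)


class TestThresholdRule:
    def test_constant_starting_material(self):
        design = PairDesign(panel_from_sa("SM", [0.2] * 5), panel_from_sa("P", [0.3, 0.25, 0.1]))
        rule = apply_threshold_rule(design, k=1.4)
        assert rule.threshold == pytest.approx(0.2)
        assert rule.sensitivity == pytest.approx(2 / 3)
        assert rule.specificity == 1.0

    def test_large_panel_matches_normal_cdf(self, rng):
        # candidate C panel (0.28, 0.05): threshold -> 0.35,
        # specificity -> Phi(1.4) ~ 0.919; candidate A sensitivity -> Phi(14/9)
        sm = panel_from_sa("SM", rng.normal(0.28, 0.05, 200_000))
        pos = panel_from_sa("P", rng.normal(0.49, 0.09, 200_000))
        rule = apply_threshold_rule(PairDesign(sm, pos), k=1.4)
        assert rule.threshold == pytest.approx(0.28 + 1.4 * 0.05, abs=0.002)
        assert rule.specificity == pytest.approx(stats.norm.cdf(1.4), abs=0.005)
        assert rule.sensitivity == pytest.approx(
            stats.norm.cdf((0.49 - 0.35) / 0.09), abs=0.005
        )


class TestReplicateSimulators:
    def test_replicate_auc_converges_to_binormal(self):
        # B vs C by activity concentration: oracle Phi(0.10/0.0781) ~ 0.900
        oracle = binormal_auc(0.28, 0.06, 0.18, 0.05)
        sim = replicate_pair_auc(0.28, 0.06, 0.18, 0.05, n=30, reps=4000, rng=77)
        assert sim == pytest.approx(oracle, abs=0.005)

    def test_threshold_rule_replicates_match_oracles(self):
        sens, spec = replicate_threshold_rule(0.28, 0.05, 0.49, 0.09,
                                              k=1.4, n=30, reps=4000, rng=78)
        assert spec >= 0.90
        assert sens >= 0.90

    def test_index_dominance_for_close_pairs(self):
        # capacity ratios < 2: specific activity separates better than
        # activity concentration in essentially every replicate batch
        models = {m.name: m for m in table1_models()}
        batches_sa_wins = 0
        n_batches = 20
        for b in range(n_batches):
            rng = np.random.default_rng(9000 + b)
            auc_sa, auc_ac = [], []
            for _ in range(50):
                for hi, lo in (("A", "B"), ("B", "C"), ("A", "C")):
                    p_hi = generate_panel(models[hi], 30, rng=rng)
                    p_lo = generate_panel(models[lo], 30, rng=rng)
                    auc_sa.append(empirical_auc(p_hi.sa_U_per_mg, p_lo.sa_U_per_mg))
                    auc_ac.append(empirical_auc(p_hi.ac_U_per_mL, p_lo.ac_U_per_mL))
            batches_sa_wins += np.mean(auc_sa) > np.mean(auc_ac)
        assert batches_sa_wins >= 0.95 * n_batches

    def test_saturated_pairs_reach_auc_one(self):
        models = {m.name: m for m in table1_models()}
        rng = np.random.default_rng(321)
        for hi, lo in (("B", "D"), ("A", "D")):
            aucs = []
            for _ in range(200):
                p_hi = generate_panel(models[hi], 30, rng=rng)
                p_lo = generate_panel(models[lo], 30, rng=rng)
                aucs.append(empirical_auc(p_hi.ac_U_per_mL, p_lo.ac_U_per_mL))
                aucs.append(empirical_auc(p_hi.sa_U_per_mg, p_lo.sa_U_per_mg))
            assert np.mean(aucs) >= 0.999

    def test_sa_threshold_rule_more_sensitive_than_ac(self):
        # the 1.4-SD rule on specific activity finds more true positives
        # than the same rule on activity concentration, on every fixture pair
        models = {m.name: m for m in table1_models()}
        rng = np.random.default_rng(654)
        for hi, lo in (("A", "B"), ("B", "C"), ("A", "C"), ("C", "D"), ("B", "D"), ("A", "D")):
            sens = {"sa": [], "ac": []}
            for _ in range(300):
                p_hi = generate_panel(models[hi], 30, rng=rng)
                p_lo = generate_panel(models[lo], 30, rng=rng)
                for key, attr in (("sa", "sa_U_per_mg"), ("ac", "ac_U_per_mL")):
                    lo_vals = getattr(p_lo, attr)
                    thr = lo_vals.mean() + 1.4 * lo_vals.std(ddof=1)
                    sens[key].append((getattr(p_hi, attr) > thr).mean())
            assert np.mean(sens["sa"]) >= np.mean(sens["ac"]) - 1e-9


class TestScreenReport:
    def test_ratios_follow_table_means(self):
        aggregate, _ = screen_report(reps=10, seed=1)
        row = aggregate.set_index("pair")
        assert row.loc["A-D", "ratio_ac"] == pytest.approx(0.30 / 0.033, abs=5e-3)
        assert row.loc["C-D", "ratio_sa"] == pytest.approx(0.28 / 0.050, abs=5e-3)
        assert row.loc["A-D", "ratio_purified"] == pytest.approx(4.10)

    def test_rerun_bit_identical(self):
        a, ra = screen_report(reps=5, seed=99)
        b, rb = screen_report(reps=5, seed=99)
        assert a.equals(b) and ra.equals(rb)

    def test_unknown_candidate_rejected(self):
        from uriscreen.errors import DomainError

        with pytest.raises(DomainError):
            screen_report(pairs=[("A", "Z")], reps=2, seed=0)


class TestStatisticalKernels:
    def test_shapiro_null_pvalues_uniform(self):
        rng = np.random.default_rng(2718)
        pvals = [normality_test(rng.normal(size=30))[1] for _ in range(1000)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_shapiro_power_against_lognormal(self):
        rng = np.random.default_rng(1618)
        rejections = sum(
            normality_test(rng.lognormal(0.0, 1.0, 30))[1] < 0.05 for _ in range(300)
        )
        assert rejections / 300 > 0.80

    def test_shapiro_bounds(self):
        with pytest.raises(InsufficientDataError):
            normality_test([1.0, 2.0])
        with pytest.raises(UndefinedStatisticError):
            normality_test([1.0] * 10)

    def test_identical_groups_give_null_statistics(self):
        x = [0.1, 0.2, 0.3, 0.4]
        f, pf = variance_homogeneity_test(x, x)
        t, pt = mean_difference_test(x, x)
        assert f == pytest.approx(1.0) and pf == pytest.approx(1.0)
        assert (t, pt) == (0.0, 1.0)

    def test_f_and_t_type_one_error_calibrated(self):
        rng = np.random.default_rng(31415)
        reps = 10_000
        a = rng.normal(size=(reps, 30))
        b = rng.normal(size=(reps, 30))
        va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        fstat = va / vb
        dist = stats.f(29, 29)
        pf = 2 * np.minimum(dist.cdf(fstat), dist.sf(fstat))
        t_res = stats.ttest_ind(a, b, axis=1, equal_var=True)
        for p in (pf, t_res.pvalue):
            rate = float(np.mean(p < 0.05))
            assert abs(rate - 0.05) < 0.008

    def test_f_test_power_at_variance_ratio_four(self):
        rng = np.random.default_rng(27182)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(0, 2.0, 30)
            b = rng.normal(0, 1.0, 30)
            _, p = variance_homogeneity_test(a, b)
            rejections += p < 0.05
        assert rejections / reps > 0.90

    def test_pearson_exact_lines(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)
        with pytest.raises(UndefinedStatisticError):
            pearson_r(x, np.ones_like(x))

    def test_panel_correlation_matches_delta_method(self):
        from uriscreen.panels import predicted_ac_protein_corr

        model = next(m for m in table1_models() if m.name == "B")
        panel = generate_panel(model, n=100_000, seed=17)
        r = pearson_r(panel.ac_U_per_mL, panel.protein_mg_per_mL)
        assert r == pytest.approx(predicted_ac_protein_corr(model), abs=0.03)
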