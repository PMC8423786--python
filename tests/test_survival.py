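"""Survival curves, the cutpoint scan, and the per-gene screens."""
import numpy as np
import pytest

import oracles
from conftest import make_norm
from sigshare.datatypes import GeneSet, ValidationError
from sigshare.stats import logrank_test
from sigshare.survival import (
    kaplan_scan,
    km_estimate,
    per_gene_age_correlation,
    per_gene_group_differential,
    per_gene_survival_groups,
    scan_signatures,
    signature_label_enrichment,
    signature_zscore_average,
)


class TestZScoreAverage:
    def test_hand_computed_toy(self):
        # 2 genes x 3 samples
        values = np.array([[1.0, 2.0, 3.0], [4.0, 6.0, 8.0]])
        norm = make_norm(values, tag="standardized")
        gs = GeneSet("s", frozenset(norm.gene_ids))
        scores = signature_zscore_average(norm, gs, for_scan=False)
        z1 = (np.array([1, 2, 3]) - 2.0) / 1.0
        z2 = (np.array([4, 6, 8]) - 6.0) / 2.0
        assert scores.to_numpy() == pytest.approx((z1 + z2) / 2)

    def test_scan_rejects_small_signatures(self):
        values = np.random.default_rng(0).normal(size=(5, 10))
        norm = make_norm(values, tag="standardized")
        with pytest.raises(ValidationError, match="more than two"):
            signature_zscore_average(norm, GeneSet("s", frozenset(norm.gene_ids[:2])))
        # three genes pass
        signature_zscore_average(norm, GeneSet("s", frozenset(norm.gene_ids[:3])))

    def test_constant_gene_excluded_with_warning(self):
        values = np.vstack([np.ones(6), np.arange(6.0), np.arange(6.0) ** 2,
                            np.cos(np.arange(6.0))])
        norm = make_norm(values, tag="standardized")
        with pytest.warns(UserWarning, match="constant"):
            scores = signature_zscore_average(norm, GeneSet("s", frozenset(norm.gene_ids)))
        assert np.isfinite(scores.to_numpy()).all()
        with pytest.raises(ValidationError, match="varies"):
            signature_zscore_average(
                norm, GeneSet("s", frozenset({norm.gene_ids[0]})), for_scan=False
            )


class TestKaplanMeier:
    def test_all_censored_is_flat_one(self):
        curve = km_estimate([5, 8, 12], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.probability_at(100.0) == 1.0

    def test_hand_product_limit(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_non_increasing_on_random_input(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 80)
        e = rng.random(80) < 0.6
        curve = km_estimate(t, e)
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 60)
        e = rng.random(60) < 0.7
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        curve = km_estimate(t, e)
        for tau, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(tau).iloc[0])
            )


def _cohort(rng, n=120, hr=3.0):
    score = rng.normal(size=n)
    lam = np.log(2) / 100.0 * hr**score
    raw = rng.exponential(1 / lam)
    times = np.minimum(raw, 400.0)
    events = raw <= 400.0
    return score, times, events


class TestKaplanScan:
    def test_constant_scores_error(self):
        with pytest.raises(ValidationError, match="no cutpoint"):
            kaplan_scan(np.ones(30), np.arange(30.0), np.ones(30, bool))

    def test_equals_exhaustive_brute_force(self):
        rng = np.random.default_rng(3)
        score, times, events = _cohort(rng, n=60)
        res = kaplan_scan(score, times, events, min_group_fraction=0.1)
        # brute force: every midpoint between consecutive distinct scores
        import math

        s_sorted = np.sort(score)
        n = len(score)
        g_min = max(3, math.ceil(0.1 * n))
        best = None
        n_valid = 0
        for k in range(1, n):
            if s_sorted[k - 1] >= s_sorted[k]:
                continue
            if k < g_min or n - k < g_min:
                continue
            n_valid += 1
            cut = (s_sorted[k - 1] + s_sorted[k]) / 2
            low = score <= cut
            ref = logrank_test(times[low], events[low], times[~low], events[~low])
            if best is None or ref.p_value < best[0]:
                best = (ref.p_value, cut, ref.statistic)
        assert res.n_cutpoints == n_valid
        assert res.p_value == pytest.approx(best[0])
        assert res.cutpoint == pytest.approx(best[1])
        assert res.statistic == pytest.approx(best[2])
        assert res.adjusted_p == pytest.approx(min(best[0] * n_valid, 1.0))

    def test_planted_separation_recovers_gap_cutpoint(self):
        rng = np.random.default_rng(4)
        n = 100
        score = np.concatenate([rng.normal(-3, 0.3, n // 2),
                                rng.normal(3, 0.3, n // 2)])
        # clean separation: every high-score sample fails early, every
        # low-score sample is censored late
        times = np.where(score > 0, rng.uniform(5, 50, n), 1000.0)
        events = score > 0
        res = kaplan_scan(score, times, events)
        assert -2 < res.cutpoint < 2
        assert res.worse_group == "high-score"

    def test_direction_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(5)
        score, times, events = _cohort(rng, n=80)
        a = kaplan_scan(score, times, events)
        b = kaplan_scan(3.5 * score + 11.0, times, events)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.worse_group == b.worse_group
        assert (a.n_low, a.n_high) == (b.n_low, b.n_high)

    def test_family_correction_label(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(8)]
        values = rng.normal(size=(8, 60))
        norm = make_norm(values, tag="standardized", genes=genes)
        _, times, events = _cohort(rng, n=60)
        sets = [GeneSet("s1", frozenset(genes[:4])),
                GeneSet("s2", frozenset(genes[4:]))]
        results = scan_signatures(norm, times, events, sets)
        assert len(results) == 2
        for r in results:
            assert r.correction == "Bonferroni"
            assert r.adjusted_p >= r.p_value


class TestPerGeneScreens:
    def test_anova_f_equals_squared_t_for_two_groups(self):
        rng = np.random.default_rng(7)
        values = rng.lognormal(size=(6, 24))
        norm = make_norm(values, tag="standardized")
        groups = np.array(["high"] * 12 + ["low"] * 12)
        _, results = per_gene_group_differential(norm, groups)
        import scipy.stats

        log_expr = np.log2(values + 1.0)
        for i, res in enumerate(results):
            t, _ = scipy.stats.ttest_ind(log_expr[i, :12], log_expr[i, 12:],
                                         equal_var=True)
            assert res.statistic == pytest.approx(t**2)

    def test_planted_fold_change_assigned_to_high_list(self):
        rng = np.random.default_rng(8)
        values = rng.lognormal(mean=3, size=(30, 40))
        values[0, :20] *= 4  # 4-fold up in the first ("high") half
        norm = make_norm(values, tag="standardized")
        groups = np.array(["high"] * 20 + ["low"] * 20)
        lists, results = per_gene_group_differential(norm, groups)
        assert "g0" in lists["high"]
        # F matched by a direct sum-of-squares decomposition
        log_expr = np.log2(values[0] + 1.0)
        grand = log_expr.mean()
        between = sum(
            20 * (log_expr[g].mean() - grand) ** 2
            for g in (slice(0, 20), slice(20, 40))
        )
        within = sum(
            ((log_expr[g] - log_expr[g].mean()) ** 2).sum()
            for g in (slice(0, 20), slice(20, 40))
        )
        f_ref = (between / 1) / (within / 38)
        assert results[0].statistic == pytest.approx(f_ref)

    def test_identical_group_means_no_discoveries(self):
        values = np.tile(np.arange(10.0)[:, None], (1, 20))
        norm = make_norm(values, tag="standardized")
        groups = np.array(["high"] * 10 + ["low"] * 10)
        lists, _ = per_gene_group_differential(norm, groups)
        assert not lists["high"] and not lists["low"]

    def test_age_correlation_exact_linear_genes(self):
        ages = np.array([10.0, 20, 30, 40, 50])
        values = np.vstack([2 * ages + 1, -3 * ages + 7,
                            np.array([5.0, 1, 4, 2, 3])])
        norm = make_norm(values, tag="standardized")
        lists, results = per_gene_age_correlation(norm, ages)
        by_gene = {r.unit_id: r for r in results}
        assert by_gene["g0"].statistic == pytest.approx(1.0)
        assert by_gene["g1"].statistic == pytest.approx(-1.0)
        assert "g0" in lists["age_direct"] and "g1" in lists["age_inverse"]

    def test_age_correlation_matches_hand_pearson(self):
        ages = np.array([12.0, 30, 7, 44, 25])
        x = np.array([[3.0, 8, 2, 9, 6]])
        norm = make_norm(x, tag="standardized")
        _, results = per_gene_age_correlation(norm, ages)
        xc, ac = x[0] - x[0].mean(), ages - ages.mean()
        r_ref = (xc * ac).sum() / np.sqrt((xc**2).sum() * (ac**2).sum())
        assert results[0].statistic == pytest.approx(r_ref)

    def test_survival_screen_flags_planted_driver(self):
        rng = np.random.default_rng(9)
        n = 100
        driver = rng.normal(size=n)
        lam = np.log(2) / 100.0 * 4.0**driver
        raw = rng.exponential(1 / lam)
        times, events = np.minimum(raw, 500.0), raw <= 500.0
        values = np.vstack([driver, rng.normal(size=(15, n))])
        norm = make_norm(values, tag="standardized")
        lists, results = per_gene_survival_groups(norm, times, events)
        assert "g0" in lists["surv_worse"]
        false = (set(lists["surv_worse"]) | set(lists["surv_better"])) - {"g0"}
        assert len(false) <= 1


class TestLabelEnrichment:
    def test_signature_identical_to_list_is_extreme(self):
        universe = [f"g{i}" for i in range(300)]
        sig = GeneSet("k1", frozenset(universe[:25]))
        lists = {
            "surv_worse": GeneSet("surv_worse", frozenset(universe[:25])),
            "age_direct": GeneSet("age_direct", frozenset(universe[100:140])),
        }
        grid = signature_label_enrichment([sig], lists, universe)
        assert grid["k1"]["surv_worse"].tier == "significant"
        assert grid["k1"]["surv_worse"].fisher_p < grid["k1"]["age_direct"].fisher_p
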