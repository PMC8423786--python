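"""Signature scores, composition tests, deconvolution expectations."""
import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_assignment, make_norm
from sigshare.datatypes import ClinicalTable, GeneSet, ValidationError
from sigshare.scoring import (
    ScoreConfig,
    composition_test,
    expected_cells_from_deconvolution,
    ls_deconvolve,
    signature_score,
)


def _cp10k_matrix(rng, n_genes=120, n_cells=25):
    counts = rng.integers(1, 40, size=(n_genes, n_cells)).astype(float)
    values = counts * (10_000.0 / counts.sum(axis=0))
    return make_norm(values)


class TestSignatureScore:
    def test_background_floor_rule(self):
        rng = np.random.default_rng(0)
        norm = _cp10k_matrix(rng)
        ref = GeneSet("ref", frozenset(norm.gene_ids[:10]))
        res = signature_score(norm, ref, ScoreConfig(seed=1))
        assert len(res.background_genes) == 50
        big = GeneSet("big", frozenset(norm.gene_ids[:60]))
        res_big = signature_score(norm, big, ScoreConfig(seed=1))
        assert len(res_big.background_genes) == 60

    def test_uniform_cell_scores_zero(self):
        values = np.full((100, 3), 7.0)
        norm = make_norm(values)
        ref = GeneSet("ref", frozenset(norm.gene_ids[:8]))
        res = signature_score(norm, ref, ScoreConfig(seed=2))
        assert res.scores == pytest.approx(np.zeros(3))

    def test_matches_manual_recomputation_of_drawn_sets(self):
        rng = np.random.default_rng(3)
        norm = _cp10k_matrix(rng, n_genes=100)
        ref = GeneSet("ref", frozenset(norm.gene_ids[:12]))
        cfg = ScoreConfig(seed=7)
        res = signature_score(norm, ref, cfg)
        gidx = norm.gene_index()
        ref_rows = [gidx[g] for g in sorted(res.reference_genes)]
        bg_rows = [gidx[g] for g in res.background_genes]
        for j, cell in enumerate(norm.cell_ids):
            ref_mean = np.mean([norm.values[i, j] + 1 for i in ref_rows])
            bg_mean = np.mean([norm.values[i, j] + 1 for i in bg_rows])
            assert res.scores[j] == pytest.approx(ref_mean - bg_mean)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        norm = _cp10k_matrix(rng)
        ref = GeneSet("ref", frozenset(norm.gene_ids[:15]))
        r1 = signature_score(norm, ref, ScoreConfig(seed=11))
        r2 = signature_score(norm, ref, ScoreConfig(seed=11))
        assert np.array_equal(r1.scores, r2.scores)
        assert r1.background_genes == r2.background_genes

    def test_translation_invariance_per_cell(self):
        rng = np.random.default_rng(5)
        norm = _cp10k_matrix(rng)
        ref = GeneSet("ref", frozenset(norm.gene_ids[:10]))
        base = signature_score(norm, ref, ScoreConfig(seed=6)).scores
        shifted = make_norm(norm.values + 37.5)
        res = signature_score(shifted, ref, ScoreConfig(seed=6)).scores
        assert res == pytest.approx(base)

    def test_null_reference_mean_near_zero(self):
        rng = np.random.default_rng(6)
        norm = _cp10k_matrix(rng, n_genes=400, n_cells=60)
        means = []
        for seed in range(50):
            pick = np.random.default_rng(seed).choice(norm.gene_ids, 20, replace=False)
            res = signature_score(norm, GeneSet("r", frozenset(pick)),
                                  ScoreConfig(seed=seed))
            means.append(res.scores.mean())
        grand = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(grand) < 3 * se + 1e-9

    def test_validation_errors(self):
        rng = np.random.default_rng(7)
        norm = _cp10k_matrix(rng, n_genes=30)
        with pytest.raises(ValidationError, match="empty reference"):
            signature_score(norm, GeneSet("e", frozenset()))
        with pytest.raises(ValidationError, match="background"):
            signature_score(norm, GeneSet("r", frozenset(norm.gene_ids[:5])))
        logged = make_norm(np.ones((60, 4)), tag="log1p_cp10k")
        with pytest.raises(ValidationError, match="cp10k"):
            signature_score(logged, GeneSet("r", frozenset(logged.gene_ids[:3])))


class TestComposition:
    def test_proportional_split_not_significant(self):
        # each cluster split 40/60 between groups: exact independence
        labels, samples = [], []
        for cl in ("a", "b"):
            for grp, n in (("s_high", 40), ("s_low", 60)):
                labels += [cl] * n
                samples += [grp] * n
        asg = make_assignment(
            labels, samples=samples,
            groups={"s_high": "high", "s_low": "low"},
            cells=[f"c{i}" for i in range(len(labels))],
        )
        results = composition_test(asg)
        assert all(r.direction == "none" for r in results)

    def test_planted_enrichment_detected_and_tables_match_counting(self):
        rng = np.random.default_rng(8)
        labels, samples = [], []
        for i in range(600):
            cl = rng.choice(["a", "b", "c"])
            if cl == "a":
                grp = "s_high" if rng.random() < 0.75 else "s_low"
            else:
                grp = "s_high" if rng.random() < 0.5 else "s_low"
            labels.append(cl)
            samples.append(grp)
        asg = make_assignment(
            labels, samples=samples,
            groups={"s_high": "high", "s_low": "low"},
            cells=[f"c{i}" for i in range(600)],
        )
        results = composition_test(asg)
        by_unit = {r.unit_id: r for r in results}
        assert by_unit["a|high"].direction == "up"
        assert by_unit["a|low"].direction == "down"
        # verify each table against a brute-force recount
        from sigshare.stats import chi_square_yates_2x2

        arr_l, arr_g = np.array(labels), np.array(
            ["high" if s == "s_high" else "low" for s in samples]
        )
        for cl in ("a", "b", "c"):
            for grp in ("high", "low"):
                a = int(((arr_l == cl) & (arr_g == grp)).sum())
                b = int(((arr_l == cl) & (arr_g != grp)).sum())
                c = int(((arr_l != cl) & (arr_g == grp)).sum())
                d = int(((arr_l != cl) & (arr_g != grp)).sum())
                ref = chi_square_yates_2x2([[a, b], [c, d]])
                assert by_unit[f"{cl}|{grp}"].statistic == pytest.approx(ref.statistic)

    def test_requires_two_groups(self):
        asg = make_assignment(["a", "b"], samples=["s", "s"], groups={"s": "high"})
        with pytest.raises(ValidationError, match="2 groups"):
            composition_test(asg)


class TestDeconvolution:
    def test_pure_profile_recovers_unit_weight(self):
        refs = pd.DataFrame(
            {"k1": [10.0, 0, 0], "k2": [0, 10.0, 0], "k3": [0, 0, 10.0]}
        )
        props = ls_deconvolve(refs["k2"].to_numpy(), refs)
        assert props["k2"] == pytest.approx(1.0)
        assert props.sum() == pytest.approx(1.0)

    def test_half_half_mixture_on_orthogonal_profiles(self):
        refs = pd.DataFrame({"k1": [8.0, 0.0], "k2": [0.0, 4.0]})
        bulk = 0.5 * refs["k1"] + 0.5 * refs["k2"]
        props = ls_deconvolve(bulk.to_numpy(), refs)
        assert props.to_numpy() == pytest.approx([0.5, 0.5])

    def test_simplex_contract_on_random_inputs(self):
        rng = np.random.default_rng(9)
        refs = pd.DataFrame(rng.lognormal(size=(50, 4)),
                            columns=["a", "b", "c", "d"])
        for _ in range(5):
            props = ls_deconvolve(rng.lognormal(size=50), refs)
            assert np.all(props.to_numpy() >= 0)
            assert props.sum() == pytest.approx(1.0)

    def test_planted_weights_recovered_on_separated_profiles(self):
        rng = np.random.default_rng(10)
        base = np.zeros((90, 3))
        for k in range(3):
            base[k * 30:(k + 1) * 30, k] = rng.uniform(5, 15, size=30)
        refs = pd.DataFrame(base, columns=["a", "b", "c"])
        w = np.array([0.2, 0.3, 0.5])
        props = ls_deconvolve(base @ w, refs)
        assert np.max(np.abs(props.to_numpy() - w)) < 0.05

    def test_rank_deficiency_warns(self):
        refs = pd.DataFrame({"k1": [1.0, 2.0], "k2": [2.0, 4.0]})
        with pytest.warns(UserWarning, match="rank-deficient"):
            ls_deconvolve(np.array([1.5, 3.0]), refs)


class TestExpectedCells:
    def _clinical(self, groups):
        return ClinicalTable(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(len(groups))],
            "risk_group": groups,
            "age_months": 24.0,
            "efs_days": 100.0,
            "efs_event": 0,
        }))

    def test_expected_count_arithmetic(self):
        # avg 300 nuclei, 10 samples, 20% cluster share -> c=3000, expect 600
        props = pd.DataFrame(
            {"k1": [0.2] * 10, "k2": [0.8] * 10},
            index=[f"s{i}" for i in range(10)],
        )
        clin = self._clinical(["high"] * 10)
        out = expected_cells_from_deconvolution(props, clin, {"high": 300.0})
        assert out.per_group.loc["high", "c"] == pytest.approx(3000.0)
        assert out.expected_counts.loc["high", "k1"] == pytest.approx(600.0)
        total = out.expected_counts.loc["high"].sum()
        assert total == pytest.approx(3000.0 * 1.0)

    def test_zero_percentage_zero_expected(self):
        props = pd.DataFrame({"k1": [0.0] * 10, "k2": [1.0] * 10},
                             index=[f"s{i}" for i in range(10)])
        clin = self._clinical(["low"] * 10)
        out = expected_cells_from_deconvolution(props, clin, {"low": 100.0})
        assert out.expected_counts.loc["low", "k1"] == 0.0

    def test_group_shift_flagged_by_composition_tests(self):
        groups = ["high"] * 10 + ["low"] * 10
        props = pd.DataFrame(
            {"k1": [0.6] * 10 + [0.1] * 10, "k2": [0.4] * 10 + [0.9] * 10},
            index=[f"s{i}" for i in range(20)],
        )
        clin = self._clinical(groups)
        out = expected_cells_from_deconvolution(
            props, clin, {"high": 200.0, "low": 200.0}
        )
        by_unit = {t.unit_id: t for t in out.tests}
        assert by_unit["k1|high"].direction == "up"
        assert by_unit["k1|low"].direction == "down"

    def test_missing_group_average_rejected(self):
        props = pd.DataFrame({"k1": [1.0] * 10}, index=[f"s{i}" for i in range(10)])
        clin = self._clinical(["intermediate"] * 10)
        with pytest.raises(ValidationError, match="average nuclei"):
            expected_cells_from_deconvolution(props, clin, {"high": 10.0})
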