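"""Expression integration: merging, clamping, concordance, GSEA, clustering,
and qPCR quantification helpers."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cotarget import (
    ExpressionRecord,
    FoldChangeMatrix,
    chip_fold_enrichment,
    clamp_fold_changes,
    gsea_enrichment_score,
    gsea_significance,
    hierarchical_cluster,
    merge_experiments,
    relative_expression,
    sign_concordance,
)
from cotarget.errors import UsageError, ValidationError


def _rec(gene, fc, p, exp):
    return ExpressionRecord(gene_id=gene, log2fc=fc, p_value=p, experiment_id=exp)


def _matrix(values: dict[str, list[float]], genes: list[str]) -> FoldChangeMatrix:
    df = pd.DataFrame(values, index=genes)
    return FoldChangeMatrix(values=df, pvalues=df * 0.0)


class TestMergeAndClamp:
    def test_all_significant_drops_gene_failing_one_experiment(self):
        recs = [_rec("g1", 1.0, 0.01, "e1"), _rec("g1", 0.5, 0.2, "e2"),
                _rec("g2", 1.0, 0.01, "e1"), _rec("g2", 0.5, 0.02, "e2")]
        m = merge_experiments(recs, policy="all_significant")
        assert m.genes == ["g2"]

    def test_any_significant_retains_it(self):
        recs = [_rec("g1", 1.0, 0.01, "e1"), _rec("g1", 0.5, 0.2, "e2")]
        m = merge_experiments(recs, policy="any_significant")
        assert m.genes == ["g1"]

    def test_gene_missing_from_one_experiment(self):
        recs = [_rec("g1", 1.0, 0.01, "e1"), _rec("g2", 1.0, 0.01, "e1"),
                _rec("g2", 0.5, 0.02, "e2")]
        all_sig = merge_experiments(recs, policy="all_significant")
        assert all_sig.genes == ["g2"]
        any_sig = merge_experiments(recs, policy="any_significant")
        assert any_sig.genes == ["g1", "g2"]
        assert np.isnan(any_sig.values.loc["g1", "e2"])

    def test_four_experiment_intersection(self):
        recs = [_rec("g1", 1.0, 0.01, f"e{i}") for i in range(4)]
        assert merge_experiments(recs, policy="all_significant").genes == ["g1"]

    def test_bad_alpha_rejected(self):
        with pytest.raises(UsageError):
            merge_experiments([_rec("g", 1, 0.5, "e")], alpha=1.5)

    def test_clamp_examples(self):
        m = _matrix({"e": [3.5, -5.0, 1.2]}, ["a", "b", "c"])
        c = clamp_fold_changes(m, 2.0)
        assert list(c.values["e"]) == [2.0, -2.0, 1.2]
        assert c.clamp_limit == 2.0

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=8))
    def test_clamp_idempotent_and_order_preserving(self, vals):
        m = _matrix({"e": vals}, [f"g{i}" for i in range(len(vals))])
        once = clamp_fold_changes(m)
        twice = clamp_fold_changes(once)
        assert once.values.equals(twice.values)
        order = np.argsort(m.values["e"].to_numpy(), kind="stable")
        clamped = once.values["e"].to_numpy()
        assert all(clamped[i] <= clamped[j]
                   for i, j in zip(order, order[1:]))


class TestSignConcordance:
    def test_eight_of_ten_concordant(self):
        x = [1.0] * 10
        y = [1.0] * 8 + [-1.0] * 2
        m = _matrix({"ex": x, "ey": y}, [f"g{i}" for i in range(10)])
        res = sign_concordance(m, "ex", "ey")
        assert (res.n_concordant, res.n_discordant) == (8, 2)
        assert res.binomial_p_two_sided == pytest.approx(112 / 1024, rel=1e-12)

    def test_all_concordant_n5(self):
        m = _matrix({"x": [1.0] * 5, "y": [2.0] * 5}, [f"g{i}" for i in range(5)])
        res = sign_concordance(m, "x", "y")
        assert res.binomial_p_two_sided == pytest.approx(2 / 32, rel=1e-12)

    def test_convention_flip_swaps_counts(self):
        m = _matrix({"x": [1, 1, 1, -1], "y": [1, 1, -1, -1]},
                    [f"g{i}" for i in range(4)])
        plain = sign_concordance(m, "x", "y", (1, 1))
        flipped = sign_concordance(m, "x", "y", (-1, 1))
        assert (plain.n_concordant, plain.n_discordant) == (
            flipped.n_discordant, flipped.n_concordant)

    def test_zeros_excluded(self):
        m = _matrix({"x": [0.0, 1.0], "y": [1.0, 1.0]}, ["g1", "g2"])
        res = sign_concordance(m, "x", "y")
        assert res.n_total == 2 and res.n_concordant + res.n_discordant == 1

    def test_all_zero_rejected(self):
        m = _matrix({"x": [0.0], "y": [0.0]}, ["g1"])
        with pytest.raises(ValidationError):
            sign_concordance(m, "x", "y")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exact_enumeration_up_to_n15(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 16))
        x = rng.choice([-1.0, 1.0], n)
        y = rng.choice([-1.0, 1.0], n)
        m = _matrix({"x": x, "y": y}, [f"g{i}" for i in range(n)])
        res = sign_concordance(m, "x", "y")
        k = res.n_concordant
        # two-sided exact binomial by summing outcomes as/more extreme than k
        pk = Fraction(comb(n, k), 2**n)
        p = sum(Fraction(comb(n, j), 2**n) for j in range(n + 1)
                if Fraction(comb(n, j), 2**n) <= pk)
        assert res.binomial_p_two_sided == pytest.approx(float(p), rel=1e-9)


def brute_force_running_sum(ranked, gene_set, weight):
    """Independent re-derivation of the weighted KS running sum."""
    genes = [g for g, _ in ranked]
    scores = [s for _, s in ranked]
    hits = [g in gene_set for g in genes]
    denom_hit = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    n_miss = sum(1 for h in hits if not h)
    total, path = 0.0, []
    for s, h in zip(scores, hits):
        if h:
            total += (abs(s) ** weight) / denom_hit if denom_hit > 0 else 1.0 / sum(hits)
        else:
            total -= 1.0 / n_miss
        path.append(total)
    max_dev, min_dev = max(max(path), 0.0), min(min(path), 0.0)
    best = max_dev if max_dev >= -min_dev - 1e-12 else min_dev
    return best, path


class TestGseaEnrichmentScore:
    def test_single_member_ranked_first_weight_zero(self):
        ranked = [("a", 4.0), ("b", 3.0), ("c", 2.0), ("d", 1.0)]
        es, _ = gsea_enrichment_score(ranked, {"a"}, weight_exponent=0)
        assert es == pytest.approx(1.0)

    def test_single_member_ranked_last_weight_zero(self):
        ranked = [("a", 4.0), ("b", 3.0), ("c", 2.0), ("d", 1.0)]
        es, _ = gsea_enrichment_score(ranked, {"d"}, weight_exponent=0)
        assert es == pytest.approx(-1.0)

    def test_worked_running_sum(self):
        ranked = [("g1", 5.0), ("g2", 4.0), ("g3", 3.0), ("g4", 2.0), ("g5", 1.0)]
        es, rs = gsea_enrichment_score(ranked, {"g1", "g4"}, weight_exponent=1)
        assert es == pytest.approx(5 / 7, rel=1e-12)
        assert rs == pytest.approx([5 / 7, 5 / 7 - 1 / 3, 5 / 7 - 2 / 3,
                                    5 / 7 - 2 / 3 + 2 / 7, 0.0], abs=1e-12)

    def test_reversing_ranking_negates_es_at_weight_zero(self):
        rng = np.random.default_rng(0)
        scores = np.sort(rng.normal(size=20))[::-1]
        ranked = [(f"g{i}", float(s)) for i, s in enumerate(scores)]
        gs = {"g1", "g5", "g6"}
        es_fwd, _ = gsea_enrichment_score(ranked, gs, weight_exponent=0)
        es_rev, _ = gsea_enrichment_score(ranked[::-1], gs, weight_exponent=0)
        assert es_fwd == pytest.approx(-es_rev, rel=1e-12)

    @pytest.mark.parametrize("weight", [0.0, 1.0, 1.5])
    def test_matches_brute_force_oracle(self, weight):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            scores = np.sort(rng.normal(size=n))[::-1]
            ranked = [(f"g{i}", float(s)) for i, s in enumerate(scores)]
            size = int(rng.integers(1, n))
            gs = {f"g{i}" for i in rng.choice(n, size=size, replace=False)}
            es, rs = gsea_enrichment_score(ranked, gs, weight_exponent=weight)
            es_bf, rs_bf = brute_force_running_sum(ranked, gs, weight)
            assert es == pytest.approx(es_bf, abs=1e-12)
            assert rs == pytest.approx(rs_bf, abs=1e-12)
            assert -1.0 <= es <= 1.0

    def test_invalid_gene_sets_rejected(self):
        ranked = [("a", 2.0), ("b", 1.0)]
        with pytest.raises(ValidationError):
            gsea_enrichment_score(ranked, set())
        with pytest.raises(ValidationError):
            gsea_enrichment_score(ranked, {"a", "b"})


class TestGseaSignificance:
    def _ranking(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        return [(f"g{i}", float(s)) for i, s in enumerate(scores)], rng

    def test_planted_top_set_is_significant(self):
        ranked, _ = self._ranking(400, 1)
        planted = {f"g{i}" for i in range(20)}
        (res,) = gsea_significance(ranked, {"planted": planted},
                                   n_permutations=500, seed=2)
        assert res.fdr_q < 0.05 and res.p_nominal < 0.05
        assert res.nes > 1.0
        assert set(res.leading_edge) <= planted

    def test_fixed_seed_reproducible(self):
        ranked, rng = self._ranking(100, 3)
        gs = {"sets": {f"g{i}" for i in rng.choice(100, 10, replace=False)}}
        r1 = gsea_significance(ranked, gs, n_permutations=200, seed=5)
        r2 = gsea_significance(ranked, gs, n_permutations=200, seed=5)
        assert r1 == r2

    def test_oversized_set_warns(self):
        ranked, _ = self._ranking(20, 4)
        big = {f"g{i}" for i in range(15)}
        with pytest.warns(UserWarning, match="half"):
            gsea_significance(ranked, {"big": big}, n_permutations=20, seed=1)

    def test_bh_alternative(self):
        ranked, rng = self._ranking(200, 6)
        sets = {"planted": {f"g{i}" for i in range(10)},
                "random": {f"g{i}" for i in rng.choice(200, 10, replace=False)}}
        res = gsea_significance(ranked, sets, n_permutations=200, seed=7,
                                fdr_method="bh")
        by_id = {r.gene_set_id: r for r in res}
        assert by_id["planted"].fdr_q < by_id["random"].fdr_q


class TestClustering:
    def test_identical_rows_merge_at_zero_height(self):
        m = _matrix({"e1": [1.0, 1.0, 5.0], "e2": [2.0, 2.0, -1.0]},
                    ["g1", "g2", "g3"])
        d = hierarchical_cluster(m, metric="euclidean")
        assert d.merges[0][:2] == (0, 1) and d.merges[0][2] == 0.0

    def test_three_point_average_linkage(self):
        m = _matrix({"e": [0.0, 1.0, 10.0]}, ["a", "b", "c"])
        d = hierarchical_cluster(m, metric="euclidean")
        assert d.merges[0] == (0, 1, 1.0)
        assert d.merges[1][2] == pytest.approx(9.5)

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            hierarchical_cluster(_matrix({"e": [1.0]}, ["g1"]), metric="euclidean")

    def test_constant_row_under_correlation_names_gene(self):
        m = _matrix({"e1": [1.0, 1.0], "e2": [1.0, 2.0]}, ["flat", "ok"])
        with pytest.raises(ValidationError, match="flat"):
            hierarchical_cluster(m, metric="one_minus_pearson")

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(9)
        m = _matrix({f"e{j}": rng.normal(size=12).tolist() for j in range(4)},
                    [f"g{i}" for i in range(12)])
        d = hierarchical_cluster(m, metric="euclidean")
        heights = [h for _, _, h in d.merges]
        assert all(a <= b for a, b in zip(heights, heights[1:]))
        assert sorted(d.leaf_order) == sorted(m.genes)


class TestQpcrHelpers:
    def test_relative_expression(self):
        assert relative_expression(20, 20, 20, 20) == pytest.approx(1.0)
        assert relative_expression(21, 20, 20, 20) == pytest.approx(0.5)
        assert relative_expression(18, 20, 20, 20) == pytest.approx(4.0)

    def test_chip_fold_enrichment(self):
        assert chip_fold_enrichment(20, 22, 20, 22) == pytest.approx(1.0)
        assert chip_fold_enrichment(19, 22, 22, 22) == pytest.approx(8.0)
        fwd = chip_fold_enrichment(19, 22, 21, 22)
        rev = chip_fold_enrichment(21, 22, 19, 22)
        assert fwd == pytest.approx(1 / rev)
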