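"""Enrichment score, permutation null, NES/p/FDR semantics."""

import numpy as np
import pytest

import crosscell as cc
from crosscell.errors import ParameterError
from crosscell.gsea import GseaCellResult, RankedList, nes_p_fdr

from conftest import brute_es, make_dataset


def ranked(symbols, scores, **kw):
    return RankedList(symbols=np.array(symbols, dtype=object), scores=np.array(scores, float),
                      class_a=kw.get("class_a", "X"), class_b=kw.get("class_b", "Y"))


def gene_set(*symbols):
    return cc.GeneSet(name="s", symbols=frozenset(symbols))


class TestRankGenes:
    def _two_class(self, a_vals, b_vals, genes=("g1",)):
        cts = {f"a{i}": "X" for i in range(len(a_vals))} | {f"b{i}": "Y" for i in range(len(b_vals))}
        vals = {g: list(a_vals) + list(b_vals) for g in genes}
        return make_dataset(vals, cts)

    def test_log2fc_of_class_means(self):
        ds = self._two_class([8.0, 8.0], [2.0, 2.0])
        rl = cc.rank_genes(ds, "X", "Y", metric="log2fc")
        assert rl.scores[0] == pytest.approx(2.0)

    def test_ties_break_lexicographically(self):
        ds = self._two_class([4.0, 4.0, 4.0], [4.0, 4.0, 4.0], genes=("gB", "gA", "gC"))
        rl = cc.rank_genes(ds, "X", "Y")
        assert np.all(rl.scores == 0)
        assert list(rl.symbols) == ["gA", "gB", "gC"]

    def test_fallback_to_log2fc_below_three_replicates(self):
        ds = self._two_class([8.0, 8.0], [2.0, 2.0])
        rl = cc.rank_genes(ds, "X", "Y", metric="signal2noise")
        assert rl.metric_used == "log2fc"

    def test_signal2noise_with_floor_matches_recomputation(self):
        rng = np.random.default_rng(2)
        cts = {f"a{i}": "X" for i in range(4)} | {f"b{i}": "Y" for i in range(4)}
        vals = {f"g{i:02d}": list(rng.uniform(1, 100, 8)) for i in range(30)}
        ds = make_dataset(vals, cts)
        rl = cc.rank_genes(ds, "X", "Y", metric="signal2noise")
        assert rl.metric_used == "signal2noise"
        # recompute independently, gene by gene
        recomputed = {}
        for g, row in vals.items():
            a, b = np.array(row[:4]), np.array(row[4:])
            sa = max(a.std(ddof=1), 0.2 * abs(a.mean()), 0.2)
            sb = max(b.std(ddof=1), 0.2 * abs(b.mean()), 0.2)
            recomputed[g] = (a.mean() - b.mean()) / (sa + sb)
        expected_order = sorted(recomputed, key=lambda g: (-recomputed[g], g))
        assert list(rl.symbols) == expected_order
        for sym, sc in zip(rl.symbols, rl.scores):
            assert sc == pytest.approx(recomputed[sym])

    def test_class_swap_negates_scores(self):
        rng = np.random.default_rng(9)
        cts = {f"a{i}": "X" for i in range(3)} | {f"b{i}": "Y" for i in range(3)}
        vals = {f"g{i:02d}": list(rng.uniform(1, 50, 6)) for i in range(20)}
        ds = make_dataset(vals, cts)
        fwd = cc.rank_genes(ds, "X", "Y")
        rev = cc.rank_genes(ds, "Y", "X")
        fwd_scores = dict(zip(fwd.symbols, fwd.scores))
        for sym, sc in zip(rev.symbols, rev.scores):
            assert sc == pytest.approx(-fwd_scores[sym])

    def test_unknown_class_rejected(self):
        ds = self._two_class([1.0], [2.0])
        with pytest.raises(ParameterError):
            cc.rank_genes(ds, "X", "Zzz")


class TestEnrichmentScore:
    def test_single_top_hit_scores_one(self):
        rl = ranked(["a", "b", "c", "d"], [4, 3, 2, 1])
        res = cc.enrichment_score(rl, gene_set("a"))
        assert res.es == pytest.approx(1.0)
        assert res.peak_index == 1

    def test_single_bottom_hit(self):
        # P_miss reaches (N - n_hits)/(N - n_hits) = 1 just before the hit,
        # so the signed extreme deviation is -1 for a lone bottom-ranked hit
        rl = ranked(["a", "b", "c", "d"], [4, 3, 2, 1])
        res = cc.enrichment_score(rl, gene_set("d"))
        assert res.es == pytest.approx(-1.0)
        oracle, _ = brute_es([4, 3, 2, 1], {"d"}, ["a", "b", "c", "d"])
        assert res.es == oracle

    def test_no_overlap_is_na_not_error(self):
        rl = ranked(["a", "b"], [2, 1])
        assert cc.enrichment_score(rl, gene_set("zz")) is None

    def test_full_coverage_rejected(self):
        rl = ranked(["a", "b"], [2, 1])
        with pytest.raises(ParameterError, match="entire"):
            cc.enrichment_score(rl, gene_set("a", "b"))

    def test_matches_enumeration_oracle_exactly(self):
        rng = np.random.default_rng(55)
        for _ in range(300):
            n = int(rng.integers(5, 51))
            syms = [f"g{i:02d}" for i in range(n)]
            scores = np.sort(rng.normal(0, 2, n))[::-1]
            k = int(rng.integers(1, min(10, n - 1) + 1))
            members = set(rng.choice(syms, size=k, replace=False))
            p = float(rng.choice([0.0, 1.0, 2.0]))
            res = cc.enrichment_score(ranked(syms, scores), frozenset(members), p=p)
            oracle, running = brute_es(list(scores), members, syms, p=p)
            assert res.es == oracle  # float-identical
            assert np.allclose(res.running_sum, running)
            assert -1.0 <= res.es <= 1.0

    def test_weight_zero_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        syms = [f"g{i:02d}" for i in range(30)]
        scores = np.sort(rng.normal(0, 1, 30))[::-1]
        members = frozenset(rng.choice(syms, 6, replace=False))
        es1 = cc.enrichment_score(ranked(syms, scores), members, p=0.0).es
        es2 = cc.enrichment_score(ranked(syms, np.exp(scores)), members, p=0.0).es
        assert es1 == pytest.approx(es2)


class TestPermutationNull:
    def test_deterministic_given_seed(self):
        rl = ranked([f"g{i:02d}" for i in range(40)], np.linspace(3, -3, 40))
        a = cc.permutation_null(rl, 5, 150, seed=42)
        b = cc.permutation_null(rl, 5, 150, seed=42)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, cc.permutation_null(rl, 5, 150, seed=43))

    def test_symmetric_under_constant_scores(self):
        rl = ranked([f"g{i:02d}" for i in range(50)], np.zeros(50))
        null = cc.permutation_null(rl, 6, 4000, seed=1)
        assert abs(np.mean(null > 0) - 0.5) < 0.03

    def test_mean_abs_matches_independent_resampling(self):
        rng = np.random.default_rng(77)
        syms = [f"g{i:03d}" for i in range(100)]
        scores = np.sort(rng.normal(0, 1, 100))[::-1]
        rl = ranked(syms, scores)
        null = cc.permutation_null(rl, 5, 10000, seed=3)
        # independent brute-force resampling oracle
        oracle_rng = np.random.default_rng(999)
        oracle = []
        for _ in range(4000):
            members = set(oracle_rng.choice(syms, 5, replace=False))
            es, _ = brute_es(list(scores), members, syms)
            oracle.append(abs(es))
        se = np.std(oracle) / np.sqrt(len(oracle))
        assert abs(np.mean(np.abs(null)) - np.mean(oracle)) < 2 * se + np.std(np.abs(null)) / np.sqrt(len(null)) * 2

    def test_invalid_set_size_rejected(self):
        rl = ranked(["a", "b", "c"], [3, 2, 1])
        with pytest.raises(ParameterError):
            cc.permutation_null(rl, 3, 200, seed=0)


class TestNesPFdr:
    def _cell(self, es, name="s", a="X", b="Y"):
        c = GseaCellResult(geneset_name=name, class_a=a, class_b=b)
        c.es = es
        c.n_hits = 5
        return c

    def test_boundary_p_value(self):
        null = np.concatenate([np.full(400, 0.2), np.full(599, -0.2)])
        cell = self._cell(0.9)
        (out,) = nes_p_fdr([cell], {("s", "X", "Y"): null})
        assert out.p_value == pytest.approx(1 / 401)  # (1+0)/(1+400)

    def test_single_cell_q_hand_computed(self):
        # 10-value symmetric null; observed ES above 4 of 5 same-sign values.
        null = np.array([0.1, 0.2, 0.3, 0.4, 0.5, -0.1, -0.2, -0.3, -0.4, -0.5])
        cell = self._cell(0.45)
        (out,) = nes_p_fdr([cell], {("s", "X", "Y"): null})
        mean_pos = 0.3
        assert out.nes == pytest.approx(0.45 / mean_pos)
        # null NES >= |NES*|: only 0.5/0.3; observed fraction = 1 (itself)
        assert out.fdr_q == pytest.approx((1 / 5) / 1.0)
        assert out.p_value == pytest.approx((1 + 1) / (1 + 5))

    def test_nes_sign_follows_es(self):
        null = np.array([0.2, 0.4, -0.2, -0.4] * 50)
        pos = self._cell(0.5, name="p")
        neg = self._cell(-0.5, name="n")
        out = nes_p_fdr([pos, neg], {("p", "X", "Y"): null, ("n", "X", "Y"): null})
        assert out[0].nes > 0 > out[1].nes
        assert abs(out[0].nes) == pytest.approx(abs(out[1].nes))

    def test_no_same_sign_null_flags_na(self):
        null = np.full(100, -0.3)
        cell = self._cell(0.5)
        (out,) = nes_p_fdr([cell], {("s", "X", "Y"): null})
        assert out.status == "na"
        assert np.isnan(out.nes)

    def test_q_clipped_to_unit_interval(self):
        rng = np.random.default_rng(6)
        cells, nulls = [], {}
        for i in range(20):
            c = self._cell(float(rng.normal(0, 0.3)), name=f"s{i}")
            cells.append(c)
            nulls[(f"s{i}", "X", "Y")] = rng.normal(0, 0.3, 200)
        out = nes_p_fdr(cells, nulls)
        for c in out:
            if c.status == "ok":
                assert 0.0 <= c.fdr_q <= 1.0
                assert 0.0 < c.p_value <= 1.0
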