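"""Probe collapsing, gene filters, centering/reduction, and merging."""

import numpy as np
import pandas as pd
import pytest

import crosscell as cc
from crosscell.errors import ParameterError, PipelineError

from conftest import make_dataset, random_dataset


def omap_for(features: dict[str, str | None], species="sp"):
    return cc.OrthologyMap(
        [cc.OrthologyRecord(species, f, sym, True) for f, sym in features.items()]
    )


class TestCollapseProbes:
    def test_max_sum_probe_wins(self):
        ds = make_dataset(
            {"p1": [5.0, 5.0], "p2": [6.0, 6.0]},
            {"s1": "A", "s2": "B"},
            level="probe",
        )
        out = cc.collapse_probes(ds, omap_for({"p1": "G1", "p2": "G1"}))
        assert list(out.values.index) == ["G1"]
        assert list(out.values.loc["G1"]) == [6.0, 6.0]
        assert out.level == "gene"

    def test_tie_breaks_to_smaller_probe_id(self):
        ds = make_dataset(
            {"pB": [5.0, 5.0], "pA": [4.0, 6.0]},
            {"s1": "A", "s2": "B"},
            level="probe",
        )
        out = cc.collapse_probes(ds, omap_for({"pA": "G1", "pB": "G1"}))
        assert list(out.values.loc["G1"]) == [4.0, 6.0]  # pA wins the 10-10 tie

    def test_unmapped_probes_dropped_or_kept(self):
        ds = make_dataset(
            {"p1": [5.0, 5.0], "px": [9.0, 9.0]},
            {"s1": "A", "s2": "B"},
            level="probe",
        )
        omap = omap_for({"p1": "G1", "px": None})
        assert list(cc.collapse_probes(ds, omap).values.index) == ["G1"]
        kept = cc.collapse_probes(ds, omap, keep_unmapped=True)
        assert list(kept.values.index) == ["G1", "px"]

    def test_matches_argmax_oracle(self):
        rng = np.random.default_rng(13)
        probes, mapping = {}, {}
        for g in range(25):
            for p in range(int(rng.integers(1, 4))):
                pid = f"g{g:02d}p{p}"
                probes[pid] = list(rng.uniform(1, 100, 6))
                mapping[pid] = f"GENE{g:02d}"
        cts = {f"s{i}": ct for i, ct in enumerate(["A"] * 3 + ["B"] * 3)}
        ds = make_dataset(probes, cts, level="probe")
        out = cc.collapse_probes(ds, omap_for(mapping))
        for gene in out.values.index:
            candidates = [p for p, sym in mapping.items() if sym == gene]
            best = max(candidates, key=lambda p: (sum(probes[p]), tuple(-ord(c) for c in p)))
            assert list(out.values.loc[gene]) == probes[best]


class TestOrthologyFilter:
    def _ds(self, genes, species):
        return make_dataset(
            {g: [1.0, 2.0] for g in genes}, {"s1": "A", "s2": "B"}, species_id=species
        )

    def test_intersection_and_common_order(self):
        out = cc.orthology_filter(
            [self._ds("ABC", "x"), self._ds("BCD", "y"), self._ds("BC", "z")]
        )
        for ds in out:
            assert list(ds.values.index) == ["B", "C"]

    def test_empty_intersection_raises_with_counts(self):
        with pytest.raises(PipelineError, match="counts"):
            cc.orthology_filter([self._ds("AB", "x"), self._ds("CD", "y")])


class TestDegFilter:
    def test_retained_above_strict_twofold(self):
        ds = make_dataset(
            {"kept": [12.0, 11.0, 4.0, 5.0], "boundary": [10.0, 10.0, 4.0, 5.0]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        out = cc.deg_filter(ds, fold=2.0)
        assert "kept" in out        # 11/5 = 2.2 > 2
        assert "boundary" not in out  # 10/5 = 2.0, strict boundary

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(19)
        ds = random_dataset(rng, n_genes=100)
        out = cc.deg_filter(ds, fold=2.0)
        cts = ds.cell_types
        expected = set()
        for gene in ds.values.index:
            best = -np.inf
            for x in cts:
                for y in cts:
                    if x == y:
                        continue
                    xv = [ds.values.at[gene, s] for s in ds.samples_of(x)]
                    yv = [ds.values.at[gene, s] for s in ds.samples_of(y)]
                    best = max(best, min(xv) / max(yv))
            if best > 2.0:
                expected.add(gene)
        assert out == expected

    def test_means_variant(self):
        ds = make_dataset(
            {"g": [12.0, 8.0, 4.0, 5.0]},  # means 10 vs 4.5 -> 2.22; extremes 8/5 = 1.6
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        assert cc.deg_filter(ds, fold=2.0, pair_stat="means") == {"g"}
        assert cc.deg_filter(ds, fold=2.0, pair_stat="extremes") == set()

    def test_single_cell_type_rejected(self):
        ds = make_dataset({"g": [1.0, 2.0]}, {"s1": "A", "s2": "A"})
        with pytest.raises(ParameterError):
            cc.deg_filter(ds)


class TestDegIntersectionAndCenter:
    def test_plain_intersection(self):
        assert cc.deg_intersection([{"A", "B", "C"}, {"B", "C"}, {"B", "C", "D"}]) == {"B", "C"}

    def test_disjoint_sets_error(self):
        with pytest.raises(PipelineError):
            cc.deg_intersection([{"A"}, {"B"}])

    def test_center_reduce_row(self):
        ds = make_dataset({"g": [1.0, 2.0, 3.0]}, {"s1": "A", "s2": "B", "s3": "C"})
        out = cc.center_reduce(ds)
        assert list(out.loc["g"]) == [-1.0, 0.0, 1.0]

    def test_constant_row_rejected(self):
        ds = make_dataset({"g": [2.0, 2.0, 2.0]}, {"s1": "A", "s2": "B", "s3": "C"})
        with pytest.raises(PipelineError, match="zero-variance"):
            cc.center_reduce(ds)

    def test_mean_variance_invariants_and_idempotence(self):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, n_genes=50)
        out = cc.center_reduce(ds)
        arr = out.to_numpy()
        assert np.abs(arr.mean(axis=1)).max() < 1e-12
        assert np.abs(arr.var(axis=1, ddof=1) - 1).max() < 1e-12
        again = cc.center_reduce(ds.with_values(out - out.to_numpy().min() + 1.0))
        # shifting to positivity then re-centering returns the same block
        assert np.allclose(again.to_numpy(), arr)


class TestMergeAndPipeline:
    def test_merge_concatenates_with_species_prefix(self):
        a = make_dataset({"G1": [1.0, 2.0], "G2": [3.0, 4.0]}, {"s1": "A", "s2": "B"}, species_id="Oa")
        b = make_dataset({"G1": [5.0, 6.0], "G2": [7.0, 8.0]}, {"t1": "A", "t2": "B"}, species_id="Hs")
        merged = cc.merge([(a, cc.center_reduce(a)), (b, cc.center_reduce(b))])
        assert list(merged.values.columns) == ["Oa_s1", "Oa_s2", "Hs_t1", "Hs_t2"]
        assert merged.species_ids == ["Oa", "Hs"]

    def test_symbol_mismatch_rejected(self):
        a = make_dataset({"G1": [1.0, 2.0]}, {"s1": "A", "s2": "B"}, species_id="x")
        b = make_dataset({"G9": [1.0, 2.0]}, {"t1": "A", "t2": "B"}, species_id="y")
        with pytest.raises(PipelineError, match="mismatch"):
            cc.merge([(a, a.values), (b, b.values)])

    def test_provenance_counts_match_recounts(self, default_synthetic):
        data = default_synthetic
        merged = cc.cross_normalize(list(data.datasets.values()), data.orthology)
        prov = merged.provenance
        gene_level = [cc.collapse_probes(ds, data.orthology) for ds in data.datasets.values()]
        common = set(gene_level[0].values.index)
        for ds in gene_level[1:]:
            common &= set(ds.values.index)
        assert prov["after_orthology_filter"] == len(common)
        assert prov["after_deg_intersection"] == merged.values.shape[0]
        assert prov["merged_samples"] == merged.values.shape[1]
        # non-increasing counts through the pipeline
        assert prov["after_deg_intersection"] <= prov["after_orthology_filter"]
        assert prov["after_orthology_filter"] <= min(prov["input_genes"].values())

    def test_sample_order_invariance_up_to_column_permutation(self, default_synthetic):
        data = default_synthetic
        datasets = list(data.datasets.values())
        shuffled = []
        rng = np.random.default_rng(0)
        for ds in datasets:
            order = list(rng.permutation(len(ds.samples)))
            samples = [ds.samples[i] for i in order]
            cols = [s.sample_id for s in samples]
            shuffled.append(
                cc.ExpressionDataset(
                    species_id=ds.species_id, values=ds.values[cols], samples=samples, level=ds.level
                )
            )
        m1 = cc.cross_normalize(datasets, data.orthology)
        m2 = cc.cross_normalize(shuffled, data.orthology)
        assert set(m1.values.columns) == set(m2.values.columns)
        pd.testing.assert_frame_equal(m1.values, m2.values[m1.values.columns])

    def test_subset_mode_refilters_degs(self, default_synthetic):
        data = default_synthetic
        full = cc.cross_normalize(list(data.datasets.values()), data.orthology)
        focused = cc.cross_normalize(
            list(data.datasets.values()), data.orthology, cell_types=["B", "pDC"]
        )
        assert set(focused.sample_cell_types.values()) == {"B", "pDC"}
        # focusing on two cell types re-selects genes: only their contrast counts
        assert set(focused.symbols) != set(full.symbols)
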