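"""Five-step cross-species normalization producing one merged matrix.

1. probe collapsing + Orthology Filter — one representative probe per gene
   (the probe with the highest total signal across samples), then keep only
   genes represented on every species' platform;
2. DEG Filter — per species, keep genes differentially expressed between at
   least two cell types by a conservative pairwise fold rule;
3. DEG intersection — genes modulated in EVERY species;
4. centering/reduction — per species and per gene, mean 0 and variance 1,
   so the dynamic ranges become comparable across platforms;
5. merge — column-concatenate the per-species blocks aligned on symbols,
   prefixing sample labels with the species id.

Steps 2-3 exist to protect step 4: standardizing an unregulated gene would
amplify pure noise into artifactual structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, PipelineError
from .io import ExpressionDataset, OrthologyMap, SampleAnnotation

__all__ = [
    "MergedDataset",
    "collapse_probes",
    "orthology_filter",
    "deg_filter",
    "deg_intersection",
    "center_reduce",
    "merge",
    "cross_normalize",
]


@dataclass
class MergedDataset:
    """Cross-normalized genes x samples matrix spanning all species.

    Columns are labelled ``<species>_<sample_id>``; per species block and per
    gene, the values have mean 0 and (n-1)-denominator variance 1.
    ``provenance`` records the gene count surviving each pipeline step.
    """

    values: pd.DataFrame
    samples: list[tuple[str, SampleAnnotation]]  # (species_id, annotation)
    provenance: dict[str, object] = field(default_factory=dict)

    @property
    def symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def species_ids(self) -> list[str]:
        seen: list[str] = []
        for sp, _ in self.samples:
            if sp not in seen:
                seen.append(sp)
        return seen

    def columns_of_species(self, species_id: str) -> list[str]:
        return [
            f"{sp}_{ann.sample_id}" for sp, ann in self.samples if sp == species_id
        ]

    @property
    def sample_cell_types(self) -> dict[str, str]:
        """Merged column label -> cell-type label (ground-truth-style partition)."""
        return {f"{sp}_{ann.sample_id}": ann.cell_type for sp, ann in self.samples}


def collapse_probes(
    dataset: ExpressionDataset, omap: OrthologyMap, keep_unmapped: bool = False
) -> ExpressionDataset:
    """Keep one probe per gene: the probe with the highest total signal.

    Multi-probe genes are collapsed to the row of their maximal-row-sum probe
    (values copied, never averaged); ties break toward the lexicographically
    smallest probe id.  Probes with no mapped gene are dropped, or kept under
    their native id when ``keep_unmapped`` (the convention for translating a
    test dataset into reference symbol space before GSEA).
    """
    sums = dataset.values.sum(axis=1)
    best: dict[str, str] = {}  # symbol -> winning probe id
    unmapped: list[str] = []
    for probe in dataset.values.index:
        sym = omap.symbol_for(dataset.species_id, probe)
        if sym is None:
            unmapped.append(probe)
            continue
        cur = best.get(sym)
        if (
            cur is None
            or sums[probe] > sums[cur]
            or (sums[probe] == sums[cur] and probe < cur)
        ):
            best[sym] = probe
    rows = sorted(best)
    probes = [best[s] for s in rows]
    if keep_unmapped:
        rows = rows + sorted(unmapped)
        probes = probes + sorted(unmapped)
    values = dataset.values.loc[probes].copy()
    values.index = rows
    return ExpressionDataset(
        species_id=dataset.species_id,
        values=values,
        samples=list(dataset.samples),
        level="gene",
    )


def orthology_filter(
    datasets: Sequence[ExpressionDataset],
) -> list[ExpressionDataset]:
    """Keep only genes represented in every species, in one common order."""
    if len(datasets) < 2:
        raise ParameterError("orthology filter needs at least 2 datasets")
    common: set[str] | None = None
    for ds in datasets:
        syms = set(ds.values.index)
        common = syms if common is None else common & syms
    if not common:
        counts = {ds.species_id: ds.n_features for ds in datasets}
        raise PipelineError(f"orthology filter left no common gene; per-species counts: {counts}")
    order = sorted(common)
    return [ds.with_values(ds.values.loc[order].copy()) for ds in datasets]


def deg_filter(
    dataset: ExpressionDataset, fold: float = 2.0, pair_stat: str = "extremes"
) -> set[str]:
    """Genes differentially expressed between at least two cell types.

    For every ordered cell-type pair (X, Y) the conservative fold
    r(X, Y) = min over X replicates / max over Y replicates is computed
    (``pair_stat='means'`` substitutes the ratio of cell-type means); a gene
    is retained iff its best ordered-pair ratio is STRICTLY above ``fold``.
    """
    cell_types = dataset.cell_types
    if len(cell_types) < 2:
        raise ParameterError("DEG filter needs at least 2 cell types")
    if pair_stat not in ("extremes", "means"):
        raise ParameterError(f"unknown pair_stat {pair_stat!r}")

    lo = {}
    hi = {}
    for ct in cell_types:
        cols = dataset.samples_of(ct)
        block = dataset.values[cols].to_numpy(dtype=float)
        if pair_stat == "extremes":
            lo[ct] = block.min(axis=1)
            hi[ct] = block.max(axis=1)
        else:
            lo[ct] = hi[ct] = block.mean(axis=1)

    n = dataset.n_features
    best = np.full(n, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        for x in cell_types:
            for y in cell_types:
                if x == y:
                    continue
                r = np.divide(lo[x], hi[y])
                r = np.where(np.isnan(r), -np.inf, r)  # 0/0: not evidence of DE
                best = np.maximum(best, r)
    keep = best > fold
    return set(np.asarray(dataset.values.index, dtype=object)[keep])


def deg_intersection(per_species_deg: Sequence[set[str]]) -> set[str]:
    """Genes modulated in every species (plain intersection)."""
    if len(per_species_deg) < 2:
        raise ParameterError("DEG intersection needs at least 2 species lists")
    out = set(per_species_deg[0])
    for s in per_species_deg[1:]:
        out &= set(s)
    if not out:
        counts = [len(s) for s in per_species_deg]
        raise PipelineError(f"empty DEG intersection; per-species DEG counts: {counts}")
    return out


def center_reduce(dataset: ExpressionDataset, symbols: Iterable[str] | None = None) -> pd.DataFrame:
    """Standardize each gene to mean 0, variance 1 over the species' samples.

    Uses the sample standard deviation (n-1 denominator).  Returns a plain
    DataFrame block: standardized values are signed and live outside the
    linear-intensity container.
    """
    values = dataset.values
    if symbols is not None:
        order = sorted(symbols)
        missing = set(order) - set(values.index)
        if missing:
            raise PipelineError(f"symbols absent from dataset {dataset.species_id!r}: {sorted(missing)[:5]}")
        values = values.loc[order]
    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = values.index[(sd == 0).ravel()].tolist()[:5]
        raise PipelineError(
            f"zero-variance gene(s) reached centering in {dataset.species_id!r}: {bad} "
            "(the DEG filter should have removed them)"
        )
    return pd.DataFrame((arr - mu) / sd, index=values.index, columns=values.columns)


def merge(
    blocks: Sequence[tuple[ExpressionDataset, pd.DataFrame]],
    provenance: dict[str, object] | None = None,
) -> MergedDataset:
    """Column-concatenate per-species standardized blocks aligned on symbols."""
    if not blocks:
        raise ParameterError("nothing to merge")
    ref_index = list(blocks[0][1].index)
    pieces = []
    samples: list[tuple[str, SampleAnnotation]] = []
    for ds, block in blocks:
        if list(block.index) != ref_index:
            raise PipelineError(
                f"symbol order mismatch when merging species {ds.species_id!r}"
            )
        renamed = block.copy()
        renamed.columns = [f"{ds.species_id}_{c}" for c in block.columns]
        pieces.append(renamed)
        samples.extend((ds.species_id, ann) for ann in ds.samples)
    values = pd.concat(pieces, axis=1)
    return MergedDataset(values=values, samples=samples, provenance=dict(provenance or {}))


def cross_normalize(
    datasets: Sequence[ExpressionDataset],
    omap: OrthologyMap | None = None,
    fold: float = 2.0,
    pair_stat: str = "extremes",
    cell_types: Iterable[str] | None = None,
) -> MergedDataset:
    """Run the full five-step procedure and return the merged matrix.

    Probe-level inputs are collapsed through ``omap`` first.  ``cell_types``
    restricts every species to a sample subset BEFORE the DEG filter
    (lineage-focused reruns re-select the genes regulated within the subset).
    """
    if len(datasets) < 2:
        raise ParameterError("cross-normalization needs at least 2 species datasets")
    prov: dict[str, object] = {}
    gene_level = []
    for ds in datasets:
        if ds.level == "probe":
            if omap is None:
                raise ParameterError("probe-level inputs require an orthology map")
            ds = collapse_probes(ds, omap)
        gene_level.append(ds)
    prov["input_genes"] = {ds.species_id: ds.n_features for ds in gene_level}

    if cell_types is not None:
        gene_level = [ds.subset_cell_types(cell_types) for ds in gene_level]

    filtered = orthology_filter(gene_level)
    prov["after_orthology_filter"] = filtered[0].n_features

    degs = [deg_filter(ds, fold=fold, pair_stat=pair_stat) for ds in filtered]
    prov["deg_per_species"] = {ds.species_id: len(d) for ds, d in zip(filtered, degs)}
    common = deg_intersection(degs)
    prov["after_deg_intersection"] = len(common)

    blocks = [(ds, center_reduce(ds, symbols=common)) for ds in filtered]
    merged = merge(blocks, provenance=prov)
    merged.provenance["merged_samples"] = merged.values.shape[1]
    return merged
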