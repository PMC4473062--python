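"""The two end-to-end workflows tying the stages together.

Workflow A (homology by enrichment): extract reference-species fingerprints,
translate the test species into reference symbol space, and run the
all-pairwise GSEA bubble map per test species.

Workflow B (homology by clustering): cross-normalize all species into one
merged matrix, cluster samples with bootstrap support, and build conserved
multi-species signatures.  A cell-type subset filter supports
lineage-focused reruns: samples are restricted BEFORE the DEG filter so the
gene selection reflects regulation within the subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .bubbles import BubbleGrid, build_grid
from .cluster import ClusterTree, DEFAULT_SCALES, annotate_tree, average_linkage, correlation_distance
from .crossnorm import MergedDataset, collapse_probes, cross_normalize
from .errors import ParameterError
from .fingerprint import absolute_params, conserved_signature, extract_fingerprint, translate_symbols
from .io import ExpressionDataset, GeneSet, OrthologyMap

__all__ = ["WorkflowAResult", "WorkflowBResult", "run_workflow_a", "run_workflow_b"]

logger = logging.getLogger(__name__)


@dataclass
class WorkflowAResult:
    fingerprints: list[GeneSet]            # reference-species sets (translated)
    grids: dict[str, BubbleGrid]           # test species -> bubble map
    skipped_sets: list[str] = field(default_factory=list)


@dataclass
class WorkflowBResult:
    merged: MergedDataset
    tree: ClusterTree
    conserved: dict[str, GeneSet] = field(default_factory=dict)


def run_workflow_a(
    reference: ExpressionDataset,
    tests: Sequence[ExpressionDataset],
    omap: OrthologyMap,
    fold: float = 1.5,
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "signal2noise",
    weight: float = 1.0,
) -> WorkflowAResult:
    """Fingerprint the reference, then bubble-map every test species."""
    ref = reference
    if ref.level == "probe":
        ref = collapse_probes(ref, omap, keep_unmapped=True)
    sets: list[GeneSet] = []
    skipped: list[str] = []
    for ct in ref.cell_types:
        gs = extract_fingerprint(ref, absolute_params(ref, ct, fold_threshold=fold))
        gs = translate_symbols(gs, omap)
        if gs.is_empty:
            logger.warning("skipping empty fingerprint for %s", ct)
            skipped.append(gs.name)
            continue
        sets.append(gs)
    if not sets:
        raise ParameterError("no non-empty fingerprint could be extracted from the reference")

    grids: dict[str, BubbleGrid] = {}
    for test in tests:
        grids[test.species_id] = build_grid(
            test,
            sets,
            omap=omap,
            n_perm=n_perm,
            seed=seed,
            weight=weight,
            metric=metric,
            reference_species=reference.species_id,
        )
        logger.info(
            "bubble map %s: %d sets x %d pairs",
            test.species_id,
            len(sets),
            len(grids[test.species_id].pairs),
        )
    return WorkflowAResult(fingerprints=sets, grids=grids, skipped_sets=skipped)


def run_workflow_b(
    datasets: Sequence[ExpressionDataset],
    omap: OrthologyMap,
    deg_fold: float = 2.0,
    conserved_fold: float = 1.0,
    conserved_inclusive: bool = True,
    cell_types: Iterable[str] | None = None,
    n_boot: int = 1000,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int = 0,
    with_conserved: bool = True,
) -> WorkflowBResult:
    """Cross-normalize, cluster with bootstrap support, build conserved signatures."""
    if len(datasets) < 2:
        raise ParameterError("workflow B needs at least 2 species")
    merged = cross_normalize(datasets, omap, fold=deg_fold, cell_types=cell_types)
    for step, count in merged.provenance.items():
        logger.info("cross-normalization %s: %s", step, count)
    dist = correlation_distance(merged)
    tree = average_linkage(dist)
    tree = annotate_tree(tree, merged, n_boot=n_boot, scales=scales, seed=seed)

    conserved: dict[str, GeneSet] = {}
    if with_conserved:
        gene_level = [
            collapse_probes(ds, omap) if ds.level == "probe" else ds for ds in datasets
        ]
        if cell_types is not None:
            gene_level = [ds.subset_cell_types(cell_types) for ds in gene_level]
        shared_types = set(gene_level[0].cell_types)
        for ds in gene_level[1:]:
            shared_types &= set(ds.cell_types)
        for ct in sorted(shared_types):
            per_species = []
            for ds in gene_level:
                gs = extract_fingerprint(
                    ds,
                    absolute_params(
                        ds, ct, fold_threshold=conserved_fold, inclusive=conserved_inclusive
                    ),
                )
                per_species.append(translate_symbols(gs, omap))
            conserved[ct] = conserved_signature(per_species, omap, name=f"conserved_{ct}")
    return WorkflowBResult(merged=merged, tree=tree, conserved=conserved)
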