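"""Cell-type transcriptomic fingerprints and conserved cross-species signatures.

A fingerprint is the list of genes selectively over-expressed in one or more
index cell types relative to comparator cell types, by the conservative
"Min (test) vs. Max (ref)" rule: the MINIMUM intensity over all replicates of
all index types divided by the MAXIMUM over all replicates of all comparator
types must reach the fold threshold (default 1.5, inclusive).  "Absolute"
fingerprints compare against all other cell types of the dataset; "relative"
ones against a chosen subset.

Conserved cross-species signatures intersect per-species fingerprints after
symbol translation, with one exception: a gene present in all species but one
is kept when its absence in that species is attributable to the platform
(no probe for the gene, or only non-functional probes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .io import ExpressionDataset, GeneSet, OrthologyMap, SampleAnnotation

__all__ = [
    "FingerprintParams",
    "absolute_params",
    "min_vs_max_ratio",
    "fingerprint_ratios",
    "extract_fingerprint",
    "translate_symbols",
    "conserved_signature",
]

logger = logging.getLogger(__name__)


@dataclass
class FingerprintParams:
    """Index/comparator cell-type groups and the fold rule.

    ``fold_threshold`` defaults to 1.5 for fingerprints; conserved-signature
    extraction per species uses 1.0.  ``inclusive`` selects ``>=`` (default)
    versus strict ``>``.
    """

    index_cell_types: tuple[str, ...]
    comparator_cell_types: tuple[str, ...]
    fold_threshold: float = 1.5
    inclusive: bool = True

    def __post_init__(self) -> None:
        self.index_cell_types = tuple(self.index_cell_types)
        self.comparator_cell_types = tuple(self.comparator_cell_types)
        if not self.index_cell_types or not self.comparator_cell_types:
            raise ParameterError("index and comparator cell-type lists must be non-empty")
        overlap = set(self.index_cell_types) & set(self.comparator_cell_types)
        if overlap:
            raise ParameterError(f"index and comparator groups overlap: {sorted(overlap)}")
        if not self.fold_threshold > 0:
            raise ParameterError(f"fold_threshold must be > 0, got {self.fold_threshold}")


def absolute_params(
    dataset: ExpressionDataset,
    index_cell_types: str | Iterable[str],
    fold_threshold: float = 1.5,
    inclusive: bool = True,
) -> FingerprintParams:
    """Params for an absolute fingerprint: comparator = all other cell types."""
    if isinstance(index_cell_types, str):
        index_cell_types = (index_cell_types,)
    index = tuple(index_cell_types)
    comparator = tuple(ct for ct in dataset.cell_types if ct not in index)
    return FingerprintParams(index, comparator, fold_threshold, inclusive)


def min_vs_max_ratio(
    gene_values_by_sample: pd.Series,
    params: FingerprintParams,
    annotations: Sequence[SampleAnnotation],
) -> float:
    """Min over all index replicates divided by max over all comparator replicates."""
    idx_samples = [s.sample_id for s in annotations if s.cell_type in params.index_cell_types]
    cmp_samples = [s.sample_id for s in annotations if s.cell_type in params.comparator_cell_types]
    if not idx_samples or not cmp_samples:
        raise ParameterError("both index and comparator groups need at least one sample")
    num = float(gene_values_by_sample[idx_samples].min())
    den = float(gene_values_by_sample[cmp_samples].max())
    if den == 0.0:
        raise DataError("comparator maximum is 0: min/max ratio undefined")
    return num / den


def fingerprint_ratios(dataset: ExpressionDataset, params: FingerprintParams) -> pd.Series:
    """Vectorized per-gene min(index)/max(comparator) ratios over all replicates."""
    idx_cols = dataset.samples_of(params.index_cell_types)
    cmp_cols = dataset.samples_of(params.comparator_cell_types)
    if not idx_cols or not cmp_cols:
        raise ParameterError(
            "index or comparator group has no samples in dataset "
            f"{dataset.species_id!r} (cell types present: {dataset.cell_types})"
        )
    num = dataset.values[idx_cols].min(axis=1)
    den = dataset.values[cmp_cols].max(axis=1)
    if (den == 0).any():
        bad = den.index[den == 0].tolist()[:5]
        raise DataError(f"comparator maximum is 0 for features {bad}: ratio undefined")
    return num / den


def extract_fingerprint(
    dataset: ExpressionDataset,
    params: FingerprintParams,
    name: str | None = None,
) -> GeneSet:
    """Features whose min(index)/max(comparator) ratio passes the fold threshold.

    An empty result is legal (some cell types have no selectively expressed
    gene at the threshold); it is returned as an empty :class:`GeneSet` whose
    ``is_empty`` flag is set, and a warning is logged.
    """
    rho = fingerprint_ratios(dataset, params)
    if params.inclusive:
        passed = rho.index[rho >= params.fold_threshold]
    else:
        passed = rho.index[rho > params.fold_threshold]
    index_label = "+".join(params.index_cell_types)
    if name is None:
        name = f"{dataset.species_id}_{index_label}"
    gs = GeneSet(
        name=name,
        description=(
            f"min/max >= {params.fold_threshold} fingerprint of {index_label} "
            f"vs {','.join(params.comparator_cell_types)} in {dataset.species_id}"
        ),
        symbols=frozenset(passed),
        source_species=dataset.species_id,
        index_cell_type=index_label,
        comparator_cell_types=params.comparator_cell_types,
        fold_threshold=params.fold_threshold,
    )
    if gs.is_empty:
        logger.warning("fingerprint %s is empty at fold %.3g", name, params.fold_threshold)
    return gs


def translate_symbols(gene_set: GeneSet, omap: OrthologyMap) -> GeneSet:
    """Rename each feature to its reference-species ortholog symbol.

    Features without a known ortholog keep their native id; features mapping
    to the same symbol collapse to a single entry.
    """
    translated = frozenset(
        omap.translate_feature(gene_set.source_species, f) for f in gene_set.symbols
    )
    return GeneSet(
        name=gene_set.name,
        description=gene_set.description,
        symbols=translated,
        source_species=gene_set.source_species,
        index_cell_type=gene_set.index_cell_type,
        comparator_cell_types=gene_set.comparator_cell_types,
        fold_threshold=gene_set.fold_threshold,
    )


def conserved_signature(
    per_species_sets: Sequence[GeneSet],
    probe_presence: OrthologyMap,
    name: str | None = None,
) -> GeneSet:
    """Intersection of per-species signatures, with the missing-probe exception.

    A symbol is included iff it is present in every species' set, or present
    in all but exactly one species while that species' platform has no
    functional probe for it (symbol unmapped, or mapped only by non-functional
    probes).  Input sets must already be translated to reference symbols and
    come from distinct species.
    """
    if len(per_species_sets) < 2:
        raise ParameterError("conserved signature needs sets from at least 2 species")
    species = [gs.source_species for gs in per_species_sets]
    if len(set(species)) != len(species):
        raise ParameterError(f"duplicate source species in input sets: {species}")

    universe = frozenset().union(*(gs.symbols for gs in per_species_sets))
    kept: set[str] = set()
    for sym in universe:
        missing = [gs.source_species for gs in per_species_sets if sym not in gs.symbols]
        if not missing:
            kept.add(sym)
        elif len(missing) == 1 and not probe_presence.has_functional_probe(missing[0], sym):
            kept.add(sym)

    cell_types = {gs.index_cell_type for gs in per_species_sets if gs.index_cell_type}
    index_label = "+".join(sorted(cell_types))
    if name is None:
        name = f"conserved_{index_label or 'signature'}"
    return GeneSet(
        name=name,
        description=f"conserved across {','.join(species)} (missing-probe exception applied)",
        symbols=frozenset(kept),
        source_species=",".join(species),
        index_cell_type=index_label,
    )
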