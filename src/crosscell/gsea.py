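"""Weighted KS-style gene-set enrichment with a gene-set permutation null.

The enrichment score (ES) is the signed maximal deviation of the classic
weighted running sum: walking down a ranked gene list, hits advance the sum
by |score|^p (normalized), misses retreat it by 1/(N - n_hits).  The null
distribution is built by rescoring random gene sets of the same size drawn
from the ranked list (gene-set permutation — the scheme the pipeline
mandates; phenotype permutation is deliberately not implemented).  NES,
p-values and map-wide FDR q-values follow the standard sign-stratified
normalization: NES = ES / mean(|null ES of the same sign|), with FDR pooled
across every cell of one bubble map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DataError, ParameterError
from .io import ExpressionDataset, GeneSet

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "GseaCellResult",
    "rank_genes",
    "enrichment_score",
    "permutation_null",
    "nes_p_fdr",
]


@dataclass
class RankedList:
    """Genes ordered by a class-contrast metric, best-in-class-A first."""

    symbols: np.ndarray  # unique strings
    scores: np.ndarray   # non-increasing floats
    class_a: str
    class_b: str
    species_id: str = ""
    metric_used: str = ""

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.symbols.shape != self.scores.shape:
            raise ParameterError("symbols and scores must have equal length")
        if len(np.unique(self.symbols)) != len(self.symbols):
            raise ParameterError("ranked symbols must be unique")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ParameterError("scores must be sorted non-increasing")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class EnrichmentResult:
    es: float
    running_sum: np.ndarray
    peak_index: int  # 1-based position of the extreme deviation
    n_hits: int


@dataclass
class GseaCellResult:
    """ES/NES/p/FDR for one gene set on one ordered cell-type pair.

    ``status`` is "ok", or "na" when the statistic is undefined for the cell
    (no gene-set overlap with the ranked list, or no same-sign null ES) —
    an NA cell is distinct from a non-significant one.
    """

    geneset_name: str
    class_a: str
    class_b: str
    es: float = float("nan")
    nes: float = float("nan")
    p_value: float = float("nan")
    fdr_q: float = float("nan")
    fdr_q_cell: float = float("nan")  # per-cell diagnostic FDR, not map-pooled
    n_hits: int = 0
    status: str = "ok"


_S2N_MIN_REPLICATES = 3


def _class_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros(values.shape[0])
    # signal-to-noise floor used by desktop GSEA: sd >= max(0.2*|mu|, 0.2)
    floor = np.maximum(0.2 * np.abs(mu), 0.2)
    return mu, np.maximum(sd, floor)


def rank_genes(
    dataset: ExpressionDataset,
    class_a: str,
    class_b: str,
    metric: str = "signal2noise",
) -> RankedList:
    """Rank the dataset's features by a two-class contrast, descending.

    ``signal2noise`` = (mu_a - mu_b)/(sd_a + sd_b) with the desktop-GSEA
    standard-deviation floor; it needs >= 3 replicates per class and falls
    back to ``log2fc`` of class means otherwise (recorded in
    ``metric_used``).  Ties are broken by symbol lexicographic order so the
    ranking is deterministic.
    """
    if metric not in ("signal2noise", "log2fc"):
        raise ParameterError(f"unknown metric {metric!r}")
    cols_a = dataset.samples_of(class_a)
    cols_b = dataset.samples_of(class_b)
    if not cols_a or not cols_b:
        missing = class_a if not cols_a else class_b
        raise ParameterError(f"cell type {missing!r} not present in dataset {dataset.species_id!r}")

    va = dataset.values[cols_a].to_numpy(dtype=float)
    vb = dataset.values[cols_b].to_numpy(dtype=float)
    used = metric
    if metric == "signal2noise" and min(len(cols_a), len(cols_b)) < _S2N_MIN_REPLICATES:
        used = "log2fc"

    if used == "signal2noise":
        mu_a, sd_a = _class_stats(va)
        mu_b, sd_b = _class_stats(vb)
        scores = (mu_a - mu_b) / (sd_a + sd_b)
    else:
        mu_a = va.mean(axis=1)
        mu_b = vb.mean(axis=1)
        if np.any(mu_a <= 0) or np.any(mu_b <= 0):
            raise DataError("log2fc metric requires positive class means")
        scores = np.log2(mu_a / mu_b)

    symbols = np.asarray(dataset.values.index, dtype=object)
    # descending score; lexicographic symbol ascending on ties
    order = np.lexsort((symbols, -scores))
    return RankedList(
        symbols=symbols[order],
        scores=scores[order],
        class_a=class_a,
        class_b=class_b,
        species_id=dataset.species_id,
        metric_used=used,
    )


def _es_from_hits(scores: np.ndarray, hits: np.ndarray, p: float) -> tuple[float, np.ndarray, int]:
    """Running-sum ES for one boolean hit vector (misses weighted 1/(N-n))."""
    n = len(scores)
    n_hits = int(hits.sum())
    w = np.abs(scores) ** p
    w_hit = np.where(hits, w, 0.0)
    cum_hit = np.cumsum(w_hit)  # sequential accumulation; total = last partial sum
    if cum_hit[-1] == 0.0:
        # degenerate all-zero hit weights (p>0, hit scores all 0): equal weights
        cum_hit = np.cumsum(hits.astype(float))
    p_hit = cum_hit / cum_hit[-1]
    p_miss = np.cumsum(~hits) / (n - n_hits)
    dev = p_hit - p_miss
    peak = int(np.argmax(np.abs(dev)))
    return float(dev[peak]), dev, peak + 1


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet | frozenset, p: float = 1.0
) -> EnrichmentResult | None:
    """Signed maximal running-sum deviation for one gene set.

    Returns ``None`` when the set has no overlap with the ranked list (the
    cell is then reported NA, which is distinct from FDR = 1).  A set
    covering the whole list has no miss complement and is rejected.
    """
    symbols = gene_set.symbols if isinstance(gene_set, GeneSet) else gene_set
    hits = np.isin(ranked.symbols, list(symbols))
    n_hits = int(hits.sum())
    if n_hits == 0:
        return None
    if n_hits == len(ranked):
        raise ParameterError("gene set covers the entire ranked list: ES undefined")
    es, dev, peak = _es_from_hits(ranked.scores, hits, p)
    return EnrichmentResult(es=es, running_sum=dev, peak_index=peak, n_hits=n_hits)


def permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    p: float = 1.0,
) -> np.ndarray:
    """Null ES from ``n_perm`` random same-size gene sets (vectorized).

    Each permutation draws ``set_size`` symbols uniformly without replacement
    from the ranked list and scores them with the same running sum.
    """
    n = len(ranked)
    if not 0 < set_size < n:
        raise ParameterError(f"set_size must be in (0, {n}), got {set_size}")
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100 for a usable null")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # hit matrix via per-row random argpartition
    u = rng.random((n_perm, n))
    hit_idx = np.argpartition(u, set_size - 1, axis=1)[:, :set_size]
    hits = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hits, hit_idx, True, axis=1)

    w = np.abs(ranked.scores) ** p
    w_hit = hits * w
    cum_hit = np.cumsum(w_hit, axis=1)
    degenerate = cum_hit[:, -1] == 0.0
    if degenerate.any():
        cum_hit[degenerate] = np.cumsum(hits[degenerate].astype(float), axis=1)
    p_hit = cum_hit / cum_hit[:, -1:]
    p_miss = np.cumsum(~hits, axis=1) / (n - set_size)
    dev = p_hit - p_miss
    peaks = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(n_perm), peaks]


def nes_p_fdr(
    observed: Sequence[GseaCellResult],
    nulls: Mapping[tuple[str, str, str], np.ndarray],
) -> list[GseaCellResult]:
    """Normalize ES, attach permutation p-values and map-wide FDR q-values.

    ``nulls`` maps (geneset_name, class_a, class_b) to the cell's null ES
    vector.  NES = ES / mean(|null ES of same sign|); p uses the +1-corrected
    same-sign exceedance count.  FDR for a cell at NES* is the ratio of the
    same-sign exceedance fraction in the pooled normalized null over the
    same fraction in the pooled observed NES, clipped to [0, 1]; pooling runs
    across ALL cells passed in (map-wide correction).  A per-cell q using only
    the cell's own null is attached as a diagnostic.
    """
    results: list[GseaCellResult] = []
    pooled_null: list[np.ndarray] = []
    for cell in observed:
        if cell.status == "na":
            results.append(cell)
            continue
        key = (cell.geneset_name, cell.class_a, cell.class_b)
        if key not in nulls:
            raise ParameterError(f"no null vector for scored cell {key}")
        null = np.asarray(nulls[key], dtype=float)
        pos = null[null > 0]
        neg = null[null < 0]
        # normalized null (both signs) for this cell, pooled map-wide below
        cell_null_nes = []
        if len(pos):
            cell_null_nes.append(pos / pos.mean())
        if len(neg):
            cell_null_nes.append(neg / np.abs(neg).mean())
        same = pos if cell.es >= 0 else neg
        if len(same) == 0:
            cell.status = "na"
            cell.nes = float("nan")
            cell.p_value = float("nan")
            results.append(cell)
            continue
        denom = np.abs(same).mean()
        cell.nes = cell.es / denom
        cell.p_value = (1 + int(np.sum(np.abs(same) >= abs(cell.es)))) / (1 + len(same))
        # per-cell diagnostic q: exceedance of this cell's own normalized null
        own = np.concatenate(cell_null_nes) if cell_null_nes else np.array([])
        own_same = own[own > 0] if cell.nes >= 0 else own[own < 0]
        if len(own_same):
            cell.fdr_q_cell = min(
                1.0, float(np.mean(np.abs(own_same) >= abs(cell.nes)) / (1.0 / 1.0))
            )
        pooled_null.extend(cell_null_nes)
        results.append(cell)

    pool = np.concatenate(pooled_null) if pooled_null else np.array([])
    obs_nes = np.array([c.nes for c in results if c.status == "ok"])
    for cell in results:
        if cell.status != "ok":
            continue
        if cell.nes >= 0:
            null_same = pool[pool > 0]
            obs_same = obs_nes[obs_nes >= 0]
        else:
            null_same = pool[pool < 0]
            obs_same = obs_nes[obs_nes < 0]
        mag = abs(cell.nes)
        num = float(np.mean(np.abs(null_same) >= mag)) if len(null_same) else 0.0
        den = float(np.mean(np.abs(obs_same) >= mag))  # includes the cell itself: > 0
        cell.fdr_q = min(1.0, num / den) if den > 0 else 0.0
    return results
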