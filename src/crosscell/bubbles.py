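"""All-pairwise GSEA of reference fingerprints within a test species ("bubble map").

For every unordered pair of cell types of the test species and every
reference gene set, one GSEA cell is computed on the pairwise ranked list;
positive NES means enrichment toward the first label of the canonical
(lexicographic) pair order.  FDR is corrected map-wide: all the map's null
and observed NES are pooled.  The rendering follows the field's bubble
convention: bubble AREA proportional to |NES|, fill color = the enriched
cell type, opacity binned by FDR; NA cells (no gene-set overlap) are left
blank, which is distinct from a non-significant bubble.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .gsea import GseaCellResult, enrichment_score, nes_p_fdr, permutation_null, rank_genes
from .io import ExpressionDataset, GeneSet, OrthologyMap

__all__ = ["BubbleGrid", "build_grid", "grid_to_frame", "render_bubbles", "DEFAULT_FDR_BINS"]


@dataclass
class BubbleGrid:
    """Complete matrix of pairwise GSEA results for one test species."""

    genesets: list[str]
    pairs: list[tuple[str, str]]
    cells: dict[tuple[str, tuple[str, str]], GseaCellResult]
    test_species: str
    reference_species: str = ""
    n_perm: int = 1000
    seed: int | None = None

    def cell(self, geneset: str, a: str, b: str) -> GseaCellResult:
        pair = (a, b) if (a, b) in self.pairs else (b, a)
        return self.cells[(geneset, pair)]

    @property
    def cell_types(self) -> list[str]:
        return sorted({ct for pair in self.pairs for ct in pair})


def build_grid(
    test: ExpressionDataset,
    sets: Sequence[GeneSet],
    omap: OrthologyMap | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    metric: str = "signal2noise",
    reference_species: str = "",
) -> BubbleGrid:
    """Score every (gene set, cell-type pair) cell of the test species.

    If ``omap`` is given the test dataset's features are first collapsed to
    reference symbols (max-total-signal probe per gene; unmapped features
    keep their native id).  Iteration order is fixed — gene sets outer,
    pairs inner — so permutation seeds are consumed deterministically.
    """
    if omap is not None:
        from .crossnorm import collapse_probes

        test = collapse_probes(test, omap, keep_unmapped=True)
    cell_types = test.cell_types
    if len(cell_types) < 2:
        raise ParameterError("bubble map needs at least 2 cell types in the test dataset")
    pairs = list(itertools.combinations(cell_types, 2))  # canonical lexicographic order

    ranked = {pair: rank_genes(test, pair[0], pair[1], metric=metric) for pair in pairs}

    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(len(sets) * len(pairs))
    observed: list[GseaCellResult] = []
    nulls: dict[tuple[str, str, str], np.ndarray] = {}
    k = 0
    for gs in sets:
        for pair in pairs:
            rl = ranked[pair]
            res = enrichment_score(rl, gs, p=weight)
            cell = GseaCellResult(geneset_name=gs.name, class_a=pair[0], class_b=pair[1])
            if res is None:
                cell.status = "na"
            else:
                cell.es = res.es
                cell.n_hits = res.n_hits
                nulls[(gs.name, pair[0], pair[1])] = permutation_null(
                    rl, res.n_hits, n_perm, np.random.default_rng(children[k]), p=weight
                )
            observed.append(cell)
            k += 1
    scored = nes_p_fdr(observed, nulls)

    cells = {(c.geneset_name, (c.class_a, c.class_b)): c for c in scored}
    return BubbleGrid(
        genesets=[gs.name for gs in sets],
        pairs=pairs,
        cells=cells,
        test_species=test.species_id,
        reference_species=reference_species,
        n_perm=n_perm,
        seed=seed,
    )


def grid_to_frame(grid: BubbleGrid) -> pd.DataFrame:
    """Tidy per-cell table: geneset, pair labels, ES, NES, p, q, hits, direction."""
    rows = []
    for gs in grid.genesets:
        for pair in grid.pairs:
            c = grid.cells[(gs, pair)]
            if c.status == "na":
                direction = "NA"
            else:
                direction = c.class_a if c.nes >= 0 else c.class_b
            rows.append(
                {
                    "geneset": gs,
                    "class_a": pair[0],
                    "class_b": pair[1],
                    "ES": c.es,
                    "NES": c.nes,
                    "p_value": c.p_value,
                    "fdr_q": c.fdr_q,
                    "n_hits": c.n_hits,
                    "direction": direction,
                    "status": c.status,
                }
            )
    return pd.DataFrame(rows)


# -- SVG rendering ----------------------------------------------------------

DEFAULT_FDR_BINS: tuple[tuple[float, float], ...] = (
    (0.001, 1.00),
    (0.01, 0.80),
    (0.05, 0.60),
    (0.25, 0.35),
)
_OPACITY_ABOVE_LAST_BIN = 0.12

_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)


def _fdr_opacity(q: float, bins) -> float:
    for edge, opacity in bins:
        if q < edge:
            return opacity
    return _OPACITY_ABOVE_LAST_BIN


def render_bubbles(
    grid: BubbleGrid,
    out_path: str | Path | None = None,
    fdr_bins=DEFAULT_FDR_BINS,
    cell_px: int = 42,
    max_radius: float = 16.0,
    nes_at_max: float | None = None,
) -> str:
    """Render the grid as a deterministic SVG string (optionally written to disk).

    Bubble area is proportional to |NES| (radius ∝ sqrt|NES|), reaching
    ``max_radius`` at the map's largest |NES| (or at ``nes_at_max``);
    fill color identifies the enriched cell type and opacity encodes the
    FDR bin.  NA cells emit no bubble element.  Output is byte-identical
    across runs for a fixed grid.
    """
    colors = {ct: _PALETTE[i % len(_PALETTE)] for i, ct in enumerate(grid.cell_types)}
    nes_vals = [abs(c.nes) for c in grid.cells.values() if c.status == "ok" and np.isfinite(c.nes)]
    nes_ref = nes_at_max if nes_at_max is not None else (max(nes_vals) if nes_vals else 1.0)
    nes_ref = max(nes_ref, 1e-12)

    left, top = 160, 60
    width = left + cell_px * len(grid.pairs) + 40
    height = top + cell_px * len(grid.genesets) + 80
    out: list[str] = []
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'font-family="sans-serif" font-size="10">'
    )
    out.append(f'<rect width="{width}" height="{height}" fill="white"/>')
    out.append(
        f'<text x="{left}" y="18" font-size="12">Bubble map: {grid.test_species} '
        f'(area ∝ |NES|, opacity: FDR)</text>'
    )
    for j, pair in enumerate(grid.pairs):
        x = left + j * cell_px + cell_px // 2
        out.append(
            f'<text x="{x}" y="{top - 8}" text-anchor="middle">{pair[0]}/{pair[1]}</text>'
        )
    for i, gs in enumerate(grid.genesets):
        y = top + i * cell_px + cell_px // 2
        out.append(f'<text x="{left - 8}" y="{y + 3}" text-anchor="end">{gs}</text>')
        for j, pair in enumerate(grid.pairs):
            x = left + j * cell_px + cell_px // 2
            out.append(
                f'<rect x="{left + j * cell_px}" y="{top + i * cell_px}" '
                f'width="{cell_px}" height="{cell_px}" fill="none" stroke="#ddd"/>'
            )
            c = grid.cells[(gs, pair)]
            if c.status != "ok" or not np.isfinite(c.nes):
                continue  # NA cell: blank position
            radius = max_radius * np.sqrt(abs(c.nes) / nes_ref)
            winner = pair[0] if c.nes >= 0 else pair[1]
            opacity = _fdr_opacity(c.fdr_q, fdr_bins)
            out.append(
                f'<circle cx="{x}" cy="{y}" r="{radius:.3f}" fill="{colors[winner]}" '
                f'fill-opacity="{opacity:.2f}"><title>{gs} {pair[0]} vs {pair[1]}: '
                f'NES={c.nes:.3f} FDR={c.fdr_q:.4f}</title></circle>'
            )
    # legend: one swatch per cell type
    ly = top + cell_px * len(grid.genesets) + 24
    for i, ct in enumerate(grid.cell_types):
        lx = left + i * 90
        out.append(f'<rect x="{lx}" y="{ly - 9}" width="10" height="10" fill="{colors[ct]}"/>')
        out.append(f'<text x="{lx + 14}" y="{ly}">{ct}</text>')
    out.append("</svg>")
    svg = "\n".join(out) + "\n"
    if out_path is not None:
        Path(out_path).write_text(svg)
    return svg
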