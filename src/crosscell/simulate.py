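"""Synthetic multi-species expression data with planted homologous cell types.

The generator emulates the structure of cross-species microarray compendia:
per-species probe-level matrices over a shared orthologous gene universe plus
species-private genes, with

* a log-normal intensity model — per-gene baseline log2 level ~ N(8, 1.5),
  shared across species (orthologous genes measure the same transcript);
* planted marker modules: each cell type over-expresses its own module by a
  fold f in EVERY species (the homology signal), optionally with
  lineage-shared modules elevated in all members of a lineage;
* species effects: per-species per-gene log2 offsets ~ N(0, species_effect_sd),
  the confounder cross-normalization exists to remove — gene-wise shifts, not
  global scalings, so centering/reduction genuinely removes them;
* replicate noise ~ N(0, noise_sd) per sample and gene;
* platform artifacts: a random number of probes per gene with per-probe
  efficiency offsets, non-functional probes reporting background-level
  signal, and orthology dropout (genes with no known reference ortholog).

Ground-truth tables (marker membership, per-species detectability, expected
per-species fingerprints, expected conserved signatures, the sample/cell-type
partition) are emitted alongside, so every downstream stage can be scored
without re-deriving the simulation.  A fold of 1 is the null mode: no
planted signal at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import ExpressionDataset, OrthologyMap, OrthologyRecord, SampleAnnotation

__all__ = [
    "CellTypePlan",
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticData",
    "generate",
    "divergent_lineage_spec",
]


@dataclass(frozen=True)
class CellTypePlan:
    """One planted cell type: marker-module size, fold, optional lineage."""

    name: str
    n_markers: int = 30
    fold: float = 4.0
    lineage: str | None = None


def _default_cell_types() -> tuple[CellTypePlan, ...]:
    return tuple(
        CellTypePlan(name=n) for n in ("B", "pDC", "cDC1", "cDC2", "MoMP")
    )


@dataclass
class SyntheticSpec:
    """Study conditions for one simulated multi-species compendium.

    Defaults model a desk-scale analogue of a 4-species mononuclear-phagocyte
    compendium: 3 species, 5 cell types with 30-gene marker modules at
    4-fold, 3 replicates, log2 replicate noise 0.5, species effect 0.3.
    """

    species_ids: tuple[str, ...] = ("spA", "spB", "spC")
    cell_types: tuple[CellTypePlan, ...] = field(default_factory=_default_cell_types)
    n_shared_genes: int = 1000
    n_private_genes: int = 60           # per species, no reference ortholog
    replicates: int = 3
    noise_sd: float = 0.5               # log2 replicate noise
    species_effect_sd: float = 0.3      # per-species per-gene log2 offset
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    lineage_n_markers: int = 40         # per lineage, if any lineage is declared
    lineage_fold: float = 3.0
    lineage_divergence: float = 0.0
    #   Probability that a species does NOT express a given lineage-module
    #   gene in the lineage members.  Lineage genes are additionally boosted
    #   in a fixed anchor cell type (the first non-member) in every species,
    #   so they stay differentially expressed — and hence in the merged
    #   matrix — even where the lineage silences them.  This species x
    #   lineage interaction survives per-gene centering/reduction and is the
    #   mechanism that can group within-lineage subsets by species; a
    #   subset-focused rerun drops these genes at the DEG filter (they never
    #   separate the members from each other) and restores grouping by type.
    probes_per_gene_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    probe_offset_sd: float = 0.25       # per-probe log2 efficiency
    orthology_dropout: float = 0.05     # P(gene unmapped on a platform)
    nonfunctional_probe_rate: float = 0.02
    n_forced_missing_per_type: int = 1  # markers engineered undetectable in one species
    background_mean: float = 4.0        # log2 level of non-functional probes
    background_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species_ids) < 2:
            raise ParameterError("need at least 2 species")
        names = [ct.name for ct in self.cell_types]
        if len(set(names)) != len(names) or len(names) < 2:
            raise ParameterError("cell types must be >= 2 and uniquely named")
        for ct in self.cell_types:
            if ct.fold < 1 or ct.n_markers < 1:
                raise ParameterError(f"cell type {ct.name}: fold >= 1 and n_markers >= 1 required")
        total = sum(ct.n_markers for ct in self.cell_types)
        total += self.lineage_n_markers * len(self.lineages)
        if total > self.n_shared_genes:
            raise ParameterError(
                f"marker modules ({total}) exceed the shared gene universe ({self.n_shared_genes})"
            )
        for p in (self.orthology_dropout, self.nonfunctional_probe_rate):
            if not 0 <= p <= 1:
                raise ParameterError("probabilities must lie in [0, 1]")
        if self.replicates < 1 or self.noise_sd < 0:
            raise ParameterError("replicates >= 1 and noise_sd >= 0 required")
        if abs(sum(self.probes_per_gene_probs.values()) - 1.0) > 1e-9:
            raise ParameterError("probes_per_gene_probs must sum to 1")

    @property
    def lineages(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for ct in self.cell_types:
            if ct.lineage is not None:
                out.setdefault(ct.lineage, []).append(ct.name)
        return out


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline against the planted structure."""

    markers: dict[str, frozenset[str]]                     # cell type -> symbols
    lineage_markers: dict[str, frozenset[str]]             # lineage -> symbols
    detectable: dict[tuple[str, str], bool]                # (species, symbol): gene-level signal present
    excused: dict[tuple[str, str], bool]                   # (species, symbol): no functional mapped probe
    per_species_fingerprint: dict[tuple[str, str], frozenset[str]]  # (species, cell type)
    conserved_expected: dict[str, frozenset[str]]          # cell type -> symbols
    partition: dict[str, str]                              # "<sp>_<sample>" -> cell type

    def marker_table(self) -> pd.DataFrame:
        rows = [
            {"cell_type": ct, "symbol": s}
            for ct, syms in sorted(self.markers.items())
            for s in sorted(syms)
        ]
        return pd.DataFrame(rows, columns=["cell_type", "symbol"])


@dataclass
class SyntheticData:
    spec: SyntheticSpec
    datasets: dict[str, ExpressionDataset]   # species -> probe-level dataset
    orthology: OrthologyMap
    truth: GroundTruth

    @property
    def reference_species(self) -> str:
        return self.spec.species_ids[0]


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Draw one compendium from the spec; byte-identical for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n_shared = spec.n_shared_genes
    symbols = [f"G{i:04d}" for i in range(1, n_shared + 1)]

    # marker-module layout over the shared universe
    cursor = 0
    markers: dict[str, frozenset[str]] = {}
    boost = np.zeros((n_shared, len(spec.cell_types)))  # log2 boosts per cell type
    names = [ct.name for ct in spec.cell_types]
    for k, ct in enumerate(spec.cell_types):
        mod = list(range(cursor, cursor + ct.n_markers))
        cursor += ct.n_markers
        markers[ct.name] = frozenset(symbols[i] for i in mod)
        boost[mod, k] += np.log2(ct.fold)
    lineage_markers: dict[str, frozenset[str]] = {}
    lineage_layout: list[tuple[np.ndarray, list[int]]] = []  # (gene idx, member cols)
    for lineage, members in sorted(spec.lineages.items()):
        mod = np.arange(cursor, cursor + spec.lineage_n_markers)
        cursor += spec.lineage_n_markers
        lineage_markers[lineage] = frozenset(symbols[i] for i in mod)
        member_cols = [k for k, ct in enumerate(spec.cell_types) if ct.name in members]
        non_members = [k for k in range(len(names)) if k not in member_cols]
        if spec.lineage_divergence > 0:
            if not non_members:
                raise ParameterError("lineage divergence needs a non-member anchor cell type")
            boost[mod, non_members[0]] += np.log2(spec.lineage_fold)  # anchor keeps genes DE
        lineage_layout.append((mod, member_cols))

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_shared)

    # engineered undetectable markers: per cell type, designate markers that a
    # round-robin species will miss (all probes non-functional / unmapped)
    forced_nonfunctional: dict[str, set[str]] = {sp: set() for sp in spec.species_ids}
    forced_unmapped: dict[str, set[str]] = {sp: set() for sp in spec.species_ids}
    rr = 0
    for ct in spec.cell_types:
        mod = sorted(markers[ct.name])
        for j in range(min(spec.n_forced_missing_per_type, len(mod) // 2)):
            sp = spec.species_ids[rr % len(spec.species_ids)]
            forced_nonfunctional[sp].add(mod[2 * j])
            rr += 1
            sp = spec.species_ids[rr % len(spec.species_ids)]
            forced_unmapped[sp].add(mod[2 * j + 1])
            rr += 1

    probe_counts = sorted(spec.probes_per_gene_probs)
    probe_probs = [spec.probes_per_gene_probs[k] for k in probe_counts]

    datasets: dict[str, ExpressionDataset] = {}
    records: list[OrthologyRecord] = []
    detectable: dict[tuple[str, str], bool] = {}
    excused: dict[tuple[str, str], bool] = {}

    for sp in spec.species_ids:
        species_eff = rng.normal(0.0, spec.species_effect_sd, size=n_shared)
        boost_sp = boost.copy()
        for mod, member_cols in lineage_layout:
            expressed = rng.random(len(mod)) >= spec.lineage_divergence
            for k in member_cols:
                boost_sp[mod[expressed], k] += np.log2(spec.lineage_fold)
        n_private = spec.n_private_genes
        private_base = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_private)

        samples = [
            SampleAnnotation(sample_id=f"{ct.name}_{r}", cell_type=ct.name, replicate=r)
            for ct in spec.cell_types
            for r in range(1, spec.replicates + 1)
        ]
        sample_type_idx = [names.index(s.cell_type) for s in samples]
        n_samples = len(samples)

        # gene-level log2 signal, shared genes: baseline + species effect + boost + noise
        noise = rng.normal(0.0, spec.noise_sd, size=(n_shared, n_samples))
        gene_log2 = (
            baseline[:, None]
            + species_eff[:, None]
            + boost_sp[:, np.array(sample_type_idx)]
            + noise
        )
        private_log2 = (
            private_base[:, None]
            + rng.normal(0.0, spec.noise_sd, size=(n_private, n_samples))
        )

        # platform: probes per gene, mapping, functionality
        n_probes_shared = rng.choice(probe_counts, size=n_shared, p=probe_probs)
        dropout = rng.random(n_shared) < spec.orthology_dropout

        probe_rows: list[np.ndarray] = []
        probe_ids: list[str] = []
        gene_probe_info: dict[str, list[tuple[str, bool, int]]] = {}  # sym -> (pid, functional, row#)
        gene_mapped: dict[str, bool] = {}
        for gi, sym in enumerate(symbols):
            unmapped = bool(dropout[gi]) or sym in forced_unmapped[sp]
            force_nf = sym in forced_nonfunctional[sp]
            gene_mapped[sym] = not unmapped
            for pj in range(int(n_probes_shared[gi])):
                pid = f"{sp}:g{gi + 1:04d}:p{pj + 1}"
                nonfunctional = force_nf or (rng.random() < spec.nonfunctional_probe_rate)
                if nonfunctional:
                    row = rng.normal(spec.background_mean, spec.background_sd, size=n_samples)
                else:
                    offset = rng.normal(0.0, spec.probe_offset_sd)
                    row = gene_log2[gi] + offset
                gene_probe_info.setdefault(sym, []).append((pid, not nonfunctional, len(probe_rows)))
                probe_rows.append(row)
                probe_ids.append(pid)
                records.append(
                    OrthologyRecord(
                        species_id=sp,
                        feature_id=pid,
                        reference_symbol=None if unmapped else sym,
                        probe_functional=not nonfunctional,
                    )
                )
        for gi in range(n_private):
            pid = f"{sp}:priv{gi + 1:04d}:p1"
            probe_rows.append(private_log2[gi])
            probe_ids.append(pid)
            records.append(
                OrthologyRecord(
                    species_id=sp, feature_id=pid, reference_symbol=None, probe_functional=True
                )
            )

        linear = np.exp2(np.vstack(probe_rows))
        values = pd.DataFrame(
            linear, index=probe_ids, columns=[s.sample_id for s in samples]
        )
        datasets[sp] = ExpressionDataset(
            species_id=sp, values=values, samples=samples, level="probe"
        )

        # ground-truth detectability at gene level: which probe wins the
        # max-total-signal collapse, and whether the platform has any
        # functional mapped probe at all (the conserved-signature excuse)
        row_sums = linear.sum(axis=1)
        for sym in symbols:
            info = gene_probe_info[sym]
            if not gene_mapped[sym]:
                detectable[(sp, sym)] = False
                excused[(sp, sym)] = True
                continue
            winner = min(info, key=lambda t: (-row_sums[t[2]], t[0]))
            detectable[(sp, sym)] = winner[1]
            excused[(sp, sym)] = not any(func for _, func, _ in info)

    omap = OrthologyMap(records)

    per_species_fp = {
        (sp, ct.name): frozenset(
            s for s in markers[ct.name] if detectable[(sp, s)]
        )
        for sp in spec.species_ids
        for ct in spec.cell_types
    }
    def _conserved(ct_name: str) -> frozenset[str]:
        kept = []
        for s in markers[ct_name]:
            missing = [sp for sp in spec.species_ids if not detectable[(sp, s)]]
            if not missing or (len(missing) == 1 and excused[(missing[0], s)]):
                kept.append(s)
        return frozenset(kept)

    conserved_expected = {ct.name: _conserved(ct.name) for ct in spec.cell_types}
    partition = {
        f"{sp}_{s.sample_id}": s.cell_type
        for sp in spec.species_ids
        for s in datasets[sp].samples
    }
    truth = GroundTruth(
        markers=markers,
        lineage_markers=lineage_markers,
        detectable=detectable,
        excused=excused,
        per_species_fingerprint=per_species_fp,
        conserved_expected=conserved_expected,
        partition=partition,
    )
    return SyntheticData(spec=spec, datasets=datasets, orthology=omap, truth=truth)


def divergent_lineage_spec(seed: int = 0) -> SyntheticSpec:
    """Conditions with a transcriptionally divergent lineage (cDC1/cDC2).

    Two related cell types share a large lineage program whose gene-wise
    expression is species-divergent (each species silences about half of the
    module in the lineage members), on top of small private marker modules.
    Under these conditions a full-compendium clustering tends to group the
    lineage members by species of origin, while a rerun focused on the two
    subsets — which re-applies the DEG filter within the subset and thereby
    drops the divergent shared program — restores grouping by cell type.
    """
    cell_types = (
        CellTypePlan("B"),
        CellTypePlan("pDC"),
        CellTypePlan("MoMP"),
        CellTypePlan("cDC1", n_markers=6, fold=4.0, lineage="cDC"),
        CellTypePlan("cDC2", n_markers=6, fold=4.0, lineage="cDC"),
    )
    return SyntheticSpec(
        cell_types=cell_types,
        lineage_n_markers=120,
        lineage_fold=6.0,
        lineage_divergence=0.5,
        noise_sd=0.3,
        seed=seed,
    )
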