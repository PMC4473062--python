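"""Typed containers and TSV/GMT readers for the cross-species pipeline.

Expression values are held on LINEAR scale throughout: the min/max fold
rules and the DEG filter are linear-ratio rules, as is conventional for
normalized microarray intensities.  Matrices deposited on a log2 scale are
converted on ingest via ``log2_input=True``.

Cell-type labels are free strings; homology between labels in different
species is only ever asserted by the downstream statistics, never by the
labels matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationError, DataError, FormatError

__all__ = [
    "SampleAnnotation",
    "ExpressionDataset",
    "OrthologyRecord",
    "OrthologyMap",
    "GeneSet",
    "read_expression",
    "write_expression",
    "read_orthology",
    "write_orthology",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class SampleAnnotation:
    """One sample: which cell type it profiles and which replicate it is."""

    sample_id: str
    cell_type: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise AnnotationError(
                f"replicate must be a positive integer, got {self.replicate} "
                f"for sample {self.sample_id!r}"
            )


@dataclass
class ExpressionDataset:
    """One species' features x samples intensity matrix plus annotations.

    ``values`` is a pandas DataFrame (rows = probes or genes, columns =
    sample ids, linear scale, finite, >= 0).  ``level`` records whether rows
    are probes or genes; probe-level data must pass through
    :func:`crosscell.crossnorm.collapse_probes` before cross-species steps.
    """

    species_id: str
    values: pd.DataFrame
    samples: list[SampleAnnotation]
    level: str = "probe"

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise DataError(f"level must be 'probe' or 'gene', got {self.level!r}")
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()[:5]
            raise FormatError(f"duplicate feature ids: {dups}")
        sample_ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != sample_ids:
            raise AnnotationError(
                "annotation order does not match matrix columns: "
                f"{list(self.values.columns)[:5]}... vs {sample_ids[:5]}..."
            )
        seen: set[tuple[str, int]] = set()
        for s in self.samples:
            key = (s.cell_type, s.replicate)
            if key in seen:
                raise AnnotationError(f"duplicate (cell_type, replicate): {key}")
            seen.add(key)
        vals = self.values.to_numpy()
        if vals.size and (not np.all(np.isfinite(vals)) or vals.min() < 0):
            raise DataError(
                f"expression values must be finite and >= 0 (linear scale) "
                f"for species {self.species_id!r}"
            )

    # -- convenience views -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def cell_types(self) -> list[str]:
        """Sorted unique cell-type labels."""
        return sorted({s.cell_type for s in self.samples})

    def samples_of(self, cell_types: str | Iterable[str]) -> list[str]:
        """Sample ids belonging to one or several cell types (matrix order)."""
        if isinstance(cell_types, str):
            cell_types = {cell_types}
        else:
            cell_types = set(cell_types)
        return [s.sample_id for s in self.samples if s.cell_type in cell_types]

    def subset_cell_types(self, keep: Iterable[str]) -> "ExpressionDataset":
        """Restrict to samples of the given cell types (lineage-focused runs)."""
        keep = set(keep)
        missing = keep - set(self.cell_types)
        if missing:
            raise AnnotationError(
                f"unknown cell types {sorted(missing)} in species {self.species_id!r}"
            )
        samples = [s for s in self.samples if s.cell_type in keep]
        cols = [s.sample_id for s in samples]
        return ExpressionDataset(
            species_id=self.species_id,
            values=self.values[cols].copy(),
            samples=samples,
            level=self.level,
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionDataset":
        return ExpressionDataset(
            species_id=self.species_id,
            values=values,
            samples=list(self.samples),
            level=self.level,
        )


@dataclass(frozen=True)
class OrthologyRecord:
    species_id: str
    feature_id: str
    reference_symbol: str | None  # None = no ortholog known on this platform
    probe_functional: bool = True


class OrthologyMap:
    """Per-platform feature -> reference gene symbol mapping.

    Reference symbols are upper-cased on ingest (human-symbol convention);
    native feature ids stay case-sensitive.  A feature with no
    ``reference_symbol`` keeps its native id through translation, mirroring
    genes with no known ortholog on a platform.
    """

    def __init__(self, records: Iterable[OrthologyRecord]):
        self._records: dict[tuple[str, str], OrthologyRecord] = {}
        for rec in records:
            sym = rec.reference_symbol
            if sym is not None:
                sym = sym.strip().upper() or None
            rec = replace(rec, reference_symbol=sym)
            key = (rec.species_id, rec.feature_id)
            if key in self._records:
                raise FormatError(f"duplicate orthology record for {key}")
            self._records[key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def symbol_for(self, species_id: str, feature_id: str) -> str | None:
        rec = self._records.get((species_id, feature_id))
        return None if rec is None else rec.reference_symbol

    def is_functional(self, species_id: str, feature_id: str) -> bool:
        rec = self._records.get((species_id, feature_id))
        return True if rec is None else rec.probe_functional

    def translate_feature(self, species_id: str, feature_id: str) -> str:
        """Reference symbol if known, else the native feature id."""
        sym = self.symbol_for(species_id, feature_id)
        return sym if sym is not None else feature_id

    def has_functional_probe(self, species_id: str, reference_symbol: str) -> bool:
        """True iff the species' platform carries >= 1 functional feature for the symbol."""
        sym = reference_symbol.upper()
        return any(
            rec.reference_symbol == sym and rec.probe_functional
            for rec in self._records.values()
            if rec.species_id == species_id
        )

    def records_for_species(self, species_id: str) -> list[OrthologyRecord]:
        return [r for r in self._records.values() if r.species_id == species_id]


@dataclass
class GeneSet:
    """Named set of reference-species gene symbols with provenance.

    ``is_empty`` flags a legal-but-empty result (a cell type may simply have
    no gene passing the fold rule); emptiness is never an exception.
    """

    name: str
    description: str = ""
    symbols: frozenset[str] = field(default_factory=frozenset)
    source_species: str = ""
    index_cell_type: str = ""
    comparator_cell_types: tuple[str, ...] = ()
    fold_threshold: float | None = None

    def __post_init__(self) -> None:
        self.symbols = frozenset(self.symbols)

    @property
    def is_empty(self) -> bool:
        return len(self.symbols) == 0

    def __len__(self) -> int:
        return len(self.symbols)


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    # engine='c' handles CRLF; blank lines are skipped by default
    return pd.read_csv(path, sep="\t", **kw)


def read_expression(
    matrix_path: str | Path,
    annotation_path: str | Path,
    species_id: str,
    log2_input: bool = False,
    level: str = "probe",
) -> ExpressionDataset:
    """Read a features x samples TSV plus a sample-annotation TSV.

    The matrix has a header row of sample ids and feature ids in the first
    column.  The annotation table needs columns ``sample_id``, ``cell_type``
    and ``replicate``; every matrix sample must be annotated.  With
    ``log2_input`` values are exponentiated (``2**x``) so that all downstream
    ratios are linear-scale.
    """
    mat = _read_tsv(matrix_path, index_col=0)
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    if mat.index.has_duplicates:
        dups = mat.index[mat.index.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate feature ids in {matrix_path}: {dups}")

    ann = _read_tsv(annotation_path, dtype={"sample_id": str, "cell_type": str})
    required = {"sample_id", "cell_type", "replicate"}
    if not required.issubset(ann.columns):
        raise FormatError(
            f"annotation file {annotation_path} must have columns {sorted(required)}"
        )
    by_id = {row.sample_id: row for row in ann.itertuples()}
    samples = []
    for sid in mat.columns:
        if sid not in by_id:
            raise AnnotationError(
                f"sample {sid!r} in matrix has no annotation in {annotation_path}"
            )
        row = by_id[sid]
        samples.append(
            SampleAnnotation(sample_id=sid, cell_type=row.cell_type, replicate=int(row.replicate))
        )

    values = mat.astype(float)
    if log2_input:
        values = np.exp2(values)
    elif values.size and values.to_numpy().min() < 0:
        raise DataError(
            f"negative values in {matrix_path} with log2_input=False; "
            "pass log2_input=True for log2-scale matrices"
        )
    return ExpressionDataset(species_id=species_id, values=values, samples=samples, level=level)


def write_expression(
    dataset: ExpressionDataset, matrix_path: str | Path, annotation_path: str | Path
) -> None:
    """Write matrix + annotations in the format :func:`read_expression` reads."""
    # repr keeps the shortest round-trip representation of every float
    dataset.values.to_csv(
        matrix_path, sep="\t", index_label="feature_id",
        float_format=lambda x: repr(float(x)),
    )
    ann = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in dataset.samples],
            "cell_type": [s.cell_type for s in dataset.samples],
            "replicate": [s.replicate for s in dataset.samples],
        }
    )
    ann.to_csv(annotation_path, sep="\t", index=False)


def read_orthology(path: str | Path) -> OrthologyMap:
    """Read an orthology TSV: species_id, feature_id, reference_symbol, probe_functional.

    ``reference_symbol`` may be empty (no known ortholog); a missing
    ``probe_functional`` column means all probes are treated as functional.
    """
    df = _read_tsv(path, dtype=str, keep_default_na=False)
    required = {"species_id", "feature_id", "reference_symbol"}
    if not required.issubset(df.columns):
        raise FormatError(f"orthology file {path} must have columns {sorted(required)}")
    has_func = "probe_functional" in df.columns
    records = []
    for row in df.itertuples():
        sym = row.reference_symbol.strip() or None
        func = True
        if has_func and str(row.probe_functional).strip() not in ("", "1", "true", "True"):
            func = False
        records.append(
            OrthologyRecord(
                species_id=row.species_id,
                feature_id=row.feature_id,
                reference_symbol=sym,
                probe_functional=func,
            )
        )
    return OrthologyMap(records)


def write_orthology(omap: OrthologyMap, path: str | Path) -> None:
    rows = [
        {
            "species_id": r.species_id,
            "feature_id": r.feature_id,
            "reference_symbol": r.reference_symbol or "",
            "probe_functional": int(r.probe_functional),
        }
        for r in omap
    ]
    pd.DataFrame(rows, columns=["species_id", "feature_id", "reference_symbol", "probe_functional"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name TAB description TAB symbols...)."""
    sets: list[GeneSet] = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            symbols = frozenset(s for s in fields[2:] if s.strip())
            sets.append(GeneSet(name=name, description=desc, symbols=symbols))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        for gs in sets:
            # an empty set still needs a third (empty) field to stay valid GMT
            fields = [gs.name, gs.description, *sorted(gs.symbols)] if gs.symbols else [gs.name, gs.description, ""]
            fh.write("\t".join(fields) + "\n")
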