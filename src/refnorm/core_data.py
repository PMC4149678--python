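"""Data model for intensity matrices and run metadata.

An acquisition campaign is described by three objects:

* :class:`IntensityMatrix` — samples x metabolites nonnegative peak
  intensities with an explicit missing marker (NaN) and a recorded chain of
  applied normalization operators;
* a list of :class:`SampleRecord` — per-sample run metadata (batch, global
  injection order, test/reference role, dry weight, internal-standard signal);
* :class:`BatchLayout` — the derived batch -> ordered-runs index with the
  run-order positions of the reference injections.

Matrices and metadata are read and written as plain CSV/TSV so they can be
produced by any peak-integration export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "MetaboliteRecord",
    "SampleRecord",
    "IntensityMatrix",
    "BatchLayout",
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "validate_records",
    "build_layout",
]

ROLES = ("test", "reference")

# Strict-mode plausibility bounds for sample dry weight (mg); typical GC-MS
# forage workflows weigh a few mg of dry powder per extraction.
STRICT_DRY_WEIGHT_MG = (2.5, 3.5)


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicates, bad role, ...)."""


class ParseError(ValueError):
    """A file cell could not be interpreted; the message names row/column."""


@dataclass(frozen=True)
class MetaboliteRecord:
    """Annotation for one metabolite column.

    ``uncertain_annotation`` marks compounds identified with high spectral
    confidence whose chemical identity was not independently verified.
    """

    metabolite_id: str
    name: str = ""
    retention_time: float | None = None  # minutes
    quant_mz: float | None = None  # quantifier mass-to-charge ratio
    uncertain_annotation: bool = False

    def validate(self) -> None:
        if not self.metabolite_id:
            raise ValidationError("metabolite_id must be non-empty")
        if self.retention_time is not None and not (
            math.isfinite(self.retention_time) and self.retention_time >= 0
        ):
            raise ValidationError(
                f"metabolite {self.metabolite_id!r}: retention_time must be finite"
                f" and >= 0, got {self.retention_time}"
            )
        if self.quant_mz is not None and not (
            math.isfinite(self.quant_mz) and self.quant_mz > 0
        ):
            raise ValidationError(
                f"metabolite {self.metabolite_id!r}: quant_mz must be finite and"
                f" > 0, got {self.quant_mz}"
            )


@dataclass(frozen=True)
class SampleRecord:
    """Run metadata for one injection.

    ``run_order`` is the global injection index across the whole acquisition
    sequence (not per batch) so run-order distances and drift models are well
    defined across batches.  ``is_intensity`` is the internal-standard
    (e.g. ribitol) peak area of this injection.
    """

    sample_id: str
    batch_id: str
    run_order: int
    role: str  # "test" or "reference"
    dry_weight_mg: float
    is_intensity: float
    entry: str = ""
    site: str = ""

    def validate(self, strict: bool = False) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown role {self.role!r};"
                f" allowed values are {ROLES}"
            )
        if not (isinstance(self.run_order, (int, np.integer)) and self.run_order > 0):
            raise ValidationError(
                f"sample {self.sample_id!r}: run_order must be a positive integer,"
                f" got {self.run_order!r}"
            )
        if not (math.isfinite(self.dry_weight_mg) and self.dry_weight_mg > 0):
            raise ValidationError(
                f"sample {self.sample_id!r}: dry_weight_mg must be > 0,"
                f" got {self.dry_weight_mg}"
            )
        if not (math.isfinite(self.is_intensity) and self.is_intensity > 0):
            raise ValidationError(
                f"sample {self.sample_id!r}: is_intensity must be > 0,"
                f" got {self.is_intensity}"
            )
        if strict:
            lo, hi = STRICT_DRY_WEIGHT_MG
            if not (lo <= self.dry_weight_mg <= hi):
                raise ValidationError(
                    f"sample {self.sample_id!r}: dry_weight_mg {self.dry_weight_mg}"
                    f" outside plausible range [{lo}, {hi}] mg (strict mode)"
                )


class IntensityMatrix:
    """Samples x metabolites nonnegative intensities with missing markers.

    Values are stored in a float DataFrame whose index are sample ids and
    whose columns are metabolite ids; missing measurements are NaN (never
    zero — zero is a legitimate measured intensity, absence is not).  Every
    normalization operator applied to the matrix appends one
    ``(method, parameters)`` entry to :attr:`normalization_chain`.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        normalization_chain: Sequence[tuple[str, dict]] | None = None,
    ) -> None:
        data = data.astype(float)
        if data.index.has_duplicates:
            dups = sorted(data.index[data.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dups}")
        if data.columns.has_duplicates:
            dups = sorted(data.columns[data.columns.duplicated()].unique())
            raise ValidationError(f"duplicate metabolite ids: {dups}")
        arr = data.to_numpy()
        if np.isinf(arr).any():
            raise ValidationError("matrix contains non-finite (inf) values")
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative intensity at sample {data.index[bad[0]]!r},"
                f" metabolite {data.columns[bad[1]]!r}"
            )
        self.data = data
        self.normalization_chain: list[tuple[str, dict]] = list(
            normalization_chain or []
        )

    # -- conveniences -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.data.copy(), list(self.normalization_chain))

    def with_step(self, data: pd.DataFrame, method: str, params: dict) -> "IntensityMatrix":
        """New matrix with one more entry appended to the chain."""
        out = IntensityMatrix(data, list(self.normalization_chain))
        out.normalization_chain.append((method, dict(params)))
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        chain = " -> ".join(m for m, _ in self.normalization_chain) or "raw"
        return f"IntensityMatrix({self.shape[0]} samples x {self.shape[1]} metabolites, {chain})"


@dataclass
class BatchLayout:
    """Derived index: batch -> run-ordered samples and reference positions.

    ``samples_by_batch`` maps each batch id to its sample ids ordered by
    run order; ``reference_positions`` holds the run orders of the reference
    injections in that batch (empty list for a batch without references —
    representable here, rejected by the operators that need references).
    """

    samples_by_batch: dict[str, list[str]]
    reference_positions: dict[str, list[int]]
    batch_of: dict[str, str] = field(default_factory=dict)

    @property
    def batch_ids(self) -> list[str]:
        return list(self.samples_by_batch)


# ---------------------------------------------------------------------------
# CSV / TSV I/O
# ---------------------------------------------------------------------------

def _resolve_delimiter(path: str | Path, dialect: str | None) -> str:
    if dialect in (",", "\t"):
        return dialect
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect is None:
        return "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raise ValidationError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")


def read_matrix(
    path: str | Path,
    dialect: str | None = None,
    transpose: bool = False,
) -> IntensityMatrix:
    """Read a wide-format intensity matrix.

    Expected layout: header row of metabolite ids, first column sample ids,
    cells decimal or empty (empty / NA cells become missing).  ``transpose``
    accepts a metabolites-in-rows file; orientation is normalized to
    samples-in-rows internally.
    """
    sep = _resolve_delimiter(path, dialect)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if transpose:
        raw = raw.T

    values = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = arr[i, j].strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric cell {cell!r} at sample {raw.index[i]!r},"
                    f" metabolite {raw.columns[j]!r}"
                ) from None
    frame = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    return IntensityMatrix(frame)


def write_matrix(matrix: IntensityMatrix, path: str | Path, dialect: str | None = None) -> None:
    """Write a matrix as CSV/TSV; missing values become empty cells."""
    sep = _resolve_delimiter(path, dialect)
    df = matrix.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, na_rep="")


_META_REQUIRED = ["sample_id", "batch_id", "run_order", "role", "dry_weight_mg", "is_intensity"]
_META_OPTIONAL = ["entry", "site"]


def read_metadata(path: str | Path, strict: bool = False) -> list[SampleRecord]:
    """Read per-sample metadata CSV and validate the records."""
    df = pd.read_csv(path, dtype={"sample_id": str, "batch_id": str})
    missing = [c for c in _META_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                batch_id=str(row.batch_id),
                run_order=int(row.run_order),
                role=str(row.role),
                dry_weight_mg=float(row.dry_weight_mg),
                is_intensity=float(row.is_intensity),
                entry="" if not hasattr(row, "entry") or pd.isna(row.entry) else str(row.entry),
                site="" if not hasattr(row, "site") or pd.isna(row.site) else str(row.site),
            )
        )
    validate_records(records, strict=strict)
    return records


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "batch_id": r.batch_id,
            "run_order": r.run_order,
            "role": r.role,
            "entry": r.entry,
            "site": r.site,
            "dry_weight_mg": r.dry_weight_mg,
            "is_intensity": r.is_intensity,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_records(records: Sequence[SampleRecord], strict: bool = False) -> None:
    """Validate a metadata set: per-record invariants plus uniqueness."""
    if not records:
        raise ValidationError("metadata is empty")
    for r in records:
        r.validate(strict=strict)
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dups = sorted({s for s in ids if ids.count(s) > 1})
        raise ValidationError(f"duplicate sample ids in metadata: {dups}")
    orders = [r.run_order for r in records]
    if len(set(orders)) != len(orders):
        dups = sorted({o for o in orders if orders.count(o) > 1})
        raise ValidationError(f"duplicate run_order values: {dups}")


def build_layout(records: Sequence[SampleRecord]) -> BatchLayout:
    """Index validated records by batch, ordered by global run order.

    A pure function of the record set: permuting the input order does not
    change the layout.  A batch with zero reference injections is recorded
    with empty ``reference_positions``; operators that require references
    reject such batches downstream.
    """
    ordered = sorted(records, key=lambda r: r.run_order)
    samples_by_batch: dict[str, list[str]] = {}
    reference_positions: dict[str, list[int]] = {}
    batch_of: dict[str, str] = {}
    for r in ordered:
        samples_by_batch.setdefault(r.batch_id, []).append(r.sample_id)
        reference_positions.setdefault(r.batch_id, [])
        if r.role == "reference":
            reference_positions[r.batch_id].append(r.run_order)
        batch_of[r.sample_id] = r.batch_id
    return BatchLayout(samples_by_batch, reference_positions, batch_of)
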