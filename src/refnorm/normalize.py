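"""Normalization operators for multi-batch GC-MS intensity matrices.

The canonical batch-correction chain is

1. :func:`normalize_is_dryweight` — divide every intensity by the sample's
   internal-standard peak area and dry weight, removing sample-level
   technical variation shared with the internal standard;
2. :func:`normalize_to_reference` — express each analyte as a ratio to its
   value in the nearest (by run order) reference injection of the same
   batch, removing analyte-specific batch effects because the reference
   samples of every batch derive from one pooled material.

The remaining operators are the baseline methods commonly used for batch
correction: per-sample scalar normalization (total sum or median), QC
median-factor correction, and QC-based robust LOESS signal correction
(QC-RLSC).  All operators preserve matrix shape, keep missing values
missing, record themselves on the matrix's normalization chain, and report
per-cell annotations through :class:`NormalizationResult.flags`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from refnorm.core_data import (
    BatchLayout,
    IntensityMatrix,
    SampleRecord,
    ValidationError,
)

__all__ = [
    "ReferenceAssignment",
    "NormalizationResult",
    "normalize_is_dryweight",
    "normalize_scalar",
    "assign_references",
    "normalize_to_reference",
    "qc_median_correction",
    "qc_rlsc",
    "write_flags",
]

FLAG_ZERO_REFERENCE = "made-missing-by-zero-reference"
FLAG_QC_MEDIAN_UNDEFINED = "qc-median-undefined"
FLAG_RLSC_FALLBACK = "rlsc-fallback-to-qc-median"
FLAG_RLSC_NONPOSITIVE_FIT = "made-missing-by-nonpositive-fit"


@dataclass
class ReferenceAssignment:
    """Mapping of each sample to its nearest reference injection(s).

    ``assigned[sample_id]`` is a list of ``(reference_sample_id, distance)``
    pairs within the sample's own batch; length 1 unless two references are
    exactly equidistant in run order (then both are kept).  A reference
    injection's nearest reference is itself (distance 0).
    """

    assigned: dict[str, list[tuple[str, int]]]

    def references_for(self, sample_id: str) -> list[str]:
        return [ref for ref, _ in self.assigned[sample_id]]


@dataclass
class NormalizationResult:
    """Transformed matrix plus the operator's identity and cell flags.

    ``flags`` is a tidy table (sample_id, metabolite_id, flag); empty when
    the operator raised no per-cell annotations.
    """

    matrix: IntensityMatrix
    method: str
    parameters: dict
    flags: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "metabolite_id", "flag"]
        )
    )


def _records_by_id(records: Sequence[SampleRecord]) -> dict[str, SampleRecord]:
    return {r.sample_id: r for r in records}


def _require_metadata(matrix: IntensityMatrix, by_id: dict[str, SampleRecord]) -> None:
    missing = [s for s in matrix.sample_ids if s not in by_id]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")


def _flags_frame(rows: list[tuple[str, str, str]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["sample_id", "metabolite_id", "flag"])


def write_flags(result: NormalizationResult, path: str | Path) -> None:
    """Write the per-cell flag sidecar CSV."""
    result.flags.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# internal standard + dry weight
# ---------------------------------------------------------------------------

def normalize_is_dryweight(
    matrix: IntensityMatrix, records: Sequence[SampleRecord]
) -> NormalizationResult:
    """Divide each sample's intensities by IS peak area x dry weight (mg).

    Output units are peak-area ratio per mg of dry tissue.  Zeros are
    preserved (a zero intensity normalizes to zero); missing stays missing.
    """
    by_id = _records_by_id(records)
    _require_metadata(matrix, by_id)
    divisor = pd.Series(
        {s: by_id[s].is_intensity * by_id[s].dry_weight_mg for s in matrix.sample_ids}
    )
    out = matrix.data.div(divisor, axis=0)
    new = matrix.with_step(out, "is_dryweight", {})
    return NormalizationResult(new, "is_dryweight", {})


# ---------------------------------------------------------------------------
# scalar baselines
# ---------------------------------------------------------------------------

def normalize_scalar(
    matrix: IntensityMatrix, statistic: str = "total_sum"
) -> NormalizationResult:
    """Divide each sample's row by its own total sum or median.

    Missing cells are excluded from the per-sample statistic.  Assumes the
    bulk of the signal is constant across samples — the assumption this
    baseline is known to violate when major metabolites shift.
    """
    if statistic not in ("total_sum", "median"):
        raise ValidationError(
            f"unknown statistic {statistic!r}; allowed: total_sum, median"
        )
    if statistic == "total_sum":
        stat = matrix.data.sum(axis=1, skipna=True)
        stat[matrix.data.isna().all(axis=1)] = np.nan
    else:
        stat = matrix.data.median(axis=1, skipna=True)
    bad = stat.index[~(stat > 0)]
    if len(bad):
        raise ValidationError(
            f"per-sample {statistic} not positive for samples: {list(bad)}"
        )
    out = matrix.data.div(stat, axis=0)
    params = {"statistic": statistic}
    new = matrix.with_step(out, "scalar", params)
    return NormalizationResult(new, "scalar", params)


# ---------------------------------------------------------------------------
# reference-ratio normalization
# ---------------------------------------------------------------------------

def assign_references(
    layout: BatchLayout, records: Sequence[SampleRecord]
) -> ReferenceAssignment:
    """Map every sample to the reference injection(s) nearest in run order.

    Closeness is measured in run-order index within the sample's own batch;
    exact ties keep both references.  A batch containing test samples but no
    reference injection is an error naming the batch.
    """
    by_id = _records_by_id(records)
    ref_by_batch: dict[str, list[SampleRecord]] = {}
    for r in records:
        if r.role == "reference":
            ref_by_batch.setdefault(r.batch_id, []).append(r)

    assigned: dict[str, list[tuple[str, int]]] = {}
    for batch, sample_ids in layout.samples_by_batch.items():
        refs = ref_by_batch.get(batch, [])
        has_tests = any(by_id[s].role == "test" for s in sample_ids)
        if has_tests and not refs:
            raise ValidationError(
                f"batch {batch!r} contains test samples but no reference injection"
            )
        for sid in sample_ids:
            rec = by_id[sid]
            if rec.role == "reference":
                assigned[sid] = [(sid, 0)]
                continue
            dists = [(abs(rec.run_order - ref.run_order), ref) for ref in refs]
            dmin = min(d for d, _ in dists)
            nearest = sorted(
                [(ref.sample_id, d) for d, ref in dists if d == dmin],
                key=lambda t: t[0],
            )
            assigned[sid] = nearest
    return ReferenceAssignment(assigned)


def normalize_to_reference(
    matrix: IntensityMatrix,
    assignment: ReferenceAssignment,
    policy: str = "flag",
) -> NormalizationResult:
    """Express each analyte as a ratio to its nearest-reference value.

    On an exact run-order tie the two reference intensities are averaged
    first and the test value divided by the mean — the two injections are
    treated as replicate measurements of one reference level.  A reference
    injection normalized against itself yields exactly 1 for every
    non-missing metabolite.

    A zero or missing reference value makes the cell missing and flags it
    (``policy="flag"``, default) or drops the whole metabolite column
    (``policy="drop"``).
    """
    if policy not in ("flag", "drop"):
        raise ValidationError(f"unknown policy {policy!r}; allowed: flag, drop")
    chain_methods = [m for m, _ in matrix.normalization_chain]
    if "is_dryweight" not in chain_methods:
        import warnings

        warnings.warn(
            "normalize_to_reference applied to a matrix without a prior"
            " is_dryweight step; ratios will include IS/dry-weight variation",
            stacklevel=2,
        )
    missing = [s for s in matrix.sample_ids if s not in assignment.assigned]
    if missing:
        raise ValidationError(f"samples missing from reference assignment: {missing}")

    data = matrix.data
    out = pd.DataFrame(
        np.nan, index=data.index, columns=data.columns, dtype=float
    )
    flag_rows: list[tuple[str, str, str]] = []
    bad_metabolites: set[str] = set()

    for sid in matrix.sample_ids:
        refs = assignment.references_for(sid)
        if refs == [sid]:
            # self-reference: exact ones wherever the measurement exists
            row = data.loc[sid]
            out.loc[sid] = np.where(row.notna(), 1.0, np.nan)
            continue
        ref_vals = data.loc[refs].mean(axis=0, skipna=False)
        ratio = data.loc[sid] / ref_vals
        invalid = (ref_vals.isna() | (ref_vals == 0)) & data.loc[sid].notna()
        ratio[invalid] = np.nan
        out.loc[sid] = ratio
        for met in data.columns[invalid]:
            flag_rows.append((sid, met, FLAG_ZERO_REFERENCE))
            bad_metabolites.add(met)

    params = {"policy": policy}
    if policy == "drop" and bad_metabolites:
        keep = [m for m in out.columns if m not in bad_metabolites]
        out = out[keep]
        flag_rows = [
            (s, m, f) for s, m, f in flag_rows if f != FLAG_ZERO_REFERENCE
        ] + [("", m, "metabolite-dropped-by-zero-reference") for m in sorted(bad_metabolites)]
    new = matrix.with_step(out, "reference_ratio", params)
    return NormalizationResult(new, "reference_ratio", params, _flags_frame(flag_rows))


# ---------------------------------------------------------------------------
# QC-based baselines
# ---------------------------------------------------------------------------

def _qc_values(
    matrix: IntensityMatrix, records: Sequence[SampleRecord]
) -> tuple[dict[str, list[str]], list[str]]:
    """Reference/QC sample ids per batch, plus the flat QC id list."""
    qc_by_batch: dict[str, list[str]] = {}
    in_matrix = set(matrix.sample_ids)
    for r in sorted(records, key=lambda r: r.run_order):
        if r.role == "reference" and r.sample_id in in_matrix:
            qc_by_batch.setdefault(r.batch_id, []).append(r.sample_id)
    qc_all = [s for batch in qc_by_batch.values() for s in batch]
    return qc_by_batch, qc_all


def qc_median_correction(
    matrix: IntensityMatrix, records: Sequence[SampleRecord]
) -> NormalizationResult:
    """Batch-median factor correction against the pooled QC signal.

    Per metabolite ``m`` and batch ``b`` the factor is
    ``median(QC values of m in b) / median(QC values of m over all batches)``;
    every value of ``m`` in batch ``b`` is divided by it.  A metabolite whose
    global QC median is nonpositive or undefined is flagged and left
    unchanged; likewise per batch for an undefined batch median.
    """
    by_id = _records_by_id(records)
    _require_metadata(matrix, by_id)
    qc_by_batch, qc_all = _qc_values(matrix, records)
    batches_present = {by_id[s].batch_id for s in matrix.sample_ids}
    missing_qc = sorted(b for b in batches_present if not qc_by_batch.get(b))
    if missing_qc:
        raise ValidationError(
            f"batches without reference/QC injections: {missing_qc}"
        )

    data = matrix.data
    out = data.copy()
    flag_rows: list[tuple[str, str, str]] = []
    global_median = data.loc[qc_all].median(axis=0, skipna=True)

    sample_batch = pd.Series({s: by_id[s].batch_id for s in matrix.sample_ids})
    for met in data.columns:
        gmed = global_median[met]
        if not (gmed > 0):
            flag_rows.append(("", met, FLAG_QC_MEDIAN_UNDEFINED))
            continue
        for batch, qcs in qc_by_batch.items():
            bmed = data.loc[qcs, met].median(skipna=True)
            if not (bmed > 0):
                flag_rows.append(("", met, FLAG_QC_MEDIAN_UNDEFINED))
                continue
            factor = bmed / gmed
            rows = sample_batch.index[sample_batch == batch]
            out.loc[rows, met] = data.loc[rows, met] / factor

    new = matrix.with_step(out, "qc_median", {})
    return NormalizationResult(new, "qc_median", {}, _flags_frame(flag_rows))


def qc_rlsc(
    matrix: IntensityMatrix,
    records: Sequence[SampleRecord],
    span: float = 0.75,
    min_qc_points: int = 4,
) -> NormalizationResult:
    """QC-based robust LOESS signal correction (QC-RLSC).

    Per metabolite, a locally weighted degree-1 regression of the QC signal
    on run order is fitted (plain LOESS, zero robustness iterations); each
    sample's value is divided by the fit evaluated at its run order —
    clamped to the QC run-order range so extrapolation uses the nearest
    fitted value — then multiplied by the metabolite's global QC median so
    corrected values stay on the intensity scale.

    A metabolite with fewer than ``min_qc_points`` non-missing QC values
    falls back to :func:`qc_median_correction` for that metabolite (flagged);
    a nonpositive fitted value makes the affected cells missing (flagged).
    """
    if not (0 < span <= 1):
        raise ValidationError(f"span must be in (0, 1], got {span}")
    by_id = _records_by_id(records)
    _require_metadata(matrix, by_id)
    qc_by_batch, qc_all = _qc_values(matrix, records)
    if not qc_all:
        raise ValidationError("no reference/QC injections present in the matrix")

    data = matrix.data
    out = data.copy()
    flag_rows: list[tuple[str, str, str]] = []
    fallback_mets: list[str] = []

    run_order = pd.Series({s: by_id[s].run_order for s in matrix.sample_ids}, dtype=float)
    qc_orders = run_order[qc_all]

    for met in data.columns:
        qc_y = data.loc[qc_all, met]
        ok = qc_y.notna()
        if ok.sum() < min_qc_points:
            fallback_mets.append(met)
            flag_rows.append(("", met, FLAG_RLSC_FALLBACK))
            continue
        x = qc_orders[ok].to_numpy()
        y = qc_y[ok].to_numpy()
        order = np.argsort(x)
        x, y = x[order], y[order]
        xv = run_order.to_numpy().clip(x.min(), x.max())
        fit = np.atleast_1d(lowess(y, x, frac=span, it=0, xvals=xv))
        bad_fit = ~np.isfinite(fit)
        if bad_fit.any():
            # degenerate local windows (e.g. only 2 QC points): interpolate
            # the fit evaluated at the QC run orders, which for a degree-1
            # window spanning both points is the exact connecting line
            at_qc = lowess(y, x, frac=span, it=0)
            fit[bad_fit] = np.interp(xv[bad_fit], at_qc[:, 0], at_qc[:, 1])
        gmed = float(np.median(y))
        with np.errstate(divide="ignore", invalid="ignore"):
            corrected = data[met].to_numpy() / fit * gmed
        nonpos = (fit <= 0) & data[met].notna().to_numpy()
        corrected[nonpos] = np.nan
        out[met] = corrected
        for sid in data.index[nonpos]:
            flag_rows.append((sid, met, FLAG_RLSC_NONPOSITIVE_FIT))

    if fallback_mets:
        qcm = qc_median_correction(matrix, records)
        out[fallback_mets] = qcm.matrix.data[fallback_mets]

    params = {"span": span, "min_qc_points": min_qc_points}
    new = matrix.with_step(out, "qc_rlsc", params)
    return NormalizationResult(new, "qc_rlsc", params, _flags_frame(flag_rows))
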