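"""Evaluation battery for batch-correction quality.

Diagnostics mirror how multi-batch GC-MS studies are judged in practice:

* per-metabolite relative standard deviation (RSD% = 100 x sd/mean, sample
  sd) within groups of nominally identical samples, compared before vs
  after correction;
* the RSD-vs-abundance relationship (technical noise is typically larger,
  relative to signal, for low-abundance analytes);
* PCA on the correlation matrix with per-component percent variance — a
  successful correction spreads variance over more components because the
  dominant batch axis is removed;
* Ward hierarchical clustering on standardized data, where batch structure
  shows up as run-order clustering of replicate samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import pearsonr

from refnorm.core_data import IntensityMatrix, ValidationError

__all__ = [
    "RsdTable",
    "PcaSummary",
    "LinkageTree",
    "compute_rsd",
    "rsd_reduction_summary",
    "rsd_vs_abundance",
    "pca_correlation",
    "pca_variance_delta",
    "average_replicates",
    "hca_ward",
]


@dataclass
class RsdTable:
    """Per-(metabolite, group) dispersion: mean abundance and RSD percent.

    ``table`` columns: metabolite_id, group, n, mean_abundance, rsd_percent.
    RSD is missing (NaN) when the group has fewer than 2 non-missing values
    or a zero mean.
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class PcaSummary:
    """Scores and percent variance from PCA of the correlation matrix."""

    scores: pd.DataFrame  # samples x components
    percent_variance: np.ndarray  # per component, eigenvalue / total x 100
    excluded_metabolites: list[str]  # zero-variance columns left out

    def to_csv(self, path) -> None:
        df = self.scores.copy()
        df.to_csv(path)


@dataclass
class LinkageTree:
    """Agglomerative merge table over n leaves (n-1 merges).

    ``merges`` is the standard 4-column linkage array (cluster a, cluster b,
    height, new size); leaves are numbered 0..n-1 in ``leaf_labels`` order.
    """

    merges: np.ndarray
    leaf_labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "height", "size"]
        ).to_csv(path, index=False)

    def to_newick(self) -> str:
        """Newick string with merge heights converted to branch lengths."""
        root = hierarchy.to_tree(self.merges)

        def walk(node) -> str:
            if node.is_leaf():
                return self.leaf_labels[node.id]
            left, right = node.get_left(), node.get_right()
            parts = []
            for child in (left, right):
                bl = node.dist - (0.0 if child.is_leaf() else child.dist)
                parts.append(f"{walk(child)}:{bl:g}")
            return f"({','.join(parts)})"

        return walk(root) + ";"


# ---------------------------------------------------------------------------
# RSD
# ---------------------------------------------------------------------------

def _as_series(grouping: Mapping[str, str] | pd.Series) -> pd.Series:
    if isinstance(grouping, pd.Series):
        return grouping.astype(str)
    return pd.Series({k: str(v) for k, v in dict(grouping).items()})


def compute_rsd(
    matrix: IntensityMatrix, grouping: Mapping[str, str] | pd.Series
) -> RsdTable:
    """Per-metabolite RSD% = 100 x sd/mean within each sample group.

    The standard deviation is the sample formula (n-1 denominator).  Groups
    with fewer than 2 non-missing values, or zero mean, yield missing RSD.
    Samples absent from ``grouping`` are excluded.
    """
    g = _as_series(grouping)
    if g.empty:
        raise ValidationError("grouping is empty")
    samples = [s for s in matrix.sample_ids if s in g.index]
    if not samples:
        raise ValidationError("grouping covers no sample of the matrix")
    data = matrix.data.loc[samples]
    labels = g[samples]

    rows = []
    for group, idx in data.groupby(labels).groups.items():
        sub = data.loc[idx]
        n = sub.notna().sum(axis=0)
        mean = sub.mean(axis=0, skipna=True)
        sd = sub.std(axis=0, ddof=1, skipna=True)
        rsd = 100.0 * sd / mean
        rsd[(n < 2) | (mean == 0) | mean.isna()] = np.nan
        for met in data.columns:
            rows.append(
                {
                    "metabolite_id": met,
                    "group": group,
                    "n": int(n[met]),
                    "mean_abundance": mean[met],
                    "rsd_percent": rsd[met],
                }
            )
    return RsdTable(pd.DataFrame(rows))


def rsd_reduction_summary(before: RsdTable, after: RsdTable) -> dict:
    """Fraction of metabolites whose RSD strictly decreased after correction.

    Ties count as not reduced (conservative toward the correction).  Returns
    the overall fractions, a per-group breakdown, and the paired
    (before, after) table for scatter plotting.
    """
    key = ["metabolite_id", "group"]
    b = before.table.set_index(key)["rsd_percent"]
    a = after.table.set_index(key)["rsd_percent"]
    if set(b.index) != set(a.index):
        only_b = sorted(set(b.index) - set(a.index))
        only_a = sorted(set(a.index) - set(b.index))
        raise ValidationError(
            f"RSD tables cover different (metabolite, group) sets;"
            f" only-before={only_b[:5]} only-after={only_a[:5]}"
        )
    paired = pd.DataFrame({"before": b, "after": a.reindex(b.index)}).dropna()
    if paired.empty:
        raise ValidationError("no (metabolite, group) pair has defined RSD in both tables")
    reduced = paired["after"] < paired["before"]
    increased = paired["after"] > paired["before"]
    per_group = (
        paired.assign(reduced=reduced)
        .groupby(level="group")["reduced"]
        .mean()
        .to_dict()
    )
    return {
        "fraction_reduced": float(reduced.mean()),
        "fraction_increased": float(increased.mean()),
        "n_pairs": int(len(paired)),
        "per_group_fraction_reduced": per_group,
        "paired": paired.reset_index(),
    }


def rsd_vs_abundance(table: RsdTable, log_abundance: bool = False) -> dict:
    """Pearson correlation of RSD% against (optionally log10) mean abundance.

    Returns the signed correlation coefficient, its p-value and the
    (abundance, RSD) pairs for scatter plotting; the correlation is missing
    when either variable has zero variance.
    """
    t = table.table.dropna(subset=["rsd_percent", "mean_abundance"])
    x = t["mean_abundance"].to_numpy(dtype=float)
    y = t["rsd_percent"].to_numpy(dtype=float)
    if log_abundance:
        keep = x > 0
        x, y = np.log10(x[keep]), y[keep]
    if len(x) < 3:
        raise ValidationError("need >= 3 metabolites with defined RSD")
    if np.std(x) == 0 or np.std(y) == 0:
        r, p = np.nan, np.nan
    else:
        r, p = pearsonr(x, y)
    return {
        "pearson_r": float(r) if np.isfinite(r) else np.nan,
        "p_value": float(p) if np.isfinite(p) else np.nan,
        "n": int(len(x)),
        "pairs": pd.DataFrame({"abundance": x, "rsd_percent": y}),
        "log_abundance": log_abundance,
    }


# ---------------------------------------------------------------------------
# PCA on the correlation matrix
# ---------------------------------------------------------------------------

def pca_correlation(matrix: IntensityMatrix, k: int | None = None) -> PcaSummary:
    """PCA of the metabolite correlation matrix.

    Columns are standardized to mean 0, sd 1 (sample sd); zero-variance or
    all-missing metabolites are excluded and reported.  Remaining missing
    cells are imputed at the column mean (0 after standardization) for the
    decomposition only.  Percent variance per component is
    eigenvalue / total x 100; each loading vector is oriented so its
    largest-magnitude element is positive, for reproducible score plots.
    """
    data = matrix.data
    if data.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    sd = data.std(axis=0, ddof=1, skipna=True)
    excluded = [m for m in data.columns if not (sd[m] > 0)]
    kept = [m for m in data.columns if m not in excluded]
    if not kept:
        raise ValidationError("all metabolites have zero variance")
    z = (data[kept] - data[kept].mean(axis=0)) / sd[kept]
    z = z.fillna(0.0)

    n = z.shape[0]
    corr = (z.to_numpy().T @ z.to_numpy()) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    # orient each loading vector: largest-magnitude element positive
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]

    percent = 100.0 * eigval / eigval.sum()
    if k is None:
        k = len(eigval)
    k = min(k, len(eigval))
    scores = pd.DataFrame(
        z.to_numpy() @ eigvec[:, :k],
        index=data.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaSummary(scores, percent[:k], excluded)


def pca_variance_delta(before: PcaSummary, after: PcaSummary) -> dict:
    """(PC1+PC2 percent before) - (PC1+PC2 percent after).

    Positive values mean the correction spread variance across more
    components; negative deltas are reported as-is, never clipped.
    """
    for name, s in (("before", before), ("after", after)):
        if len(s.percent_variance) < 2:
            raise ValidationError(f"{name} summary reports fewer than 2 components")
    b = float(before.percent_variance[0] + before.percent_variance[1])
    a = float(after.percent_variance[0] + after.percent_variance[1])
    return {"pc12_before": b, "pc12_after": a, "delta": b - a}


# ---------------------------------------------------------------------------
# replicate averaging and Ward clustering
# ---------------------------------------------------------------------------

def average_replicates(
    matrix: IntensityMatrix, grouping: Mapping[str, str] | pd.Series
) -> IntensityMatrix:
    """Collapse replicate samples to one row per group (mean of non-missing).

    All-missing cells stay missing; singleton groups pass through unchanged.
    """
    g = _as_series(grouping)
    uncovered = [s for s in matrix.sample_ids if s not in g.index]
    if uncovered:
        raise ValidationError(f"grouping does not cover samples: {uncovered}")
    out = matrix.data.groupby(g[matrix.sample_ids]).mean()
    out.index = out.index.astype(str)
    collapsed = IntensityMatrix(out, list(matrix.normalization_chain))
    collapsed.normalization_chain.append(("average_replicates", {}))
    return collapsed


def hca_ward(matrix: IntensityMatrix, standardize: bool = True) -> LinkageTree:
    """Ward hierarchical clustering of samples on Euclidean distances.

    Metabolites are standardized to mean 0, sd 1 before computing distances
    (``standardize=False`` skips this, for clustering pre-scaled data).  The
    Ward variant is the one whose merge height between two singletons equals
    their Euclidean distance (heights are sqrt(2 x ESS increment)), so
    heights are nondecreasing.  Missing cells are imputed at the column mean
    for the distance computation; zero-variance columns are dropped when
    standardizing.
    """
    data = matrix.data
    if data.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 samples")
    if standardize:
        sd = data.std(axis=0, ddof=1, skipna=True)
        kept = [m for m in data.columns if sd[m] > 0]
        if not kept:
            raise ValidationError("all metabolites have zero variance")
        z = (data[kept] - data[kept].mean(axis=0)) / sd[kept]
    else:
        z = data - 0.0
    z = z.apply(lambda col: col.fillna(col.mean()), axis=0).fillna(0.0)
    merges = hierarchy.linkage(z.to_numpy(), method="ward")
    return LinkageTree(merges, list(data.index))
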