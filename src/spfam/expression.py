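"""RPKM transforms, hierarchical clustering and qPCR normalisation.

RPKM matrices are log2-transformed (zeros become missing, matching the
heat-map convention of rendering unexpressed genes gray), genes are
clustered with Euclidean distance and complete linkage, per-sample
expressed-gene counts use a strict RPKM > threshold rule (default 0),
and qPCR Ct values are normalised against a housekeeping reference gene
(2^-dCt, optionally ddCt against a calibrator sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .seqio import ExpressionMatrix

__all__ = [
    "ClusterResult",
    "log2_transform",
    "missing_euclidean",
    "hcluster_genes",
    "expressed_counts",
    "qpcr_relative_expression",
]


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2 of positive RPKM; zeros become missing; missing stays missing."""
    data = m.data.copy()
    arr = data.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(arr > 0, np.log2(np.where(arr > 0, arr, 1.0)), np.nan)
    return ExpressionMatrixLog(pd.DataFrame(out, index=data.index, columns=data.columns))


class ExpressionMatrixLog(ExpressionMatrix):
    """Log-scale matrix: values may be negative (log2 of RPKM < 1)."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates or data.columns.has_duplicates:
            raise ValueError("duplicate labels in expression matrix")
        self.data = data.astype(float)


def missing_euclidean(values: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance over mutually present columns,
    rescaled by total/present column counts (Cluster 3.0 convention)."""
    n, p = values.shape
    present = ~np.isnan(values)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            k = int(both.sum())
            if k == 0:
                raise ValueError(
                    f"rows {i} and {j} share no present columns"
                )
            diff = values[i, both] - values[j, both]
            d = float(np.sqrt(np.sum(diff * diff) * (p / k)))
            out[i, j] = out[j, i] = d
    return out


@dataclass
class ClusterResult:
    genes: list[str]            # input order (post-exclusion), sorted by id
    merge_tree: np.ndarray      # scipy linkage matrix
    leaf_order: list[str]       # dendrogram leaf order
    excluded: list[str]         # all-missing genes dropped before clustering

    def cut(self, k: int) -> dict[str, int]:
        """Flat groups at k clusters (labels 1..k)."""
        labels = fcluster(self.merge_tree, t=k, criterion="maxclust")
        return dict(zip(self.genes, (int(l) for l in labels)))

    def merge_heights(self) -> np.ndarray:
        return self.merge_tree[:, 2]


def hcluster_genes(
    m: ExpressionMatrix,
    metric: str = "euclidean",
    method: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of gene rows (Euclidean / complete linkage).

    Genes are processed in sorted-id order for deterministic
    tie-breaking; all-missing rows are excluded with a warning.
    Missing-aware distances follow the Cluster 3.0 rescaling.
    """
    if metric != "euclidean":
        raise ValueError("only the Euclidean metric is supported")
    data = m.data.sort_index()
    arr = data.to_numpy(dtype=float)
    all_missing = np.isnan(arr).all(axis=1)
    excluded = [g for g, bad in zip(data.index, all_missing) if bad]
    if excluded:
        warnings.warn(f"excluding all-missing genes from clustering: {excluded}")
        data = data.loc[~all_missing]
        arr = data.to_numpy(dtype=float)
    if len(data) < 2:
        raise ValueError("clustering requires >= 2 genes with data")
    dist = missing_euclidean(arr)
    Z = linkage(squareform(dist, checks=False), method=method)
    order = [data.index[i] for i in leaves_list(Z)]
    return ClusterResult(
        genes=list(data.index),
        merge_tree=Z,
        leaf_order=order,
        excluded=excluded,
    )


def expressed_counts(
    m: ExpressionMatrix, threshold: float = 0.0
) -> tuple[pd.Series, int]:
    """Per-sample expressed-gene counts (RPKM > threshold) and the number
    of genes expressed in at least one sample.  Missing never counts."""
    arr = m.data.to_numpy(dtype=float)
    expressed = np.where(np.isnan(arr), False, arr > threshold)
    per_sample = pd.Series(expressed.sum(axis=0), index=m.samples, dtype=int)
    any_sample = int(expressed.any(axis=1).sum())
    return per_sample, any_sample


def qpcr_relative_expression(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str | None = None,
) -> pd.DataFrame:
    """Housekeeping-normalised qPCR expression (2^-dCt per gene x sample).

    Replicate Ct values are averaged per gene x sample; dCt subtracts
    the reference gene's mean Ct in the same sample.  With a calibrator
    sample, returns 2^-ddCt relative to it instead.  A sample without
    the reference gene is a hard error.
    """
    mean_ct = table.groupby(["gene", "sample"])["Ct"].mean().unstack("sample")
    if reference_gene not in mean_ct.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    ref = mean_ct.loc[reference_gene]
    if ref.isna().any():
        bad = list(ref.index[ref.isna()])
        raise ValueError(f"reference gene missing in samples: {bad}")
    dct = mean_ct.drop(index=reference_gene).sub(ref, axis=1)
    if calibrator_sample is not None:
        if calibrator_sample not in dct.columns:
            raise ValueError(f"calibrator sample {calibrator_sample!r} absent")
        dct = dct.sub(dct[calibrator_sample], axis=0)
    return np.power(2.0, -dct)
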