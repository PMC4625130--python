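"""Expression normalization chain and sample clustering.

The chain runs in a fixed, auditable order:

1. FPKM from raw counts and transcript lengths,
2. per-sample OLS residuals of log2(FPKM + pseudocount) on GC content,
   log10 transcript length, and their interaction (covariate-bias removal),
3. across-sample quantile normalization of the residuals,
4. per-individual centering by the 10% trimmed (Tukey's) mean of each
   transcript across that individual's treatments.

Each stage tags its output (``df.attrs["stage"]``) and refuses input from
the wrong stage, so the order is enforced. Stages are also exposed as
sklearn transformers composable in a Pipeline.

Clustering is average-linkage agglomeration on 1 - Pearson correlation
between sample columns, with dendrogram, leaf order, and Newick export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ClusterResult",
    "fpkm",
    "regress_out_covariates",
    "quantile_normalize",
    "trimmed_center",
    "correlate_and_cluster",
    "FpkmTransformer",
    "CovariateResidualTransformer",
    "QuantileNormalizer",
    "TrimmedMeanCenterer",
    "normalization_pipeline",
]

STAGES = ("counts", "fpkm", "residual", "quantile", "centered")


def _stage_of(df: pd.DataFrame) -> str:
    return df.attrs.get("stage", "counts")


def _require_stage(df: pd.DataFrame, expected: str, op: str):
    got = _stage_of(df)
    if got != expected:
        raise ValueError(f"{op} expects a {expected!r}-stage matrix, got {got!r}")


def _tagged(values, template: pd.DataFrame, stage: str) -> pd.DataFrame:
    out = pd.DataFrame(values, index=template.index, columns=template.columns)
    out.attrs["stage"] = stage
    return out


def fpkm(counts: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Fragments per kilobase per million: count * 1e9 / (length * sample total)."""
    lengths = annotation["length_bp"].reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"transcripts missing from annotation (first few): {missing}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be > 0")
    totals = counts.sum(axis=0).astype(float)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    vals = counts.to_numpy(float) * 1e9 / (lengths.to_numpy(float)[:, None] * totals.to_numpy()[None, :])
    return _tagged(vals, counts, "fpkm")


def regress_out_covariates(
    expr: pd.DataFrame, annotation: pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-sample OLS residuals of log2(FPKM + pseudocount) on GC, log10 length, GC x log10 length."""
    _require_stage(expr, "fpkm", "regress_out_covariates")
    ann = annotation.reindex(expr.index)
    gc = ann["gc_fraction"].to_numpy(float)
    loglen = np.log10(ann["length_bp"].to_numpy(float))
    X = np.column_stack([np.ones(len(gc)), gc, loglen, gc * loglen])
    # drop collinear columns (e.g. constant GC) instead of failing
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(f"covariate column {j} is collinear; dropped from the regression")
    Xk = X[:, keep]
    Y = np.log2(expr.to_numpy(float) + pseudocount)
    beta, *_ = np.linalg.lstsq(Xk, Y, rcond=None)
    resid = Y - Xk @ beta
    return _tagged(resid, expr, "residual")


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Across-sample quantile normalization.

    Every sample's values are replaced by the mean of the order statistics
    across samples at the same rank; ties receive the mean of the reference
    values they span (average ranks interpolated into the reference).
    """
    _require_stage(expr, "residual", "quantile_normalize")
    x = expr.to_numpy(float)
    n = x.shape[0]
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, ref)
    return _tagged(out, expr, "quantile")


def trimmed_center(
    expr: pd.DataFrame, individuals, trim: float = 0.1
) -> pd.DataFrame:
    """Center each transcript within each individual by its trimmed mean.

    The trimmed mean drops floor(trim * n) values from each tail (R
    ``mean(x, trim=)`` semantics). Individuals with fewer than 3 samples get
    a plain mean (with a warning).
    """
    _require_stage(expr, "quantile", "trimmed_center")
    if not 0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    ind = pd.Series(individuals).reindex(expr.columns)
    if ind.isna().any():
        raise ValueError("individual labels missing for some samples")
    out = expr.copy()
    for person, cols in ind.groupby(ind).groups.items():
        cols = list(cols)
        block = expr[cols].to_numpy(float)
        if len(cols) < 3 and trim > 0:
            warnings.warn(f"individual {person!r} has < 3 samples; plain mean used")
            center = block.mean(axis=1)
        else:
            center = stats.trim_mean(block, trim, axis=1)
        out[cols] = block - center[:, None]
    return _tagged(out.to_numpy(), expr, "centered")


@dataclass
class ClusterResult:
    """Pairwise sample correlations plus their hierarchical clustering."""

    correlation: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list
    newick: str
    excluded: list

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels for the retained samples."""
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.correlation.index, name="cluster")


def correlate_and_cluster(expr: pd.DataFrame, linkage_method: str = "average") -> ClusterResult:
    """Pearson correlation between samples + agglomerative clustering on 1 - r.

    Zero-variance samples cannot be correlated and are excluded with a
    warning. Requires >= 3 usable samples.
    """
    x = expr.to_numpy(float)
    sd = x.std(axis=0)
    excluded = [c for c, s in zip(expr.columns, sd) if s == 0]
    if excluded:
        warnings.warn(f"zero-variance samples excluded from clustering: {excluded}")
    keep = [c for c in expr.columns if c not in excluded]
    if len(keep) < 3:
        raise ValueError("need at least 3 samples with variance to cluster")
    sub = expr[keep]
    corr = pd.DataFrame(np.corrcoef(sub.to_numpy(float), rowvar=False), index=keep, columns=keep)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    from scipy.spatial.distance import squareform

    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    order = [keep[i] for i in hierarchy.leaves_list(Z)]
    newick = _to_newick(Z, keep)
    return ClusterResult(correlation=corr, linkage=Z, leaf_order=order, newick=newick, excluded=excluded)


def _to_newick(Z: np.ndarray, labels: list) -> str:
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist).rsplit(":", 1)[0] + ";"


def plot_correlation_heatmap(result: ClusterResult, path) -> None:
    """Write the clustered correlation heatmap to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = result.leaf_order
    mat = result.correlation.loc[order, order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# sklearn transformer facade


class FpkmTransformer(TransformerMixin, BaseEstimator):
    """Counts -> FPKM (stateless; annotation supplied at construction)."""

    def __init__(self, annotation: Optional[pd.DataFrame] = None):
        self.annotation = annotation

    def fit(self, X, y=None):
        if self.annotation is None:
            raise ValueError("annotation is required")
        return self

    def transform(self, X):
        return fpkm(X, self.annotation)


class CovariateResidualTransformer(TransformerMixin, BaseEstimator):
    """FPKM -> per-sample residuals of log2(FPKM + pseudocount) on GC/length."""

    def __init__(self, annotation: Optional[pd.DataFrame] = None, pseudocount: float = 0.5):
        self.annotation = annotation
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        if self.annotation is None:
            raise ValueError("annotation is required")
        return self

    def transform(self, X):
        return regress_out_covariates(X, self.annotation, self.pseudocount)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Residuals -> across-sample quantile-normalized values."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return quantile_normalize(X)


class TrimmedMeanCenterer(TransformerMixin, BaseEstimator):
    """Quantile-normalized values -> per-individual trimmed-mean-centered values."""

    def __init__(self, individuals=None, trim: float = 0.1):
        self.individuals = individuals
        self.trim = trim

    def fit(self, X, y=None):
        if self.individuals is None:
            raise ValueError("a sample -> individual mapping is required")
        return self

    def transform(self, X):
        return trimmed_center(X, self.individuals, self.trim)


def normalization_pipeline(annotation: pd.DataFrame, individuals, trim: float = 0.1, pseudocount: float = 0.5):
    """The full chain as an sklearn Pipeline over DataFrames."""
    from sklearn.pipeline import Pipeline

    return Pipeline(
        [
            ("fpkm", FpkmTransformer(annotation)),
            ("residual", CovariateResidualTransformer(annotation, pseudocount)),
            ("quantile", QuantileNormalizer()),
            ("center", TrimmedMeanCenterer(individuals, trim)),
        ]
    )
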