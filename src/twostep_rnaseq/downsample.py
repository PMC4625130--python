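"""Shallow-versus-deep concordance by binomial downsampling.

Thinning every count c to Binomial(c, r) is the count-level equivalent of
retaining each read independently with probability r, so DE results on
thinned matrices estimate what a run multiplexed 1/r-fold higher would have
produced. The evaluation reports, per ratio, the Spearman correlation of
log2 fold changes against a deep reference, the number of DE genes, and the
fraction of reference DE genes recovered.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import NBDifferentialExpression, de_gene_set

__all__ = [
    "DownsampleSpec",
    "thin_counts",
    "fc_correlation",
    "recovery_fraction",
    "depth_response_curve",
    "rank_correlation",
    "downsample_report",
]

DEFAULT_RATIOS = (1.0, 1 / 2, 1 / 4, 1 / 6, 1 / 8, 1 / 10, 1 / 12)
BASE_MULTIPLEX = 96  # the reference multiplexing level ratios are quoted against


@dataclass(frozen=True)
class DownsampleSpec:
    """Ratios (sorted descending, each in (0, 1]), seed, and FDR level."""

    ratios: tuple = DEFAULT_RATIOS
    seed: int = 0
    fdr: float = 0.1

    def __post_init__(self):
        r = tuple(float(v) for v in self.ratios)
        if any(not 0 < v <= 1 for v in r):
            raise ValueError("ratios must be in (0, 1]")
        if list(r) != sorted(r, reverse=True):
            raise ValueError("ratios must be sorted descending")
        object.__setattr__(self, "ratios", r)


def thin_counts(counts: pd.DataFrame, ratio: float, seed=None, rng=None) -> pd.DataFrame:
    """Binomial(count, ratio) thinning; ratio 1 is the identity (no RNG used)."""
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    if ratio == 1.0:
        return counts.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    vals = rng.binomial(counts.to_numpy(np.int64), ratio)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def fc_correlation(results_a: pd.DataFrame, results_b: pd.DataFrame) -> float:
    """Spearman rho of log2 fold changes over genes tested in both results."""
    shared = results_a.index.intersection(results_b.index)
    a = results_a.loc[shared]
    b = results_b.loc[shared]
    ok = (
        a["tested"].astype(bool)
        & b["tested"].astype(bool)
        & a["log2FoldChange"].notna()
        & b["log2FoldChange"].notna()
    )
    if ok.sum() < 10:
        raise ValueError(f"only {int(ok.sum())} genes tested in both results; need >= 10")
    rho = stats.spearmanr(a.loc[ok, "log2FoldChange"], b.loc[ok, "log2FoldChange"]).statistic
    return float(rho)


def recovery_fraction(reference: set, test: set) -> float:
    """|reference ∩ test| / |reference|; NaN (with a warning) if the reference is empty."""
    reference = set(reference)
    if not reference:
        warnings.warn("empty reference DE set; recovery undefined")
        return float("nan")
    return len(reference & set(test)) / len(reference)


def rank_correlation(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rho with an exact permutation p for small n.

    For n <= ``exact_max_n`` the two-sided p-value enumerates all n!
    permutations of one rank vector; above that a normal approximation
    z = rho * sqrt(n - 1) is used. Constant input leaves rho undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector; rank correlation undefined")
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        # exhaustive null distribution of rho given the observed rank vectors
        rx_c = rx - rx.mean()
        denom = math.sqrt(np.sum(rx_c**2))
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        ry_c = ry - ry.mean()
        sy = math.sqrt(np.sum(ry_c**2))
        for perm in itertools.permutations(ry_c):
            r = float(np.dot(rx_c, perm)) / (denom * sy)
            if abs(r) >= target:
                count += 1
            total += 1
        p = count / total
    else:
        z = rho * math.sqrt(n - 1)
        p = 2 * stats.norm.sf(abs(z))
    return rho, float(p)


def depth_response_curve(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    depths: Sequence[float],
    annotation: Optional[pd.DataFrame] = None,
    fdr: float = 0.1,
    n_seeds: int = 3,
    seed: int = 0,
    **de_kwargs,
) -> pd.DataFrame:
    """DE-gene counts after thinning every sample to each target mean depth.

    Each sample column is thinned by min(1, depth / its observed total); the
    DE engine runs on the thinned matrix and DE genes at ``fdr`` are counted.
    Replicated over ``n_seeds`` seeds; mean and sd reported per depth.
    """
    totals = counts.sum(axis=0).astype(float)
    rows = []
    ss = np.random.SeedSequence(seed)
    for depth in depths:
        if depth > totals.max():
            raise ValueError(f"target depth {depth} exceeds the observed depth")
        counts_per_seed = []
        for child in ss.spawn(n_seeds):
            rng = np.random.default_rng(child)
            thinned = counts.copy()
            for c in counts.columns:
                r = min(1.0, depth / totals[c])
                if r < 1.0:
                    thinned[c] = rng.binomial(counts[c].to_numpy(np.int64), r)
            model = NBDifferentialExpression(fdr=fdr, **de_kwargs).fit(thinned, design, annotation)
            n_de = sum(len(de_gene_set(res, fdr)) for res in model.results_.values())
            counts_per_seed.append(n_de)
        rows.append(
            {
                "depth": float(depth),
                "n_de_mean": float(np.mean(counts_per_seed)),
                "n_de_sd": float(np.std(counts_per_seed, ddof=1)) if n_seeds > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def downsample_report(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    reference_results: dict,
    spec: DownsampleSpec = DownsampleSpec(),
    annotation: Optional[pd.DataFrame] = None,
    **de_kwargs,
) -> pd.DataFrame:
    """Per-ratio concordance against deep-reference DE results.

    ``reference_results`` maps treatment label -> result DataFrame from the
    deep run. For each ratio the counts are thinned, the DE engine re-run,
    and per treatment the Spearman rho of log2 fold changes, the DE-gene
    count, and the recovery of the reference DE set are reported (one row per
    ratio x treatment, plus the pooled mean across treatments as
    treatment="__mean__").
    """
    ref_sets = {t: de_gene_set(res, spec.fdr) for t, res in reference_results.items()}
    rows = []
    rng = np.random.default_rng(spec.seed)
    for ratio in spec.ratios:
        thinned = thin_counts(counts, ratio, rng=rng)
        model = NBDifferentialExpression(fdr=spec.fdr, **de_kwargs).fit(thinned, design, annotation)
        per_t = []
        for t, ref in reference_results.items():
            res = model.results_[t]
            rho = fc_correlation(res, ref)
            n_de = len(de_gene_set(res, spec.fdr))
            rec = recovery_fraction(ref_sets[t], de_gene_set(res, spec.fdr))
            per_t.append((rho, n_de, rec))
            rows.append(
                {
                    "ratio": ratio,
                    "multiplex_equiv": BASE_MULTIPLEX / ratio,
                    "treatment": t,
                    "rho": rho,
                    "n_de": n_de,
                    "recovery": rec,
                }
            )
        if len(per_t) > 1:
            arr = np.array(per_t, dtype=float)
            rows.append(
                {
                    "ratio": ratio,
                    "multiplex_equiv": BASE_MULTIPLEX / ratio,
                    "treatment": "__mean__",
                    "rho": float(np.nanmean(arr[:, 0])),
                    "n_de": float(np.nanmean(arr[:, 1])),
                    "recovery": float(np.nanmean(arr[:, 2])),
                }
            )
    return pd.DataFrame(rows)
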