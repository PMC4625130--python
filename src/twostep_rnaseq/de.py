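"""Negative-binomial differential expression.

A desk-scale NB testing engine in the mold of count-based DE tools:
median-of-ratios size factors, per-gene method-of-moments dispersions
shrunk toward a fitted mean trend alpha(mu) = a0 + a1/mu, per-contrast NB
GLM Wald tests with size factors as offsets, Benjamini-Hochberg FDR, a
low-count filter (transcripts with more than ``min_total_reads`` raw reads),
and QQ calibration summaries.

The model for gene g in sample s of a two-group contrast is

    K_gs ~ NB(mu_gs, alpha_g),  mu_gs = s_s * exp(b0_g + b1_g * x_s),

with x_s = 1 for treated samples; Var(K) = mu + alpha * mu^2. The Wald
statistic is b1 / SE(b1) (reported on the log2 scale) against a standard
normal reference. This is deliberately simpler than full empirical-Bayes
machinery: no Cox-Reid adjustment, no outlier replacement, no independent
filtering, no fold-change shrinkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DispersionModel",
    "QQResult",
    "size_factors",
    "filter_low",
    "estimate_dispersions",
    "wald_test",
    "bh_adjust",
    "de_genes",
    "de_gene_set",
    "qq_calibration",
    "NBDifferentialExpression",
]

_ALPHA_FLOOR = 1e-8
_BETA_BOUND = 22.0  # natural-log bound on coefficients (~2^31-fold change)

RESULT_COLUMNS = [
    "gene_id",
    "baseMean",
    "log2FoldChange",
    "lfcSE",
    "stat",
    "pvalue",
    "padj",
    "tested",
    "converged",
]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Each sample's factor is the median over transcripts of
    count / geometric-mean-across-samples, computed on transcripts observed
    in every sample. If no transcript is positive everywhere, geometric means
    fall back to positive entries only (with a warning).
    """
    x = counts.to_numpy(float)
    if x.shape[0] == 0:
        raise ValueError("empty count matrix")
    if (x.sum(axis=0) == 0).any():
        bad = counts.columns[x.sum(axis=0) == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    all_pos = np.isfinite(logx).all(axis=1)
    if all_pos.any():
        loggeo = logx[all_pos].mean(axis=1, keepdims=True)
        ratios = logx[all_pos] - loggeo
        logsf = np.median(ratios, axis=0)
    else:
        warnings.warn(
            "no transcript observed in every sample; using positive-count geometric means"
        )
        npos = np.isfinite(logx).sum(axis=1)
        loggeo = np.where(npos > 0, np.nansum(np.where(np.isfinite(logx), logx, 0), axis=1) / np.maximum(npos, 1), np.nan)
        ratios = logx - loggeo[:, None]
        logsf = np.nanmedian(np.where(np.isfinite(ratios), ratios, np.nan), axis=0)
    logsf = logsf - logsf.mean()  # geometric mean 1
    return pd.Series(np.exp(logsf), index=counts.columns, name="size_factor")


def filter_low(counts: pd.DataFrame, threshold: int = 20, samples=None) -> pd.DataFrame:
    """Keep transcripts with total raw count strictly greater than ``threshold``.

    ``samples`` restricts the total to a subset of columns (the fitted set).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sub = counts if samples is None else counts[list(samples)]
    return counts.loc[sub.sum(axis=1) > threshold]


@dataclass
class DispersionModel:
    """Raw, trend, and final (shrunken) per-transcript NB dispersions."""

    raw: pd.Series  # method-of-moments estimate; NaN where no estimate
    trend_a0: float
    trend_a1: float
    trend: pd.Series
    final: pd.Series
    shrink_weight: float

    def trend_at(self, mu) -> np.ndarray:
        return np.maximum(self.trend_a0 + self.trend_a1 / np.maximum(mu, 1e-8), _ALPHA_FLOOR)


def estimate_dispersions(
    counts: pd.DataFrame,
    conditions: pd.Series,
    sf: pd.Series,
    shrink_weight="auto",
) -> DispersionModel:
    """Pooled method-of-moments dispersions with a 1/mu trend and log-scale shrinkage.

    Within every condition having >= 2 replicates, normalized counts
    k = K/s give a mean m_c and variance v_c; the shot-noise expectation
    m_c * mean(1/s) is subtracted and the per-gene estimate pooled as

        alpha_hat = sum_c (n_c - 1) (v_c - m_c * xi_c) / sum_c (n_c - 1) m_c^2,

    clipped below at 1e-8. A gamma GLM (identity link) of alpha_hat on 1/mu
    gives the mean trend a0 + a1/mu — the gamma family matches the
    multiplicative, right-skewed sampling noise of moment estimates, so the
    fit targets the mean rather than the (downward-biased) median. The final
    dispersion interpolates raw and trend on the log scale with weight
    ``shrink_weight`` toward the trend. The default ``"auto"`` picks the
    weight empirically: w = s2_samp / (s2_samp + s2_gene), where s2_samp is
    the expected sampling variance of log alpha_hat (~ 2/df) and s2_gene the
    excess spread of log(raw/trend) beyond it — i.e. genes are shrunk hard
    when the scatter around the trend is explainable by estimation noise and
    gently when there is real gene-level dispersion signal. Conditions with a
    single replicate contribute nothing (warned).
    """
    if shrink_weight != "auto" and not 0.0 <= float(shrink_weight) <= 1.0:
        raise ValueError("shrink_weight must be 'auto' or in [0, 1]")
    conditions = pd.Series(conditions).reindex(counts.columns)
    if conditions.isna().any():
        raise ValueError("conditions missing for some samples")
    sf = pd.Series(sf).reindex(counts.columns)
    norm = counts.to_numpy(float) / sf.to_numpy(float)[None, :]

    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    any_repl = False
    for cond, cols in conditions.groupby(conditions).groups.items():
        idx = [counts.columns.get_loc(c) for c in cols]
        n_c = len(idx)
        if n_c < 2:
            warnings.warn(f"condition {cond!r} has a single replicate; skipped in dispersion fit")
            continue
        any_repl = True
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        xi = float(np.mean(1.0 / sf.iloc[idx]))
        num += (n_c - 1) * (v - m * xi)
        den += (n_c - 1) * m**2
    if not any_repl:
        raise ValueError("no condition has >= 2 replicates")

    with np.errstate(divide="ignore", invalid="ignore"):
        raw_vals = num / den
    mu = norm.mean(axis=1)
    has_est = (den > 0) & np.isfinite(raw_vals)
    raw = pd.Series(np.where(has_est, raw_vals, np.nan), index=counts.index, name="raw")

    a0, a1 = _fit_trend(raw_vals[has_est], mu[has_est])
    trend = pd.Series(
        np.maximum(a0 + a1 / np.maximum(mu, 1e-8), _ALPHA_FLOOR), index=counts.index, name="trend"
    )
    if shrink_weight == "auto":
        df_resid = float(np.sum([max(n - 1, 0) for n in conditions.value_counts()]))
        shrink_weight = _auto_weight(raw_vals, trend.to_numpy(), mu, has_est, df_resid)
    else:
        shrink_weight = float(shrink_weight)
    raw_clipped = np.maximum(np.where(has_est, raw_vals, trend.to_numpy()), _ALPHA_FLOOR)
    log_final = shrink_weight * np.log(trend.to_numpy()) + (1 - shrink_weight) * np.log(raw_clipped)
    final = pd.Series(np.maximum(np.exp(log_final), _ALPHA_FLOOR), index=counts.index, name="final")
    return DispersionModel(
        raw=raw, trend_a0=a0, trend_a1=a1, trend=trend, final=final, shrink_weight=shrink_weight
    )


def _auto_weight(raw_vals, trend_vals, mu, has_est, df_resid: float) -> float:
    """Empirical-Bayes-style trend weight from the excess scatter of log(raw/trend).

    A variance-type estimate at df residual degrees of freedom has
    var(log alpha_hat) ~ trigamma(df/2) when overdispersion dominates shot
    noise; scatter beyond that reflects true gene-level departures from the
    trend and earns the raw estimates weight. The scatter is measured with a
    MAD (the skewed tail of moment estimates would dominate a plain variance)
    on high-information genes (alpha * mu > 20, i.e. overdispersion at least
    ~20x shot noise), where shot noise does not inflate it.
    """
    from scipy.special import polygamma

    s2_samp = float(polygamma(1, max(df_resid, 1.0) / 2.0))
    usable = has_est & (raw_vals > _ALPHA_FLOOR)
    hi = usable & (trend_vals * mu > 20.0)
    sel = hi if hi.sum() >= 50 else usable
    if sel.sum() < 50:
        return 0.5
    logdev = np.log(raw_vals[sel]) - np.log(trend_vals[sel])
    mad = np.median(np.abs(logdev - np.median(logdev)))
    s2_tot = (1.4826 * mad) ** 2
    s2_gene = max(s2_tot - s2_samp, 0.0)
    return float(s2_samp / (s2_samp + s2_gene))


def _fit_trend(raw: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Gamma-GLM fit of raw dispersions on 1/mu, coefficients clipped at >= 0.

    Moment-based dispersion estimates scatter multiplicatively around their
    mean, so a gamma family with identity link targets E[alpha_hat | mu]
    robustly to the skew; an iteration re-excludes gross outliers (> 10x off
    the current fit), mirroring standard practice for dispersion trends.
    """
    import statsmodels.api as sm

    pos = (raw > _ALPHA_FLOOR) & (mu > 0)
    if pos.sum() < 10:
        # too few informative genes for a trend; flat fallback
        a0 = float(np.median(raw[pos])) if pos.any() else _ALPHA_FLOOR
        return max(a0, _ALPHA_FLOOR), 0.0
    y = raw[pos]
    X = np.column_stack([np.ones(pos.sum()), 1.0 / mu[pos]])
    a0, a1 = _ls_nonneg(X, y)
    keep = np.ones(y.size, dtype=bool)
    for _ in range(3):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # identity link outside Gamma domain
                fit = sm.GLM(
                    y[keep],
                    X[keep],
                    family=sm.families.Gamma(link=sm.families.links.Identity()),
                ).fit(start_params=[max(a0, 1e-4), max(a1, 1e-4)])
            cand0, cand1 = float(fit.params[0]), float(fit.params[1])
            if cand0 >= 0 and cand1 >= 0 and np.isfinite([cand0, cand1]).all():
                a0, a1 = cand0, cand1
        except Exception:
            break
        pred = np.maximum(a0 + a1 / mu[pos], _ALPHA_FLOOR)
        new_keep = np.abs(np.log(y) - np.log(pred)) < np.log(10)
        if new_keep.sum() < 10 or (new_keep == keep).all():
            break
        keep = new_keep
    return max(a0, _ALPHA_FLOOR), max(a1, 0.0)


def _ls_nonneg(X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    from scipy.optimize import nnls

    sol, _ = nnls(X, np.maximum(y, 0))
    return float(sol[0]), float(sol[1])


def _nb_loglik(y, mu, alpha):
    # up to terms constant in beta
    return np.sum(y * np.log(np.maximum(mu, 1e-300)) - (y + 1.0 / alpha) * np.log1p(alpha * mu), axis=-1)


def _fit_nb_glm(y, x, sf, alpha, max_iter=100, tol=1e-8):
    """Vectorized Fisher scoring for per-gene NB GLM: log mu = log sf + b0 + b1 x.

    y: (G, n) counts; x: (n,) 0/1 indicator; sf: (n,); alpha: (G,).
    Returns (b0, b1, se_b1, converged).
    """
    G, n = y.shape
    alpha = np.maximum(alpha, _ALPHA_FLOOR)[:, None]
    ctrl = x == 0
    trt = x == 1
    m0 = (y[:, ctrl] / sf[ctrl]).mean(axis=1)
    m1 = (y[:, trt] / sf[trt]).mean(axis=1)
    b0 = np.log(np.maximum(m0, 1e-4))
    b1 = np.log(np.maximum(m1, 1e-4)) - b0
    b0 = np.clip(b0, -_BETA_BOUND, _BETA_BOUND)
    b1 = np.clip(b1, -_BETA_BOUND, _BETA_BOUND)

    ll = np.full(G, -np.inf)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    for _ in range(max_iter):
        mu = sf[None, :] * np.exp(b0[:, None] + b1[:, None] * x[None, :])
        w = mu / (1.0 + alpha * mu)
        r = (y - mu) / (1.0 + alpha * mu)
        U0 = r.sum(axis=1)
        U1 = (r * x[None, :]).sum(axis=1)
        I00 = w.sum(axis=1)
        I01 = (w * x[None, :]).sum(axis=1)
        I11 = (w * (x**2)[None, :]).sum(axis=1)
        det = I00 * I11 - I01**2
        ok = det > 1e-12
        d0 = np.where(ok, (I11 * U0 - I01 * U1) / np.where(ok, det, 1.0), 0.0)
        d1 = np.where(ok, (I00 * U1 - I01 * U0) / np.where(ok, det, 1.0), 0.0)
        d0 = np.clip(d0, -5, 5)
        d1 = np.clip(d1, -5, 5)
        step = active & ok
        b0 = np.where(step, np.clip(b0 + d0, -_BETA_BOUND, _BETA_BOUND), b0)
        b1 = np.where(step, np.clip(b1 + d1, -_BETA_BOUND, _BETA_BOUND), b1)
        mu_new = sf[None, :] * np.exp(b0[:, None] + b1[:, None] * x[None, :])
        ll_new = _nb_loglik(y, mu_new, alpha)
        done = step & (np.abs(ll_new - ll) < tol * (np.abs(ll_new) + 1.0))
        converged |= done
        converged |= active & ~ok  # flat information: nothing further to do
        ll = np.where(step, ll_new, ll)
        active = active & ~done & ok
        if not active.any():
            break

    mu = sf[None, :] * np.exp(b0[:, None] + b1[:, None] * x[None, :])
    w = mu / (1.0 + alpha * mu)
    I00 = w.sum(axis=1)
    I01 = (w * x[None, :]).sum(axis=1)
    I11 = (w * (x**2)[None, :]).sum(axis=1)
    det = np.maximum(I00 * I11 - I01**2, 1e-300)
    var_b1 = I00 / det
    se_b1 = np.sqrt(np.maximum(var_b1, 0))
    return b0, b1, se_b1, converged


def wald_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    sf: pd.Series,
    dispersion,
    contrast: tuple[str, str],
    annotation: Optional[pd.DataFrame] = None,
    min_total_reads: int = 20,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-transcript NB Wald test for one treatment-vs-control contrast.

    ``dispersion`` is a per-transcript Series of final dispersions (or a
    DispersionModel). Transcripts failing the low-count filter (total raw
    reads across the contrast's samples <= ``min_total_reads``) are marked
    untested with missing p/q. Returns the de-facto standard result columns
    (baseMean, log2FoldChange, lfcSE, stat, pvalue, padj).
    """
    treatment, control = contrast
    cond = design["condition"]
    t_samples = design.index[cond == treatment]
    c_samples = design.index[cond == control]
    if len(t_samples) == 0 or len(c_samples) == 0:
        raise ValueError(f"contrast {contrast} names conditions absent from the design")
    samples = list(c_samples) + list(t_samples)
    missing = [s for s in samples if s not in counts.columns]
    if missing:
        raise ValueError(f"samples missing from count matrix: {missing}")

    if isinstance(dispersion, DispersionModel):
        dispersion = dispersion.final
    disp = pd.Series(dispersion).reindex(counts.index)

    sub = counts[samples]
    tested = sub.sum(axis=1) > min_total_reads
    tested &= disp.notna()

    sf_sub = pd.Series(sf).reindex(samples).to_numpy(float)
    x = np.array([0] * len(c_samples) + [1] * len(t_samples), dtype=float)
    norm = sub.to_numpy(float) / sf_sub[None, :]
    base_mean = norm.mean(axis=1)

    res = pd.DataFrame(index=counts.index, columns=RESULT_COLUMNS)
    res["gene_id"] = (
        annotation["gene_id"].reindex(counts.index)
        if annotation is not None
        else pd.Series(counts.index, index=counts.index)
    )
    res["baseMean"] = base_mean
    res["tested"] = tested
    res["converged"] = False

    if tested.any():
        y = sub.loc[tested].to_numpy(float)
        alpha = disp[tested].to_numpy(float)
        b0, b1, se_b1, conv = _fit_nb_glm(y, x, sf_sub, alpha, max_iter=max_iter, tol=tol)
        ln2 = np.log(2.0)
        lfc = b1 / ln2
        se = se_b1 / ln2
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(se > 0, lfc / se, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(stat))
        p = np.where(conv, p, np.nan)  # non-converged fits are reported missing, never silent
        res.loc[tested, "log2FoldChange"] = lfc
        res.loc[tested, "lfcSE"] = se
        res.loc[tested, "stat"] = stat
        res.loc[tested, "pvalue"] = p
        res.loc[tested, "converged"] = conv
        n_bad = int((~conv).sum())
        if n_bad:
            warnings.warn(f"{n_bad} transcripts did not converge; reported as missing")
    res["padj"] = bh_adjust(res["pvalue"].to_numpy(float))
    for col in ["baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj"]:
        res[col] = res[col].astype(float)
    res["tested"] = res["tested"].astype(bool)
    res["converged"] = res["converged"].astype(bool)
    return res


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values; NaNs pass through unadjusted.

    q_(i) = min_{j >= i} (m/j) p_(j), capped at 1, with m the number of
    non-missing p-values.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must be in [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def de_genes(
    results: pd.DataFrame,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Per-gene DE calls: a gene is DE if >= 1 transcript has q <= fdr.

    Direction is reported under two conventions: ``direction_any`` marks a
    gene up and/or down if any significant transcript has that sign (a gene
    with conflicting transcript signs is counted once in each direction and
    flagged), while ``direction_best`` uses the most significant transcript.
    """
    sig = results[(results["padj"] <= fdr) & results["padj"].notna()]
    if sig.empty:
        return pd.DataFrame(
            columns=["up_any", "down_any", "conflict", "direction_best", "n_sig_transcripts"]
        ).rename_axis("gene_id")
    rows = []
    for gene, grp in sig.groupby("gene_id"):
        signs = np.sign(grp["log2FoldChange"].to_numpy(float))
        up = bool((signs > 0).any())
        down = bool((signs < 0).any())
        best = grp.loc[grp["padj"].idxmin()]
        rows.append(
            {
                "gene_id": gene,
                "up_any": up,
                "down_any": down,
                "conflict": up and down,
                "direction_best": "up" if best["log2FoldChange"] > 0 else "down",
                "n_sig_transcripts": len(grp),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def de_gene_set(results: pd.DataFrame, fdr: float = 0.1) -> set:
    """Set of DE gene ids at the given FDR."""
    return set(de_genes(results, fdr=fdr).index)


@dataclass
class QQResult:
    """QQ summary of a p-value vector against the uniform expectation."""

    table: pd.DataFrame  # columns: expected, observed (-log10 scale)
    ks_stat: float
    ks_p: float
    flagged: bool  # extreme departure from uniformity


def qq_calibration(p) -> QQResult:
    """Sorted observed p against (i - 0.5)/m, plus a KS uniformity test."""
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    m = p.size
    if m < 10:
        raise ValueError("need at least 10 p-values")
    obs = np.sort(p)
    exp = (np.arange(1, m + 1) - 0.5) / m
    ks = stats.kstest(p, "uniform")
    with np.errstate(divide="ignore"):
        table = pd.DataFrame(
            {"expected": -np.log10(exp), "observed": -np.log10(np.maximum(obs, 1e-300))}
        )
    return QQResult(
        table=table,
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
        flagged=bool(ks.pvalue < 1e-3),
    )


class NBDifferentialExpression(BaseEstimator):
    """Sklearn-style NB differential-expression estimator.

    Fit on a count matrix (transcripts x samples) and a design table
    (indexed by sample id, with ``condition`` and ``control`` columns; every
    treated condition names its matched vehicle control). Dispersions are
    estimated jointly on all samples, then each treatment-control contrast
    gets an NB Wald test.

    Parameters
    ----------
    fdr : float
        BH-FDR level for DE-gene calls (default 0.1).
    min_total_reads : int
        Low-count filter: keep transcripts with total raw reads strictly
        greater than this (default 20).
    shrink_weight : "auto" or float
        Weight of the dispersion trend in the log-scale shrinkage. The
        default "auto" sets it from the excess scatter of raw estimates
        around the trend (strong shrinkage when scatter is explainable by
        estimation noise); a float in [0, 1] fixes it (0.5 = geometric
        midpoint).
    filter_scope : {"contrast", "global"}
        Whether the low-count filter totals reads over each contrast's
        samples or over all samples.

    Attributes
    ----------
    size_factors_ : Series
    dispersion_ : DispersionModel
    results_ : dict mapping treatment label -> result DataFrame
    contrasts_ : list of (treatment, control)
    """

    def __init__(
        self,
        fdr: float = 0.1,
        min_total_reads: int = 20,
        shrink_weight="auto",
        filter_scope: str = "contrast",
        max_iter: int = 100,
        tol: float = 1e-8,
    ):
        self.fdr = fdr
        self.min_total_reads = min_total_reads
        self.shrink_weight = shrink_weight
        self.filter_scope = filter_scope
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, counts: pd.DataFrame, design: pd.DataFrame, annotation: Optional[pd.DataFrame] = None):
        counts = _validate_counts(counts)
        design = design.loc[[s for s in design.index if s in counts.columns]]
        if design.empty:
            raise ValueError("no design samples present in the count matrix")
        counts = counts[design.index]
        if self.filter_scope not in ("contrast", "global"):
            raise ValueError("filter_scope must be 'contrast' or 'global'")

        self.size_factors_ = size_factors(counts)
        # dispersion is fit on all sequencing data simultaneously
        fit_counts = filter_low(counts, self.min_total_reads)
        self.dispersion_ = estimate_dispersions(
            fit_counts, design["condition"], self.size_factors_, self.shrink_weight
        )
        disp = self.dispersion_.final.reindex(counts.index)
        # transcripts outside the jointly-filtered set fall back to the trend
        mu_all = (counts.to_numpy(float) / self.size_factors_.to_numpy(float)[None, :]).mean(axis=1)
        disp = pd.Series(
            np.where(disp.notna(), disp, self.dispersion_.trend_at(mu_all)), index=counts.index
        )

        self.contrasts_ = [
            (t, c)
            for t, c in design[["condition", "control"]].drop_duplicates().itertuples(index=False)
            if isinstance(c, str) and c != ""
        ]
        self.results_ = {}
        for treatment, control in self.contrasts_:
            # "contrast" scope lets wald_test total reads over the contrast's
            # samples; "global" pre-restricts to the jointly-filtered set
            sub = counts if self.filter_scope == "contrast" else fit_counts
            self.results_[treatment] = wald_test(
                sub,
                design,
                self.size_factors_,
                disp,
                (treatment, control),
                annotation=annotation,
                min_total_reads=self.min_total_reads,
                max_iter=self.max_iter,
                tol=self.tol,
            )
        self.design_ = design
        return self

    def de_genes(self, treatment: str, fdr: Optional[float] = None) -> pd.DataFrame:
        self._check_fitted()
        return de_genes(self.results_[treatment], fdr=self.fdr if fdr is None else fdr)

    def summary(self, fdr: Optional[float] = None) -> pd.DataFrame:
        """Per-contrast DE-gene counts (any-transcript direction rule)."""
        self._check_fitted()
        rows = []
        for t, c in self.contrasts_:
            g = self.de_genes(t, fdr=fdr)
            rows.append(
                {
                    "contrast": t,
                    "control": c,
                    "n_de": len(g),
                    "n_up": int(g["up_any"].sum()) if len(g) else 0,
                    "n_down": int(g["down_any"].sum()) if len(g) else 0,
                }
            )
        return pd.DataFrame(rows)

    def _check_fitted(self):
        if not hasattr(self, "results_"):
            raise RuntimeError("estimator is not fitted")


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.shape[0] == 0:
        raise ValueError("no transcripts in count matrix")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    if counts.index.duplicated().any():
        raise ValueError("duplicate transcript ids")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("counts must be numeric")
    if (arr < 0).any():
        raise ValueError("counts must be >= 0")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    return counts.astype(np.int64)
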