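"""Shared brute-force oracle: NB profile likelihood on a log2 fold-change grid."""

import numpy as np

import twostep_rnaseq as tr
from twostep_rnaseq.de import size_factors, wald_test


def profile_loglik_lfc(y, x, sf, alpha, lfc_grid):
    """Maximize the NB log-likelihood over b0 for each grid log2fc; return the argmax."""
    best, best_lfc = -np.inf, 0.0
    for lfc in lfc_grid:
        b1 = lfc * np.log(2)
        m = np.log(max(np.mean(y / (sf * np.exp(b1 * x))), 1e-8))
        b0s = np.linspace(m - 1.5, m + 1.5, 121)
        for _ in range(2):
            mu = sf[None, :] * np.exp(b0s[:, None] + b1 * x[None, :])
            ll = (y[None, :] * np.log(mu) - (y[None, :] + 1 / alpha) * np.log1p(alpha * mu)).sum(axis=1)
            k = int(np.argmax(ll))
            lo = b0s[max(k - 1, 0)]
            hi = b0s[min(k + 1, len(b0s) - 1)]
            b0s = np.linspace(lo, hi, 101)
        if ll.max() > best:
            best, best_lfc = ll.max(), lfc
    return best_lfc


def profile_grid_check(n_genes=200, seed=13, window=0.05, spacing=0.001):
    """Fraction of tested genes whose Wald MLE matches the grid argmax within 0.01."""
    cfg = tr.SimConfig(n_genes=n_genes, seed=seed, baseline_log_sd=1.0)
    ann = tr.simulate_annotation(cfg)
    truth = tr.make_truth(cfg, ann)
    counts = tr.simulate_counts(cfg, truth, 1e6, ann)
    design = tr.make_design(cfg)
    sf = size_factors(counts)
    res = wald_test(counts, design, sf, truth.dispersion, ("treatment", "control"))
    tested = res.index[res["tested"] & res["converged"]]
    cols = list(design.index[design["condition"] == "control"]) + list(
        design.index[design["condition"] == "treatment"]
    )
    x = np.array([0.0] * 3 + [1.0] * 3)
    sf_vec = sf[cols].to_numpy()
    hits = 0
    for t in tested:
        est = res.loc[t, "log2FoldChange"]
        grid = np.arange(est - window, est + window, spacing)
        oracle = profile_loglik_lfc(
            counts.loc[t, cols].to_numpy(float), x, sf_vec, max(truth.dispersion[t], 1e-8), grid
        )
        hits += abs(oracle - est) <= 0.01
    return hits / len(tested)
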