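"""Synthetic multiplexed RNA-seq experiments.

This module generates everything the downstream stages consume without any
real sequencing data: transcript annotations (length, GC), per-library
cluster efficiencies, flow-cell read allocation, and negative-binomial gene
counts with planted treatment effects and GC/length expression bias.

The count model is a hierarchical Gamma-Poisson. Each library (sample) draws
a latent relative expression rate per transcript once,

    q_gs ~ Gamma(shape=1/alpha_g, mean=r_gs),

where r_gs is the expected relative abundance (baseline x treatment effect x
covariate bias, renormalized per sample) and alpha_g the per-gene dispersion.
Sequencing a library at depth d then yields counts ~ Poisson(d * q_gs), so a
single count matrix is marginally NB(mu = d * r_gs, alpha_g) with
variance mu + alpha * mu^2, while matrices produced at several depths from
the *same* library rates are correlated exactly as re-sequencing the same
physical libraries would make them. That coupling is what a two-step design
exploits: the deep run re-pools the step-one libraries rather than preparing
new ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupSpec",
    "SimConfig",
    "TruthSet",
    "simulate_annotation",
    "simulate_efficiencies",
    "allocate_reads",
    "make_design",
    "make_truth",
    "expected_rates",
    "simulate_library_rates",
    "counts_from_rates",
    "simulate_counts",
    "simulate_two_depths",
]

# fixed substream ids so stages can be re-run independently yet reproducibly
_STREAM_ANNOTATION = 0
_STREAM_BASELINE = 1
_STREAM_EFFECTS = 2
_STREAM_EFFICIENCY = 3
_STREAM_RATES = 4
_STREAM_COUNTS = 5

_DISPERSION_FLOOR = 1e-12


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


@dataclass(frozen=True)
class GroupSpec:
    """One experimental condition: a label, its replicate count, and its matched control.

    ``control is None`` marks the group itself as a vehicle control.
    """

    label: str
    n: int
    control: Optional[str] = None


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated multiplexed screen.

    Defaults describe one treatment against its vehicle control, three
    replicates each, with 10% of genes truly responding (log2 fold changes
    ~ N(0, 1)), a dispersion trend alpha(mu) = a0 + a1/mu, log-normal gene
    abundance spanning roughly four orders of magnitude, and modest GC/length
    expression bias.
    """

    n_genes: int = 10_000
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("control", 3, None),
        GroupSpec("treatment", 3, "control"),
    )
    frac_de: float = 0.1
    effect_sd: float = 1.0
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 2.0
    disp_a0: float = 0.05
    disp_a1: float = 2.0
    eff_log_sd: float = 0.5
    gc_beta: float = 1.0
    len_beta: float = 0.3
    gclen_beta: float = 0.0
    ref_depth: float = 5e6  # depth anchoring the dispersion trend's mu scale
    seed: int = 0

    def __post_init__(self):
        groups = tuple(
            g if isinstance(g, GroupSpec) else GroupSpec(*g) for g in self.groups
        )
        object.__setattr__(self, "groups", groups)
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not groups:
            raise ValueError("at least one group is required")
        labels = [g.label for g in groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        for g in groups:
            if g.n < 1:
                raise ValueError(f"group {g.label!r} must have size >= 1")
            if g.control is not None and g.control not in labels:
                raise ValueError(f"group {g.label!r} names unknown control {g.control!r}")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        if self.disp_a0 < 0 or self.disp_a1 < 0:
            raise ValueError("dispersion trend coefficients must be >= 0")
        if self.eff_log_sd < 0:
            raise ValueError("eff_log_sd must be >= 0")
        if self.ref_depth <= 0:
            raise ValueError("ref_depth must be > 0")

    @property
    def n_samples(self) -> int:
        return sum(g.n for g in self.groups)

    @property
    def treatments(self) -> list[str]:
        return [g.label for g in self.groups if g.control is not None]

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TruthSet:
    """Ground truth underlying a simulated experiment.

    Attributes
    ----------
    log2fc : DataFrame, genes x treatments
        True log2 fold changes; exactly round(frac_de * n_genes) nonzero per
        treatment.
    dispersion : Series, per gene
        True NB dispersion alpha_g (> 0), from the trend a0 + a1/mu evaluated
        at the gene's expected control count at ``ref_depth``.
    efficiency : Series, per sample
        Per-library cluster-efficiency factors, mean 1.
    baseline : Series, per gene
        Baseline (control) abundance before covariate bias, arbitrary units.
    """

    log2fc: pd.DataFrame
    dispersion: pd.Series
    efficiency: pd.Series
    baseline: pd.Series

    def __post_init__(self):
        if (self.dispersion <= 0).any():
            raise ValueError("dispersions must be > 0")


def _transcript_ids(n: int) -> pd.Index:
    width = max(5, len(str(n)))
    return pd.Index([f"T{i:0{width}d}" for i in range(1, n + 1)], name="transcript_id")


def simulate_annotation(cfg: SimConfig) -> pd.DataFrame:
    """Per-transcript annotation: gene id, length (bp), GC fraction.

    Lengths are log-uniform in [200, 20000] bp; GC is Beta-shaped within
    [0.2, 0.8]. One transcript per gene.
    """
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(cfg.seed, _STREAM_ANNOTATION)
    tids = _transcript_ids(cfg.n_genes)
    length = np.exp(rng.uniform(np.log(200), np.log(20_000), cfg.n_genes))
    length = np.clip(np.round(length), 200, 20_000).astype(int)
    gc = 0.2 + 0.6 * rng.beta(5.0, 5.0, cfg.n_genes)
    gene_ids = [t.replace("T", "G", 1) for t in tids]
    return pd.DataFrame(
        {"gene_id": gene_ids, "length_bp": length, "gc_fraction": gc}, index=tids
    )


def simulate_efficiencies(cfg: SimConfig) -> pd.Series:
    """Per-library cluster-efficiency factors.

    Log-normal with log-sd ``eff_log_sd``, rescaled to sample mean exactly 1,
    emulating uneven flow-cell cluster formation across barcoded libraries.
    """
    if cfg.n_samples < 1:
        raise ValueError("need at least one sample")
    rng = _rng(cfg.seed, _STREAM_EFFICIENCY)
    design = make_design(cfg)
    if cfg.eff_log_sd == 0:
        eff = np.ones(cfg.n_samples)
    else:
        eff = np.exp(rng.normal(0.0, cfg.eff_log_sd, cfg.n_samples))
        eff = eff / eff.mean()
    return pd.Series(eff, index=design.index, name="efficiency")


def allocate_reads(total_output, pooled_mass, seed=None, rng=None):
    """Distribute a run's reads across libraries by multinomial sampling.

    Probabilities are proportional to ``pooled_mass`` (effective pooled
    material, e.g. volume x efficiency). Counts sum exactly to
    ``total_output``.
    """
    total_output = int(total_output)
    if total_output < 0:
        raise ValueError("total_output must be >= 0")
    index = pooled_mass.index if isinstance(pooled_mass, pd.Series) else None
    mass = np.asarray(pooled_mass, dtype=float)
    if (mass < 0).any():
        raise ValueError("pooled_mass must be non-negative")
    tot = mass.sum()
    if tot <= 0:
        raise ValueError("pooled_mass must have at least one positive entry")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = rng.multinomial(total_output, mass / tot)
    if index is not None:
        return pd.Series(counts, index=index, name="reads")
    return counts


def make_design(cfg: SimConfig) -> pd.DataFrame:
    """Sample sheet implied by the config: sample id, individual, condition, control.

    Replicates within a group are assigned to individuals ind1, ind2, ... so
    replicate k of every condition comes from the same individual, mirroring
    a cell-line panel treated in parallel.
    """
    rows = []
    for g in cfg.groups:
        for k in range(g.n):
            rows.append(
                {
                    "sample_id": f"{g.label}_{k + 1}",
                    "individual": f"ind{k + 1}",
                    "condition": g.label,
                    "control": g.control if g.control is not None else "",
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def make_truth(cfg: SimConfig, annotation: Optional[pd.DataFrame] = None) -> TruthSet:
    """Draw the ground truth: baselines, planted effects, dispersions, efficiencies."""
    if annotation is None:
        annotation = simulate_annotation(cfg)
    rng_base = _rng(cfg.seed, _STREAM_BASELINE)
    rng_eff = _rng(cfg.seed, _STREAM_EFFECTS)
    genes = annotation.index

    baseline = pd.Series(
        np.exp(rng_base.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)),
        index=genes,
        name="baseline",
    )

    n_de = int(round(cfg.frac_de * cfg.n_genes))
    lfc = pd.DataFrame(0.0, index=genes, columns=cfg.treatments)
    for t in cfg.treatments:
        hit = rng_eff.choice(cfg.n_genes, size=n_de, replace=False)
        lfc.iloc[hit, lfc.columns.get_loc(t)] = rng_eff.normal(0.0, cfg.effect_sd, n_de)

    # dispersion from the trend at the gene's expected control-sample count
    bias = _covariate_bias(cfg, annotation)
    rel = baseline * bias
    rel = rel / rel.sum()
    mu_ref = np.maximum(rel * cfg.ref_depth, 1e-8)
    dispersion = pd.Series(
        np.maximum(cfg.disp_a0 + cfg.disp_a1 / mu_ref, _DISPERSION_FLOOR),
        index=genes,
        name="dispersion",
    )

    efficiency = simulate_efficiencies(cfg)
    return TruthSet(log2fc=lfc, dispersion=dispersion, efficiency=efficiency, baseline=baseline)


def _covariate_bias(cfg: SimConfig, annotation: pd.DataFrame) -> pd.Series:
    gc = annotation["gc_fraction"].to_numpy(float)
    loglen = np.log10(annotation["length_bp"].to_numpy(float))
    eta = cfg.gc_beta * gc + cfg.len_beta * loglen + cfg.gclen_beta * gc * loglen
    eta = eta - eta.mean()  # bias is relative; center to keep scales comparable
    return pd.Series(np.exp(eta), index=annotation.index)


def expected_rates(
    cfg: SimConfig,
    truth: TruthSet,
    annotation: Optional[pd.DataFrame] = None,
    design: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Expected relative abundance per (gene, sample), columns summing to 1.

    Folds baseline, the sample's treatment effect (2**log2fc), and the
    GC/length bias, then renormalizes per sample: sequencing is
    compositional, so depth is the only column-total driver.
    """
    if annotation is None:
        annotation = simulate_annotation(cfg)
    if design is None:
        design = make_design(cfg)
    bias = _covariate_bias(cfg, annotation)
    base = truth.baseline * bias
    cols = {}
    for sid, row in design.iterrows():
        cond = row["condition"]
        if cond in truth.log2fc.columns:
            r = base * np.exp2(truth.log2fc[cond])
        else:
            r = base.copy()
        cols[sid] = r / r.sum()
    return pd.DataFrame(cols, index=annotation.index)


def simulate_library_rates(
    cfg: SimConfig,
    truth: TruthSet,
    annotation: Optional[pd.DataFrame] = None,
    design: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Latent per-library relative expression rates (one draw per library).

    Gamma with mean = expected rate and dispersion alpha_g; renormalized per
    sample. Sequencing the same rates at two depths emulates re-pooling the
    same libraries.
    """
    rates = expected_rates(cfg, truth, annotation, design)
    if rng is None:
        rng = _rng(cfg.seed, _STREAM_RATES)
    alpha = truth.dispersion.to_numpy(float)[:, None]
    r = rates.to_numpy(float)
    q = np.where(
        alpha > _DISPERSION_FLOOR,
        rng.gamma(np.maximum(1.0 / np.maximum(alpha, _DISPERSION_FLOOR), 1e-12), 1.0, r.shape)
        * np.maximum(alpha, _DISPERSION_FLOOR)
        * r,
        r,
    )
    q = q / np.maximum(q.sum(axis=0, keepdims=True), 1e-300)
    return pd.DataFrame(q, index=rates.index, columns=rates.columns)


def counts_from_rates(
    rates: pd.DataFrame,
    per_sample_depth,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Poisson reads at the given depths from fixed library rates."""
    depths = np.asarray(
        per_sample_depth
        if np.ndim(per_sample_depth)
        else np.full(rates.shape[1], per_sample_depth),
        dtype=float,
    )
    if depths.shape != (rates.shape[1],):
        raise ValueError("per_sample_depth must be scalar or one value per sample")
    if (depths < 0).any():
        raise ValueError("depths must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    mu = rates.to_numpy(float) * depths[None, :]
    counts = rng.poisson(mu)
    return pd.DataFrame(counts, index=rates.index, columns=rates.columns)


def simulate_counts(
    cfg: SimConfig,
    truth: TruthSet,
    per_sample_depth,
    annotation: Optional[pd.DataFrame] = None,
    design: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """One count matrix: fresh library rates, then reads at the given depths.

    Marginally, count_{g,s} ~ NB(depth_s * rate_{g,s}, alpha_g) with
    variance mu + alpha mu^2.
    """
    if rng is None:
        rng = _rng(cfg.seed, _STREAM_COUNTS)
    rates = simulate_library_rates(cfg, truth, annotation, design, rng=rng)
    return counts_from_rates(rates, per_sample_depth, rng=rng)


def simulate_two_depths(
    cfg: SimConfig,
    shallow_depth: float,
    deep_depth: float,
    truth: Optional[TruthSet] = None,
    annotation: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet, pd.DataFrame]:
    """Shallow and deep count matrices from the *same* simulated libraries.

    Returns (shallow_counts, deep_counts, truth, annotation). The two
    matrices share per-library latent rates — the deep run re-sequences the
    step-one libraries — so their noise is coupled the way a real two-step
    experiment's is.
    """
    if annotation is None:
        annotation = simulate_annotation(cfg)
    if truth is None:
        truth = make_truth(cfg, annotation)
    rng = _rng(cfg.seed, _STREAM_COUNTS)
    rates = simulate_library_rates(cfg, truth, annotation, rng=rng)
    shallow = counts_from_rates(rates, shallow_depth, rng=rng)
    deep = counts_from_rates(rates, deep_depth, rng=rng)
    return shallow, deep, truth, annotation
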