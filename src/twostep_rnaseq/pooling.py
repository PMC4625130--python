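"""Digital-concentration re-pooling.

After a shallow multiplexed run, each library's "digital concentration"
R_i = reads_i / volume_i (reads per uL actually delivered to the flow cell)
is a direct measurement of how efficiently that library converts volume into
sequenced reads — it folds in cluster-formation efficiency, which no
fluorometric or qPCR quantification sees. Given a cumulative per-sample read
target T and reads already collected D_i, the volume to re-pool is

    V_i = max(0, T - D_i) / R_i,

and the pool proportions V_i / sum(V). If a planned run delivers
run_output = sum of remaining deficits, every deficient library lands exactly
on T (up to multinomial noise in read allocation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "RunManifest",
    "PoolPlan",
    "DepthProfile",
    "digital_concentration",
    "repool_volumes",
    "iterate_plan",
    "depth_profile",
]


@dataclass
class RunManifest:
    """Per-barcode read yields of one sequencing run.

    ``total_output`` may exceed the sum of assigned reads (undetermined
    barcodes); undetermined reads never enter concentration estimates.
    """

    run_id: str
    total_output: int
    reads: pd.Series  # library_id -> raw reads

    def __post_init__(self):
        self.reads = pd.Series(self.reads, dtype="int64")
        self.reads.index.name = "library_id"
        if (self.reads < 0).any():
            raise ValueError("per-library reads must be >= 0")
        if self.reads.sum() > self.total_output:
            raise ValueError("assigned reads exceed the run's total output")


@dataclass
class PoolPlan:
    """A re-pooling plan: volumes, proportions, and predicted next-run reads."""

    target: float  # T, desired cumulative reads per library
    collected: pd.Series  # D_i
    concentration: pd.Series  # R_i, reads/uL
    volume: pd.Series  # V_i, uL
    proportion: pd.Series
    predicted_reads: pd.Series
    run_output: float
    cumulative_volume: Optional[pd.Series] = None  # uL sequenced so far, for pooled R updates

    @property
    def nothing_to_pool(self) -> bool:
        return bool((self.volume <= 0).all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "D": self.collected,
                "R": self.concentration,
                "volume_ul": self.volume.round(2),
                "proportion": self.proportion,
                "predicted_reads": self.predicted_reads,
            }
        ).rename_axis("library_id")


@dataclass
class DepthProfile:
    """Summary of per-sample depth uniformity (cv = sd/mean)."""

    depths: pd.Series
    mean: float
    sd: float
    cv: float


def digital_concentration(manifest: RunManifest, pooled_volume) -> pd.Series:
    """Reads per uL for every library in the manifest.

    ``pooled_volume`` gives the uL of each library that went into the
    sequenced pool. Zero reads give R_i = 0; a non-positive volume is an
    error naming the library.
    """
    vol = pd.Series(pooled_volume, dtype=float).reindex(manifest.reads.index)
    if vol.isna().any():
        missing = vol.index[vol.isna()].tolist()
        raise ValueError(f"no pooled volume for libraries: {missing}")
    bad = vol.index[vol <= 0].tolist()
    if bad:
        raise ValueError(f"pooled volume must be > 0; offending libraries: {bad}")
    r = manifest.reads / vol
    r.name = "R"
    return r


def repool_volumes(
    target: float,
    collected,
    concentration,
    run_output: float,
    assignable_fraction: float = 1.0,
    cumulative_volume=None,
) -> PoolPlan:
    """Eq.-style re-pooling: V_i = max(0, T - D_i) / R_i, normalized to proportions.

    ``run_output`` is the expected assignable read yield of the planned run;
    predicted reads split it proportionally to the remaining deficits
    (expected reads scale with R_i * V_i = deficit_i). Libraries already at or
    above target get volume 0. If every library is satisfied the plan is an
    explicit "nothing to pool" result.
    """
    if target <= 0:
        raise ValueError("target T must be > 0")
    if not 0 < assignable_fraction <= 1:
        raise ValueError("assignable_fraction must be in (0, 1]")
    D = pd.Series(collected, dtype=float)
    R = pd.Series(concentration, dtype=float).reindex(D.index)
    if R.isna().any():
        raise ValueError("concentration missing for some libraries")
    deficit = (target - D).clip(lower=0.0)
    unquantifiable = deficit.index[(deficit > 0) & (R <= 0)].tolist()
    if unquantifiable:
        raise ValueError(
            f"libraries below target with zero digital concentration: {unquantifiable}"
        )
    volume = pd.Series(0.0, index=D.index, name="volume_ul")
    mask = deficit > 0
    volume[mask] = deficit[mask] / R[mask]
    total_v = volume.sum()
    if total_v > 0:
        proportion = volume / total_v
        predicted = assignable_fraction * run_output * deficit / deficit.sum()
    else:
        proportion = pd.Series(0.0, index=D.index)
        predicted = pd.Series(0.0, index=D.index)
    proportion.name = "proportion"
    predicted.name = "predicted_reads"
    if cumulative_volume is not None:
        cumulative_volume = pd.Series(cumulative_volume, dtype=float).reindex(D.index)
    return PoolPlan(
        target=float(target),
        collected=D,
        concentration=R,
        volume=volume,
        proportion=proportion,
        predicted_reads=predicted,
        run_output=float(run_output),
        cumulative_volume=cumulative_volume,
    )


def iterate_plan(
    previous: PoolPlan,
    new_manifest: RunManifest,
    run_output: Optional[float] = None,
    r_update: str = "latest",
) -> PoolPlan:
    """Fold a new run into the plan and recompute volumes.

    D_i accumulates the new reads. R_i is re-estimated from the most recent
    run (reads delivered per uL pooled in it); ``r_update="pooled"`` instead
    volume-weights across all runs. Libraries with zero new reads (or zero
    pooled volume) keep their previous R_i.
    """
    if r_update not in ("latest", "pooled"):
        raise ValueError("r_update must be 'latest' or 'pooled'")
    new_reads = new_manifest.reads.reindex(previous.collected.index)
    if new_reads.isna().any():
        missing = new_reads.index[new_reads.isna()].tolist()
        raise ValueError(f"new manifest does not cover libraries: {missing}")
    D = previous.collected + new_reads

    vol_prev = previous.volume
    cum_vol = (
        previous.cumulative_volume
        if previous.cumulative_volume is not None
        else pd.Series(0.0, index=previous.collected.index)
    )
    cum_vol = cum_vol + vol_prev

    R = previous.concentration.copy()
    informative = (new_reads > 0) & (vol_prev > 0)
    if r_update == "latest":
        R[informative] = new_reads[informative] / vol_prev[informative]
    else:
        has_vol = cum_vol > 0
        R[has_vol] = D[has_vol] / cum_vol[has_vol]

    if run_output is None:
        run_output = float((previous.target - D).clip(lower=0).sum())
    return repool_volumes(
        previous.target, D, R, run_output, cumulative_volume=cum_vol
    )


def depth_profile(depths, replicate_groups=None) -> DepthProfile:
    """Mean, sd (n-1), and cv of per-sample depths.

    ``replicate_groups`` (sample -> group label) pools technical replicates
    before profiling, as is done when controls are split across replicate
    barcodes. All-zero depths leave the cv undefined (NaN).
    """
    d = pd.Series(depths, dtype=float)
    if replicate_groups is not None:
        d = d.groupby(pd.Series(replicate_groups).reindex(d.index)).sum()
    if len(d) < 2:
        raise ValueError("need at least 2 samples to profile depths")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if mean > 0:
        cv = sd / mean
    else:
        warnings.warn("all depths are zero; cv undefined")
        cv = float("nan")
    return DepthProfile(depths=d, mean=mean, sd=sd, cv=cv)
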