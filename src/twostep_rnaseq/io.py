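"""File formats, validation, provenance, and the two-step workflow driver.

Formats (all plain text):
  counts       TSV, first column transcript_id, one column per sample, integer
  annotation   TSV: transcript_id, gene_id, length_bp, gc_fraction
  sample sheet CSV: sample_id, barcode, individual, treatment, control, pooled_volume_ul
  manifest     first line ``total_output=<int>``, then CSV library_id,reads
  pool plan    CSV: library_id, D, R, volume_ul, proportion, predicted_reads

Every writer prepends ``#``-comment provenance lines (tool version, config
hash, seed); readers skip them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .simulate import GroupSpec, SimConfig

log = logging.getLogger("twostep")

__all__ = [
    "WorkflowConfig",
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "read_samplesheet",
    "write_samplesheet",
    "read_manifest",
    "write_manifest",
    "write_pool_plan",
    "write_results",
    "sim_config_from_dict",
    "run_two_step",
]


def _provenance_header(seed=None, config_hash=None) -> str:
    parts = [f"# twostep-rnaseq v{__version__}"]
    if config_hash is not None:
        parts.append(f"# config_hash={config_hash}")
    if seed is not None:
        parts.append(f"# seed={seed}")
    return "\n".join(parts) + "\n"


def _hash_config(obj) -> str:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path, sep, seed=None, config_hash=None, index=True):
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_header(seed=seed, config_hash=config_hash))
        df.to_csv(fh, sep=sep, index=index)


def write_counts(counts: pd.DataFrame, path, **meta):
    _write_table(counts.rename_axis("transcript_id"), path, "\t", **meta)


def read_counts(path) -> pd.DataFrame:
    """Read and validate a genes x samples integer count TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"{path}: no transcripts or no samples")
    df = df.set_index(df.columns[0])
    df.index.name = "transcript_id"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][:3].tolist()
        raise ValueError(f"{path}: duplicate transcript ids, e.g. {dup}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals)) | (vals < 0)
        if bad.any():
            row = df.index[bad][0]
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(
                f"{path}: non-integer or negative count at transcript {row!r}, "
                f"column {col!r} (data line {line})"
            )
    return df.astype(np.int64)


def write_annotation(annotation: pd.DataFrame, path, **meta):
    _write_table(annotation.rename_axis("transcript_id"), path, "\t", **meta)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"transcript_id": str, "gene_id": str})
    required = {"transcript_id", "gene_id", "length_bp", "gc_fraction"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation needs columns {sorted(required)}")
    df = df.set_index("transcript_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate transcript ids")
    if (df["length_bp"] <= 0).any():
        raise ValueError(f"{path}: transcript lengths must be > 0")
    if ((df["gc_fraction"] < 0) | (df["gc_fraction"] > 1)).any():
        raise ValueError(f"{path}: gc_fraction must be in [0, 1]")
    return df


def write_samplesheet(sheet: pd.DataFrame, path, **meta):
    _write_table(sheet.rename_axis("sample_id"), path, ",", **meta)


def read_samplesheet(path) -> pd.DataFrame:
    """Sample sheet -> design table indexed by sample_id.

    Accepts either treatment/control columns (sample sheet) or
    condition/control (design CSV); ``condition`` is the canonical name.
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: sample sheet needs a sample_id column")
    if "condition" not in df.columns:
        if "treatment" in df.columns:
            df = df.rename(columns={"treatment": "condition"})
        else:
            raise ValueError(f"{path}: sample sheet needs a condition/treatment column")
    if "control" not in df.columns:
        raise ValueError(f"{path}: sample sheet needs a control column")
    if "individual" not in df.columns:
        df["individual"] = "ind1"
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    df["control"] = df["control"].fillna("")
    if "pooled_volume_ul" in df.columns:
        df["pooled_volume_ul"] = df["pooled_volume_ul"].astype(float)
    return df


def write_manifest(run_id: str, total_output: int, reads: pd.Series, path, **meta):
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_header(**meta))
        fh.write(f"total_output={int(total_output)}\n")
        fh.write(f"# run_id={run_id}\n")
        reads.rename("reads").rename_axis("library_id").to_csv(fh)


def read_manifest(path):
    """Parse a run manifest (``total_output=`` line + library_id,reads CSV)."""
    from .pooling import RunManifest

    path = Path(path)
    total = None
    run_id = path.stem
    rows = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("# run_id="):
                run_id = line.split("=", 1)[1]
                continue
            if line.startswith("#"):
                continue
            if line.startswith("total_output="):
                total = int(float(line.split("=", 1)[1]))
                continue
            if line.startswith("library_id"):
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'library_id,reads', got {line!r}")
            try:
                rows.append((parts[0], int(float(parts[1]))))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer read count {parts[1]!r}")
    if total is None:
        raise ValueError(f"{path}: missing 'total_output=<int>' line")
    if not rows:
        raise ValueError(f"{path}: no libraries")
    reads = pd.Series(dict(rows), name="reads")
    reads.index.name = "library_id"
    return RunManifest(run_id=run_id, total_output=total, reads=reads)


def write_pool_plan(plan, path, **meta):
    _write_table(plan.to_frame(), path, ",", **meta)


def write_results(results: pd.DataFrame, path, **meta):
    _write_table(results.rename_axis("transcript_id"), path, "\t", **meta)


# ---------------------------------------------------------------------------
# workflow configuration and the end-to-end two-step run


@dataclass
class WorkflowConfig:
    """Everything needed to run the simulated two-step workflow end to end."""

    out_dir: str = "twostep_out"
    sim: SimConfig = field(default_factory=SimConfig)
    step_one_depth: float = 1e6  # mean reads/sample aimed at in step one
    target_T: float = 5e6  # desired cumulative reads/sample for selected conditions
    n_select: int = 1  # conditions carried into step two
    fdr: float = 0.1
    min_total_reads: int = 20
    trim: float = 0.1
    ratios: tuple = (1.0, 0.5, 0.25, 0.125)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self):
        if self.step_one_depth <= 0 or self.target_T <= 0:
            raise ValueError("depths must be > 0")
        if self.n_select < 0:
            raise ValueError("n_select must be >= 0")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        return self


def sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "groups" in d:
        d["groups"] = tuple(
            GroupSpec(g["label"], int(g["n"]), g.get("control")) if isinstance(g, dict) else GroupSpec(*g)
            for g in d["groups"]
        )
    return SimConfig(**d)


def workflow_config_from_yaml(path) -> WorkflowConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = sim_config_from_dict(raw.pop("sim", {}))
    if "ratios" in raw:
        raw["ratios"] = tuple(float(r) for r in raw["ratios"])
    # YAML 1.1 reads exponent literals like 4.0e5 as strings; coerce numerics
    for key, cast in [
        ("step_one_depth", float), ("target_T", float), ("n_select", int),
        ("fdr", float), ("min_total_reads", int), ("trim", float), ("seed", int),
    ]:
        if key in raw:
            raw[key] = cast(raw[key])
    return WorkflowConfig(sim=sim, **raw).validate()


def run_two_step(cfg: WorkflowConfig) -> dict:
    """Simulate and execute the full two-step workflow; write all artifacts.

    Stages: simulate libraries -> step-one shallow run -> shallow DE ->
    rank conditions by DE-gene count -> re-pooling plan for the selected
    conditions -> step-two deep run of the re-pooled libraries -> deep DE ->
    shallow/deep concordance report. Step-one and step-two counts are never
    merged for DE; cumulative depth D_i accumulates across runs for pooling.
    """
    from .de import NBDifferentialExpression, de_gene_set
    from .downsample import fc_correlation, recovery_fraction
    from .pooling import depth_profile, digital_concentration, repool_volumes, RunManifest
    from .simulate import (
        allocate_reads,
        counts_from_rates,
        make_design,
        make_truth,
        simulate_annotation,
        simulate_library_rates,
    )

    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _hash_config(cfg)
    meta = {"seed": cfg.seed, "config_hash": chash}
    logging.basicConfig(level=cfg.log_level)
    stage = "simulate"
    try:
        sim = cfg.sim.replace(seed=cfg.seed)
        annotation = simulate_annotation(sim)
        truth = make_truth(sim, annotation)
        design = make_design(sim)
        rates = simulate_library_rates(sim, truth, annotation, design)
        write_annotation(annotation, out / "annotation.tsv", **meta)
        sheet = design.copy()
        sheet["barcode"] = [f"BC{i + 1:03d}" for i in range(len(sheet))]
        sheet["pooled_volume_ul"] = 2.0
        write_samplesheet(sheet, out / "samples.csv", **meta)

        stage = "step_one_run"
        rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(100,)))
        total_step1 = int(cfg.step_one_depth * sim.n_samples)
        mass1 = sheet["pooled_volume_ul"] * truth.efficiency
        depths1 = allocate_reads(total_step1, mass1, rng=rng)
        counts1 = counts_from_rates(rates, depths1.to_numpy(), rng=rng)
        write_counts(counts1, out / "counts_step1.tsv", **meta)
        write_manifest("step1", total_step1, depths1, out / "manifest_step1.csv", **meta)

        stage = "step_one_de"
        de1 = NBDifferentialExpression(fdr=cfg.fdr, min_total_reads=cfg.min_total_reads).fit(
            counts1, design, annotation
        )
        summary1 = de1.summary()
        _write_table(summary1, out / "de_summary_step1.csv", ",", index=False, **meta)
        for t, res in de1.results_.items():
            write_results(res, out / f"de_step1_{t}.tsv", **meta)

        stage = "select_conditions"
        ranked = summary1.sort_values("n_de", ascending=False)
        selected = list(ranked["contrast"].head(cfg.n_select))
        log.info("selected conditions for step two: %s", selected)
        controls = {t: c for t, c in de1.contrasts_}
        selected_conditions = set(selected) | {controls[t] for t in selected}
        selected_samples = design.index[design["condition"].isin(selected_conditions)]

        stage = "pool_plan"
        manifest1 = RunManifest("step1", total_step1, depths1)
        if selected:
            R = digital_concentration(manifest1, sheet["pooled_volume_ul"]).loc[selected_samples]
            D = depths1.loc[selected_samples].astype(float)
            run_output = float((cfg.target_T - D).clip(lower=0).sum())
            plan = repool_volumes(cfg.target_T, D, R, run_output)
        else:
            plan = None
        if plan is not None:
            write_pool_plan(plan, out / "pool_plan.csv", **meta)

        report = {
            "selected": selected,
            "step1_summary": summary1,
            "step1_depth_cv": depth_profile(depths1).cv,
        }
        if plan is None or plan.nothing_to_pool:
            log.info("nothing to pool for step two; stopping after step one")
            report["step2_summary"] = None
            _write_run_log(out, cfg, chash, report)
            return report

        stage = "step_two_run"
        # deep run re-pools the same libraries: same latent rates, new reads
        mass2 = plan.volume * truth.efficiency.loc[selected_samples]
        depths2 = allocate_reads(int(plan.run_output), mass2, rng=rng)
        counts2 = counts_from_rates(rates[selected_samples.tolist()], depths2.to_numpy(), rng=rng)
        write_counts(counts2, out / "counts_step2.tsv", **meta)
        write_manifest("step2", int(plan.run_output), depths2, out / "manifest_step2.csv", **meta)
        report["step2_depth_cv"] = depth_profile(depths1.loc[selected_samples] + depths2).cv

        stage = "step_two_de"
        design2 = design.loc[selected_samples]
        de2 = NBDifferentialExpression(fdr=cfg.fdr, min_total_reads=cfg.min_total_reads).fit(
            counts2, design2, annotation
        )
        summary2 = de2.summary()
        _write_table(summary2, out / "de_summary_step2.csv", ",", index=False, **meta)
        for t, res in de2.results_.items():
            write_results(res, out / f"de_step2_{t}.tsv", **meta)

        stage = "concordance"
        rows = []
        for t in selected:
            rho = fc_correlation(de1.results_[t], de2.results_[t])
            rec = recovery_fraction(
                de_gene_set(de2.results_[t], cfg.fdr), de_gene_set(de1.results_[t], cfg.fdr)
            )
            rows.append({"treatment": t, "rho_shallow_vs_deep": rho, "shallow_recovery_of_deep": rec})
        concordance = pd.DataFrame(rows)
        _write_table(concordance, out / "concordance.csv", ",", index=False, **meta)
        report["step2_summary"] = summary2
        report["concordance"] = concordance
        _write_run_log(out, cfg, chash, report)
        return report
    except Exception as err:
        raise RuntimeError(f"two-step workflow failed at stage {stage!r}: {err}") from err


def _write_run_log(out: Path, cfg: WorkflowConfig, chash: str, report: dict):
    payload = {
        "version": __version__,
        "config_hash": chash,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "selected": report.get("selected"),
        "step1_depth_cv": report.get("step1_depth_cv"),
        "step2_depth_cv": report.get("step2_depth_cv"),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
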