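"""End-to-end orchestration: simulate -> qc -> predict -> glad -> compare.

A run is driven by a PipelineConfig holding either real input paths or an
inline simulation block (exactly one of the two). A single global seed is
split into per-stage substreams via ``numpy.random.SeedSequence`` so partial
reruns stay reproducible, and every persisted file's SHA-256 lands in the run
manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as tio
from .clocks import ClockModel, apply_clock, load_clock, parse_transform
from .compare import ComparisonReport, run_comparisons, welch_ttest
from .glad import build_glad_table, predicted_age_difference
from .qc import QCConfig, run_sample_qc
from .simulate import CohortBundle, SimConfig, dlk1_cpg_ids, generate_cohort, write_cohort

__all__ = [
    "ConfigError",
    "StageError",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "power_analysis",
    "simulate_and_score",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


@dataclass
class InputPaths:
    sperm_betas: str
    blood_betas: str
    sheet: str
    sperm_clock: str
    blood_clock: str
    sperm_transform: str = "identity"
    blood_transform: str = "identity"
    dlk1: str | None = None
    intensity: str | None = None


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    sim: SimConfig | None = None
    inputs: InputPaths | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    glad_scope: str = "pooled"
    glad_form: str = "centered"
    missing_policy: str = "fail"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ConfigError("config must set exactly one of: sim block, real input paths")

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            sim = SimConfig(**raw["sim"]) if "sim" in raw else None
            inputs = InputPaths(**raw["inputs"]) if "inputs" in raw else None
            qc = QCConfig(**raw.get("qc", {}))
            return cls(
                outdir=str(outdir if outdir is not None else raw.get("outdir", "tsage_run")),
                seed=int(seed if seed is not None else raw.get("seed", 0)),
                sim=sim,
                inputs=inputs,
                qc=qc,
                glad_scope=raw.get("glad_scope", "pooled"),
                glad_form=raw.get("glad_form", "centered"),
                missing_policy=raw.get("missing_policy", "fail"),
                make_plots=bool(raw.get("make_plots", True)),
            )
        except (TypeError, ValueError, KeyError) as exc:
            raise ConfigError(f"bad pipeline config {path}: {exc}") from exc


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    started: str
    finished: str = ""
    checksums: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence(seed).spawn(stage + 1)[stage].generate_state(1)[0])


def _scatter_plot(sub: pd.DataFrame, tissue: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(sub["age_years"], sub["predicted_age_years"], s=18, alpha=0.8)
    lo = min(sub["age_years"].min(), sub["predicted_age_years"].min())
    hi = max(sub["age_years"].max(), sub["predicted_age_years"].max())
    ax.plot([lo, hi], [lo, hi], ls="--", c="grey", lw=1)
    ax.set_xlabel("chronological age (years)")
    ax.set_ylabel("predicted age (years)")
    ax.set_title(tissue)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> tuple[RunManifest, ComparisonReport]:
    """Execute all stages, persisting every intermediate table under outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cfg_repr = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_repr.encode()).hexdigest(),
        version=__version__,
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def persist(name: str, path: Path) -> None:
        manifest.checksums[name] = _sha256(path)

    # ---- stage 1: obtain inputs (simulate or load) -------------------------
    stage = "simulate/load"
    try:
        if config.sim is not None:
            sim_cfg = dataclasses.replace(config.sim, seed=_stage_seed(config.seed, 0))
            bundle: CohortBundle | None = generate_cohort(sim_cfg)
            paths = write_cohort(bundle, outdir / "inputs")
            for key, p in paths.items():
                persist(f"inputs/{key}", p)
            sperm_betas, blood_betas = bundle.sperm_betas, bundle.blood_betas
            sheet = bundle.sheet
            sperm_clock: ClockModel = bundle.true_sperm_clock
            blood_clock: ClockModel = bundle.true_blood_clock
            dlk1 = dlk1_cpg_ids(bundle)
            intensity = None
        else:
            inp = config.inputs
            sperm_betas = tio.read_beta_matrix(inp.sperm_betas)
            blood_betas = tio.read_beta_matrix(inp.blood_betas)
            sheet = tio.read_sample_sheet(inp.sheet)
            sperm_clock = load_clock(inp.sperm_clock, parse_transform(inp.sperm_transform))
            blood_clock = load_clock(inp.blood_clock, parse_transform(inp.blood_transform))
            dlk1 = tio.read_dlk1_annotation(inp.dlk1) if inp.dlk1 else None
            intensity = tio.read_intensity_table(inp.intensity) if inp.intensity else None
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError(f"stage {stage} failed: {exc}") from exc

    # ---- stage 2: QC -------------------------------------------------------
    stage = "qc"
    try:
        kept = {}
        qc_frames, qc_reports = [], {}
        for tissue, betas in (("sperm", sperm_betas), ("blood", blood_betas)):
            filtered, report = run_sample_qc(
                betas, sheet, config=config.qc, dlk1_cpg_ids=dlk1,
                intensity_table=intensity,
            )
            kept[tissue] = filtered
            qc_frames.append(report.to_frame())
            qc_reports[tissue] = report.to_dict()
        qc_path = outdir / "qc_report.tsv"
        pd.concat(qc_frames, ignore_index=True).to_csv(qc_path, sep="\t", index=False)
        persist("qc_report", qc_path)
        qc_json = outdir / "qc_report.json"
        qc_json.write_text(json.dumps(qc_reports, indent=2))
        persist("qc_report_json", qc_json)
    except Exception as exc:
        raise StageError(f"stage {stage} failed: {exc}") from exc

    # ---- stage 3: predict --------------------------------------------------
    stage = "predict"
    try:
        preds = []
        for tissue, clock in (("sperm", sperm_clock), ("blood", blood_clock)):
            preds.append(apply_clock(clock, kept[tissue],
                                     missing_policy=config.missing_policy, sheet=sheet))
        predictions = pd.concat(preds, ignore_index=True)
        pred_path = outdir / "predictions.tsv"
        predictions.to_csv(pred_path, sep="\t", index=False)
        persist("predictions", pred_path)
    except Exception as exc:
        raise StageError(f"stage {stage} failed: {exc}") from exc

    # ---- stage 4: GLAD -----------------------------------------------------
    stage = "glad"
    try:
        glad_table = build_glad_table(predictions, sheet, scope=config.glad_scope,
                                      form=config.glad_form)
        glad_path = outdir / "glad_table.tsv"
        glad_table.to_csv(glad_path, sep="\t", index=False)
        persist("glad_table", glad_path)

        diffs = predicted_age_difference(predictions, sheet)
        diff_path = outdir / "predicted_differences.tsv"
        diffs.to_csv(diff_path, sep="\t", index=False)
        persist("predicted_differences", diff_path)
    except Exception as exc:
        raise StageError(f"stage {stage} failed: {exc}") from exc

    # ---- stage 5: compare --------------------------------------------------
    stage = "compare"
    try:
        report = run_comparisons(glad_table, predictions, sheet)
        (outdir / "comparison_report.json").write_text(report.to_json())
        persist("comparison_report_json", outdir / "comparison_report.json")
        (outdir / "comparison_report.md").write_text(report.to_markdown())
        persist("comparison_report_md", outdir / "comparison_report.md")
        report.to_rows().to_csv(outdir / "comparison_tests.tsv", sep="\t", index=False)
        persist("comparison_tests", outdir / "comparison_tests.tsv")

        if config.make_plots:
            merged = predictions.merge(sheet[["sample_id", "age_years"]], on="sample_id")
            for tissue in ("sperm", "blood"):
                sub = merged[merged["tissue"] == tissue]
                if len(sub):
                    _scatter_plot(sub, tissue, outdir / f"scatter_{tissue}.png")
    except Exception as exc:
        raise StageError(f"stage {stage} failed: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest, report


# ---------------------------------------------------------------------------
# fast in-memory replicate path used by power analysis and calibration tests
# ---------------------------------------------------------------------------

def simulate_and_score(sim_config: SimConfig) -> dict[str, float]:
    """One in-memory replicate: simulate, score with the true clocks, GLAD,
    group tests. Skips QC and file I/O — intended for Monte-Carlo loops.

    Returns sperm/blood GLAD group gaps (oligo mean - normo mean) and the
    Welch p-values of the per-tissue group tests.
    """
    bundle = generate_cohort(sim_config)
    preds = pd.concat([
        apply_clock(bundle.true_sperm_clock, bundle.sperm_betas, sheet=bundle.sheet),
        apply_clock(bundle.true_blood_clock, bundle.blood_betas, sheet=bundle.sheet),
    ], ignore_index=True)
    glad_table = build_glad_table(preds, bundle.sheet)
    out: dict[str, float] = {}
    for tissue in ("sperm", "blood"):
        sub = glad_table[glad_table["tissue"] == tissue]
        oligo = sub.loc[sub["group"] == "oligozoospermic", "glad"].to_numpy()
        normo = sub.loc[sub["group"] == "normozoospermic", "glad"].to_numpy()
        res = welch_ttest(oligo, normo)
        out[f"{tissue}_glad_gap"] = float(oligo.mean() - normo.mean())
        out[f"{tissue}_p"] = res.p_value
    return out


def power_analysis(base_config: SimConfig, accel_grid, n_replicates: int = 100,
                   alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Fraction of replicates where the sperm GLAD test rejects at alpha,
    per injected acceleration, with the Monte-Carlo standard error."""
    accel_grid = list(accel_grid)
    if not accel_grid:
        raise ConfigError("accel_grid must be non-empty")
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates * len(accel_grid))
    rows = []
    k = 0
    for accel in accel_grid:
        hits = 0
        for _ in range(n_replicates):
            cfg = dataclasses.replace(base_config, sperm_accel_oligo=float(accel),
                                      seed=int(seeds[k]))
            k += 1
            if simulate_and_score(cfg)["sperm_p"] < alpha:
                hits += 1
        power = hits / n_replicates
        rows.append({
            "accel": float(accel),
            "power": power,
            "mc_se": float(np.sqrt(power * (1 - power) / n_replicates)),
            "n_replicates": n_replicates,
            "alpha": alpha,
        })
    return pd.DataFrame(rows)
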