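"""Synthetic methylome cohorts with known aging structure.

Generates paired sperm/blood beta matrices, a sample sheet, and the "true"
linear clocks that exactly invert the generative model, so the whole
downstream analysis can be exercised with parameter recovery as ground truth.

Generative model
----------------
* Chronological ages are drawn per group from a normal whose SD is
  ``SE * sqrt(n)`` (so the cohort standard error matches the configured SE in
  expectation), truncated to [18, 60] by rejection.
* Each tissue has its own set of clock CpGs with per-CpG baseline ``b0`` and
  slope ``s``; in that tissue ``beta = clip(b0 + s * effective_age + eps, 0, 1)``
  with ``eps ~ N(0, beta_noise_sd)``. In the *other* tissue the same CpGs sit
  flat at their baseline (plus noise).
* ``effective_age = chronological * (1 + accel)`` where accel applies to the
  oligozoospermic group only, per tissue.
* Background CpGs follow a strongly bimodal two-component mixture (low /
  high methylation), background for both tissues.
* DLK1-region CpGs sit near 0.05 in pure sperm and near 0.8 in blood, so
  somatic contamination raises the sperm DLK1 mean affinely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .clocks import ClockModel, IDENTITY, save_clock

__all__ = [
    "SimConfig",
    "CohortBundle",
    "generate_cohort",
    "mix_contamination",
    "build_true_clock",
    "write_cohort",
]

TISSUES = ("sperm", "blood")
GROUP_OLIGO = "oligozoospermic"
GROUP_NORMO = "normozoospermic"

AGE_LOW, AGE_HIGH = 18.0, 60.0

# per-CpG generative parameter ranges; chosen so trajectories stay inside
# [0,1] over ages 18-60 without clipping (0.35 + 0.008*60 = 0.83)
SLOPE_RANGE = (0.002, 0.008)
BASELINE_LOW = (0.15, 0.35)
BASELINE_HIGH = (0.65, 0.85)

DLK1_SPERM_MEAN = 0.05
DLK1_BLOOD_MEAN = 0.80


class SaturationError(ValueError):
    """Generative regime would clip >1% of clock-CpG values at age 60."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator."""

    n_oligo: int = 10
    n_normo: int = 24
    age_mean_oligo: float = 32.73
    age_se_oligo: float = 1.9
    age_mean_normo: float = 31.64
    age_se_normo: float = 1.3
    n_clock_cpgs: int = 50
    n_background_cpgs: int = 2000
    n_dlk1_cpgs: int = 5
    sperm_accel_oligo: float = 0.0
    blood_accel_oligo: float = 0.0
    beta_noise_sd: float = 0.01
    contamination_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_oligo", "n_normo", "n_clock_cpgs", "n_background_cpgs", "n_dlk1_cpgs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("age_se_oligo", "age_se_normo", "beta_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction must be in [0,1]")
        for name in ("sperm_accel_oligo", "blood_accel_oligo"):
            if getattr(self, name) <= -1.0:
                raise ValueError(f"{name} must be > -1")


@dataclass
class CohortBundle:
    """Everything a downstream pipeline run needs, plus the ground truth."""

    sperm_betas: pd.DataFrame
    blood_betas: pd.DataFrame
    sheet: pd.DataFrame
    true_sperm_clock: ClockModel
    true_blood_clock: ClockModel
    truth: pd.Series  # sample_id -> effective age (years)
    config: SimConfig


def build_true_clock(baselines, slopes, cpg_ids, name: str = "true-clock") -> ClockModel:
    """Construct the identity-transform clock that inverts the linear
    generative map ``beta_i = b0_i + s_i * age``.

    The least-squares inversion is ``age_hat = sum(s_i (beta_i - b0_i)) /
    sum(s_i^2)``, i.e. coefficient ``s_i / sum(s^2)`` on CpG i and intercept
    ``-sum(s_i b0_i) / sum(s^2)``; on noise-free data the residual is 0.
    """
    baselines = np.asarray(baselines, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    if baselines.shape != slopes.shape or len(baselines) != len(cpg_ids):
        raise ValueError("baselines, slopes and cpg_ids must have equal length")
    if np.any(slopes == 0.0):
        raise ValueError("all slopes must be nonzero")
    denom = float(np.sum(slopes**2))
    if denom == 0.0 or not np.isfinite(denom):
        raise ValueError("degenerate slope set")
    coeffs = pd.Series(slopes / denom, index=list(cpg_ids))
    intercept = -float(np.sum(slopes * baselines)) / denom
    return ClockModel(name=name, intercept=intercept, coefficients=coeffs, transform=IDENTITY)


def mix_contamination(sperm_profile: pd.Series, blood_profile: pd.Series, fraction: float) -> pd.Series:
    """Elementwise convex mixture ``(1-f)*sperm + f*blood`` over matching CpGs."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0,1]")
    if len(sperm_profile) != len(blood_profile) or set(sperm_profile.index) != set(blood_profile.index):
        raise ValueError("mismatched CpG sets")
    blood = blood_profile.reindex(sperm_profile.index)
    return (1.0 - fraction) * sperm_profile + fraction * blood


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Rejection-sample a normal truncated to [AGE_LOW, AGE_HIGH]."""
    if sd == 0.0:
        if not AGE_LOW <= mean <= AGE_HIGH:
            raise ValueError("degenerate age distribution outside truncation bounds")
        return np.full(n, mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        keep = draw[(draw >= AGE_LOW) & (draw <= AGE_HIGH)]
        take = min(len(keep), n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def _draw_clock_params(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Baselines and slopes for one tissue's clock CpGs.

    Low baselines get positive slopes and high baselines negative ones so that
    noise-free trajectories never leave [0,1] on ages 18-60.
    """
    low = rng.random(n) < 0.5
    baselines = np.where(
        low,
        rng.uniform(*BASELINE_LOW, size=n),
        rng.uniform(*BASELINE_HIGH, size=n),
    )
    magnitude = rng.uniform(*SLOPE_RANGE, size=n)
    slopes = np.where(low, magnitude, -magnitude)
    return baselines, slopes


def _check_saturation(baselines: np.ndarray, slopes: np.ndarray) -> None:
    endpoint = baselines + slopes * AGE_HIGH
    start = baselines + slopes * AGE_LOW
    bad = ((endpoint < 0) | (endpoint > 1) | (start < 0) | (start > 1)).mean()
    if bad > 0.01:
        raise SaturationError(
            f"{bad:.1%} of clock-CpG trajectories leave [0,1] over ages "
            f"[{AGE_LOW}, {AGE_HIGH}]; slope/baseline ranges are unusable"
        )


def generate_cohort(config: SimConfig) -> CohortBundle:
    """Generate a paired sperm/blood cohort. Deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)

    n_total = config.n_oligo + config.n_normo
    groups = [GROUP_OLIGO] * config.n_oligo + [GROUP_NORMO] * config.n_normo
    individuals = [f"I{i + 1:03d}" for i in range(n_total)]

    ages = np.concatenate([
        _truncated_normal(rng, config.age_mean_oligo,
                          config.age_se_oligo * np.sqrt(config.n_oligo), config.n_oligo),
        _truncated_normal(rng, config.age_mean_normo,
                          config.age_se_normo * np.sqrt(config.n_normo), config.n_normo),
    ])

    rows = []
    for ind, group, age in zip(individuals, groups, ages):
        for tissue in TISSUES:
            rows.append({
                "sample_id": f"{ind}_{tissue}",
                "individual_id": ind,
                "tissue": tissue,
                "group": group,
                "age_years": age,
            })
    sheet = pd.DataFrame(rows)

    is_oligo = np.array([g == GROUP_OLIGO for g in groups])
    eff_sperm = ages * np.where(is_oligo, 1.0 + config.sperm_accel_oligo, 1.0)
    eff_blood = ages * np.where(is_oligo, 1.0 + config.blood_accel_oligo, 1.0)

    clock_params = {}
    for tissue in TISSUES:
        b0, s = _draw_clock_params(rng, config.n_clock_cpgs)
        _check_saturation(b0, s)
        ids = [f"cg_{tissue}_clk{i:05d}" for i in range(config.n_clock_cpgs)]
        clock_params[tissue] = (b0, s, ids)

    bg_ids = [f"cg_bg{i:06d}" for i in range(config.n_background_cpgs)]
    bg_low = rng.random(config.n_background_cpgs) < 0.5
    bg_center = np.where(
        bg_low,
        rng.uniform(0.02, 0.15, size=config.n_background_cpgs),
        rng.uniform(0.85, 0.98, size=config.n_background_cpgs),
    )
    dlk1_ids = [f"cg_dlk1_{i:03d}" for i in range(config.n_dlk1_cpgs)]

    def tissue_matrix(tissue: str, eff_ages: np.ndarray, tissue_rng: np.random.Generator) -> pd.DataFrame:
        blocks, index = [], []
        for clk_tissue in TISSUES:
            b0, s, ids = clock_params[clk_tissue]
            if clk_tissue == tissue:
                det = b0[:, None] + s[:, None] * eff_ages[None, :]
            else:
                det = np.broadcast_to((b0 + s * np.mean(eff_ages))[:, None],
                                      (len(b0), n_total)).copy()
            blocks.append(det)
            index.extend(ids)
        blocks.append(np.broadcast_to(bg_center[:, None],
                                      (config.n_background_cpgs, n_total)).copy())
        index.extend(bg_ids)
        dlk1_mean = DLK1_SPERM_MEAN if tissue == "sperm" else DLK1_BLOOD_MEAN
        blocks.append(np.full((config.n_dlk1_cpgs, n_total), dlk1_mean))
        index.extend(dlk1_ids)
        values = np.vstack(blocks)
        if config.beta_noise_sd > 0:
            values = values + tissue_rng.normal(0.0, config.beta_noise_sd, size=values.shape)
        values = np.clip(values, 0.0, 1.0)
        cols = [f"{ind}_{tissue}" for ind in individuals]
        return pd.DataFrame(values, index=index, columns=cols)

    sperm_betas = tissue_matrix("sperm", eff_sperm, rng)
    blood_betas = tissue_matrix("blood", eff_blood, rng)

    if config.contamination_fraction > 0:
        f = config.contamination_fraction
        for ind in individuals:
            mixed = mix_contamination(
                sperm_betas[f"{ind}_sperm"],
                blood_betas[f"{ind}_blood"].set_axis(sperm_betas.index),
                f,
            )
            sperm_betas[f"{ind}_sperm"] = mixed

    b0, s, ids = clock_params["sperm"]
    true_sperm_clock = build_true_clock(b0, s, ids, name="true-sperm-clock")
    b0, s, ids = clock_params["blood"]
    true_blood_clock = build_true_clock(b0, s, ids, name="true-blood-clock")

    truth = pd.Series(
        np.concatenate([eff_sperm, eff_blood]),
        index=[f"{ind}_sperm" for ind in individuals] + [f"{ind}_blood" for ind in individuals],
        name="effective_age_years",
    )

    return CohortBundle(
        sperm_betas=sperm_betas,
        blood_betas=blood_betas,
        sheet=sheet,
        true_sperm_clock=true_sperm_clock,
        true_blood_clock=true_blood_clock,
        truth=truth,
        config=config,
    )


def simulate_intensity_table(bundle: CohortBundle, mean_log2: float = 11.5,
                             sd_log2: float = 0.3, seed: int | None = None) -> pd.DataFrame:
    """Optional per-sample log2 median intensity summaries (log2-normal)."""
    rng = np.random.default_rng(bundle.config.seed + 104729 if seed is None else seed)
    samples = list(bundle.sperm_betas.columns) + list(bundle.blood_betas.columns)
    return pd.DataFrame({
        "sample_id": samples,
        "median_log2_intensity": rng.normal(mean_log2, sd_log2, size=len(samples)),
    })


def dlk1_cpg_ids(bundle: CohortBundle) -> list[str]:
    return [c for c in bundle.sperm_betas.index if c.startswith("cg_dlk1_")]


def write_cohort(bundle: CohortBundle, outdir) -> dict[str, Path]:
    """Persist the bundle as plain-text tables plus a JSON truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    for tissue, betas in (("sperm", bundle.sperm_betas), ("blood", bundle.blood_betas)):
        p = outdir / f"betas_{tissue}.tsv"
        betas.rename_axis("cpg_id").to_csv(p, sep="\t")
        paths[f"betas_{tissue}"] = p

    p = outdir / "sample_sheet.csv"
    bundle.sheet.to_csv(p, index=False)
    paths["sheet"] = p

    for tissue, clock in (("sperm", bundle.true_sperm_clock), ("blood", bundle.true_blood_clock)):
        p = outdir / f"clock_{tissue}.csv"
        save_clock(clock, p)
        paths[f"clock_{tissue}"] = p

    p = outdir / "dlk1_cpgs.txt"
    p.write_text("\n".join(dlk1_cpg_ids(bundle)) + "\n")
    paths["dlk1"] = p

    p = outdir / "truth.json"
    p.write_text(json.dumps({
        "config": asdict(bundle.config),
        "seed": bundle.config.seed,
        "effective_age_years": bundle.truth.to_dict(),
    }, indent=2))
    paths["truth"] = p
    return paths
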