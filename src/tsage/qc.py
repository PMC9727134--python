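"""Sample-level quality control.

Four checks, mirroring a standard methylation-array workflow:

* beta-distribution bimodality (interval-mass surrogate for the visual
  "prominent peaks at the extremes, flat valley in the middle" criterion),
* DLK1-region mean beta as a sentinel for somatic contamination of sperm,
* optional median log2 intensity floor,
* a Welch t-test confirming chronological age is not confounded with group.

Inputs are assumed pre-normalized beta values; no probe-level filtering or
renormalization is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .compare import TestResult, welch_ttest

__all__ = [
    "QCConfig",
    "QCResult",
    "QCReport",
    "bimodality_check",
    "dlk1_contamination_check",
    "median_intensity_check",
    "age_confound_check",
    "run_sample_qc",
]


@dataclass
class QCConfig:
    """Thresholds and toggles for the sample filters.

    The bimodality thresholds operationalize "prominent peaks between 0.0-0.2
    and 0.8-1.0 and a flat valley from 0.2-0.8" as interval masses; the DLK1
    direction (pass when mean <= threshold) reflects pure sperm being the
    low-methylation clean state. Both are configurable.
    """

    p_peak: float = 0.25
    p_valley: float = 0.35
    min_beta_values: int = 1000
    dlk1_threshold: float = 0.25
    dlk1_tissues: tuple[str, ...] = ("sperm",)
    intensity_threshold: float = 10.5  # conventional log2 cutoff
    enable_bimodality: bool = True
    enable_dlk1: bool = True
    enable_intensity: bool = True


@dataclass
class QCResult:
    sample_id: str
    check_name: str
    passed: bool
    statistic: float
    threshold: float
    detail: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class QCReport:
    results: list[QCResult] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    removed: dict[str, list[str]] = field(default_factory=dict)  # sample -> failed checks
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [r.to_dict() for r in self.results],
            columns=["sample_id", "check_name", "passed", "statistic", "threshold", "detail"],
        )

    def to_dict(self) -> dict:
        return {
            "retained": list(self.retained),
            "removed": {k: list(v) for k, v in self.removed.items()},
            "notes": list(self.notes),
            "results": [r.to_dict() for r in self.results],
        }


def bimodality_check(sample_betas, sample_id: str = "", p_peak: float = 0.25,
                     p_valley: float = 0.35, min_values: int = 1000) -> QCResult:
    """Pass iff P(beta<=0.2) >= p_peak, P(beta>=0.8) >= p_peak and
    P(0.2<beta<0.8) <= p_valley. The reported statistic is the mid mass."""
    values = np.asarray(sample_betas, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < min_values:
        raise ValueError(
            f"bimodality check needs >= {min_values} beta values, got {len(values)}"
        )
    f_low = float(np.mean(values <= 0.2))
    f_high = float(np.mean(values >= 0.8))
    f_mid = float(np.mean((values > 0.2) & (values < 0.8)))
    passed = (f_low >= p_peak) and (f_high >= p_peak) and (f_mid <= p_valley)
    return QCResult(
        sample_id=sample_id,
        check_name="bimodality",
        passed=passed,
        statistic=f_mid,
        threshold=p_valley,
        detail=f"f_low={f_low:.3f} f_high={f_high:.3f} f_mid={f_mid:.3f}",
    )


def dlk1_contamination_check(sample_betas: pd.Series, dlk1_cpg_ids,
                             sample_id: str = "", threshold: float = 0.25) -> QCResult:
    """Mean beta over DLK1-region CpGs; pass iff <= threshold (inclusive)."""
    present = [c for c in dlk1_cpg_ids if c in sample_betas.index]
    if not present:
        raise ValueError("no DLK1 CpGs found in the beta matrix (incompatible annotation)")
    statistic = float(sample_betas.loc[present].mean())
    return QCResult(
        sample_id=sample_id,
        check_name="dlk1_contamination",
        passed=statistic <= threshold,
        statistic=statistic,
        threshold=threshold,
        detail=f"{len(present)} DLK1 CpGs",
    )


def median_intensity_check(intensity: float, sample_id: str = "",
                           threshold: float = 10.5) -> QCResult:
    """Pass iff the sample's median log2 intensity >= threshold."""
    if intensity < 0:
        raise ValueError(f"negative intensity {intensity} for {sample_id}")
    return QCResult(
        sample_id=sample_id,
        check_name="median_intensity",
        passed=bool(intensity >= threshold),
        statistic=float(intensity),
        threshold=threshold,
    )


def age_confound_check(sheet: pd.DataFrame,
                       grouping: tuple[str, str] = ("oligozoospermic", "normozoospermic")) -> TestResult:
    """Welch t-test on chronological ages between groups (one row per
    individual). Flags, rather than raises on, zero-variance degeneracy."""
    per_ind = sheet.drop_duplicates("individual_id")
    a, b = grouping
    x = per_ind.loc[per_ind["group"] == a, "age_years"].to_numpy(dtype=float)
    y = per_ind.loc[per_ind["group"] == b, "age_years"].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("age confound check needs >= 2 individuals per group")
    return welch_ttest(x, y, labels=grouping, test_name="age_confound")


def run_sample_qc(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    config: QCConfig | None = None,
    dlk1_cpg_ids=None,
    intensity_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply all enabled checks; drop samples failing any of them.

    Returns the filtered matrix (columns restricted to retained samples) and
    a report listing every decision. Raises if every sample is removed, or if
    the matrix contains a sample absent from the sheet.
    """
    config = config or QCConfig()
    report = QCReport()

    annotated = set(sheet["sample_id"])
    unannotated = [s for s in betas.columns if s not in annotated]
    if unannotated:
        raise ValueError(f"unannotated sample(s) in beta matrix: {unannotated}")

    tissue_of = sheet.set_index("sample_id")["tissue"]
    intensities = None
    if intensity_table is not None:
        intensities = intensity_table.set_index("sample_id")["median_log2_intensity"]

    for sample in betas.columns:
        column = betas[sample]
        failures = []

        if config.enable_bimodality:
            res = bimodality_check(column, sample_id=sample, p_peak=config.p_peak,
                                   p_valley=config.p_valley, min_values=config.min_beta_values)
            report.results.append(res)
            if not res.passed:
                failures.append(res.check_name)

        if config.enable_dlk1 and dlk1_cpg_ids is not None \
                and tissue_of.get(sample) in config.dlk1_tissues:
            res = dlk1_contamination_check(column, dlk1_cpg_ids, sample_id=sample,
                                           threshold=config.dlk1_threshold)
            report.results.append(res)
            if not res.passed:
                failures.append(res.check_name)

        if config.enable_intensity:
            if intensities is None:
                pass  # noted once below
            elif sample in intensities.index:
                res = median_intensity_check(float(intensities[sample]), sample_id=sample,
                                             threshold=config.intensity_threshold)
                report.results.append(res)
                if not res.passed:
                    failures.append(res.check_name)

        if failures:
            report.removed[sample] = failures
        else:
            report.retained.append(sample)

    if config.enable_intensity and intensities is None:
        report.notes.append("median_intensity: not evaluated (no intensity table supplied)")
    if config.enable_dlk1 and dlk1_cpg_ids is None:
        report.notes.append("dlk1_contamination: not evaluated (no DLK1 annotation supplied)")

    if not report.retained:
        raise ValueError(f"all samples removed by QC: {report.removed}")

    return betas[report.retained], report
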