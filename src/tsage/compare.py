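"""Statistical battery: Welch t-tests, OLS regressions, report assembly.

Note on test choice: between-group comparisons use unpaired Welch
(unequal-variance) t-tests with Satterthwaite degrees of freedom — the group
sizes are unequal by design — while pairing enters only through the
per-individual sperm-minus-blood predicted-age differences. All p-values are
two-sided and uncorrected; an optional Bonferroni flag is provided for users
who want family-wise control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "RegressionResult",
    "ComparisonReport",
    "welch_ttest",
    "glad_group_test",
    "regression_fit",
    "predicted_difference_test",
    "run_comparisons",
]


@dataclass
class TestResult:
    test_name: str
    group_labels: tuple[str, str]
    group_means: tuple[float, float]
    group_ses: tuple[float, float]
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    paired: bool = False
    degenerate: bool = False
    n: tuple[int, int] = (0, 0)
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RegressionResult:
    tissue: str
    slope: float
    intercept: float
    r_squared: float
    adjusted_r_squared: float
    slope_p_value: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _se(x: np.ndarray) -> float:
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def welch_ttest(x, y, labels: tuple[str, str] = ("x", "y"),
                test_name: str = "welch_ttest", paired: bool = False) -> TestResult:
    """Welch two-sample t-test with Satterthwaite df, two-sided p.

    Degenerate inputs (both samples constant) return flagged non-finite
    statistics instead of raising, so batch simulations never abort; equal
    constants give t = 0, p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample must have length >= 2")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    base = dict(
        test_name=test_name,
        group_labels=labels,
        group_means=(float(np.mean(x)), float(np.mean(y))),
        group_ses=(_se(x), _se(y)),
        paired=paired,
        n=(len(x), len(y)),
    )
    if vx == 0.0 and vy == 0.0:
        if np.mean(x) == np.mean(y):
            return TestResult(t_statistic=0.0, degrees_of_freedom=float(len(x) + len(y) - 2),
                              p_value=1.0, **base)
        return TestResult(t_statistic=float("inf") if np.mean(x) > np.mean(y) else float("-inf"),
                          degrees_of_freedom=float("nan"), p_value=float("nan"),
                          degenerate=True, note="zero variance in both groups, unequal means",
                          **base)
    res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        **base,
    )


def regression_fit(chronological, predicted, tissue: str = "") -> RegressionResult:
    """OLS of predicted age on chronological age.

    Slope p is the two-sided t-test with n-2 df; adjusted r-squared is
    ``1 - (1 - r2)(n - 1)/(n - 2)``.
    """
    chronological = np.asarray(chronological, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    n = len(chronological)
    if n != len(predicted):
        raise ValueError("mismatched lengths")
    if n < 3:
        raise ValueError("regression needs n >= 3")
    if np.ptp(chronological) == 0.0:
        raise ValueError("constant chronological ages: regression undefined")
    if np.ptp(predicted) == 0.0:
        # flat response: slope 0, no variance explained
        return RegressionResult(
            tissue=tissue, slope=0.0, intercept=float(predicted[0]),
            r_squared=0.0, adjusted_r_squared=1.0 - (n - 1) / (n - 2),
            slope_p_value=1.0, n=n,
        )
    res = stats.linregress(chronological, predicted)
    r2 = float(res.rvalue**2)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        tissue=tissue,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        adjusted_r_squared=float(adj),
        slope_p_value=float(res.pvalue),
        n=n,
    )


def glad_group_test(glad_table: pd.DataFrame, tissue: str,
                    grouping: tuple[str, str] = ("oligozoospermic", "normozoospermic")) -> TestResult:
    """Unpaired Welch test on GLAD values between the two groups in a tissue."""
    sub = glad_table[glad_table["tissue"] == tissue]
    if sub.empty:
        raise ValueError(f"unknown tissue {tissue!r}")
    a, b = grouping
    x = sub.loc[sub["group"] == a, "glad"].to_numpy()
    y = sub.loc[sub["group"] == b, "glad"].to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValueError(f"group absent in tissue {tissue!r}")
    return welch_ttest(x, y, labels=grouping, test_name=f"glad_{tissue}")


def predicted_difference_test(diff_table: pd.DataFrame, sheet: pd.DataFrame,
                              grouping: tuple[str, str] = ("oligozoospermic", "normozoospermic")) -> TestResult:
    """Welch test of per-individual sperm-minus-blood differences between groups."""
    group_of = sheet.drop_duplicates("individual_id").set_index("individual_id")["group"]
    merged = diff_table.assign(group=diff_table["individual_id"].map(group_of))
    a, b = grouping
    x = merged.loc[merged["group"] == a, "difference"].to_numpy()
    y = merged.loc[merged["group"] == b, "difference"].to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("a group is absent from the difference table")
    return welch_ttest(x, y, labels=grouping, test_name="predicted_age_difference")


@dataclass
class ComparisonReport:
    """All six components of the analysis battery.

    Missing inputs leave a component as None with the reason in ``notes``.
    """

    sperm_glad_test: TestResult | None = None
    blood_glad_test: TestResult | None = None
    predicted_difference_test: TestResult | None = None
    sperm_regression: RegressionResult | None = None
    blood_regression: RegressionResult | None = None
    age_confound: TestResult | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {"notes": list(self.notes)}
        for key in ("sperm_glad_test", "blood_glad_test", "predicted_difference_test",
                    "sperm_regression", "blood_regression", "age_confound"):
            item = getattr(self, key)
            out[key] = item.to_dict() if item is not None else "not evaluated"
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_markdown(self) -> str:
        lines = ["# Comparison report", ""]
        if self.notes:
            lines += [f"> {n}" for n in self.notes] + [""]
        lines += ["| test | group A mean | group B mean | t | df | p |",
                  "|---|---|---|---|---|---|"]
        for key in ("sperm_glad_test", "blood_glad_test", "predicted_difference_test", "age_confound"):
            r = getattr(self, key)
            if r is None:
                lines.append(f"| {key} | — | — | — | — | not evaluated |")
            else:
                lines.append(
                    f"| {r.test_name} | {r.group_means[0]:.4g} | {r.group_means[1]:.4g} "
                    f"| {r.t_statistic:.4g} | {r.degrees_of_freedom:.4g} | {r.p_value:.4g} |"
                )
        lines += ["", "| regression | slope | adjusted r² | slope p | n |", "|---|---|---|---|---|"]
        for key in ("sperm_regression", "blood_regression"):
            r = getattr(self, key)
            if r is None:
                lines.append(f"| {key} | — | — | not evaluated | — |")
            else:
                lines.append(f"| {r.tissue} | {r.slope:.4g} | {r.adjusted_r_squared:.4g} "
                             f"| {r.slope_p_value:.4g} | {r.n} |")
        return "\n".join(lines) + "\n"

    def to_rows(self) -> pd.DataFrame:
        rows = []
        for key in ("sperm_glad_test", "blood_glad_test", "predicted_difference_test", "age_confound"):
            r = getattr(self, key)
            if r is not None:
                rows.append({"test": r.test_name, "group_a_mean": r.group_means[0],
                             "group_b_mean": r.group_means[1], "t": r.t_statistic,
                             "df": r.degrees_of_freedom, "p": r.p_value})
        return pd.DataFrame(rows)


def run_comparisons(glad_table: pd.DataFrame, predictions: pd.DataFrame,
                    sheet: pd.DataFrame,
                    grouping: tuple[str, str] = ("oligozoospermic", "normozoospermic"),
                    bonferroni: bool = False) -> ComparisonReport:
    """Assemble the full battery from the GLAD table and predictions.

    Components whose inputs are missing are marked not-evaluated rather than
    aborting the rest of the report.
    """
    from .glad import predicted_age_difference  # late import avoids cycle
    from .qc import age_confound_check

    report = ComparisonReport()
    report.notes.append(
        "Between-group tests are unpaired Welch t-tests; pairing is used only "
        "to form per-individual sperm-minus-blood differences."
    )

    merged = predictions.merge(
        sheet[["sample_id", "age_years", "group"]], on="sample_id", how="left"
    )

    for tissue, test_attr, reg_attr in (
        ("sperm", "sperm_glad_test", "sperm_regression"),
        ("blood", "blood_glad_test", "blood_regression"),
    ):
        try:
            setattr(report, test_attr, glad_group_test(glad_table, tissue, grouping))
        except ValueError as exc:
            report.notes.append(f"{test_attr}: not evaluated ({exc})")
        sub = merged[merged["tissue"] == tissue].dropna(subset=["age_years"])
        try:
            setattr(report, reg_attr,
                    regression_fit(sub["age_years"], sub["predicted_age_years"], tissue=tissue))
        except ValueError as exc:
            report.notes.append(f"{reg_attr}: not evaluated ({exc})")

    try:
        diffs = predicted_age_difference(predictions, sheet)
        if diffs.empty:
            raise ValueError("no complete sperm/blood pairs")
        report.predicted_difference_test = predicted_difference_test(diffs, sheet, grouping)
    except ValueError as exc:
        report.notes.append(f"predicted_difference_test: not evaluated ({exc})")

    try:
        report.age_confound = age_confound_check(sheet, grouping)
    except ValueError as exc:
        report.notes.append(f"age_confound: not evaluated ({exc})")

    if bonferroni:
        k = sum(getattr(report, a) is not None for a in
                ("sperm_glad_test", "blood_glad_test", "predicted_difference_test"))
        report.notes.append(f"Bonferroni factor {k} applies to the three primary tests.")
        for attr in ("sperm_glad_test", "blood_glad_test", "predicted_difference_test"):
            r = getattr(report, attr)
            if r is not None and np.isfinite(r.p_value):
                r.p_value = min(1.0, r.p_value * k)

    return report
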