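"""Mean-matching age adjustment, GLAD scores, paired tissue differences.

GLAD (germ-line age differential) is a ratio statistic of mean-matched
predicted age relative to chronological age. The centered form
``(adjusted - chronological) / chronological`` is the default — it places a
perfectly calibrated cohort at 0, matching the scale on which group means
are reported — while the raw ratio ``adjusted / chronological`` (centered at
1) is available via ``form="ratio"``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "mean_match_adjust",
    "compute_glad",
    "build_glad_table",
    "predicted_age_difference",
]

GLAD_COLUMNS = [
    "sample_id", "individual_id", "tissue", "group",
    "age_years", "predicted_age", "adjusted_age", "glad",
]


def mean_match_adjust(predicted, chronological) -> np.ndarray:
    """Shift all predicted ages by ``d = mean(chronological) - mean(predicted)``
    so that mean(adjusted) equals mean(chronological) exactly."""
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if predicted.size == 0:
        raise ValueError("empty vectors")
    if predicted.shape != chronological.shape:
        raise ValueError("mismatched lengths")
    if predicted.size < 2:
        raise ValueError("mean matching needs n >= 2")
    d = chronological.mean() - predicted.mean()
    return predicted + d


def compute_glad(adjusted, chronological, form: str = "centered") -> np.ndarray:
    """Per-sample GLAD values.

    centered: ``(adjusted - chronological) / chronological`` (default).
    ratio: ``adjusted / chronological``.
    """
    adjusted = np.asarray(adjusted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if np.any(chronological <= 0):
        raise ValueError("chronological ages must be > 0")
    ratio = adjusted / chronological
    if form == "centered":
        return ratio - 1.0
    if form == "ratio":
        return ratio
    raise ValueError(f"unknown GLAD form {form!r}")


def build_glad_table(
    predictions: pd.DataFrame,
    sheet: pd.DataFrame,
    scope: str = "pooled",
    form: str = "centered",
) -> pd.DataFrame:
    """Mean-match within tissue and compute GLAD for every sample.

    scope:
      * ``pooled`` (default) — mean-matching within tissue across both groups,
        so group contrasts survive the adjustment.
      * ``per-group`` — mean-matching within each tissue x group cell.
    """
    if scope not in ("pooled", "per-group"):
        raise ValueError(f"unknown scope {scope!r}")
    merged = predictions.merge(
        sheet[["sample_id", "individual_id", "group", "age_years"]],
        on="sample_id", how="inner", validate="one_to_one",
    )
    if len(merged) != len(predictions):
        missing = set(predictions["sample_id"]) - set(merged["sample_id"])
        raise ValueError(f"predictions for samples absent from the sheet: {sorted(missing)}")

    keys = ["tissue"] if scope == "pooled" else ["tissue", "group"]
    parts = []
    for _, block in merged.groupby(keys, sort=False):
        block = block.copy()
        block["adjusted_age"] = mean_match_adjust(
            block["predicted_age_years"], block["age_years"]
        )
        block["glad"] = compute_glad(block["adjusted_age"], block["age_years"], form=form)
        parts.append(block)
    out = pd.concat(parts, ignore_index=True)
    out = out.rename(columns={"predicted_age_years": "predicted_age"})
    return out[GLAD_COLUMNS]


def predicted_age_difference(predictions: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-individual sperm-minus-blood difference of raw predicted ages.

    Individuals missing either tissue are excluded with a warning.
    """
    merged = predictions.merge(
        sheet[["sample_id", "individual_id"]], on="sample_id", how="inner"
    )
    wide = merged.pivot_table(
        index="individual_id", columns="tissue", values="predicted_age_years",
        aggfunc="first",
    )
    for col in ("sperm", "blood"):
        if col not in wide.columns:
            wide[col] = np.nan
    incomplete = wide.index[wide[["sperm", "blood"]].isna().any(axis=1)].tolist()
    if incomplete:
        warnings.warn(
            f"individuals missing a tissue, excluded from paired differences: {incomplete}",
            stacklevel=2,
        )
        wide = wide.drop(index=incomplete)
    out = pd.DataFrame({
        "individual_id": wide.index,
        "sperm_predicted_age": wide["sperm"].to_numpy(),
        "blood_predicted_age": wide["blood"].to_numpy(),
    })
    out["difference"] = out["sperm_predicted_age"] - out["blood_predicted_age"]
    return out.reset_index(drop=True)
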