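"""Linear methylation clocks: coefficient files, age transforms, prediction.

A clock is a linear model on beta values followed by an invertible age
transform. The ``log-adult`` transform is the piecewise map used by common
blood-age calculators: ages at or below ``adult_age`` are modelled on a log
scale, adult ages linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Transform",
    "ClockModel",
    "AgePredictionTable",
    "forward_transform",
    "inverse_transform",
    "parse_transform",
    "load_clock",
    "save_clock",
    "apply_clock",
]

INTERCEPT_LABEL = "(Intercept)"

#: beta values may stray outside [0,1] by at most this before we abort
BETA_DUST = 1e-6


@dataclass(frozen=True)
class Transform:
    """Age transform attached to a clock.

    kind: ``"identity"`` or ``"log-adult"``.
    adult_age: knot of the log-adult transform (ignored for identity).
    """

    kind: str = "identity"
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "log-adult"):
            raise ValueError(f"unknown transform kind: {self.kind!r}")
        if self.kind == "log-adult" and not self.adult_age > 0:
            raise ValueError("adult_age must be > 0")


IDENTITY = Transform("identity")


def parse_transform(spec: str) -> Transform:
    """Parse a transform spec string, e.g. ``identity`` or ``log-adult:20``."""
    if spec == "identity":
        return IDENTITY
    if spec == "log-adult":
        return Transform("log-adult")
    if spec.startswith("log-adult:"):
        return Transform("log-adult", float(spec.split(":", 1)[1]))
    raise ValueError(f"cannot parse transform spec {spec!r}")


def forward_transform(age, transform: Transform):
    """Map age in years to the clock's linear scale.

    log-adult: ``log((age+1)/(adult+1))`` for age <= adult, else
    ``(age - adult)/(adult + 1)``. Exact inverse of :func:`inverse_transform`.
    """
    age = np.asarray(age, dtype=float)
    if transform.kind == "identity":
        return age if age.ndim else float(age)
    a = transform.adult_age
    out = np.where(age <= a, np.log((age + 1.0) / (a + 1.0)), (age - a) / (a + 1.0))
    return out if out.ndim else float(out)


def inverse_transform(m, transform: Transform):
    """Map a transformed-age score back to years."""
    m = np.asarray(m, dtype=float)
    if transform.kind == "identity":
        return m if m.ndim else float(m)
    a = transform.adult_age
    out = np.where(m < 0, (a + 1.0) * np.exp(m) - 1.0, (a + 1.0) * m + a)
    return out if out.ndim else float(out)


@dataclass
class ClockModel:
    """Intercept + CpG coefficient map + age transform."""

    name: str
    intercept: float
    coefficients: pd.Series  # index: CpG id, values: weight per beta unit
    transform: Transform = field(default_factory=lambda: IDENTITY)
    allow_intercept_only: bool = False

    def __post_init__(self) -> None:
        coef = pd.Series(self.coefficients, dtype=float)
        if coef.index.has_duplicates:
            dups = sorted(coef.index[coef.index.duplicated()].unique())
            raise ValueError(f"duplicate CpG ids in clock: {dups}")
        if len(coef) == 0 and not self.allow_intercept_only:
            raise ValueError("clock has no CpGs (pass allow_intercept_only to permit)")
        object.__setattr__(self, "coefficients", coef)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.coefficients.index)

    def predict_age(self, betas: pd.Series) -> float:
        """Predict age for one sample whose index covers the clock's CpGs."""
        m = self.intercept + float(betas.reindex(self.coefficients.index) @ self.coefficients)
        return float(inverse_transform(m, self.transform))


#: prediction output: one row per sample
AgePredictionTable = pd.DataFrame
PREDICTION_COLUMNS = [
    "sample_id",
    "tissue",
    "predicted_age_years",
    "n_cpgs_used",
    "n_cpgs_imputed",
]


def load_clock(path, transform: Transform | str = IDENTITY, name: str | None = None,
               allow_intercept_only: bool = False) -> ClockModel:
    """Load a clock from CSV with columns ``cpg_id,coefficient``.

    Exactly one ``(Intercept)`` row is required; duplicate CpG rows are
    rejected.
    """
    if isinstance(transform, str):
        transform = parse_transform(transform)
    table = pd.read_csv(path, dtype={"cpg_id": str})
    missing_cols = {"cpg_id", "coefficient"} - set(table.columns)
    if missing_cols:
        raise ValueError(f"clock file {path} lacks columns: {sorted(missing_cols)}")
    coeffs = pd.to_numeric(table["coefficient"], errors="coerce")
    if coeffs.isna().any():
        bad = table.loc[coeffs.isna(), "cpg_id"].tolist()
        raise ValueError(f"non-numeric coefficient for: {bad}")
    is_intercept = table["cpg_id"] == INTERCEPT_LABEL
    n_int = int(is_intercept.sum())
    if n_int != 1:
        raise ValueError(f"clock file must contain exactly one {INTERCEPT_LABEL} row, found {n_int}")
    intercept = float(coeffs[is_intercept].iloc[0])
    body = pd.Series(coeffs[~is_intercept].values,
                     index=table.loc[~is_intercept, "cpg_id"].values, dtype=float)
    if len(body) == 0 and not allow_intercept_only:
        raise ValueError("clock file has no CpGs")
    return ClockModel(
        name=name or str(path),
        intercept=intercept,
        coefficients=body,
        transform=transform,
        allow_intercept_only=allow_intercept_only,
    )


def save_clock(clock: ClockModel, path) -> None:
    rows = [{"cpg_id": INTERCEPT_LABEL, "coefficient": clock.intercept}]
    rows += [{"cpg_id": cpg, "coefficient": w} for cpg, w in clock.coefficients.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def _validate_betas(betas: pd.DataFrame) -> pd.DataFrame:
    values = betas.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size and (finite.min() < -BETA_DUST or finite.max() > 1.0 + BETA_DUST):
        raise ValueError(
            f"beta values outside [0,1] beyond tolerance {BETA_DUST}: "
            f"range [{finite.min():.6g}, {finite.max():.6g}]"
        )
    return betas.clip(lower=0.0, upper=1.0)


def apply_clock(
    clock: ClockModel,
    betas: pd.DataFrame,
    missing_policy: str = "fail",
    reference: pd.Series | None = None,
    sheet: pd.DataFrame | None = None,
) -> AgePredictionTable:
    """Predict per-sample ages from a CpG x sample beta matrix.

    missing_policy:
      * ``fail`` (default) — any clock CpG absent from the matrix aborts.
      * ``mean_impute`` — NaN cells take the CpG's cross-sample mean; CpGs
        entirely absent take each sample's mean over the present clock CpGs.
      * ``reference_impute`` — absent CpGs / NaN cells are filled from
        ``reference`` (CpG id -> beta); a CpG absent there aborts.

    Returns a table ``sample_id, tissue, predicted_age_years, n_cpgs_used,
    n_cpgs_imputed``. Tissue comes from ``sheet`` when given, else empty.
    """
    if missing_policy not in ("fail", "mean_impute", "reference_impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    betas = _validate_betas(betas)
    cpgs = clock.coefficients.index
    sub = betas.reindex(cpgs)  # absent CpGs become all-NaN rows
    absent = sub.isna().all(axis=1)

    if missing_policy == "fail":
        if sub.isna().any().any():
            missing = sorted(sub.index[sub.isna().any(axis=1)])
            raise KeyError(f"clock CpGs missing from beta matrix: {missing}")
        imputed_counts = pd.Series(0, index=betas.columns)
    elif missing_policy == "mean_impute":
        imputed_mask = sub.isna()
        row_means = sub.mean(axis=1)
        sub = sub.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
        # fully-absent CpGs: fall back to each sample's mean over present CpGs
        if absent.any():
            col_means = sub.loc[~absent].mean(axis=0)
            if col_means.isna().any():
                raise ValueError("cannot mean-impute: no clock CpGs present at all")
            sub.loc[absent] = np.broadcast_to(col_means.to_numpy(),
                                              (int(absent.sum()), len(col_means)))
        imputed_counts = imputed_mask.sum(axis=0)
    else:  # reference_impute
        if reference is None:
            raise ValueError("reference_impute requires a reference series")
        imputed_mask = sub.isna()
        need = sub.index[imputed_mask.any(axis=1)]
        not_in_ref = sorted(set(need) - set(reference.index))
        if not_in_ref:
            raise KeyError(f"CpGs absent from reference: {not_in_ref}")
        fill = pd.DataFrame(
            np.broadcast_to(reference.reindex(sub.index).to_numpy()[:, None], sub.shape),
            index=sub.index, columns=sub.columns,
        )
        sub = sub.where(~imputed_mask, fill)
        imputed_counts = imputed_mask.sum(axis=0)

    m = clock.intercept + sub.T @ clock.coefficients
    predicted = inverse_transform(m.to_numpy(), clock.transform)
    predicted = np.atleast_1d(predicted)

    tissue = pd.Series("", index=betas.columns, dtype=object)
    if sheet is not None:
        lookup = sheet.set_index("sample_id")["tissue"]
        tissue = lookup.reindex(betas.columns).fillna("")

    return pd.DataFrame(
        {
            "sample_id": betas.columns,
            "tissue": tissue.to_numpy(),
            "predicted_age_years": predicted,
            "n_cpgs_used": len(cpgs),
            "n_cpgs_imputed": imputed_counts.reindex(betas.columns).to_numpy(),
        }
    ).reset_index(drop=True)
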