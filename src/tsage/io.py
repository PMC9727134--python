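"""Plain-text table readers/writers shared across stages.

All intermediates are TSV/CSV so that any stage can be rerun standalone from
persisted files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SHEET_COLUMNS = ["sample_id", "individual_id", "tissue", "group", "age_years"]


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a CpG x sample beta matrix; first column is the CpG id."""
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, index_col=0)
    table.index = table.index.astype(str)
    table.index.name = "cpg_id"
    return table.astype(float)


def write_beta_matrix(betas: pd.DataFrame, path) -> None:
    betas.rename_axis("cpg_id").to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    missing = set(SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dups}")
    return sheet


def read_dlk1_annotation(path) -> list[str]:
    """One CpG id per line, plain text."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    ids = [ln for ln in lines if ln and not ln.startswith("#")]
    if not ids:
        raise ValueError(f"no CpG ids found in DLK1 annotation {path}")
    return ids


def read_intensity_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep)
    missing = {"sample_id", "median_log2_intensity"} - set(table.columns)
    if missing:
        raise ValueError(f"intensity table lacks columns: {sorted(missing)}")
    return table


def read_predictions(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep)
    missing = {"sample_id", "predicted_age_years"} - set(table.columns)
    if missing:
        raise ValueError(f"prediction table lacks columns: {sorted(missing)}")
    return table
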