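"""Tab-separated I/O for expression matrices, sample sheets and results.

The canonical on-disk form is a TSV expression matrix (first column probe
ID, header row of sample IDs) plus a two-column sample sheet (sample ID,
group).  Parse errors name the offending row/column.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .dataset import DatasetError, ExpressionDataset
from .simulate import GroundTruth


def read_expression_matrix(path, sample_sheet_path) -> ExpressionDataset:
    """Load and validate an expression TSV plus its sample sheet.

    Duplicate probe IDs, non-numeric cells, samples missing from the sheet
    and sheet entries missing from the matrix are all rejected with explicit
    coordinates.
    """
    path, sheet_path = Path(path), Path(sample_sheet_path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = next(zip(*bad.to_numpy().nonzero()))
        raise DatasetError(
            f"{path.name}: non-numeric cell at probe {values.index[i]!r}, "
            f"sample {values.columns[j]!r}: {raw.iat[i, j]!r}"
        )
    if values.isna().to_numpy().any():
        i, j = next(zip(*values.isna().to_numpy().nonzero()))
        raise DatasetError(
            f"{path.name}: missing value at probe {values.index[i]!r}, "
            f"sample {values.columns[j]!r}"
        )
    sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
    expected = {"sample_id", "group"}
    if not expected.issubset(sheet.columns):
        raise DatasetError(
            f"{sheet_path.name}: expected columns {sorted(expected)}, "
            f"found {list(sheet.columns)}"
        )
    unknown = set(sheet["sample_id"]) - set(values.columns)
    if unknown:
        raise DatasetError(
            f"{sheet_path.name}: sample(s) not in the matrix: {sorted(unknown)[:5]}"
        )
    groups = sheet.set_index("sample_id")["group"]
    return ExpressionDataset(values, groups)


def write_dataset(ds: ExpressionDataset, matrix_path, sample_sheet_path) -> None:
    out = ds.values.copy()
    out.index.name = "probe_id"
    out.to_csv(matrix_path, sep="\t")
    sheet = pd.DataFrame(
        {"sample_id": ds.sample_groups.index, "group": ds.sample_groups.values}
    )
    sheet.to_csv(sample_sheet_path, sep="\t", index=False)


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
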