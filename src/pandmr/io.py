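"""TSV readers/writers with schema validation.

All tabular interchange is tab-separated text:

* manifest: columns ``probe_id, chrom, pos`` (pos 1-based);
* beta matrix: ``probe_id`` then one column per sample, values in [0, 1];
* sample sheet: ``sample_id, cohort, group`` with group in {normal, tumor};
* expression matrix: ``gene`` then one column per sample.

Validation errors name the first offending row/column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import GROUP_LABELS, ProbeManifest, ValidationError

__all__ = [
    "read_manifest", "write_manifest",
    "read_beta_matrix", "write_beta_matrix",
    "read_sample_sheet", "write_sample_sheet",
    "read_expression", "write_expression",
]


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    return pd.read_csv(path, sep="\t", **kwargs)


def read_manifest(path: str | Path) -> ProbeManifest:
    df = _read_tsv(path)
    missing = [c for c in ProbeManifest.COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing manifest columns {missing}")
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, sep="\t", index=False)


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.columns[0] != "probe_id":
        raise ValidationError(f"{path}: first column must be 'probe_id', got {df.columns[0]!r}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate probe_id {dup!r}")
    matrix = df.set_index("probe_id")
    values = matrix.to_numpy(dtype=float)
    bad = (values < 0) | (values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: beta value {values[i, j]} outside [0, 1] at row "
            f"{matrix.index[i]!r} (line {i + 2}), column {matrix.columns[j]!r}"
        )
    return matrix


def write_beta_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, dtype=str)
    expected = ["sample_id", "cohort", "group"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing sample-sheet columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate sample_id {dup!r}")
    unknown = set(df["group"]) - set(GROUP_LABELS)
    if unknown:
        raise ValidationError(
            f"{path}: unknown group label(s) {sorted(unknown)}; allowed: {list(GROUP_LABELS)}"
        )
    return df[expected]


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.columns[0] != "gene":
        raise ValidationError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene {dup!r}")
    return df.set_index("gene").astype(float)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def check_sheet_matches_matrix(
    sheet: pd.DataFrame, matrix: pd.DataFrame, path_hint: str = "matrix"
) -> None:
    """Every sample in the sheet must be a column of the matrix."""
    missing = [s for s in sheet["sample_id"] if s not in matrix.columns]
    if missing:
        raise ValidationError(
            f"sample(s) in sheet missing from {path_hint}: {missing[:5]}"
        )
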