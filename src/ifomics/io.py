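"""TSV and metadata I/O in the toolkit's dialect.

Matrices are tab-delimited UTF-8 with a header row of sample ids and the
first column holding feature ids (features in rows).  ``orientation``
lets callers load samples-in-rows variants; metadata is a TSV with a
``sample_id`` column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_metadata",
    "write_metadata",
]

_CATEGORICAL_META = ("group", "genotype", "timepoint")


def read_matrix_tsv(path, orientation: str = "features_in_rows",
                    allow_nan: bool = False) -> pd.DataFrame:
    """Read a numeric matrix TSV; returns features x samples.

    ``orientation="samples_in_rows"`` transposes on load so the returned
    frame is always features x samples.  Duplicate ids and (for count
    tables) missing values are rejected.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError("unknown orientation")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature id(s) in {path}: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in {path}: {dups}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if not allow_nan and df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in {path} (columns {bad}); "
                         "impute before loading or pass allow_nan=True")
    if orientation == "samples_in_rows":
        df = df.T
    return df


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "feature_id"):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)


def read_metadata(path, block_samples=None) -> pd.DataFrame:
    """Read sample metadata; optionally align to a block's sample order.

    Group/genotype/timepoint columns are typed categorical; remaining
    columns are kept numeric where possible.  When ``block_samples`` is
    given, metadata must cover all of them and is returned in that order.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path} lacks a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    df = df.set_index("sample_id")
    for col in df.columns:
        if col in _CATEGORICAL_META:
            df[col] = df[col].astype("category")
    if block_samples is not None:
        missing = [s for s in block_samples if s not in df.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        df = df.loc[list(block_samples)]
    return df


def write_metadata(df: pd.DataFrame, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label="sample_id")
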