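"""Reading and writing of feature, phenotype and matrix tables.

All files are delimited text (UTF-8, tab or comma; the delimiter is sniffed
from the header line, tab winning when both occur). Feature tables may be
stored with samples in rows or features in rows; on read the orientation is
normalized to samples-in-rows. Empty numeric cells are legal only in
metabolome layers, where they become NaN (peak absent).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .tables import (
    METABOLOME_LAYERS,
    FeatureTable,
    PhenotypeTable,
    TableValidationError,
)


def _sniff_sep(path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_numeric(path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    out = df.replace("", np.nan)
    try:
        return out.astype(float)
    except ValueError as exc:
        raise TableValidationError(f"non-numeric cell in {path}: {exc}") from exc


def read_feature_table(
    path,
    layer_kind: str,
    value_kind: str,
    orientation: str = "samples_in_rows",
    feature_meta_path=None,
) -> FeatureTable:
    """Read one omics layer from a delimited text file.

    ``orientation`` declares the on-disk layout; the returned table always
    has samples in rows. An optional sidecar file keyed by feature id may
    carry per-feature metadata (``similarity``, ``identified``, ``lineage``).
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_numeric(path, _sniff_sep(path))
    if orientation == "features_in_rows":
        df = df.T
    if df.isna().to_numpy().any() and layer_kind not in METABOLOME_LAYERS:
        raise TableValidationError(
            f"empty/NaN cells in {path} are only allowed for metabolome layers"
        )
    meta = None
    if feature_meta_path is not None:
        meta = pd.read_csv(feature_meta_path, sep=_sniff_sep(feature_meta_path), index_col=0)
        meta.index = meta.index.astype(str)
        if "identified" in meta.columns:
            meta["identified"] = meta["identified"].astype(bool)
    return FeatureTable(df, layer_kind, value_kind, meta)


def write_feature_table(t: FeatureTable, path, sep: str = "\t") -> None:
    t.data.to_csv(path, sep=sep, index_label="sample_id")
    if t.feature_meta is not None:
        root, ext = os.path.splitext(str(path))
        t.feature_meta.to_csv(root + ".meta" + ext, sep=sep, index_label="feature_id")


def read_phenotype_table(path) -> PhenotypeTable:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return PhenotypeTable(df)


def write_phenotype_table(p: PhenotypeTable, path, sep: str = "\t") -> None:
    p.data.to_csv(path, sep=sep, index_label="sample_id")


def read_square_matrix(path) -> pd.DataFrame:
    """Read an n-by-n matrix stored with sample ids as header and first column."""
    df = _read_numeric(path, _sniff_sep(path))
    if list(df.index) != list(df.columns):
        raise TableValidationError(f"{path} is not a square id-labelled matrix")
    return df


def write_square_matrix(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index_label="sample_id")
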