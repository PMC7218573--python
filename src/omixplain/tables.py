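"""Core in-memory containers for omics feature tables and phenotypes.

A cohort is a set of animals with up to four omics layers measured on the
same individuals — rumen microbial taxa (compositional relative abundances),
microbial KEGG-function abundances (counts per million), rumen metabolite
intensities, and serum metabolite intensities — plus a phenotype table
holding milk protein yield (MPY, kg/day) and covariates.

Both containers are thin, validating wrappers around a pandas DataFrame:
samples in rows, features (or phenotype columns) in columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYER_KINDS = ("taxa", "function", "rumen_metabolome", "serum_metabolome")
VALUE_KINDS = ("count", "relative", "cpm", "intensity", "zscore")

#: layers where a missing value means "peak not detected in this sample"
METABOLOME_LAYERS = ("rumen_metabolome", "serum_metabolome")

_REL_TOL = 1e-9
_CPM_TOL = 1e-3
_Z_TOL = 1e-9


class TableValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate {what}: {dups}")


@dataclass
class FeatureTable:
    """Sample-by-feature numeric table for one omics layer.

    Parameters
    ----------
    data:
        DataFrame with sample ids as index and feature ids as columns.
        Values are non-negative reals; NaN is permitted only for metabolome
        layers, where it encodes an absent peak.
    layer_kind:
        One of :data:`LAYER_KINDS`.
    value_kind:
        One of :data:`VALUE_KINDS`. ``relative`` rows sum to 1, ``cpm`` rows
        sum to 1e6, ``zscore`` columns have mean 0 / sample sd 1.
    feature_meta:
        Optional per-feature attributes indexed by feature id (e.g. spectral
        ``similarity`` score and ``identified`` flag for metabolites, or a
        taxonomic ``lineage`` for taxa).
    """

    data: pd.DataFrame
    layer_kind: str
    value_kind: str
    feature_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.layer_kind not in LAYER_KINDS:
            raise TableValidationError(f"unknown layer_kind {self.layer_kind!r}")
        if self.value_kind not in VALUE_KINDS:
            raise TableValidationError(f"unknown value_kind {self.value_kind!r}")
        if not isinstance(self.data, pd.DataFrame):
            raise TableValidationError("data must be a pandas DataFrame")
        _check_unique(self.data.index, "sample_ids")
        _check_unique(self.data.columns, "feature_ids")
        self.data = self.data.astype(float)
        self.validate_values()

    # -- public accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    # -- validation -------------------------------------------------------
    def validate_values(self) -> None:
        vals = self.data.to_numpy()
        nan_mask = np.isnan(vals)
        if nan_mask.any() and self.layer_kind not in METABOLOME_LAYERS:
            raise TableValidationError(
                f"NaN values are only allowed in metabolome layers, not {self.layer_kind!r}"
            )
        if self.value_kind != "zscore":
            if np.nanmin(vals, initial=0.0) < 0:
                raise TableValidationError(
                    f"negative values are not allowed for value_kind={self.value_kind!r}"
                )
        if self.value_kind == "relative" and self.n_features > 0:
            sums = np.nansum(vals, axis=1)
            if np.max(np.abs(sums - 1.0)) > _REL_TOL:
                raise TableValidationError("relative-abundance rows must sum to 1")
        if self.value_kind == "cpm" and self.n_features > 0:
            sums = np.nansum(vals, axis=1)
            if np.max(np.abs(sums - 1e6)) > _CPM_TOL:
                raise TableValidationError("cpm rows must sum to 1e6")
        if self.value_kind == "zscore" and self.n_features > 0:
            if nan_mask.any():
                raise TableValidationError("zscore tables must not contain NaN")
            means = vals.mean(axis=0)
            sds = vals.std(axis=0, ddof=1)
            if np.max(np.abs(means)) > 1e-8 or np.max(np.abs(sds - 1.0)) > 1e-8:
                raise TableValidationError(
                    "zscore columns must have mean 0 and unit sample sd"
                )
        if self.feature_meta is not None:
            missing = set(self.feature_ids) - set(self.feature_meta.index)
            if missing:
                raise TableValidationError(
                    f"feature_meta is missing {len(missing)} feature ids"
                )

    # -- convenience ------------------------------------------------------
    def subset_features(self, feature_ids) -> "FeatureTable":
        """Return a new table restricted to ``feature_ids`` (order preserved)."""
        meta = None
        if self.feature_meta is not None:
            meta = self.feature_meta.loc[list(feature_ids)]
        return FeatureTable(
            self.data[list(feature_ids)].copy(), self.layer_kind, self.value_kind, meta
        )

    def reorder_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(
            self.data.loc[list(sample_ids)].copy(),
            self.layer_kind,
            self.value_kind,
            self.feature_meta,
        )


@dataclass
class PhenotypeTable:
    """Per-animal phenotype and covariates.

    Columns: ``mpy`` (milk protein yield, kg/day; may be NaN before the
    phenotype has been simulated or measured), ``parity`` (lactation number,
    integer >= 1), ``dim`` (days in milk, > 0), and optionally ``milk_yield``
    (kg/day), ``protein_content`` (fraction) and ``group`` (HH / LL extreme
    MPY groups).
    """

    data: pd.DataFrame

    REQUIRED = ("mpy", "parity", "dim")

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample_ids")
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise TableValidationError(f"phenotype table lacks column {col!r}")
        mpy = self.data["mpy"].to_numpy(dtype=float)
        filled = ~np.isnan(mpy)
        if np.any(mpy[filled] <= 0):
            raise TableValidationError("mpy must be strictly positive")
        parity = self.data["parity"].to_numpy(dtype=float)
        if np.any(parity < 1) or np.any(parity != np.round(parity)):
            raise TableValidationError("parity must be an integer >= 1")
        dim = self.data["dim"].to_numpy(dtype=float)
        if np.any(dim <= 0):
            raise TableValidationError("days-in-milk must be > 0")
        if {"milk_yield", "protein_content"} <= set(self.data.columns):
            my = self.data["milk_yield"].to_numpy(dtype=float)
            pc = self.data["protein_content"].to_numpy(dtype=float)
            ok = ~(np.isnan(my) | np.isnan(pc) | np.isnan(mpy))
            if np.any(np.abs(mpy[ok] - my[ok] * pc[ok]) > 1e-6):
                raise TableValidationError(
                    "mpy must equal milk_yield * protein_content"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def mpy(self) -> pd.Series:
        return self.data["mpy"]

    @property
    def group(self) -> pd.Series | None:
        return self.data["group"] if "group" in self.data.columns else None

    def reorder_samples(self, sample_ids) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(sample_ids)].copy())


def align_samples(*tables):
    """Check that all tables share an identical ordered sample-id list.

    Raises a :class:`TableValidationError` naming the differing samples.
    """
    ref = tables[0].sample_ids
    for t in tables[1:]:
        if t.sample_ids != ref:
            extra = sorted(set(t.sample_ids) - set(ref))
            missing = sorted(set(ref) - set(t.sample_ids))
            raise TableValidationError(
                f"sample sets differ: missing={missing}, extra={extra}"
                if (extra or missing)
                else "sample order differs between tables"
            )
    return ref
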