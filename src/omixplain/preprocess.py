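"""Normalization and feature-retention rules.

The retention rules mirror common practice for rumen metagenome and
GC-TOF-MS metabolome studies:

* taxa are kept when their relative abundance exceeds a cutoff (default
  0.1%) in at least half the animals of *every* phenotype group;
* functional features (KEGG etc.) are kept when cpm exceeds a cutoff
  (default 5) in at least half the animals of every group;
* metabolite peaks are kept when present (non-missing) in at least half the
  samples, with relative standard deviation at most 30%, spectral-library
  similarity at least 200, and a positive identification flag.

``zscore_standardize`` performs the column standardization (zero mean, unit
sample sd) applied before relationship-matrix construction and PLS-DA.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import FeatureTable, TableValidationError


def to_relative_abundance(t: FeatureTable) -> FeatureTable:
    """Close each sample's counts to relative abundances (rows sum to 1)."""
    vals = t.values
    sums = vals.sum(axis=1)
    if np.any(sums <= 0):
        bad = [t.sample_ids[i] for i in np.nonzero(sums <= 0)[0]]
        raise TableValidationError(f"zero total abundance for samples {bad}")
    rel = pd.DataFrame(vals / sums[:, None], index=t.data.index, columns=t.data.columns)
    return FeatureTable(rel, t.layer_kind, "relative", t.feature_meta)


def to_cpm(t: FeatureTable) -> FeatureTable:
    """Rescale each sample's counts to counts per million (rows sum to 1e6)."""
    vals = t.values
    sums = vals.sum(axis=1)
    if np.any(sums <= 0):
        bad = [t.sample_ids[i] for i in np.nonzero(sums <= 0)[0]]
        raise TableValidationError(f"zero total abundance for samples {bad}")
    cpm = pd.DataFrame(
        vals * 1e6 / sums[:, None], index=t.data.index, columns=t.data.columns
    )
    return FeatureTable(cpm, t.layer_kind, "cpm", t.feature_meta)


def filter_prevalent_features(
    t: FeatureTable,
    groups: Mapping[str, str] | pd.Series,
    threshold: float,
    min_fraction: float = 0.5,
) -> FeatureTable:
    """Keep features exceeding ``threshold`` in >= ``min_fraction`` of every group.

    The abundance comparison is strict (``value > threshold``); the
    prevalence comparison is inclusive (``fraction >= min_fraction``). A
    feature must satisfy the rule within each group separately.

    Relative and cpm tables are re-closed after subsetting so the row-sum
    invariant still holds. Re-closure only increases values, so applying
    the filter twice retains exactly the features of a single application.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    missing = [s for s in t.sample_ids if s not in groups.index]
    if missing:
        raise ValueError(f"samples without group assignment: {missing}")
    groups = groups.loc[t.sample_ids]
    keep = np.ones(t.n_features, dtype=bool)
    for g, members in groups.groupby(groups).groups.items():
        sub = t.data.loc[list(members)]
        if sub.shape[0] == 0:
            raise ValueError(f"empty group {g!r}")
        frac = (sub.to_numpy() > threshold).mean(axis=0)
        keep &= frac >= min_fraction
    kept = [f for f, k in zip(t.feature_ids, keep) if k]
    sub = t.data[kept].copy()
    if t.value_kind == "relative":
        sub = sub.div(sub.sum(axis=1), axis=0)
    elif t.value_kind == "cpm":
        sub = sub.mul(1e6).div(sub.sum(axis=1), axis=0)
    meta = t.feature_meta.loc[kept] if t.feature_meta is not None else None
    return FeatureTable(sub, t.layer_kind, t.value_kind, meta)


def filter_metabolite_peaks(
    t: FeatureTable,
    qc_samples=None,
    min_presence: float = 0.5,
    max_rsd: float = 30.0,
    min_similarity: float = 200.0,
) -> FeatureTable:
    """Apply the metabolite peak-quality filter.

    A peak is removed when any of the following fails: non-missing in at
    least ``min_presence`` of samples; relative standard deviation
    (sample sd / mean * 100, over ``qc_samples`` when given, else over all
    non-missing samples) at most ``max_rsd``; spectral similarity at least
    ``min_similarity``; identified flag true. A peak whose mean intensity is
    zero has an undefined RSD and is treated as failing the RSD rule.
    """
    meta = t.feature_meta
    if meta is None or not {"similarity", "identified"} <= set(meta.columns):
        raise TableValidationError(
            "metabolite filtering requires feature_meta with 'similarity' and 'identified'"
        )
    vals = t.data
    presence = vals.notna().mean(axis=0).to_numpy()
    rsd_frame = vals.loc[list(qc_samples)] if qc_samples is not None else vals
    mean = rsd_frame.mean(axis=0, skipna=True).to_numpy()
    sd = rsd_frame.std(axis=0, ddof=1, skipna=True).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean > 0, sd / mean * 100.0, np.inf)
    if np.any(mean <= 0):
        warnings.warn(
            "metabolite(s) with non-positive mean intensity fail the RSD filter",
            stacklevel=2,
        )
    sim = meta.loc[t.feature_ids, "similarity"].to_numpy(dtype=float)
    ident = meta.loc[t.feature_ids, "identified"].to_numpy(dtype=bool)
    keep = (
        (presence >= min_presence)
        & (rsd <= max_rsd)
        & (sim >= min_similarity)
        & ident
    )
    return t.subset_features([f for f, k in zip(t.feature_ids, keep) if k])


def aggregate_features(t: FeatureTable, mapping: Mapping[str, str]) -> FeatureTable:
    """Sum features into higher-level groups (e.g. KEGG KOs into modules).

    ``mapping`` sends feature ids to group ids; unmapped features are
    dropped. The result keeps the input's layer and value kinds except
    that closed kinds (relative/cpm) stay closed only if the mapping is a
    partition of all features — otherwise the output is plain counts.
    """
    cols = {}
    for fid in t.feature_ids:
        g = mapping.get(fid)
        if g is not None:
            cols.setdefault(g, []).append(fid)
    if not cols:
        raise ValueError("mapping covers no feature of the table")
    agg = pd.DataFrame(
        {g: t.data[fids].sum(axis=1, skipna=True) for g, fids in cols.items()},
        index=t.data.index,
    )
    complete = sum(len(v) for v in cols.values()) == t.n_features
    kind = t.value_kind if (t.value_kind not in ("relative", "cpm") or complete) else "count"
    return FeatureTable(agg, t.layer_kind, kind)


def zscore_standardize(t: FeatureTable) -> FeatureTable:
    """Column-standardize to zero mean and unit sample sd (n-1 denominator).

    Missing metabolite intensities are imputed to the column mean (hence 0
    after standardization). Zero-variance columns carry no between-animal
    information and are dropped with a warning.
    """
    if t.n_samples < 2:
        raise ValueError("standardization needs at least 2 samples")
    filled = t.data.fillna(t.data.mean(axis=0, skipna=True))
    sd = filled.std(axis=0, ddof=1)
    degenerate = [
        f for f in t.feature_ids if not np.isfinite(sd[f]) or sd[f] <= 0.0
    ]
    if degenerate:
        warnings.warn(
            f"dropping {len(degenerate)} zero-variance feature(s) before z-scoring",
            stacklevel=2,
        )
        filled = filled.drop(columns=degenerate)
        sd = sd.drop(index=degenerate)
    z = (filled - filled.mean(axis=0)) / sd
    return FeatureTable(z, t.layer_kind, "zscore", None)
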