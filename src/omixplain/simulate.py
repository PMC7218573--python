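"""Synthetic multi-omics cohort generator with known planted structure.

The generator emulates the statistical shape of a rumen multi-omics study
of mid-lactation dairy cows: a compositional taxa table dominated by one
genus block (Prevotella-like, ~42% mean share), a counts-per-million
functional table, log-normal rumen (263) and serum (177) metabolite
intensity tables with missing peaks, parity and days-in-milk covariates,
and an MPY phenotype built *from* the omics layers with user-specified
true variance fractions:

    mpy = mu + parity effect + dim * slope + sum_layer u_layer + e,
    u_layer = Z_layer w,  w ~ N(0, sigma2_layer / q_layer) per feature,

so each u_layer has exactly the relationship-matrix covariance
sigma2_layer * Z Z'/q assumed by the variance-component model. Extreme
HH / LL group labels are assigned by ranking the realized MPY, mirroring
extreme-group selection in the emulated design. The returned
:class:`SyntheticTruth` records every planted quantity for parameter-
recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import to_relative_abundance, to_cpm, zscore_standardize
from .tables import FeatureTable, PhenotypeTable

#: default feature counts per layer kind
DEFAULT_N_FEATURES = {
    "taxa": 200,
    "function": 500,
    "rumen_metabolome": 263,
    "serum_metabolome": 177,
}

#: default planted variance fractions for the four-layer demonstration
#: cohort — ordered rumen metabolome > serum metabolome > function > taxa,
#: the qualitative ordering the analysis is expected to recover
DEFAULT_FRACTIONS = {
    "taxa": 0.08,
    "function": 0.16,
    "serum_metabolome": 0.24,
    "rumen_metabolome": 0.32,
}

DEFAULT_PARITY_EFFECTS = {1: 0.0, 2: 0.15, 3: 0.25, 4: 0.30}
DEFAULT_DIM_SLOPE = -0.003  # kg/day per day in milk


def derive_seed(seed: int, offset: int) -> int:
    """Per-stage seed from one global seed by a fixed affine offset."""
    return int((seed * 1000003 + 17 * offset + 1) % (2**31 - 1))


@dataclass
class CompositionSpec:
    """Dominance structure of the taxa layer."""

    n_dominant: int = 15
    dominance: float = 0.42  # target mean share of the dominant block
    sigma_log: float = 1.0


@dataclass
class MetabolomeSpec:
    missing_rate: float = 0.08
    junk_fraction: float = 0.05  # low-similarity / unidentified peaks
    #: biological log-sd; CV ~ 25%, so most peaks clear a 30% RSD cutoff
    sigma_log: float = 0.25


@dataclass
class SyntheticTruth:
    seed: int
    n_animals: int
    true_fractions: dict
    fixed_effects: dict
    planted_differential_features: dict = field(default_factory=dict)
    planted_metabotypes: dict = field(default_factory=dict)
    residual_variance: float = 0.0
    total_variance: float = 1.0
    mean_mpy: float = 5.0
    mpy_shift: float = 0.0

    def __post_init__(self) -> None:
        total_frac = sum(self.true_fractions.values())
        if not all(0 <= f < 1 for f in self.true_fractions.values()) or total_frac >= 1:
            raise ValueError("true_fractions must each be in [0,1) and sum below 1")
        self.residual_variance = (1.0 - total_frac) * self.total_variance


def generate_cohort(
    seed: int,
    n_animals: int = 16,
    n_hh: int = 7,
    parity_range: tuple[int, int] = (1, 4),
    dim_range: tuple[int, int] = (60, 180),
) -> PhenotypeTable:
    """Covariate skeleton of a cohort (MPY filled later, groups after that)."""
    if n_hh > n_animals:
        raise ValueError("n_hh cannot exceed n_animals")
    if parity_range[1] < parity_range[0] or dim_range[1] < dim_range[0]:
        raise ValueError("empty covariate range")
    rng = np.random.default_rng(seed)
    ids = [f"cow_{i + 1:03d}" for i in range(n_animals)]
    df = pd.DataFrame(
        {
            "mpy": np.nan,
            "parity": rng.integers(parity_range[0], parity_range[1] + 1, n_animals),
            "dim": rng.integers(dim_range[0], dim_range[1] + 1, n_animals),
        },
        index=ids,
    )
    df.attrs["n_hh"] = n_hh
    return PhenotypeTable(df)


def generate_omics_layer(
    seed: int,
    cohort: PhenotypeTable,
    layer_kind: str,
    n_features: int | None = None,
    effect_spec: dict | None = None,
    composition_spec=None,
) -> FeatureTable:
    """One omics layer for the cohort.

    * taxa: log-normal abundances closed to relative form, with a dominant
      feature block whose mean share is set by ``composition_spec``;
    * function: log-normal counts rescaled to cpm;
    * metabolomes: log-normal intensities with random missing peaks and a
      similarity/identification sidecar.

    ``effect_spec`` maps feature ids to natural-log fold effects applied to
    HH animals; it requires the cohort to carry group labels already.
    """
    n_features = n_features or DEFAULT_N_FEATURES[layer_kind]
    rng = np.random.default_rng(seed)
    n = len(cohort.sample_ids)
    if layer_kind == "taxa":
        spec = composition_spec or CompositionSpec()
        n_dom = min(spec.n_dominant, max(0, n_features - 1))
        ids = [f"Prevotella_sp_{i + 1:03d}" for i in range(n_dom)] + [
            f"species_{i + 1:04d}" for i in range(n_features - n_dom)
        ]
        mu = np.zeros(n_features)
        if n_dom:
            ratio = spec.dominance / (1.0 - spec.dominance)
            # mean of the dominant block set so its expected share hits the target
            mu[:n_dom] = np.log(ratio * (n_features - n_dom) / n_dom)
        raw = np.exp(mu + spec.sigma_log * rng.standard_normal((n, n_features)))
        tbl = FeatureTable(
            pd.DataFrame(raw, index=cohort.sample_ids, columns=ids),
            "taxa",
            "count",
        )
        tbl = _apply_effects(tbl, cohort, effect_spec)
        return to_relative_abundance(tbl)
    if layer_kind == "function":
        ids = [f"K{i + 1:05d}" for i in range(n_features)]
        raw = np.exp(0.8 * rng.standard_normal((n, n_features)))
        tbl = FeatureTable(
            pd.DataFrame(raw, index=cohort.sample_ids, columns=ids),
            "function",
            "count",
        )
        tbl = _apply_effects(tbl, cohort, effect_spec)
        return to_cpm(tbl)
    if layer_kind in ("rumen_metabolome", "serum_metabolome"):
        spec = composition_spec or MetabolomeSpec()
        prefix = "rmet" if layer_kind == "rumen_metabolome" else "smet"
        ids = [f"{prefix}_{i + 1:03d}" for i in range(n_features)]
        raw = np.exp(
            rng.normal(4.0, 1.0, n_features)
            + spec.sigma_log * rng.standard_normal((n, n_features))
        )
        mask = rng.random((n, n_features)) < spec.missing_rate
        # never blank out a whole column
        full_col = mask.all(axis=0)
        mask[:, full_col] = False
        raw = np.where(mask, np.nan, raw)
        n_junk = int(round(spec.junk_fraction * n_features))
        junk = rng.choice(n_features, size=n_junk, replace=False)
        similarity = rng.uniform(300, 950, n_features)
        identified = np.ones(n_features, dtype=bool)
        if n_junk:
            half = n_junk // 2
            similarity[junk[:half]] = rng.uniform(50, 199, half)
            identified[junk[half:]] = False
        meta = pd.DataFrame(
            {"similarity": similarity, "identified": identified}, index=ids
        )
        tbl = FeatureTable(
            pd.DataFrame(raw, index=cohort.sample_ids, columns=ids),
            layer_kind,
            "intensity",
            meta,
        )
        return _apply_effects(tbl, cohort, effect_spec)
    raise ValueError(f"unknown layer_kind {layer_kind!r}")


def _apply_effects(
    t: FeatureTable, cohort: PhenotypeTable, effect_spec: dict | None
) -> FeatureTable:
    if not effect_spec:
        return t
    group = cohort.group
    if group is None or group.isna().any():
        raise ValueError("effect_spec requires group labels on the cohort")
    missing = set(effect_spec) - set(t.feature_ids)
    if missing:
        raise ValueError(f"effect on nonexistent feature(s): {sorted(missing)}")
    data = t.data.copy()
    hh = group[group == "HH"].index
    for fid, logfold in effect_spec.items():
        data.loc[hh, fid] = data.loc[hh, fid] * np.exp(logfold)
    return FeatureTable(data, t.layer_kind, t.value_kind, t.feature_meta)


def apply_group_effects(
    t: FeatureTable, cohort: PhenotypeTable, effect_spec: dict
) -> FeatureTable:
    """Plant HH-vs-LL log-fold effects into an existing layer.

    Relative-abundance tables are re-closed after the shift so rows still
    sum to one.
    """
    if t.value_kind == "relative":
        raw = FeatureTable(t.data.copy(), t.layer_kind, "count", t.feature_meta)
        return to_relative_abundance(_apply_effects(raw, cohort, effect_spec))
    if t.value_kind == "cpm":
        raw = FeatureTable(t.data.copy(), t.layer_kind, "count", t.feature_meta)
        return to_cpm(_apply_effects(raw, cohort, effect_spec))
    return _apply_effects(t, cohort, effect_spec)


def generate_phenotype_from_layers(
    seed: int,
    cohort: PhenotypeTable,
    layers: dict[str, FeatureTable],
    truth: SyntheticTruth,
) -> PhenotypeTable:
    """Fill MPY from z-scored layers according to the planted fractions.

    Also derives a consistent milk yield / protein content split and
    assigns HH/LL labels by ranking the realized MPY (top ``n_hh`` animals
    are HH).
    """
    rng = np.random.default_rng(seed)
    ids = cohort.sample_ids
    for kind, z in layers.items():
        if z.sample_ids != ids:
            raise ValueError(f"layer {kind} does not share the cohort sample order")
        if z.value_kind != "zscore":
            raise ValueError(f"layer {kind} must be z-scored")
    n = len(ids)
    parity_eff = truth.fixed_effects.get("parity_effects", DEFAULT_PARITY_EFFECTS)
    slope = truth.fixed_effects.get("dim_slope", DEFAULT_DIM_SLOPE)
    parity = cohort.data["parity"].astype(int)
    fixed = (
        truth.mean_mpy
        + parity.map(lambda p: parity_eff.get(p, max(parity_eff.values()))).to_numpy()
        + slope * cohort.data["dim"].to_numpy(dtype=float)
    )
    u_total = np.zeros(n)
    for kind, z in layers.items():
        frac = truth.true_fractions.get(kind, 0.0)
        if frac == 0.0:
            continue
        q = z.n_features
        w = rng.normal(0.0, np.sqrt(frac * truth.total_variance / q), q)
        u_total += z.values @ w
    e = rng.normal(0.0, np.sqrt(truth.residual_variance), n)
    mpy = fixed + u_total + e
    shift = 0.0
    if mpy.min() <= 0:
        shift = 0.05 * abs(truth.mean_mpy) - mpy.min()
        mpy = mpy + shift
    truth.mpy_shift = float(shift)

    df = cohort.data.copy()
    df["mpy"] = mpy
    protein_content = np.clip(rng.normal(0.032, 0.002, n), 0.025, 0.040)
    df["protein_content"] = protein_content
    df["milk_yield"] = mpy / protein_content
    n_hh = cohort.data.attrs.get("n_hh", max(1, n // 2))
    order = np.argsort(-mpy, kind="stable")
    labels = np.array(["LL"] * n, dtype=object)
    labels[order[:n_hh]] = "HH"
    df["group"] = labels
    out = PhenotypeTable(df)
    out.data.attrs["n_hh"] = n_hh
    return out


@dataclass
class SyntheticCohort:
    phenotype: PhenotypeTable
    layers: dict  # layer_kind -> FeatureTable on its natural scale
    truth: SyntheticTruth


def simulate_cohort(
    seed: int,
    n_animals: int = 16,
    n_hh: int = 7,
    true_fractions: dict | None = None,
    n_features: dict | None = None,
    effect_specs: dict | None = None,
    metabotype_spec: dict | None = None,
    total_variance: float = 1.0,
    mean_mpy: float = 5.0,
    parity_range: tuple[int, int] = (1, 4),
    dim_range: tuple[int, int] = (60, 180),
) -> SyntheticCohort:
    """End-to-end cohort: covariates, four layers, phenotype, planted effects.

    ``effect_specs`` maps layer kind to {feature_id: log-fold in HH};
    ``metabotype_spec`` maps metabolome layer kind to
    {metabolite_id: +1 or -1}, planting metabolites monotonically coupled
    to MPY with the requested sign (target |rho| about 0.8).
    """
    fractions = dict(DEFAULT_FRACTIONS if true_fractions is None else true_fractions)
    sizes = dict(DEFAULT_N_FEATURES)
    if n_features:
        sizes.update(n_features)
    cohort = generate_cohort(
        derive_seed(seed, 0), n_animals, n_hh, parity_range, dim_range
    )
    layers = {}
    for i, kind in enumerate(DEFAULT_N_FEATURES):
        layers[kind] = generate_omics_layer(
            derive_seed(seed, 10 + i), cohort, kind, sizes[kind]
        )
    zlayers = {k: zscore_standardize(t) for k, t in layers.items()}
    truth = SyntheticTruth(
        seed=seed,
        n_animals=n_animals,
        true_fractions=fractions,
        fixed_effects={
            "parity_effects": dict(DEFAULT_PARITY_EFFECTS),
            "dim_slope": DEFAULT_DIM_SLOPE,
        },
        total_variance=total_variance,
        mean_mpy=mean_mpy,
    )
    phenotype = generate_phenotype_from_layers(
        derive_seed(seed, 50), cohort, zlayers, truth
    )
    if effect_specs:
        for kind, spec in effect_specs.items():
            layers[kind] = apply_group_effects(layers[kind], phenotype, spec)
            truth.planted_differential_features[kind] = dict(spec)
    if metabotype_spec:
        rng = np.random.default_rng(derive_seed(seed, 90))
        for kind, spec in metabotype_spec.items():
            layers[kind] = plant_metabotypes(
                rng, layers[kind], phenotype.mpy.to_numpy(), spec
            )
            truth.planted_metabotypes.update(spec)
    return SyntheticCohort(phenotype, layers, truth)


def plant_metabotypes(
    rng: np.random.Generator,
    layer: FeatureTable,
    driver: np.ndarray,
    spec: dict,
    coupling: float = 0.85,
) -> FeatureTable:
    """Overwrite metabolite columns with values monotonically tied to a driver.

    The planted intensity is exp(mu + coupling*sign*z(driver) +
    sqrt(1-coupling^2)*noise): a monotone transform of a Gaussian blend, so
    the Spearman correlation with the driver approaches ``coupling`` with
    the requested sign. Planted columns carry no missing values.
    """
    missing = set(spec) - set(layer.feature_ids)
    if missing:
        raise ValueError(f"unknown metabolite id(s): {sorted(missing)}")
    z = (driver - driver.mean()) / driver.std(ddof=1)
    data = layer.data.copy()
    for fid, sign in spec.items():
        noise = rng.standard_normal(len(z))
        latent = coupling * np.sign(sign) * z + np.sqrt(1 - coupling**2) * noise
        data[fid] = np.exp(4.0 + 0.25 * latent)
    return FeatureTable(data, layer.layer_kind, layer.value_kind, layer.feature_meta)


def generate_microbiome_linked_cohort(
    seed: int,
    n_animals: int = 60,
    n_taxa: int = 150,
    n_linked_taxa: int = 20,
    n_metabolites: int = 100,
    n_linked: int = 20,
    taxa_coupling: float = 0.8,
    metabolite_coupling: float = 0.9,
    phenotype_coupling: float = 0.8,
):
    """Cohort where one latent factor drives taxa, metabolites and MPY.

    Used to exercise the composed metabotype screen: the latent factor
    shifts ``n_linked_taxa`` taxa (so Bray-Curtis distances track it),
    drives ``n_linked`` planted metabotypes, and loads on MPY. Returns
    (taxa relative-abundance table, rumen metabolome table, phenotype,
    list of planted metabolite ids).
    """
    rng = np.random.default_rng(seed)
    ids = [f"cow_{i + 1:03d}" for i in range(n_animals)]
    factor = rng.standard_normal(n_animals)

    raw = np.exp(rng.standard_normal((n_animals, n_taxa)))
    raw[:, :n_linked_taxa] *= np.exp(taxa_coupling * factor[:, None])
    taxa_ids = [f"species_{i + 1:04d}" for i in range(n_taxa)]
    taxa = to_relative_abundance(
        FeatureTable(pd.DataFrame(raw, index=ids, columns=taxa_ids), "taxa", "count")
    )

    met_ids = [f"rmet_{i + 1:03d}" for i in range(n_metabolites)]
    intens = np.exp(
        rng.normal(4.0, 1.0, n_metabolites)
        + 0.8 * rng.standard_normal((n_animals, n_metabolites))
    )
    linked_ids = met_ids[:n_linked]
    for j in range(n_linked):
        noise = rng.standard_normal(n_animals)
        latent = (
            metabolite_coupling * factor
            + np.sqrt(1 - metabolite_coupling**2) * noise
        )
        intens[:, j] = np.exp(4.0 + 0.8 * latent)
    metabolome = FeatureTable(
        pd.DataFrame(intens, index=ids, columns=met_ids),
        "rumen_metabolome",
        "intensity",
        pd.DataFrame(
            {"similarity": 800.0, "identified": True}, index=met_ids
        ),
    )

    mpy = (
        5.0
        + phenotype_coupling * factor
        + np.sqrt(1 - phenotype_coupling**2) * rng.standard_normal(n_animals)
    )
    mpy = mpy - min(0.0, mpy.min() - 0.25)
    phen = PhenotypeTable(
        pd.DataFrame(
            {
                "mpy": mpy,
                "parity": rng.integers(1, 5, n_animals),
                "dim": rng.integers(60, 181, n_animals),
            },
            index=ids,
        )
    )
    return taxa, metabolome, phen, linked_ids


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write all cohort tables plus the truth record as plain text."""
    from .io import write_feature_table, write_phenotype_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_phenotype_table(cohort.phenotype, out / "phenotype.tsv")
    for kind, t in cohort.layers.items():
        write_feature_table(t, out / f"{kind}.tsv")
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(cohort.truth), fh, indent=2, default=str)
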