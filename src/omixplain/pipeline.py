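"""Config-driven orchestration of the full analysis.

Stage order follows the study workflow: feature retention -> normalization
-> relationship matrices and ordination -> per-layer omics-explainability
-> metabotype screening and microbiome responsiveness -> differential
features -> correlation networks. Every run writes a JSON manifest listing
the seed, every threshold actually applied, and a hash of the full
configuration, so any non-default run is distinguishable from a default
one by its manifest alone. One global seed expands into per-stage seeds by
fixed offsets, so adding a stage never perturbs the randomness of earlier
stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import (
    assess_microbiome_responsiveness,
    build_correlation_network,
    metabotype_frame,
    screen_metabotypes,
)
from .differential import (
    differential_metabolites,
    lefse_style_score,
    wilcoxon_differential,
)
from .io import (
    read_feature_table,
    read_phenotype_table,
    write_feature_table,
    write_square_matrix,
)
from .preprocess import filter_metabolite_peaks, filter_prevalent_features, zscore_standardize
from .similarity import bray_curtis, build_relationship_matrix, pcoa
from .simulate import derive_seed
from .tables import METABOLOME_LAYERS, TableValidationError
from .varcomp import explainability_report, reml_fit


@dataclass
class RunConfig:
    """All inputs and thresholds of one analysis run."""

    phenotype_path: str
    taxa_path: str | None = None
    function_path: str | None = None
    rumen_metabolome_path: str | None = None
    serum_metabolome_path: str | None = None
    out_dir: str = "omixplain_run"
    seed: int = 0

    # feature retention
    taxa_abundance_threshold: float = 0.001
    function_cpm_threshold: float = 5.0
    prevalence_min_fraction: float = 0.5
    prevalence_in_every_group: bool = True
    metabolite_min_presence: float = 0.5
    metabolite_max_rsd: float = 30.0
    metabolite_min_similarity: float = 200.0

    # testing thresholds
    alpha: float = 0.05
    fdr: float = 0.05
    r_threshold: float = 0.5
    lda_threshold: float = 2.0
    vip_threshold: float = 1.0
    n_perm: int = 999

    # model options
    dim_as_class: bool = False
    explainability_denominator: str = "model"
    metabolite_use_fdr: bool = True
    pls_components: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _logger(out: Path) -> logging.Logger:
    log = logging.getLogger(f"omixplain.run.{out}")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.FileHandler(out / "run.log", mode="w"), logging.StreamHandler(sys.stderr)):
        h.setFormatter(fmt)
        log.addHandler(h)
    return log


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Re-running with an identical config and inputs reproduces identical
    numeric outputs (the log carries the only timestamps).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "filtered").mkdir(exist_ok=True)
    (out / "matrices").mkdir(exist_ok=True)
    log = _logger(out)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    t0 = time.perf_counter()

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        info = stage("load")
        phen = read_phenotype_table(config.phenotype_path)
        layers = {}
        kinds = {
            "taxa": (config.taxa_path, "relative"),
            "function": (config.function_path, "cpm"),
            "rumen_metabolome": (config.rumen_metabolome_path, "intensity"),
            "serum_metabolome": (config.serum_metabolome_path, "intensity"),
        }
        for kind, (path, value_kind) in kinds.items():
            if path is None:
                continue
            meta_path = Path(path).with_suffix(".meta.tsv")
            layers[kind] = read_feature_table(
                path,
                kind,
                value_kind,
                feature_meta_path=meta_path if meta_path.exists() else None,
            )
        for kind, t in layers.items():
            if set(t.sample_ids) != set(phen.sample_ids):
                missing = sorted(set(phen.sample_ids) - set(t.sample_ids))
                extra = sorted(set(t.sample_ids) - set(phen.sample_ids))
                raise TableValidationError(
                    f"{kind} samples differ from phenotype: missing={missing}, extra={extra}"
                )
            layers[kind] = t.reorder_samples(phen.sample_ids)
        info["n_samples"] = len(phen.sample_ids)
        info["layers"] = {k: t.n_features for k, t in layers.items()}
        groups = phen.group
        if groups is None:
            raise TableValidationError("phenotype table must carry HH/LL group labels")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("load", exc) from exc

    try:
        info = stage("filter")
        pseudo = groups if config.prevalence_in_every_group else pd.Series(
            "all", index=phen.sample_ids
        )
        if "taxa" in layers:
            layers["taxa"] = filter_prevalent_features(
                layers["taxa"], pseudo, config.taxa_abundance_threshold,
                config.prevalence_min_fraction,
            )
        if "function" in layers:
            layers["function"] = filter_prevalent_features(
                layers["function"], pseudo, config.function_cpm_threshold,
                config.prevalence_min_fraction,
            )
        for kind in METABOLOME_LAYERS:
            if kind in layers:
                layers[kind] = filter_metabolite_peaks(
                    layers[kind],
                    min_presence=config.metabolite_min_presence,
                    max_rsd=config.metabolite_max_rsd,
                    min_similarity=config.metabolite_min_similarity,
                )
        for kind, t in layers.items():
            write_feature_table(t, out / "filtered" / f"{kind}.tsv")
        info["retained"] = {k: t.n_features for k, t in layers.items()}
    except Exception as exc:
        raise StageError("filter", exc) from exc

    try:
        info = stage("matrices")
        zlayers = {k: zscore_standardize(t) for k, t in layers.items()}
        rels = {k: build_relationship_matrix(z) for k, z in zlayers.items()}
        for kind, rel in rels.items():
            write_square_matrix(rel.data, out / "matrices" / f"relationship_{kind}.tsv")
        taxa_dist = None
        if "taxa" in layers:
            taxa_dist = bray_curtis(layers["taxa"])
            write_square_matrix(
                taxa_dist.data, out / "matrices" / "distance_taxa_braycurtis.tsv"
            )
            ord_ = pcoa(taxa_dist, k=2)
            coords = ord_.coordinates.copy()
            coords["group"] = groups
            coords.to_csv(out / "pcoa_taxa.tsv", sep="\t", index_label="sample_id")
            info["pcoa_prop_explained"] = [float(v) for v in ord_.proportion_explained]
        info["n_features_used"] = {k: r.n_features_used for k, r in rels.items()}
    except Exception as exc:
        raise StageError("matrices", exc) from exc

    try:
        info = stage("explainability")
        fits = {
            kind: reml_fit(
                phen.mpy,
                phen.data[["parity", "dim"]],
                rel,
                dim_as_class=config.dim_as_class,
                denominator=config.explainability_denominator,
            )
            for kind, rel in rels.items()
        }
        report = explainability_report(fits)
        report.to_csv(out / "explainability.tsv", sep="\t")
        info["explainability_pct"] = report["explainability_pct"].to_dict()
    except Exception as exc:
        raise StageError("explainability", exc) from exc

    try:
        info = stage("metabotypes")
        for kind in METABOLOME_LAYERS:
            if kind not in layers:
                continue
            results = screen_metabotypes(layers[kind], phen, alpha=config.alpha)
            if kind == "rumen_metabolome" and taxa_dist is not None:
                results = assess_microbiome_responsiveness(
                    results,
                    layers[kind],
                    taxa_dist,
                    n_perm=config.n_perm,
                    seed=derive_seed(config.seed, 300),
                    q_threshold=config.fdr,
                )
            frame = metabotype_frame(results)
            frame.to_csv(out / f"metabotypes_{kind}.tsv", sep="\t")
            info[kind] = {
                "n_metabotypes": int((frame["sign_class"] != "none").sum()),
                "n_microbiome_responsive": int(frame["microbiome_responsive"].sum()),
            }
    except Exception as exc:
        raise StageError("metabotypes", exc) from exc

    try:
        info = stage("differential")
        if "taxa" in layers:
            wilcoxon_differential(layers["taxa"], groups, alpha=config.fdr).to_csv(
                out / "differential_taxa_wilcoxon.tsv", sep="\t"
            )
            lefse = lefse_style_score(
                layers["taxa"], groups, kw_alpha=config.alpha,
                lda_threshold=config.lda_threshold,
            )
            lefse.to_csv(out / "differential_taxa_lefse.tsv", sep="\t")
            info["taxa_lefse_significant"] = int(lefse["significant"].sum())
        if "function" in layers:
            lefse = lefse_style_score(
                layers["function"], groups, kw_alpha=config.alpha,
                lda_threshold=config.lda_threshold,
            )
            lefse.to_csv(out / "differential_function_lefse.tsv", sep="\t")
            info["function_lefse_significant"] = int(lefse["significant"].sum())
        for kind in METABOLOME_LAYERS:
            if kind not in layers:
                continue
            diff = differential_metabolites(
                layers[kind], groups, alpha=config.fdr,
                vip_threshold=config.vip_threshold,
                n_components=config.pls_components,
                use_fdr=config.metabolite_use_fdr,
            )
            diff.to_csv(out / f"differential_{kind}.tsv", sep="\t")
            info[f"{kind}_significant"] = int(diff["significant"].sum())
    except Exception as exc:
        raise StageError("differential", exc) from exc

    try:
        info = stage("networks")
        if "taxa" in layers:
            for kind in METABOLOME_LAYERS:
                if kind not in layers:
                    continue
                edges = build_correlation_network(
                    layers["taxa"], layers[kind],
                    r_threshold=config.r_threshold, alpha=config.alpha,
                )
                edges.to_csv(out / f"network_taxa_{kind}.tsv", sep="\t", index=False)
                info[f"taxa_{kind}_edges"] = int(len(edges))
    except Exception as exc:
        raise StageError("networks", exc) from exc

    manifest["thresholds_applied"] = {
        "taxa_abundance_threshold": config.taxa_abundance_threshold,
        "function_cpm_threshold": config.function_cpm_threshold,
        "prevalence_min_fraction": config.prevalence_min_fraction,
        "metabolite_min_presence": config.metabolite_min_presence,
        "metabolite_max_rsd": config.metabolite_max_rsd,
        "metabolite_min_similarity": config.metabolite_min_similarity,
        "alpha": config.alpha,
        "fdr": config.fdr,
        "r_threshold": config.r_threshold,
        "lda_threshold": config.lda_threshold,
        "vip_threshold": config.vip_threshold,
        "n_perm": config.n_perm,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run complete in %.1f s", time.perf_counter() - t0)
    for h in log.handlers:
        h.close()
    log.handlers.clear()
    return out
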