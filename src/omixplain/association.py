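"""Phenotype-metabolite association screening and microbiome responsiveness.

A *metabotype* is a metabolite whose intensity is significantly Spearman-
correlated with the phenotype (MPY), split into MPY-positive and
MPY-negative classes at raw p < alpha. A metabotype is *microbiome-
responsive* when, used as a continuous covariate in a PERMANOVA on the
microbial Bray-Curtis distance matrix, it explains significant variation
after Benjamini-Hochberg FDR correction across the screened metabotypes.
Thresholded Spearman correlation networks link features of two layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .similarity import DistanceMatrix, gower_center
from .tables import FeatureTable, PhenotypeTable


@dataclass
class MetabotypeResult:
    metabolite_id: str
    rho: float
    p_spearman: float
    sign_class: str  # "MPY-positive" | "MPY-negative" | "none"
    permanova_F: float = np.nan
    p_permanova: float = np.nan
    q_permanova: float = np.nan
    microbiome_responsive: bool = False


def _rank_matrix(x: np.ndarray) -> np.ndarray:
    """Column-wise mid-ranks (ties get average ranks)."""
    return np.apply_along_axis(stats.rankdata, 0, x)


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via the t approximation on n-2 df."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    # perfectly monotone pairs: report the smallest positive double
    tiny = np.nextafter(0.0, 1.0)
    return np.where(np.abs(rho) >= 1.0, tiny, np.clip(p, tiny, 1.0))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Mid-ranks are used for ties. Perfectly monotone input yields the
    smallest representable positive p (flagged with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 4:
        raise ValueError("Spearman correlation requires n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        warnings.warn("exact monotone relationship: p is the minimum representable",
                      stacklevel=2)
    p = float(_t_approx_p(np.array([rho]), n)[0])
    return rho, p


def spearman_matrix(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All cross correlations between columns of two sample-aligned frames.

    Returns (rho, p) DataFrames of shape (n_features_a, n_features_b).
    """
    n = a.shape[0]
    ra = _rank_matrix(a.to_numpy())
    rb = _rank_matrix(b.to_numpy())
    ra = (ra - ra.mean(axis=0)) / ra.std(axis=0, ddof=0)
    rb = (rb - rb.mean(axis=0)) / rb.std(axis=0, ddof=0)
    rho = np.clip(ra.T @ rb / n, -1.0, 1.0)
    p = _t_approx_p(rho, n)
    return (
        pd.DataFrame(rho, index=a.columns, columns=b.columns),
        pd.DataFrame(p, index=a.columns, columns=b.columns),
    )


def screen_metabotypes(
    metabolome: FeatureTable,
    phenotype: PhenotypeTable,
    alpha: float = 0.05,
) -> list[MetabotypeResult]:
    """Spearman-screen every metabolite against MPY and assign sign classes.

    Missing peak intensities are imputed to the column mean for ranking;
    constant metabolites are excluded with a warning.
    """
    if metabolome.sample_ids != phenotype.sample_ids:
        raise ValueError("metabolome and phenotype must share sample order")
    y = phenotype.mpy.to_numpy(dtype=float)
    results = []
    data = metabolome.data.fillna(metabolome.data.mean(axis=0, skipna=True))
    skipped = []
    for fid in metabolome.feature_ids:
        x = data[fid].to_numpy()
        if np.ptp(x) == 0 or not np.isfinite(x).all():
            skipped.append(fid)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = spearman(x, y)
        if p < alpha:
            sign = "MPY-positive" if rho > 0 else "MPY-negative"
        else:
            sign = "none"
        results.append(MetabotypeResult(fid, rho, p, sign))
    if skipped:
        warnings.warn(f"excluded {len(skipped)} constant metabolite(s)", stacklevel=2)
    return results


def permanova(
    d: DistanceMatrix,
    covariate,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """PERMANOVA of a distance matrix on a single continuous covariate.

    pseudo-F = [tr(HGH)/m] / [tr((I-H)G(I-H))/(n-m-1)] with G the
    Gower-centered distance matrix and H the hat matrix of [1, covariate];
    because G is doubly centered this reduces to a quadratic form in the
    centered covariate. The p-value uses the add-one permutation estimator,
    permuting covariate entries.
    """
    c = np.asarray(covariate, dtype=float)
    n = len(d.sample_ids)
    if c.shape != (n,):
        raise ValueError("covariate length must match the distance matrix")
    if np.isnan(d.values).any():
        raise ValueError("distance matrix contains NaN")
    if np.ptp(c) == 0:
        raise ValueError("constant covariate")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    g = gower_center(d.values)
    f_obs = _pseudo_f(g, c)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += _pseudo_f(g, rng.permutation(c)) >= f_obs
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)


def _pseudo_f(g: np.ndarray, c: np.ndarray) -> float:
    # J G = G J = 0 after Gower centering, so tr(HGH) = c~' G c~ / ||c~||^2
    n = g.shape[0]
    cc = c - c.mean()
    ss_model = float(cc @ g @ cc) / float(cc @ cc)
    ss_resid = float(np.trace(g)) - ss_model
    if ss_resid <= 1e-12 * max(abs(ss_model), 1.0):
        return np.inf  # covariate explains all dispersion
    return (ss_model / 1.0) / (ss_resid / (n - 2))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def assess_microbiome_responsiveness(
    results: list[MetabotypeResult],
    metabolome: FeatureTable,
    taxa_distance: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    q_threshold: float = 0.05,
) -> list[MetabotypeResult]:
    """PERMANOVA each screened metabotype against the microbiome distances.

    Only metabolites with a non-``none`` sign class are tested (mirroring
    the screen-then-test design); FDR correction is applied across the
    tested set. Results are updated in place and returned.
    """
    if metabolome.sample_ids != taxa_distance.sample_ids:
        raise ValueError("metabolome and distance matrix must share sample order")
    data = metabolome.data.fillna(metabolome.data.mean(axis=0, skipna=True))
    tested = [r for r in results if r.sign_class != "none"]
    for i, r in enumerate(tested):
        f, p = permanova(
            taxa_distance,
            data[r.metabolite_id].to_numpy(),
            n_perm=n_perm,
            seed=_metabolite_seed(seed, i),
        )
        r.permanova_F, r.p_permanova = f, p
    if tested:
        q = bh_fdr([r.p_permanova for r in tested])
        for r, qv in zip(tested, q):
            r.q_permanova = float(qv)
            r.microbiome_responsive = bool(qv < q_threshold)
    return results


def _metabolite_seed(seed: int, index: int) -> int:
    # fixed offset per metabolite so adding metabolites never reshuffles others
    return int((seed * 100003 + 7919 * index) % (2**31 - 1))


def metabotype_frame(results: list[MetabotypeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite_id": r.metabolite_id,
                "rho": r.rho,
                "p_spearman": r.p_spearman,
                "sign_class": r.sign_class,
                "permanova_F": r.permanova_F,
                "p_permanova": r.p_permanova,
                "q_permanova": r.q_permanova,
                "microbiome_responsive": r.microbiome_responsive,
            }
            for r in results
        ]
    ).set_index("metabolite_id")


def build_correlation_network(
    table_a: FeatureTable,
    table_b: FeatureTable,
    r_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Edges between features of two layers with |rho| > r_threshold and p < alpha.

    Samples are intersected (in table_a's order); edges are returned sorted
    by (source, target).
    """
    shared = [s for s in table_a.sample_ids if s in set(table_b.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between the two tables")
    a = table_a.data.loc[shared].fillna(table_a.data.loc[shared].mean(axis=0))
    b = table_b.data.loc[shared].fillna(table_b.data.loc[shared].mean(axis=0))
    a = a.loc[:, a.std(axis=0) > 0]
    b = b.loc[:, b.std(axis=0) > 0]
    rho, p = spearman_matrix(a, b)
    keep = (rho.abs() > r_threshold) & (p < alpha)
    rows = []
    for fa in rho.index:
        for fb in rho.columns[keep.loc[fa].to_numpy()]:
            rows.append(
                {"source": fa, "target": fb, "rho": rho.at[fa, fb], "p": p.at[fa, fb]}
            )
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p"])
    return edges.sort_values(["source", "target"]).reset_index(drop=True)
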