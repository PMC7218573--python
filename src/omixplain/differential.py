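"""Two-group differential-feature procedures.

Three procedures cover the feature types of a rumen multi-omics study:

* Wilcoxon rank-sum with BH FDR for taxonomic levels (domains, phyla,
  genera);
* a documented LEfSe-style score for species / functional features:
  Kruskal-Wallis screening (equivalent to Wilcoxon for two groups)
  followed by a regularized two-class Fisher linear discriminant, the
  effect size of feature f being |(w_f * delta_f + delta_f) / 2| on the
  per-million abundance scale, reported as lda_score = log10(1 + effect);
  significant when p < alpha and lda_score > 2. This is a simplified
  reimplementation (no bootstrap rounds, no subclass logic — the design
  has two classes only), so scores are comparable in spirit, not
  bit-identical, to the published LEfSe tool;
* Welch t-test + BH FDR combined with PLS-DA VIP > 1 for metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .association import bh_fdr
from .preprocess import zscore_standardize
from .tables import FeatureTable


@dataclass
class DifferentialResult:
    feature_id: str
    statistic: float
    p_raw: float
    q_bh: float = np.nan
    effect_direction: str = ""
    lda_score: float = np.nan
    vip: float = np.nan
    fold_change: float = np.nan
    significant: bool = False


def wilcoxon_rank_sum(x, y, exact_if: int = 10) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank sum of the first group under
    mid-ranks. The p-value is exact (full enumeration) when both groups
    have at most ``exact_if`` observations and there are no ties, else a
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= exact_if and y.size <= exact_if and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return w, float(res.pvalue)


def wilcoxon_differential(
    t: FeatureTable,
    groups: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature Wilcoxon rank-sum with BH FDR; significant when q < alpha."""
    g1, g2, labels = _split_groups(t, groups)
    rows = []
    for fid in t.feature_ids:
        stat, p = wilcoxon_rank_sum(g1[fid], g2[fid])
        direction = labels[0] if g1[fid].mean() > g2[fid].mean() else labels[1]
        rows.append({"feature_id": fid, "statistic": stat, "p_raw": p,
                     "effect_direction": direction})
    out = pd.DataFrame(rows).set_index("feature_id")
    out["q_bh"] = bh_fdr(out["p_raw"].to_numpy())
    out["significant"] = out["q_bh"] < alpha
    return out


def lefse_style_score(
    t: FeatureTable,
    groups: pd.Series,
    kw_alpha: float = 0.05,
    lda_threshold: float = 2.0,
    regularizer: float = 1e-6,
) -> pd.DataFrame:
    """LEfSe-style two-stage differential score on the per-million scale.

    Stage 1 screens each feature by Kruskal-Wallis (two groups: Wilcoxon);
    stage 2 fits one regularized Fisher discriminant to the features that
    survive and scores each as log10(1 + |(w_f*delta_f + delta_f)/2|), with
    delta_f the HH-LL mean difference per million and w the unit-norm
    discriminant direction. ``regularizer`` scales trace(S_w) to give the
    ridge added to the within-class scatter.
    """
    scale_tbl = _to_per_million(t)
    g1, g2, labels = _split_groups(scale_tbl, groups)
    rows = []
    for fid in scale_tbl.feature_ids:
        stat, p = wilcoxon_rank_sum(g1[fid], g2[fid])
        rows.append({"feature_id": fid, "statistic": stat, "p_raw": p})
    out = pd.DataFrame(rows).set_index("feature_id")
    out["effect_direction"] = [
        labels[0] if g1[f].mean() > g2[f].mean() else labels[1]
        for f in out.index
    ]
    out["lda_score"] = np.nan
    survivors = out.index[out["p_raw"] < kw_alpha]
    if len(survivors) > 0:
        x1 = g1[survivors].to_numpy()
        x2 = g2[survivors].to_numpy()
        delta = x1.mean(axis=0) - x2.mean(axis=0)
        s_w = _scatter(x1) + _scatter(x2)
        lam = regularizer * max(np.trace(s_w), 1e-300)
        w = np.linalg.solve(s_w + lam * np.eye(len(survivors)), delta)
        norm = np.linalg.norm(w)
        if norm > 0:
            w = w / norm
        effect = np.abs((w * delta + delta) / 2.0)
        out.loc[survivors, "lda_score"] = np.log10(1.0 + effect)
    out["significant"] = (out["p_raw"] < kw_alpha) & (out["lda_score"] > lda_threshold)
    return out


def _scatter(x: np.ndarray) -> np.ndarray:
    c = x - x.mean(axis=0)
    return c.T @ c


def _to_per_million(t: FeatureTable) -> FeatureTable:
    """Bring a table to the per-million abundance scale expected by the score."""
    if t.value_kind == "cpm":
        return t
    if t.value_kind == "relative":
        df = t.data * 1e6
        return FeatureTable(df, t.layer_kind, "cpm", t.feature_meta) if np.allclose(
            df.sum(axis=1), 1e6
        ) else FeatureTable(df, t.layer_kind, "intensity", t.feature_meta)
    raise ValueError(
        "LEfSe-style scoring expects a relative or cpm table "
        f"(got value_kind={t.value_kind!r}); the LDA threshold is scale-bound"
    )


def plsda_vip(
    t: FeatureTable,
    groups: pd.Series,
    n_components: int = 2,
) -> pd.Series:
    """Variable importance in projection from a two-class PLS-DA.

    The response is the group indicator coded +1/-1; X is the z-scored
    feature matrix. VIP_f = sqrt(q * sum_c SS_c w~_fc^2 / sum_c SS_c)
    with SS_c the response sum of squares captured by component c and w~
    the unit-norm weight vectors, so sum_f VIP_f^2 = q identically.
    """
    z = t if t.value_kind == "zscore" else zscore_standardize(t)
    labels = _group_labels(groups.loc[z.sample_ids])
    y = np.where(groups.loc[z.sample_ids] == labels[0], 1.0, -1.0)
    q = z.n_features
    max_comp = min(z.n_samples - 1, q)
    if n_components > max_comp:
        raise ValueError(f"n_components must be <= {max_comp}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(z.values, y)
    w = pls.x_weights_  # (q, c), unit-norm columns from NIPALS
    w = w / np.linalg.norm(w, axis=0, keepdims=True)
    tt = pls.x_scores_  # (n, c)
    qload = pls.y_loadings_.ravel()  # (c,)
    ss = (qload**2) * (tt**2).sum(axis=0)
    vip = np.sqrt(q * (w**2 @ ss) / ss.sum())
    return pd.Series(vip, index=z.feature_ids, name="vip")


def differential_metabolites(
    t: FeatureTable,
    groups: pd.Series,
    alpha: float = 0.05,
    vip_threshold: float = 1.0,
    n_components: int = 2,
    use_fdr: bool = True,
) -> pd.DataFrame:
    """Welch t-test (BH FDR) combined with PLS-DA VIP for metabolites.

    A metabolite is significant when q_bh < alpha (or raw p < alpha with
    ``use_fdr=False``) and VIP > vip_threshold. Metabolites with zero
    variance in both groups have no defined t statistic and are excluded
    with a warning. Fold change is the HH/LL group-mean ratio on the input
    intensity scale.
    """
    g1, g2, labels = _split_groups(t, groups)
    g1 = g1.fillna(t.data.mean(axis=0, skipna=True))
    g2 = g2.fillna(t.data.mean(axis=0, skipna=True))
    testable, skipped = [], []
    for fid in t.feature_ids:
        if g1[fid].std(ddof=1) == 0 and g2[fid].std(ddof=1) == 0:
            skipped.append(fid)
        else:
            testable.append(fid)
    if skipped:
        warnings.warn(
            f"excluded {len(skipped)} metabolite(s) with zero within-group variance",
            stacklevel=2,
        )
    rows = []
    for fid in testable:
        res = stats.ttest_ind(g1[fid], g2[fid], equal_var=False)
        m1, m2 = g1[fid].mean(), g2[fid].mean()
        rows.append(
            {
                "feature_id": fid,
                "statistic": float(res.statistic),
                "p_raw": float(res.pvalue),
                "effect_direction": labels[0] if m1 > m2 else labels[1],
                "fold_change": m1 / m2 if m2 != 0 else np.inf,
            }
        )
    out = pd.DataFrame(rows).set_index("feature_id")
    out["q_bh"] = bh_fdr(out["p_raw"].to_numpy())
    sub = t.subset_features(testable)
    # cap components at the rank the retained features allow
    n_comp = min(n_components, len(testable), t.n_samples - 1)
    out["vip"] = plsda_vip(sub, groups, n_components=n_comp)
    p_gate = out["q_bh"] if use_fdr else out["p_raw"]
    out["significant"] = (p_gate < alpha) & (out["vip"] > vip_threshold)
    return out


def _group_labels(groups: pd.Series) -> tuple[str, str]:
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    # HH before LL when present, else lexicographic
    if "HH" in labels:
        labels = ["HH"] + [l for l in labels if l != "HH"]
    return labels[0], labels[1]


def _split_groups(t: FeatureTable, groups: pd.Series):
    groups = pd.Series(groups).loc[t.sample_ids]
    l1, l2 = _group_labels(groups)
    g1 = t.data.loc[groups[groups == l1].index]
    g2 = t.data.loc[groups[groups == l2].index]
    return g1, g2, (l1, l2)
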