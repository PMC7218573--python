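"""REML variance components and omics-explainability.

The model for animal phenotype y (MPY, kg/day) with one omics layer is

    y = X beta + u + e,   u ~ N(0, A sigma2_a),   e ~ N(0, I sigma2_e)

where X holds the intercept, parity class contrasts and a days-in-milk
covariate, and A is the layer's relationship matrix (Z Z'/q). The layer's
omics-explainability is sigma2_a / (sigma2_a + sigma2_e) — the share of
phenotypic variance attributable to between-animal similarity in that omics
layer, the multi-omics generalization of "microbiability".

Fitting uses the standard single-kernel trick: eigendecompose A = U L U'
once, rotate y and X by U', and the covariance becomes diagonal,
sigma2 * diag(h2 * lambda_i + 1 - h2) with h2 = sigma2_a / sigma2 and
sigma2 = sigma2_a + sigma2_e. The restricted likelihood then profiles beta
and sigma2 in closed form, leaving a bounded one-dimensional optimization
over h2. The significance of the random effect is a likelihood-ratio test
against sigma2_a = 0 with the boundary-corrected 0.5*chi2_0 + 0.5*chi2_1
null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .similarity import RelationshipMatrix

_H2_LO = 1e-6
_H2_HI = 1.0 - 1e-6
_XATOL = 1e-8


class RemlError(RuntimeError):
    pass


@dataclass
class VarianceComponentFit:
    """REML estimates for one omics layer's random effect."""

    layer: str
    sigma2_a: float
    sigma2_e: float
    explainability: float
    loglik_full: float
    loglik_null: float
    lrt_stat: float
    p_value: float
    fixed_effect_estimates: dict = field(default_factory=dict)
    converged: bool = True
    identifiable: bool = True
    n: int = 0
    sample_ids: tuple = ()

    @property
    def explainability_pct(self) -> float:
        return round(100.0 * self.explainability, 2)


def build_design(covariates: pd.DataFrame, dim_as_class: bool = False) -> pd.DataFrame:
    """Fixed-effect design: intercept + parity contrasts + days in milk.

    Parity enters as a class effect (first level is the reference); days in
    milk enters as a continuous covariate by default, or as a class effect
    when ``dim_as_class`` is set. Columns that would make the design
    singular (e.g. a single parity level, or constant dim) are dropped with
    a warning.
    """
    n = covariates.shape[0]
    cols = {"intercept": np.ones(n)}
    parity = covariates["parity"].astype(int)
    levels = sorted(parity.unique())
    for lev in levels[1:]:
        cols[f"parity_{lev}"] = (parity == lev).to_numpy(dtype=float)
    dim = covariates["dim"].astype(float)
    if dim_as_class:
        dlevels = sorted(dim.unique())
        for lev in dlevels[1:]:
            cols[f"dim_{lev:g}"] = (dim == lev).to_numpy(dtype=float)
    else:
        cols["dim"] = dim.to_numpy()
    X = pd.DataFrame(cols, index=covariates.index)
    # greedy rank filter keeps the earliest independent columns
    keep: list[str] = []
    for c in X.columns:
        trial = X[keep + [c]].to_numpy()
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(c)
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping collinear fixed-effect columns {dropped}", stacklevel=2)
    return X[keep]


def _reml_loglik(h2: float, lam: np.ndarray, yr: np.ndarray, xr: np.ndarray) -> tuple:
    """Restricted log-likelihood at heritability-like ratio h2.

    Returns (loglik, beta_hat, sigma2_hat) with sigma2 = sigma2_a + sigma2_e
    profiled out. Constant terms independent of h2 (including log|X'X|) are
    omitted consistently, so differences of returned values are valid LRT
    inputs.
    """
    n, p = xr.shape
    d = h2 * lam + (1.0 - h2)
    w = 1.0 / d
    xtwx = xr.T @ (w[:, None] * xr)
    xtwy = xr.T @ (w * yr)
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise RemlError("singular weighted design") from exc
    resid = yr - xr @ beta
    rss = float(resid @ (w * resid))
    if rss <= 0:
        raise RemlError("non-positive residual sum of squares")
    sigma2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        raise RemlError("weighted design lost rank")
    ll = -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
        + np.sum(np.log(d))
        + logdet_xtwx
    )
    return ll, beta, sigma2


def reml_fit(
    y,
    covariates: pd.DataFrame,
    A: RelationshipMatrix,
    dim_as_class: bool = False,
    denominator: str = "model",
) -> VarianceComponentFit:
    """Fit the single-random-effect LMM by REML.

    Parameters
    ----------
    y:
        Phenotype vector (pd.Series indexed by sample, or array in the
        order of ``A.sample_ids``).
    covariates:
        DataFrame with ``parity`` and ``dim`` columns, same samples as A.
    A:
        The omics relationship matrix.
    denominator:
        ``"model"`` defines phenotypic variance as sigma2_a + sigma2_e;
        ``"sample"`` divides sigma2_a by the sample variance of y instead.

    The optimum over h2 in [1e-6, 1-1e-6] is located by bounded scalar
    minimization restarted on three subintervals; near-ties are resolved
    toward the smaller h2. A relationship matrix whose eigenvalue spectrum
    is (numerically) constant carries no contrast between animals — the
    likelihood is then flat in the sigma2_a/sigma2_e split, and the fit is
    reported at the h2 = 0 boundary with ``identifiable=False`` instead of
    an arbitrary interior optimum.
    """
    ids = A.sample_ids
    if isinstance(y, pd.Series):
        y = y.loc[ids]
    yv = np.asarray(y, dtype=float)
    cov = covariates.loc[ids]
    X = build_design(cov, dim_as_class=dim_as_class).to_numpy()
    n, p = X.shape
    if n < p + 2:
        raise RemlError(f"need at least {p + 2} samples for {p} fixed effects")

    lam, U = np.linalg.eigh((A.values + A.values.T) / 2)
    lam = np.clip(lam, 0.0, None)
    # work on unit-sd phenotype so estimates are exactly scale-equivariant
    y_scale = float(np.std(yv, ddof=1))
    if y_scale <= 0:
        raise RemlError("phenotype has zero variance")
    yr = U.T @ (yv / y_scale)
    xr = U.T @ X

    ll_null, beta_null, sig2_null = _reml_loglik(0.0, lam, yr, xr)

    spread = lam.max() - lam.min()
    identifiable = spread > 1e-8 * max(lam.max(), 1.0)
    if not identifiable:
        warnings.warn(
            "relationship matrix has a flat eigenvalue spectrum; the variance "
            "split is not identifiable — reporting the h2=0 boundary",
            stacklevel=2,
        )
        ll0 = ll_null - (n - p) * np.log(y_scale)
        return VarianceComponentFit(
            layer=A.source_layer,
            sigma2_a=0.0,
            sigma2_e=sig2_null * y_scale**2,
            explainability=0.0,
            loglik_full=ll0,
            loglik_null=ll0,
            lrt_stat=0.0,
            p_value=1.0,
            fixed_effect_estimates=_beta_dict(beta_null * y_scale, cov, dim_as_class),
            converged=True,
            identifiable=False,
            n=n,
            sample_ids=tuple(ids),
        )

    def neg_ll(h2: float) -> float:
        return -_reml_loglik(h2, lam, yr, xr)[0]

    edges = [_H2_LO, 1.0 / 3.0, 2.0 / 3.0, _H2_HI]
    # h2 = 0 (the null boundary) is always a candidate, so ties resolve to it
    best_h2, best_ll, ok = 0.0, ll_null, True
    for lo, hi in zip(edges[:-1], edges[1:]):
        res = optimize.minimize_scalar(
            neg_ll, bounds=(lo, hi), method="bounded", options={"xatol": _XATOL}
        )
        ok = ok and bool(res.success)
        cand_ll = -res.fun
        # ties go to the smaller h2
        if cand_ll > best_ll + 1e-9 or (
            abs(cand_ll - best_ll) <= 1e-9 and res.x < best_h2
        ):
            best_h2, best_ll = float(res.x), cand_ll

    ll_full, beta, sigma2 = _reml_loglik(best_h2, lam, yr, xr)
    if ll_null > ll_full + 1e-6:
        raise RemlError("null restricted likelihood exceeds the full fit")
    # the bounded optimum cannot fall below the h2->0 boundary value
    if ll_null >= ll_full:
        best_h2, ll_full, beta, sigma2 = 0.0, ll_null, beta_null, sig2_null

    sigma2_a = best_h2 * sigma2 * y_scale**2
    sigma2_e = (1.0 - best_h2) * sigma2 * y_scale**2
    beta = beta * y_scale
    # restricted likelihoods on the original phenotype scale
    log_c = np.log(y_scale)
    ll_full = ll_full - (n - p) * log_c
    ll_null_orig = ll_null - (n - p) * log_c
    if denominator == "model":
        expl = sigma2_a / (sigma2_a + sigma2_e)
    elif denominator == "sample":
        expl = min(1.0, max(0.0, sigma2_a / np.var(yv, ddof=1)))
    else:
        raise ValueError("denominator must be 'model' or 'sample'")

    lrt = max(0.0, 2.0 * (ll_full - ll_null_orig))
    return VarianceComponentFit(
        layer=A.source_layer,
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        explainability=expl,
        loglik_full=ll_full,
        loglik_null=ll_null_orig,
        lrt_stat=lrt,
        p_value=_boundary_p(lrt),
        fixed_effect_estimates=_beta_dict(beta, cov, dim_as_class),
        converged=ok,
        identifiable=True,
        n=n,
        sample_ids=tuple(ids),
    )


def _beta_dict(beta: np.ndarray, cov: pd.DataFrame, dim_as_class: bool) -> dict:
    names = list(build_design(cov, dim_as_class=dim_as_class).columns)
    return dict(zip(names, map(float, beta)))


def _boundary_p(lrt_stat: float) -> float:
    """P-value from the 0.5*chi2_0 + 0.5*chi2_1 boundary mixture."""
    if lrt_stat <= 0:
        return 1.0
    return 0.5 * float(stats.chi2.sf(lrt_stat, df=1))


def lrt_random_effect(fit: VarianceComponentFit) -> float:
    """Boundary-corrected LRT p-value for sigma2_a = 0 (recomputed from the fit)."""
    if not fit.converged:
        raise RemlError("cannot test a non-converged fit")
    if fit.loglik_null > fit.loglik_full + 1e-6:
        raise RemlError("null likelihood exceeds full likelihood")
    return _boundary_p(fit.lrt_stat)


def explainability_report(fits: dict) -> pd.DataFrame:
    """Tabulate per-layer explainability percentages and LRT p-values.

    Each layer comes from a *separate* single-random-effect model on the
    same phenotype vector; the percentages are not constrained to sum
    to 100.
    """
    ref = None
    rows = []
    for layer, fit in fits.items():
        if ref is None:
            ref = fit.sample_ids
        elif fit.sample_ids != ref:
            raise ValueError("fits were made on different sample sets")
        rows.append(
            {
                "layer": layer,
                "explainability_pct": fit.explainability_pct,
                "sigma2_a": fit.sigma2_a,
                "sigma2_e": fit.sigma2_e,
                "lrt_stat": fit.lrt_stat,
                "p_value": fit.p_value,
                "converged": fit.converged,
                "identifiable": fit.identifiable,
            }
        )
    return pd.DataFrame(rows).set_index("layer")
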