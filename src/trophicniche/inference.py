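"""Group-comparison machinery.

* ``hotelling_t2`` — parametric two-sample test for a common bivariate mean,
  with the exact F transform of T².
* ``rpp_test`` — residual permutation procedure: a permutation null for
  differences in dispersion-type niche metrics (CD, MNND) or centroid
  location, built by centering each group on its own centroid, pooling the
  residuals, and reassigning them to groups of the original sizes.
* ``pearson`` — Pearson correlation with the two-sided t test (df = n−2).
* ``fit_lmm`` / ``lrt_compare`` — the gut-fullness linear mixed model
  (fixed group/time effects, season random intercept) fitted by maximum
  likelihood, and likelihood-ratio χ² comparisons between nested fits.
  ML (not REML) is used throughout because the fixed effects are what the
  LRTs compare.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .datatypes import (
    FullnessTable,
    InsufficientDataError,
    LmmFit,
    TestResult,
    ValidationError,
)


def _as_xy(a) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError(f"expected an (n, 2) sample, got shape {arr.shape}")
    return arr


def hotelling_t2(a, b) -> TestResult:
    """Two-sample Hotelling's T² for equality of bivariate means.

    Uses the pooled covariance; the p-value comes from
    F = T² (n₁+n₂−p−1) / ((n₁+n₂−2) p) with p = 2 dimensions.
    """
    a, b = _as_xy(a), _as_xy(b)
    n1, n2 = len(a), len(b)
    if n1 + n2 < 4 or min(n1, n2) < 2:
        raise InsufficientDataError("hotelling_t2: need n1+n2 >= 4 with n >= 2 each")
    p = 2
    diff = a.mean(axis=0) - b.mean(axis=0)
    s_pooled = ((n1 - 1) * np.cov(a, rowvar=False) + (n2 - 1) * np.cov(b, rowvar=False))
    s_pooled /= n1 + n2 - 2
    eig = np.linalg.eigvalsh(s_pooled)
    if eig.min() <= 1e-12 * max(eig.max(), 1e-30):
        raise ValidationError("hotelling_t2: singular pooled covariance")
    sol = np.linalg.solve(s_pooled, diff)
    t2 = float(n1 * n2 / (n1 + n2) * diff @ sol)
    dof2 = n1 + n2 - p - 1
    f = t2 * dof2 / ((n1 + n2 - 2) * p)
    p_value = float(stats.f.sf(f, p, dof2))
    return TestResult(statistic=t2, p_value=p_value, method="hotelling_t2",
                      n1=n1, n2=n2)


def _metric_cd(xy: np.ndarray) -> float:
    return float(np.linalg.norm(xy - xy.mean(axis=0), axis=1).mean())


def _metric_mnnd(xy: np.ndarray) -> float:
    d = squareform(pdist(xy))
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


_RPP_METRICS = {"CD": _metric_cd, "MNND": _metric_mnnd}


def rpp_test(a, b, metric: str = "CD", B: int = 9999, seed: int = 0,
             raw_labels: bool = False) -> TestResult:
    """Residual permutation test for a difference in CD, MNND or centroid location.

    The observed statistic is |metric(a) − metric(b)| (Euclidean distance
    between centroids for ``metric='centroid_distance'``). The null pools the
    group-centered residuals, permutes them into groups of the original
    sizes around a common centroid, and recomputes; the add-one estimator
    gives p = (1 + #{null ≥ observed}) / (B + 1) ≥ 1/(B+1).

    ``raw_labels=True`` permutes the raw points instead of residuals (only
    meaningful for the centroid test).
    """
    if B < 99:
        raise ValidationError("rpp_test: need B >= 99 permutations")
    a, b = _as_xy(a), _as_xy(b)
    n1, n2 = len(a), len(b)
    if metric in _RPP_METRICS:
        fn = _RPP_METRICS[metric]
        if min(n1, n2) < 2:
            raise InsufficientDataError(f"rpp_test[{metric}]: need n >= 2 per group")
        observed = abs(fn(a) - fn(b))
        stat = lambda x, y: abs(fn(x) - fn(y))  # noqa: E731
    elif metric == "centroid_distance":
        observed = float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
        stat = lambda x, y: float(np.linalg.norm(x.mean(axis=0) - y.mean(axis=0)))  # noqa: E731
    else:
        raise ValueError(f"unknown metric {metric!r}")

    rng = np.random.default_rng(seed)
    if raw_labels:
        pool = np.vstack([a, b])
    else:
        grand = np.vstack([a, b]).mean(axis=0)
        pool = np.vstack([a - a.mean(axis=0), b - b.mean(axis=0)]) + grand
    exceed = 0
    for _ in range(B):
        perm = rng.permutation(len(pool))
        null = stat(pool[perm[:n1]], pool[perm[n1:]])
        if null >= observed:
            exceed += 1
    p_value = (1 + exceed) / (B + 1)
    return TestResult(statistic=observed, p_value=p_value,
                      method=f"rpp[{metric}]", n1=n1, n2=n2,
                      permutations=B, seed=seed)


def pearson(x, y) -> TestResult:
    """Pearson correlation with the two-sided t test (df = n − 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("pearson: need equal-length 1-D vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("pearson: zero-variance input")
    r, p = stats.pearsonr(x, y)
    return TestResult(statistic=float(r), p_value=float(p), method="pearson",
                      n1=len(x), n2=len(x))


# ---------------------------------------------------------------------------
# gut-fullness linear mixed model

#: nested-model formula tags, in step-down order
LMM_FORMULAS = {
    "full": "ff ~ C(group) + C(time_h) + C(group):C(time_h)",
    "additive": "ff ~ C(group) + C(time_h)",
    "time": "ff ~ C(time_h)",
    "group": "ff ~ C(group)",
    "null": "ff ~ 1",
}


def fit_lmm(ft: FullnessTable, formula: str = "full") -> LmmFit:
    """ML fit of gut fullness on group/time fixed effects + season intercept."""
    if formula not in LMM_FORMULAS:
        raise ValueError(f"formula must be one of {sorted(LMM_FORMULAS)}")
    df = ft.data
    if df["season"].nunique() < 2:
        raise InsufficientDataError("fit_lmm: need >= 2 seasons for the random intercept")
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(LMM_FORMULAS[formula], df, groups=df["season"])
        # the season variance often sits on the zero boundary, where some
        # optimizers report an infinite likelihood; cascade until one is sane
        for method in (None, "powell", "nm"):
            kwargs = {} if method is None else {"method": method}
            try:
                cand = model.fit(reml=False, **kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(cand.llf):
                if fit is None or cand.llf > fit.llf:
                    fit = cand
                if cand.converged:
                    break
    if fit is None:
        raise ValidationError(f"fit_lmm[{formula}]: all optimizers failed")
    return LmmFit(
        formula=formula,
        fixed_effects=dict(zip(fit.fe_params.index, map(float, fit.fe_params))),
        fixed_effects_se=dict(
            zip(fit.fe_params.index, map(float, fit.bse_fe))
        ),
        season_variance=float(np.atleast_2d(fit.cov_re)[0, 0]),
        residual_variance=float(fit.scale),
        log_likelihood=float(fit.llf),
        n_fixed_params=len(fit.fe_params),
        converged=bool(fit.converged),
    )


def lrt_compare(full: LmmFit, reduced: LmmFit) -> TestResult:
    """Likelihood-ratio χ² between two nested ML fits of the fullness model.

    χ² = 2(ℓ_full − ℓ_reduced) (clipped at 0 against optimizer noise);
    df is the difference in fixed-effect parameter counts.
    """
    df_diff = full.n_fixed_params - reduced.n_fixed_params
    if df_diff < 0:
        raise ValidationError("lrt_compare: reduced model must be nested in full")
    chi2 = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    # identical models compare trivially: no evidence, p = 1
    p = float(stats.chi2.sf(chi2, df_diff)) if df_diff > 0 else 1.0
    return TestResult(statistic=chi2, p_value=p,
                      method=f"lrt[{full.formula} vs {reduced.formula}]")


def rhythm_tests(ft: FullnessTable, order: str = "interaction_first") -> dict[str, TestResult]:
    """Step-down LRTs for the feeding-rhythm model.

    ``interaction_first`` (default) drops the group×time interaction from the
    full model, then tests time and group by dropping each from the additive
    model. ``from_full`` tests each term against the full model directly.
    """
    fits = {tag: fit_lmm(ft, tag) for tag in ("full", "additive", "time", "group")}
    out = {"interaction": lrt_compare(fits["full"], fits["additive"])}
    if order == "interaction_first":
        out["time"] = lrt_compare(fits["additive"], fits["group"])
        out["group"] = lrt_compare(fits["additive"], fits["time"])
    elif order == "from_full":
        out["time"] = lrt_compare(fits["full"], fits["group"])
        out["group"] = lrt_compare(fits["full"], fits["time"])
    else:
        raise ValueError(f"unknown step-down order {order!r}")
    return out
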