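"""Commonality analysis: how much explained variance the treatment shares
with the covariates.

For a model with treatment T and covariate block C, the explained variance
R2(T,C) splits into three parts:

    unique_T = R2(T,C) - R2(C)
    unique_C = R2(T,C) - R2(T)
    common   = R2(T) + R2(C) - R2(T,C)

``common`` is the confounded share — variance the data cannot attribute to
either T or C alone (it may be negative under suppression, and is reported
signed).  Gaussian models use ordinary R2; binomial models McFadden's
pseudo-R2.  Averaged across propensity groups and compared with the direct
whole-data model via a paired t-test, the drop in ``common`` quantifies how
much stratification reduced confounding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .effects import ModelSpec, _fit_glm
from .propensity import Stratification


@dataclass
class CommonalityPartition:
    """Three-part variance partition for one fitted model."""

    total: float            # R2(T, C)
    unique_treatment: float
    unique_covariates: float
    common: float

    def identity_residual(self) -> float:
        return abs(self.unique_treatment + self.unique_covariates
                   + self.common - self.total)


@dataclass
class ConfoundingComparison:
    """Paired comparison of common components: direct vs propensity arms."""

    responses: list[str]
    propensity_common: np.ndarray
    direct_common: np.ndarray
    mean_difference: float    # direct - propensity
    t_statistic: float
    p_value: float


def _r2(sub: pd.DataFrame, spec: ModelSpec) -> float:
    """Ordinary R2 (gaussian) or McFadden pseudo-R2 (binomial/poisson)."""
    res, X = _fit_glm(sub, spec)
    y = sub[spec.response].to_numpy(float)
    if spec.family == "gaussian":
        sst = np.sum((y - y.mean()) ** 2)
        ssr = np.sum((y - res.fittedvalues) ** 2)
        return float(1.0 - ssr / sst) if sst > 0 else 0.0
    return float(1.0 - res.llf / res.llnull) if res.llnull != 0 else 0.0


def commonality_partition(sites: pd.DataFrame, spec: ModelSpec) -> CommonalityPartition:
    """Partition a response model's explained variance into the treatment's
    unique share, the covariates' unique share, and the common share."""
    full = _r2(sites, spec)
    cov_only = _r2_drop_treatment(sites, spec)
    treat_only = _r2(sites, replace(spec, continuous=[], categorical=[]))
    return CommonalityPartition(
        total=full,
        unique_treatment=full - cov_only,
        unique_covariates=full - treat_only,
        common=treat_only + cov_only - full,
    )


def _r2_drop_treatment(sites: pd.DataFrame, spec: ModelSpec) -> float:
    """R2 of the covariates-only model (treatment column removed)."""
    import warnings as _w

    import statsmodels.api as sm

    from .effects import _design
    X = _design(sites, spec).drop(columns=spec.treatment)
    y = sites[spec.response].to_numpy(float)
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        res = sm.GLM(y, X, family=spec.glm_family()).fit(maxiter=200)
    if spec.family == "gaussian":
        sst = np.sum((y - y.mean()) ** 2)
        return float(1.0 - np.sum((y - res.fittedvalues) ** 2) / sst) if sst > 0 else 0.0
    return float(1.0 - res.llf / res.llnull) if res.llnull != 0 else 0.0


def commonality_expansion(sites: pd.DataFrame, response: str,
                          predictors: list[str], family: str = "gaussian") -> dict:
    """Full commonality expansion over individual predictors (<= 5).

    Returns {frozenset(subset): coefficient}; coefficients for singletons are
    unique contributions, higher-order sets are shared contributions, and the
    whole table sums to the full-model R2.  Uses the Moebius-inversion form
    c_S = -sum_{B subseteq S} (-1)^{|S|-|B|} R2(P \\ B).
    """
    if len(predictors) > 5:
        raise ValueError("full expansion limited to 5 predictors")
    p = list(predictors)

    def r2_of(subset: tuple[str, ...]) -> float:
        if not subset:
            return 0.0
        spec = ModelSpec(response=response, family=family, treatment=subset[0],
                         continuous=list(subset[1:]), categorical=[])
        return _r2(sites, spec)

    cache = {frozenset(s): r2_of(tuple(s))
             for r in range(len(p) + 1) for s in combinations(p, r)}
    full = frozenset(p)
    out = {}
    for r in range(1, len(p) + 1):
        for s in combinations(p, r):
            S = frozenset(s)
            c = 0.0
            for rb in range(len(s) + 1):
                for b in combinations(s, rb):
                    c -= (-1) ** (len(s) - len(b)) * cache[full - frozenset(b)]
            out[S] = c
    return out


def group_commonality(sites: pd.DataFrame, strat: Stratification,
                      spec: ModelSpec, weighted: bool = True) -> float:
    """Common component averaged across propensity groups (group-size
    weights by default, matching the pooled-effect weighting)."""
    labels = strat.labels.to_numpy()
    commons, sizes = [], []
    for g in range(strat.k):
        sub = sites[labels == g]
        try:
            part = commonality_partition(sub, spec)
        except Exception:
            continue
        commons.append(part.common)
        sizes.append(len(sub))
    if not commons:
        raise ValueError("no group produced a commonality partition")
    w = np.array(sizes, float)
    w = w / w.sum() if weighted else np.full(len(w), 1.0 / len(w))
    return float(w @ np.array(commons))


def compare_confounding(propensity_common: dict[str, float],
                        direct_common: dict[str, float]) -> ConfoundingComparison:
    """Paired t-test of common components (direct minus propensity), paired
    by response variable."""
    responses = sorted(set(propensity_common) & set(direct_common))
    if len(responses) < 2:
        raise ValueError("need at least 2 paired responses")
    prop = np.array([propensity_common[r] for r in responses])
    direct = np.array([direct_common[r] for r in responses])
    diff = direct - prop
    if np.allclose(diff.std(ddof=1), 0.0):
        t, pval = (0.0, 1.0) if np.allclose(diff, 0.0) else (np.inf * np.sign(diff.mean()), 0.0)
    else:
        t, pval = stats.ttest_rel(direct, prop)
    return ConfoundingComparison(
        responses=responses, propensity_common=prop, direct_common=direct,
        mean_difference=float(diff.mean()), t_statistic=float(t),
        p_value=float(pval))
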