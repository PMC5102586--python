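"""Within-stratum treatment-effect models and weighted pooling.

Inside each propensity group a GLM relates the response to percent treatment
cover, with the propensity covariates entered linearly to soak up remaining
within-group variability.  Group coefficients are pooled as a weighted mean
(weights = group share of observations), with the 95% confidence half-width

    CI = z * sqrt( sum_k SE_k^2 * (n_k / N)^2 ),  z = 1.96,

the variance of a weighted mean of independent per-group estimates.  With m
response models per family of tests, confidence limits are widened to level
alpha / c(m), c(m) = sum_{i<=m} 1/i (Benjamini–Yekutieli), before flagging
significance: an effect is significant when the widened interval excludes 0
on the link scale (equivalently 1 on the odds-ratio scale).

Effect sizes are per 1% land cover; ``translate_effect`` converts them to
0 -> 100% contrasts (odds multipliers, mg/L differences, extra families).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .propensity import DEFAULT_CONTINUOUS, DEFAULT_CATEGORICAL, Stratification

Z95 = stats.norm.ppf(0.975)  # 1.959964...


@dataclass
class ModelSpec:
    """Response model description: error family and covariate entry."""

    response: str
    family: str                      # 'binomial' | 'gaussian' | 'poisson'
    treatment: str = "arable_catch"
    continuous: list[str] = field(default_factory=lambda: list(DEFAULT_CONTINUOUS))
    categorical: list[str] = field(default_factory=lambda: list(DEFAULT_CATEGORICAL))
    notes: str = ""

    def glm_family(self):
        fams = {"binomial": sm.families.Binomial,
                "gaussian": sm.families.Gaussian,
                "poisson": sm.families.Poisson}
        if self.family not in fams:
            raise ValueError(f"unknown family {self.family!r}")
        return fams[self.family]()


@dataclass
class GroupEffect:
    """Treatment coefficient (per 1% cover, link scale) from one stratum."""

    group: int
    coef: float
    se: float
    n: int

    def __post_init__(self):
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValueError(f"group {self.group}: standard error must be positive")


@dataclass
class PooledEffect:
    """Weighted pooled effect with unadjusted and (optionally) widened CIs."""

    response: str
    family: str
    estimate: float
    se: float                       # sqrt(sum SE_k^2 (n_k/N)^2)
    k: int
    n: int
    ci_halfwidth: float = np.nan    # 1.96 * se
    adj_halfwidth: float = np.nan   # widened (NaN until adjust_fcr)
    significant: bool | None = None
    excluded_groups: list[int] = field(default_factory=list)

    @property
    def ci(self) -> tuple[float, float]:
        return self.estimate - self.ci_halfwidth, self.estimate + self.ci_halfwidth

    @property
    def adj_ci(self) -> tuple[float, float]:
        hw = self.ci_halfwidth if np.isnan(self.adj_halfwidth) else self.adj_halfwidth
        return self.estimate - hw, self.estimate + hw

    @property
    def odds_ratio(self) -> float | None:
        """Per-1% odds ratio for binomial responses (<1 decrease, >1 increase)."""
        return float(np.exp(self.estimate)) if self.family == "binomial" else None

    @property
    def odds_ratio_ci(self) -> tuple[float, float] | None:
        if self.family != "binomial":
            return None
        lo, hi = self.adj_ci
        return float(np.exp(lo)), float(np.exp(hi))


# ---------------------------------------------------------------------------
# design and single-model fit

def _design(sub: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(sub)), spec.treatment: sub[spec.treatment].to_numpy(float)}
    for c in spec.continuous:
        cols[c] = sub[c].to_numpy(float)
    X = pd.DataFrame(cols, index=sub.index)
    for c in spec.categorical:
        d = pd.get_dummies(sub[c].astype(str), prefix=c, drop_first=True, dtype=float)
        X = pd.concat([X, d], axis=1)
    # drop within-subset constant columns (absent factor levels etc.)
    keep = ["intercept"] + [c for c in X.columns[1:] if X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    if spec.treatment in dropped:
        raise ValueError("treatment is constant within this subset")
    return X[keep]


def _fit_glm(sub: pd.DataFrame, spec: ModelSpec):
    X = _design(sub, spec)
    y = sub[spec.response].to_numpy(float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError(f"{X.shape[0]} observations for {X.shape[1]} parameters")
    model = sm.GLM(y, X, family=spec.glm_family())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    return res, X


def fit_group_models(sites: pd.DataFrame, strat: Stratification,
                     spec: ModelSpec) -> list[GroupEffect]:
    """One GLM per propensity group; returns the treatment coefficient and
    its standard error for each usable group.

    Groups where the binomial fit separates (response constant, or absurd /
    non-finite treatment SE) are excluded with a warning; downstream pooling
    renormalizes the weights over the remaining groups.
    """
    labels = strat.labels.to_numpy()
    out: list[GroupEffect] = []
    for g in range(strat.k):
        sub = sites[labels == g]
        if spec.family == "binomial" and sub[spec.response].nunique() < 2:
            warnings.warn(f"group {g}: response constant (separation); excluded")
            continue
        try:
            res, _ = _fit_glm(sub, spec)
        except Exception as err:  # separation, singularity
            warnings.warn(f"group {g}: fit failed ({err}); excluded")
            continue
        coef = float(res.params[spec.treatment])
        se = float(res.bse[spec.treatment])
        if not np.isfinite(se) or se <= 0 or se > 1e3:
            warnings.warn(f"group {g}: degenerate treatment SE {se}; excluded")
            continue
        out.append(GroupEffect(group=g, coef=coef, se=se, n=len(sub)))
    return out


# ---------------------------------------------------------------------------
# pooling, adjustment, flags

def pool_estimates(groups: list[GroupEffect], response: str = "",
                   family: str = "gaussian") -> PooledEffect:
    """Weighted mean of group coefficients with the stratified-CI half-width
    1.96 * sqrt(sum SE_k^2 (n_k/N)^2)."""
    if not groups:
        raise ValueError("no group estimates to pool")
    n = np.array([g.n for g in groups], float)
    w = n / n.sum()
    coefs = np.array([g.coef for g in groups])
    ses = np.array([g.se for g in groups])
    est = float(w @ coefs)
    se = float(np.sqrt(np.sum(ses ** 2 * w ** 2)))
    return PooledEffect(response=response, family=family, estimate=est, se=se,
                        k=len(groups), n=int(n.sum()),
                        ci_halfwidth=float(Z95 * se))


def by_widening_factor(m: int, q: float = 0.05) -> float:
    """Ratio of the Benjamini–Yekutieli-adjusted z to the nominal z: the
    adjusted level is q / c(m) with c(m) = sum_{i=1..m} 1/i."""
    z_adj = stats.norm.ppf(1 - (q / harmonic(m)) / 2)
    return float(z_adj / stats.norm.ppf(1 - q / 2))


def harmonic(m: int) -> float:
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def adjust_fcr(pooled: list[PooledEffect], m: int | None = None,
               q: float = 0.05, method: str = "by") -> list[PooledEffect]:
    """Widen confidence limits across a family of m estimated effects.

    ``method='by'`` (default): every interval is recomputed at level
    q / c(m), c(m) the harmonic sum — a deterministic, conservative
    Benjamini–Yekutieli widening (m > 1 strictly widens).  ``method='fcr'``
    applies the selection-dependent false-coverage-rate level 1 - R*q/m,
    where R counts intervals excluding the null at the nominal level.
    Significance flags are re-evaluated on the widened intervals.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = len(pooled) if m is None else m
    if method == "by":
        z_adj = stats.norm.ppf(1 - (q / harmonic(m)) / 2)
    elif method == "fcr":
        r = sum(1 for p in pooled
                if abs(p.estimate) > stats.norm.ppf(1 - q / 2) * p.se)
        r = max(r, 1)
        z_adj = stats.norm.ppf(1 - (r * q / m) / 2)
    else:
        raise ValueError("method must be 'by' or 'fcr'")
    out = []
    for p in pooled:
        adj = replace(p, adj_halfwidth=float(z_adj * p.se))
        adj.significant = flag_significance(adj)
        out.append(adj)
    return out


def flag_significance(effect: PooledEffect) -> bool:
    """True when the (adjusted) interval excludes 0 on the link scale —
    equivalently excludes 1 on the odds-ratio scale for binomial models."""
    lo, hi = effect.adj_ci
    return bool(lo > 0 or hi < 0)


# ---------------------------------------------------------------------------
# estimator facade and direct comparator

class StratifiedEffectEstimator(BaseEstimator):
    """Propensity-stratified effect of percent land cover on one response.

    ``fit(X, y=None, groups=...)`` expects the site table as ``X`` (the
    response is a named column) and stratum labels in ``groups``.  Fitted
    attributes: ``group_effects_`` and ``pooled_``.
    """

    def __init__(self, spec: ModelSpec | None = None):
        self.spec = spec

    def fit(self, X: pd.DataFrame, y=None, groups=None):
        if self.spec is None:
            raise ValueError("a ModelSpec is required")
        if groups is None:
            raise ValueError("stratum labels must be passed as groups=")
        groups = pd.Series(np.asarray(groups), index=X.index)
        strat = Stratification(k=int(groups.max()) + 1, labels=groups,
                               boundaries=np.array([]))
        self.group_effects_ = fit_group_models(X, strat, self.spec)
        pooled = pool_estimates(self.group_effects_, response=self.spec.response,
                                family=self.spec.family)
        pooled.excluded_groups = sorted(
            set(range(strat.k)) - {g.group for g in self.group_effects_})
        self.pooled_ = pooled
        return self


def fit_direct_model(sites: pd.DataFrame, spec: ModelSpec) -> PooledEffect:
    """Conventional whole-data GLM of the response on treatment + covariates:
    the comparator for the propensity approach (same adjustment path)."""
    res, _ = _fit_glm(sites, spec)
    se = float(res.bse[spec.treatment])
    if not np.isfinite(se) or se <= 0:
        raise ValueError("direct model produced a degenerate treatment SE")
    return PooledEffect(response=spec.response, family=spec.family,
                        estimate=float(res.params[spec.treatment]), se=se,
                        k=1, n=len(sites), ci_halfwidth=float(Z95 * se))


# ---------------------------------------------------------------------------
# effect translation and spatial diagnostic

def translate_effect(effect: PooledEffect, delta: float = 100.0,
                     baseline: float | None = None,
                     scale: str | None = None) -> dict:
    """Express a per-1% effect as a contrast over ``delta`` percentage points.

    binomial -> odds multiplier exp(b*delta); log10-scale chemistry ->
    concentration difference baseline*(10^(b*delta) - 1) in original units
    (``baseline`` = concentration at 0% cover, covariates at reference
    values); poisson -> extra counts baseline*(exp(b*delta) - 1); gaussian ->
    b*delta in response units.
    """
    b = effect.estimate
    scale = scale or effect.family
    out = {"response": effect.response, "delta": delta, "scale": scale}
    if scale == "binomial":
        out["odds_multiplier"] = float(np.exp(b * delta))
    elif scale == "log10chem":
        if baseline is None:
            raise ValueError("log10 chemistry contrast needs a baseline concentration")
        out["difference"] = float(baseline * (10.0 ** (b * delta) - 1.0))
        out["baseline"] = baseline
        out["at_delta"] = float(baseline * 10.0 ** (b * delta))
    elif scale == "poisson":
        if baseline is None:
            raise ValueError("count contrast needs a baseline count")
        out["difference"] = float(baseline * (np.exp(b * delta) - 1.0))
        out["baseline"] = baseline
    elif scale == "gaussian":
        out["difference"] = float(b * delta)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return out


def reference_baseline(sites: pd.DataFrame, spec: ModelSpec) -> float:
    """Model prediction at 0% treatment cover with covariates held at sample
    medians (continuous) and modes (categorical), on the response scale."""
    res, X = _fit_glm(sites, spec)
    ref = {}
    for c in X.columns:
        if c == "intercept":
            ref[c] = 1.0
        elif c == spec.treatment:
            ref[c] = 0.0
        elif any(c.startswith(f"{cat}_") for cat in spec.categorical):
            ref[c] = float(X[c].mode().iloc[0])
        else:
            ref[c] = float(X[c].median())
    lin = float(np.asarray(res.params) @ np.array([ref[c] for c in X.columns]))
    if spec.family == "binomial":
        return float(1 / (1 + np.exp(-lin)))
    if spec.family == "poisson":
        return float(np.exp(lin))
    return lin


def residual_semivariogram(residuals, coords, bins: int = 10,
                           flat_tolerance: float = 0.35) -> pd.DataFrame:
    """Empirical semivariogram gamma(h) = mean squared residual difference / 2
    per distance bin, with a flat-profile flag.

    A flat profile (every bin within ``flat_tolerance`` of the sill, the
    residual variance) indicates no residual spatial autocorrelation.
    """
    r = np.asarray(residuals, float)
    xy = np.asarray(coords, float)
    if len(r) < 2:
        raise ValueError("need at least 2 residuals")
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(len(r), k=1)
    dist = d[iu]
    if dist.max() == 0:
        raise ValueError("all sites at one location")
    sq = (r[:, None] - r[None, :])[iu] ** 2 / 2.0
    edges = np.linspace(0, dist.max(), bins + 1)
    idx = np.clip(np.digitize(dist, edges) - 1, 0, bins - 1)
    rows = []
    for b in range(bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        rows.append({"h": float(edges[b:b + 2].mean()),
                     "gamma": float(sq[sel].mean()),
                     "n_pairs": int(sel.sum())})
    out = pd.DataFrame(rows)
    sill = float(r.var())
    out.attrs["sill"] = sill
    out.attrs["flat"] = bool(np.all(np.abs(out["gamma"] - sill) <= flat_tolerance * sill)) \
        if sill > 0 else True
    return out
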