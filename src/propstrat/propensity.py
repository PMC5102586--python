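"""Propensity modelling for a continuous land-cover treatment.

An additive regression of percent treatment cover on environmental
covariates — univariate cubic regression splines for continuous covariates,
categorical effects for lithology/soil, and a tensor-product spline surface
over Easting/Northing — produces per-site predictions ("propensity scores").
Sites are then stratified into k quantile groups of the scores, within which
treatment–covariate collinearity is much weaker; the balance report
quantifies that reduction.

The model is deliberately not simplified or term-selected: its only job is
to rank sites by expected treatment intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.preprocessing import SplineTransformer

DEFAULT_CONTINUOUS = ["altitude", "slope", "rainfall", "temperature",
                      "urban_pct", "other_agri_pct"]
DEFAULT_CATEGORICAL = ["lithology", "soil"]
DEFAULT_COORDS = ("easting", "northing")


@dataclass
class PropensityFit:
    """Predicted scores plus goodness of fit and a model description."""

    scores: pd.Series
    explained: float
    description: dict = field(default_factory=dict)
    model: "PropensityStratifier | None" = None


@dataclass
class Stratification:
    """Quantile-group assignment of sites by propensity score."""

    k: int
    labels: pd.Series           # integer group per site, 0 = lowest scores
    boundaries: np.ndarray      # k+1 score quantiles

    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.labels.to_numpy(), minlength=self.k)


class PropensityStratifier(RegressorMixin, BaseEstimator):
    """Additive spline model of treatment percent cover on covariates.

    Parameters
    ----------
    continuous, categorical : lists of covariate column names.
    coords : pair of coordinate columns entering as a tensor-product surface
        (set to None to drop the spatial term).
    n_knots : knots per univariate spline (cubic; n_knots+1 basis columns).
    spatial_knots : knots per marginal basis of the coordinate surface.
    k : default number of strata for :meth:`transform`.

    After ``fit``: ``coef_``, ``explained_variance_`` (in-sample R^2, in
    [0, 1]), ``feature_names_``, ``n_features_in_``.
    """

    def __init__(self, continuous=None, categorical=None, coords=DEFAULT_COORDS,
                 n_knots=5, spatial_knots=4, k=5):
        self.continuous = continuous
        self.categorical = categorical
        self.coords = coords
        self.n_knots = n_knots
        self.spatial_knots = spatial_knots
        self.k = k

    # -- design matrix ------------------------------------------------------
    def _resolved_columns(self, X: pd.DataFrame):
        cont = self.continuous if self.continuous is not None else \
            [c for c in DEFAULT_CONTINUOUS if c in X.columns]
        cat = self.categorical if self.categorical is not None else \
            [c for c in DEFAULT_CATEGORICAL if c in X.columns]
        return list(cont), list(cat)

    def _build_design(self, X: pd.DataFrame, fitting: bool) -> np.ndarray:
        blocks = [np.ones((len(X), 1))]
        names = ["intercept"]
        if fitting:
            self._splines_ = {}
            self._dropped_ = []
            self._levels_ = {}
        for col in self._cont_:
            x = X[col].to_numpy(float).reshape(-1, 1)
            if fitting:
                if np.ptp(x) == 0:
                    warnings.warn(f"covariate {col!r} is constant; term dropped")
                    self._dropped_.append(col)
                    continue
                st = SplineTransformer(n_knots=self.n_knots, degree=3,
                                       include_bias=False,
                                       extrapolation="continue")
                self._splines_[col] = st.fit(x)
            if col in self._dropped_:
                continue
            b = self._splines_[col].transform(x)
            blocks.append(b)
            names += [f"s({col}).{j}" for j in range(b.shape[1])]
        for col in self._cat_:
            if fitting:
                self._levels_[col] = sorted(pd.unique(X[col].astype(str)))
            levels = self._levels_[col]
            vals = X[col].astype(str).to_numpy()
            b = np.column_stack([(vals == lv).astype(float) for lv in levels[1:]]) \
                if len(levels) > 1 else np.zeros((len(X), 0))
            blocks.append(b)
            names += [f"{col}[{lv}]" for lv in levels[1:]]
        if self.coords is not None:
            e, n = self.coords
            xe = X[e].to_numpy(float).reshape(-1, 1)
            xn = X[n].to_numpy(float).reshape(-1, 1)
            if fitting:
                self._splines_["__east"] = SplineTransformer(
                    n_knots=self.spatial_knots, degree=3, include_bias=True,
                    extrapolation="continue").fit(xe)
                self._splines_["__north"] = SplineTransformer(
                    n_knots=self.spatial_knots, degree=3, include_bias=True,
                    extrapolation="continue").fit(xn)
            be = self._splines_["__east"].transform(xe)
            bn = self._splines_["__north"].transform(xn)
            tensor = np.einsum("ij,ik->ijk", be, bn).reshape(len(X), -1)
            blocks.append(tensor)
            names += [f"te({e},{n}).{j}" for j in range(tensor.shape[1])]
        if fitting:
            self.feature_names_ = names
        return np.hstack(blocks)

    # -- sklearn API --------------------------------------------------------
    def fit(self, X: pd.DataFrame, y) -> "PropensityStratifier":
        y = np.asarray(y, float)
        if y.dtype.kind not in "fiu" or not np.all(np.isfinite(y)):
            raise ValueError("treatment must be numeric and finite")
        self._cont_, self._cat_ = self._resolved_columns(X)
        D = self._build_design(X, fitting=True)
        coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
        self.coef_ = coef
        self.rank_ = int(rank)
        fitted = D @ coef
        sst = np.sum((y - y.mean()) ** 2)
        ssr = np.sum((y - fitted) ** 2)
        self.explained_variance_ = float(1.0 - ssr / sst) if sst > 0 else 0.0
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Propensity scores: predicted percent cover (unclipped — only the
        ranks matter for stratification)."""
        D = self._build_design(X, fitting=False)
        return D @ self.coef_

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Quantile-group labels for new sites under the fitted model."""
        return stratify_scores(self.predict(X), self.k).labels.to_numpy()

    def describe(self) -> dict:
        return {
            "continuous": list(self._cont_), "categorical": list(self._cat_),
            "dropped": list(self._dropped_),
            "n_knots": self.n_knots, "spatial_knots": self.spatial_knots,
            "n_features": len(self.feature_names_),
            "rank": self.rank_,
            "explained": self.explained_variance_,
        }


def fit_propensity(sites: pd.DataFrame, treatment_column: str,
                   spec: dict | None = None) -> PropensityFit:
    """Fit the additive propensity model and predict scores for all sites."""
    spec = spec or {}
    model = PropensityStratifier(**spec)
    cont, cat = model._resolved_columns(sites)
    needed = 10 * model.k
    if len(sites) < needed:
        raise ValueError(f"need at least {needed} sites for k={model.k} strata")
    model.fit(sites[cont + cat + list(model.coords or ())], sites[treatment_column])
    scores = pd.Series(model.predict(sites), index=sites.index, name="score")
    return PropensityFit(scores=scores, explained=model.explained_variance_,
                         description=model.describe(), model=model)


def stratify_scores(scores, k: int) -> Stratification:
    """Split scores into k quantile groups of near-equal size.

    Assignment is by rank (stable sort, ties broken by input order) so group
    sizes differ by at most one; with n = qk + r the first r groups take the
    extra site.  All-identical scores make stratification meaningless and
    raise an error; ties crossing a boundary emit a warning.
    """
    scores = pd.Series(scores).astype(float)
    if not 2 <= k <= 10:
        raise ValueError("k must be in 2..10")
    n = len(scores)
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} sites for k={k}")
    vals = scores.to_numpy()
    if np.ptp(vals) == 0:
        raise ValueError("all propensity scores identical: stratification is meaningless")
    order = np.argsort(vals, kind="stable")
    labels = np.empty(n, dtype=int)
    for g, chunk in enumerate(np.array_split(order, k)):
        labels[chunk] = g
    boundaries = np.quantile(vals, np.linspace(0, 1, k + 1))
    for g in range(k - 1):
        hi = vals[labels == g].max()
        lo = vals[labels == g + 1].min()
        if hi == lo:
            warnings.warn(f"tied scores straddle the boundary between groups "
                          f"{g} and {g + 1}; assignment follows input order")
    return Stratification(k=k, labels=pd.Series(labels, index=scores.index,
                                                name="group"),
                          boundaries=boundaries)


def stratify(fit: PropensityFit, k: int) -> Stratification:
    """Quantile-group the sites of a propensity fit (k = 4, 5 or 6 in the
    sensitivity design; 2..10 accepted)."""
    return stratify_scores(fit.scores, k)


# ---------------------------------------------------------------------------
# balance diagnostics

def _eta(treatment: np.ndarray, classes: np.ndarray) -> float:
    """Correlation ratio: sqrt of between-class share of treatment variance."""
    sst = np.sum((treatment - treatment.mean()) ** 2)
    if sst == 0:
        return 0.0
    ssb = 0.0
    for lv in np.unique(classes):
        sub = treatment[classes == lv]
        ssb += len(sub) * (sub.mean() - treatment.mean()) ** 2
    return float(np.sqrt(ssb / sst))


def _association(sites: pd.DataFrame, treatment_column: str, col: str,
                 categorical: bool) -> float:
    t = sites[treatment_column].to_numpy(float)
    if t.std() == 0:
        warnings.warn(f"zero-variance treatment; association with {col!r} set to 0")
        return 0.0
    if categorical:
        return _eta(t, sites[col].astype(str).to_numpy())
    x = sites[col].to_numpy(float)
    if x.std() == 0:
        return 0.0
    return float(np.corrcoef(x, t)[0, 1])


def balance_report(sites: pd.DataFrame, treatment_column: str,
                   strat: Stratification,
                   continuous: list[str] | None = None,
                   categorical: list[str] | None = None) -> pd.DataFrame:
    """Treatment–covariate association before vs within propensity groups.

    Continuous covariates use Pearson correlation; categorical ones the
    correlation ratio (eta).  Within-group values are averaged over groups
    weighted by group size.  The table carries a ``reduction`` attribute:
    1 - mean|within| / mean|overall| across covariates.
    """
    if continuous is None:
        continuous = [c for c in DEFAULT_CONTINUOUS if c in sites.columns]
    if categorical is None:
        categorical = [c for c in DEFAULT_CATEGORICAL if c in sites.columns]
    labels = strat.labels.to_numpy()
    sizes = strat.group_sizes()
    rows = []
    for col, is_cat in [(c, False) for c in continuous] + [(c, True) for c in categorical]:
        overall = _association(sites, treatment_column, col, is_cat)
        within = 0.0
        for g in range(strat.k):
            sub = sites[labels == g]
            within += sizes[g] / sizes.sum() * abs(
                _association(sub, treatment_column, col, is_cat))
        rows.append({"covariate": col, "type": "categorical" if is_cat else "continuous",
                     "overall": overall, "abs_overall": abs(overall),
                     "mean_within": within})
    report = pd.DataFrame(rows)
    mean_overall = report["abs_overall"].mean()
    mean_within = report["mean_within"].mean()
    report.attrs["mean_abs_overall"] = float(mean_overall)
    report.attrs["mean_abs_within"] = float(mean_within)
    # a ratio of sampling noise is meaningless when there is nothing to
    # remove: below the |r| noise floor ~3/sqrt(n) the reduction is 0
    noise_floor = 3.0 / np.sqrt(len(sites))
    if mean_overall <= noise_floor:
        report.attrs["reduction"] = 0.0
        report.attrs["negligible_overall_association"] = True
    else:
        report.attrs["reduction"] = float(1.0 - mean_within / mean_overall)
        report.attrs["negligible_overall_association"] = False
    return report
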