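"""Response-variable computation from raw monitoring-style inputs.

Covers the biotic indices (family richness, ASPT, functional-feeding-guild
Simpson diversity), left-censored annual-median chemistry via regression on
order statistics (ROS), and the dichotomization of River Habitat Survey
spot-check counts into binary habitat features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedMetricError(ValueError):
    """Raised when a biotic index is requested for an empty family set."""


# ---------------------------------------------------------------------------
# trait table helpers

def validate_trait_table(traits: pd.DataFrame) -> list[str]:
    """Check score range and affinity-simplex invariants; return guild columns."""
    guild_cols = [c for c in traits.columns if c.startswith("guild_")]
    if "family" not in traits.columns or "score" not in traits.columns:
        raise ValueError("trait table needs 'family' and 'score' columns")
    scores = traits["score"].to_numpy(float)
    if np.any(scores < 1) or np.any(scores > 10):
        raise ValueError("sensitivity scores must lie in [1, 10]")
    if guild_cols:
        sums = traits[guild_cols].to_numpy(float).sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("guild affinity rows must sum to 1")
    return guild_cols


# ---------------------------------------------------------------------------
# biotic indices

def combine_seasonal_presence(spring: set[str], autumn: set[str]) -> tuple[set[str], int]:
    """Union of spring and autumn family sets, with richness = its size."""
    presence = set(spring) | set(autumn)
    return presence, len(presence)


def compute_aspt(presence: set[str], traits: pd.DataFrame) -> float:
    """Average score per taxon: mean sensitivity score (1=tolerant,
    10=highly sensitive) over families present."""
    if not presence:
        raise UndefinedMetricError("ASPT is undefined for an empty family set")
    scores = traits.set_index("family")["score"]
    missing = sorted(set(presence) - set(scores.index))
    if missing:
        raise KeyError(f"families without sensitivity scores: {missing}")
    return float(scores.loc[sorted(presence)].mean())


def ffg_simpson(presence: set[str], traits: pd.DataFrame) -> float:
    """Simpson diversity (1 - sum p_g^2) of feeding-guild affinities.

    Guild proportions are the normalized column sums of the present
    families' affinity vectors; 0 means all affinity mass in one guild,
    values near 1 - 1/G mean equitability across the G guilds.
    """
    if not presence:
        raise UndefinedMetricError("guild diversity is undefined for an empty family set")
    guild_cols = validate_trait_table(traits)
    sub = traits[traits["family"].isin(presence)]
    missing = sorted(set(presence) - set(sub["family"]))
    if missing:
        raise KeyError(f"families without guild affinities: {missing}")
    totals = sub[guild_cols].to_numpy(float).sum(axis=0)
    p = totals / totals.sum()
    return float(1.0 - np.sum(p ** 2))


# ---------------------------------------------------------------------------
# censored chemistry

@dataclass
class CensoredSeries:
    """Monthly values with left-censoring flags; censored values are reported
    at the detection limit."""

    values: np.ndarray
    censored: np.ndarray
    detection_limit: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.censored = np.asarray(self.censored, bool)
        if self.values.shape != self.censored.shape:
            raise ValueError("values and censored flags must align")
        if len(self.values) < 2:
            raise ValueError("need at least 2 observations for a median")
        if np.any(self.censored) and not np.allclose(
                self.values[self.censored], self.detection_limit):
            raise ValueError("censored values must be reported at the detection limit")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CensoredSeries":
        return cls(frame["value"].to_numpy(float),
                   frame["censored"].to_numpy(bool),
                   float(frame["detection_limit"].iloc[0]))


def ros_median(series: CensoredSeries) -> float:
    """Annual median of a left-censored series.

    With fewer than 50% of observations censored the median rank falls in the
    uncensored tail, so the plain (lower-) median of the reported values is
    returned.  At >=50% censoring the median is estimated by regression on
    order statistics: log uncensored values are regressed on the normal
    quantiles of Weibull plotting positions i/(n+1) over the full ordered
    sample, censored values are imputed from the fit, and the median of the
    completed sample is returned.
    """
    vals, cens = series.values, series.censored
    n = len(vals)
    n_cens = int(cens.sum())
    if n_cens < 0.5 * n:
        return float(np.median(vals))
    if n_cens == n:
        raise ValueError("all observations censored: median not estimable")
    uncens_vals = vals[~cens]
    if np.any(uncens_vals <= 0):
        raise ValueError("non-positive uncensored values: log scale undefined")
    # censored observations occupy the lowest ranks (left-censoring below the
    # limit); ranks among themselves are arbitrary and do not affect the fit
    order_uncens = np.sort(uncens_vals)
    ranks_uncens = np.arange(n_cens + 1, n + 1)
    pp = ranks_uncens / (n + 1.0)
    q = stats.norm.ppf(pp)
    slope, intercept = np.polyfit(q, np.log(order_uncens), 1)
    ranks_cens = np.arange(1, n_cens + 1)
    q_cens = stats.norm.ppf(ranks_cens / (n + 1.0))
    imputed = np.exp(intercept + slope * q_cens)
    completed = np.concatenate([imputed, order_uncens])
    return float(np.median(completed))


def annual_median_table(chem: pd.DataFrame) -> pd.DataFrame:
    """Per site x determinand ROS medians from a long-format chemistry table
    (site_id, determinand, value, censored, detection_limit).

    Fully censored series have no estimable median; they are reported at the
    detection limit (an upper bound) with a warning, so one sensor-floor site
    cannot abort a whole-network analysis.
    """
    rows = []
    for (site, det), grp in chem.groupby(["site_id", "determinand"], sort=True):
        series = CensoredSeries.from_frame(grp)
        if series.censored.all():
            warnings.warn(f"{site}/{det}: all observations censored; median "
                          f"reported at the detection limit (upper bound)")
            med = series.detection_limit
        else:
            med = ros_median(series)
        rows.append({"site_id": site, "determinand": det, "median": med,
                     "censor_fraction": float(series.censored.mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RHS dichotomization

#: feature -> (count threshold out of 10 spot checks)
DEFAULT_RHS_THRESHOLDS: dict[str, int] = {
    "bankside_trees": 5,       # >=50% of spot checks with broadleaf woodland
    "macrophytes": 1,          # >=1 spot check with in-channel vegetation
    "filamentous_algae": 1,
    "silt_deposits": 1,        # >=1 spot check with sand/silt substrate
    "sediment_storage": 1,     # sweep-up bar presence (0/1 flag scaled to count)
}

#: alternative thresholds for sensitivity reruns
ALTERNATIVE_RHS_THRESHOLDS: dict[str, tuple[int, ...]] = {
    "bankside_trees": (4, 6),  # >=40% and >=60% of spot checks
    "macrophytes": (2,),
    "filamentous_algae": (2,),
    "silt_deposits": (2,),
    "sediment_storage": (),
}


def dichotomize_rhs(counts: pd.DataFrame | dict[str, int],
                    thresholds: dict[str, int] | None = None) -> pd.DataFrame:
    """Binary habitat features from spot-check hit counts (0-10 per feature).

    ``counts`` maps feature name -> hits out of 10 (or a DataFrame of
    ``spotchk_<feature>`` / feature columns, one row per site); a feature is
    scored Yes (1) when its count meets its threshold.
    """
    thresholds = dict(DEFAULT_RHS_THRESHOLDS if thresholds is None else thresholds)
    if isinstance(counts, dict):
        counts = pd.DataFrame([counts])
        squeeze = True
    else:
        squeeze = False
    out = {}
    for feat, thr in thresholds.items():
        col = f"spotchk_{feat}" if f"spotchk_{feat}" in counts.columns else feat
        if col not in counts.columns:
            raise KeyError(f"threshold names unknown feature {feat!r}")
        c = counts[col].to_numpy(float)
        if np.any((c < 0) | (c > 10)):
            raise ValueError(f"spot-check counts for {feat!r} must lie in [0, 10]")
        out[feat] = (c >= thr).astype(int)
    result = pd.DataFrame(out, index=counts.index)
    return result.iloc[0] if squeeze else result
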