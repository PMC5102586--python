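"""Biotic index, censored-median and dichotomization tests, each pinned to
an independently coded oracle where the computation is non-trivial."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from propstrat.metrics import (CensoredSeries, DEFAULT_RHS_THRESHOLDS,
                               UndefinedMetricError, annual_median_table,
                               combine_seasonal_presence, compute_aspt,
                               dichotomize_rhs, ffg_simpson, ros_median)
from propstrat.synthetic import generate_trait_table


# ---------------------------------------------------------------------------
# independent oracles

def ros_oracle(values, censored, limit):
    """Reference regression-on-order-statistics median, coded separately:
    Weibull plotting positions i/(n+1), censored observations in the lowest
    ranks, scipy.linregress of log values on normal quantiles."""
    values = np.asarray(values, float)
    censored = np.asarray(censored, bool)
    n = len(values)
    uncens = np.sort(values[~censored])
    c = int(censored.sum())
    pos_uncens = [(c + j + 1) / (n + 1) for j in range(len(uncens))]
    fit = stats.linregress(stats.norm.ppf(pos_uncens), np.log(uncens))
    imputed = [math.exp(fit.intercept + fit.slope * stats.norm.ppf((i + 1) / (n + 1)))
               for i in range(c)]
    return float(np.median(np.concatenate([imputed, uncens])))


def simpson_oracle(presence, traits):
    """Brute-force guild-proportion Simpson index."""
    guilds = [c for c in traits.columns if c.startswith("guild_")]
    totals = {g: 0.0 for g in guilds}
    for fam in presence:
        row = traits[traits["family"] == fam].iloc[0]
        for g in guilds:
            totals[g] += row[g]
    grand = sum(totals.values())
    return 1.0 - sum((v / grand) ** 2 for v in totals.values())


# ---------------------------------------------------------------------------
# seasonal combination and ASPT

def test_seasonal_union():
    presence, richness = combine_seasonal_presence({"A", "B"}, {"B", "C"})
    assert presence == {"A", "B", "C"} and richness == 3
    assert combine_seasonal_presence({"A", "B"}, {"A", "B"})[1] == 2
    assert combine_seasonal_presence(set(), set()) == (set(), 0)


def test_aspt_is_mean_of_scores(toy_trait_table):
    assert compute_aspt({"A", "B", "C"}, toy_trait_table) == pytest.approx(6.0)
    assert compute_aspt({"B"}, toy_trait_table) == pytest.approx(6.0)


def test_aspt_against_naive_sum():
    traits = generate_trait_table(23, 4, seed=13)
    present = set(traits["family"])
    naive = sum(traits.set_index("family")["score"][f] for f in present) / 23
    assert compute_aspt(present, traits) == pytest.approx(naive, abs=1e-12)


def test_aspt_errors(toy_trait_table):
    with pytest.raises(UndefinedMetricError):
        compute_aspt(set(), toy_trait_table)
    with pytest.raises(KeyError, match="ZZ"):
        compute_aspt({"A", "ZZ"}, toy_trait_table)


@settings(derandomize=True, max_examples=40)
@given(st.sets(st.sampled_from([f"F{i:03d}" for i in range(23)]), min_size=1))
def test_aspt_bounded_by_present_scores(present):
    traits = generate_trait_table(23, 4, seed=13)
    scores = traits.set_index("family")["score"]
    val = compute_aspt(present, traits)
    assert scores[list(present)].min() <= val <= scores[list(present)].max()


# ---------------------------------------------------------------------------
# feeding-guild Simpson diversity

def test_single_guild_dominance_gives_zero():
    traits = pd.DataFrame({"family": ["A", "B"], "score": [5, 5],
                           "guild_1": [1.0, 1.0], "guild_2": [0.0, 0.0]})
    assert ffg_simpson({"A", "B"}, traits) == pytest.approx(0.0)


def test_uniform_affinities_hit_equitability_bound():
    traits = pd.DataFrame({"family": ["A"], "score": [5],
                           **{f"guild_{g}": [0.25] for g in range(1, 5)}})
    assert ffg_simpson({"A"}, traits) == pytest.approx(0.75)


def test_simpson_matches_bruteforce(toy_trait_table):
    got = ffg_simpson({"A", "B", "C"}, toy_trait_table)
    assert got == pytest.approx(simpson_oracle({"A", "B", "C"}, toy_trait_table),
                                abs=1e-12)


@settings(derandomize=True, max_examples=40)
@given(st.sets(st.sampled_from([f"F{i:03d}" for i in range(15)]), min_size=1))
def test_simpson_bounded_by_guild_count(present):
    traits = generate_trait_table(15, 5, seed=2)
    val = ffg_simpson(present, traits)
    assert 0.0 <= val <= 1.0 - 1.0 / 5 + 1e-12


def test_simpson_empty_presence_raises(toy_trait_table):
    with pytest.raises(UndefinedMetricError):
        ffg_simpson(set(), toy_trait_table)


# ---------------------------------------------------------------------------
# ROS censored medians

def test_uncensored_median_is_plain_and_outlier_robust():
    s = CensoredSeries(np.array([1, 2, 3, 4, 100.0]), np.zeros(5, bool), 0.0)
    assert ros_median(s) == pytest.approx(3.0)


def test_below_half_censoring_uses_reported_values():
    vals = np.array([1.0] * 5 + [2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    cens = np.array([True] * 5 + [False] * 7)
    s = CensoredSeries(vals, cens, 1.0)
    assert ros_median(s) == pytest.approx(np.median(vals))


@pytest.mark.parametrize("seed", range(10))
def test_ros_matches_independent_oracle(seed):
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.normal(0.0, 0.8, 12))
    n_cens = rng.integers(6, 10)
    srt = np.sort(raw)
    limit = float((srt[n_cens - 1] + srt[n_cens]) / 2)
    cens = raw < limit
    vals = np.where(cens, limit, raw)
    got = ros_median(CensoredSeries(vals, cens, limit))
    assert got == pytest.approx(ros_oracle(vals, cens, limit), abs=1e-6)


def test_ros_errors():
    with pytest.raises(ValueError, match="censored"):
        ros_median(CensoredSeries(np.full(4, 1.0), np.ones(4, bool), 1.0))
    with pytest.raises(ValueError):
        CensoredSeries(np.array([1.0]), np.array([False]), 0.0)


@settings(derandomize=True, max_examples=30)
@given(st.floats(min_value=0.01, max_value=2.0))
def test_ros_monotone_in_data(shift):
    rng = np.random.default_rng(77)
    raw = np.exp(rng.normal(0, 0.5, 12))
    limit = np.quantile(raw, 0.6)
    cens = raw < limit
    base = ros_median(CensoredSeries(np.where(cens, limit, raw), cens, limit))
    raised_raw = raw * (1 + shift)
    raised_limit = limit * (1 + shift)
    cens2 = raised_raw < raised_limit
    raised = ros_median(CensoredSeries(np.where(cens2, raised_limit, raised_raw),
                                       cens2, raised_limit))
    assert raised >= base


def test_annual_median_table_groups_by_site_and_determinand():
    chem = pd.DataFrame({
        "site_id": ["s1"] * 4 + ["s2"] * 4,
        "determinand": ["nitrate"] * 8,
        "value": [1, 2, 3, 4, 10, 20, 30, 40.0],
        "censored": [False] * 8,
        "detection_limit": [0.0] * 8,
    })
    out = annual_median_table(chem).set_index("site_id")
    assert out.loc["s1", "median"] == pytest.approx(2.5)
    assert out.loc["s2", "median"] == pytest.approx(25.0)


# ---------------------------------------------------------------------------
# RHS dichotomization

def test_default_thresholds_match_feature_rules():
    row = {"bankside_trees": 5, "macrophytes": 0, "filamentous_algae": 1,
           "silt_deposits": 0, "sediment_storage": 2}
    out = dichotomize_rhs(row)
    assert out["bankside_trees"] == 1      # >=50% of spot checks
    assert out["filamentous_algae"] == 1   # >=1 spot check
    assert out["macrophytes"] == 0 and out["silt_deposits"] == 0


def test_alternative_threshold_changes_verdict():
    row = {"macrophytes": 1}
    assert dichotomize_rhs(row, {"macrophytes": 1})["macrophytes"] == 1
    assert dichotomize_rhs(row, {"macrophytes": 2})["macrophytes"] == 0


def test_unknown_feature_and_range_errors():
    with pytest.raises(KeyError, match="nonesuch"):
        dichotomize_rhs({"bankside_trees": 3}, {"nonesuch": 1})
    with pytest.raises(ValueError):
        dichotomize_rhs({"bankside_trees": 11}, {"bankside_trees": 5})


@settings(derandomize=True, max_examples=30)
@given(st.integers(min_value=0, max_value=9), st.integers(min_value=1, max_value=10))
def test_dichotomization_monotone_in_count(count, threshold):
    lo = dichotomize_rhs({"bankside_trees": count}, {"bankside_trees": threshold})
    hi = dichotomize_rhs({"bankside_trees": count + 1}, {"bankside_trees": threshold})
    assert hi["bankside_trees"] >= lo["bankside_trees"]


def test_dichotomize_frame_input(default_sites):
    sites, _, _ = default_sites
    out = dichotomize_rhs(sites, DEFAULT_RHS_THRESHOLDS)
    assert set(out.columns) == set(DEFAULT_RHS_THRESHOLDS)
    assert out.isin([0, 1]).all().all()
    assert len(out) == len(sites)
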