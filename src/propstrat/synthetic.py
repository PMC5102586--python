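"""Synthetic confounded-landscape generator.

Emulates the structure of national stream-monitoring data: environmental
covariates that vary smoothly in space, agricultural land-cover "treatments"
strongly collinear with those covariates, and habitat / chemistry /
macroinvertebrate responses with *known* effects per 1% land cover.  Because
the true effects and the true covariate->treatment signal are recorded, every
downstream stage (propensity fitting, stratification, pooled effect
estimation, commonality analysis) can be verified by parameter recovery.

Covariates
----------
altitude (m), slope (m/km), rainfall (mm/yr), temperature (degC) are smooth
random fields over Easting/Northing plus site noise; lithology (5 classes:
hard, chalk, limestone, sandstone, sedimentary) and soil (4 classes: loam,
clay, sand, other) are spatially blocked categorical fields.  urban_pct and
pasture/arable percentages complete the covariate set, mirroring the use of
"other agriculture" as a predictor for each treatment.

Treatments
----------
``arable_catch`` is the primary treatment: a standardized covariate index
eta* is mixed with Gaussian noise so that the index explains a target share
``confounding_strength`` of the treatment variance, scaled to percent cover
on [0, 100] (clipping fraction recorded).  ``arable_rip`` is a noisy copy of
the catchment value (riparian and catchment cover are strongly correlated in
real landscapes); ``pasture_catch``/``pasture_rip`` follow the same recipe
with a weaker covariate index.

Responses
---------
Each named response has a declared family: ``binary`` (Bernoulli, logistic
link), ``count`` (Poisson, log link), ``log10chem`` (Gaussian on log10
concentration) or ``gaussian``.  The linear predictor is
intercept + effect * primary_treatment + g(covariates), where g picks up
quadratic and threshold terms when ``nonlinearity`` > 0 — the feature that
makes naive linear adjustment biased while stratification remains valid.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

LITHOLOGY_CLASSES = ("hard", "chalk", "limestone", "sandstone", "sedimentary")
SOIL_CLASSES = ("loam", "clay", "sand", "other")

CONTINUOUS_COVARIATES = (
    "altitude", "slope", "rainfall", "temperature", "urban_pct", "other_agri_pct",
)
CATEGORICAL_COVARIATES = ("lithology", "soil")

#: response name -> (family, intercept on the link scale)
DEFAULT_RESPONSE_FAMILIES: dict[str, tuple[str, float]] = {
    "silt_deposits": ("binary", -0.7),
    "bankside_trees": ("binary", 0.3),
    "macrophytes": ("binary", 0.5),
    "filamentous_algae": ("binary", -0.4),
    "sediment_storage": ("binary", 0.0),
    "nitrate": ("log10chem", np.log10(2.0)),     # 2 mg/L at 0% cover
    "phosphate": ("log10chem", np.log10(0.08)),
    "richness": ("count", np.log(23.0)),          # ~23 families nationwide
    "aspt": ("gaussian", 5.8),
    "ffg_diversity": ("gaussian", 0.62),
}

#: default true effects per 1% primary treatment cover (link scale)
DEFAULT_TRUE_EFFECTS: dict[str, float] = {
    "silt_deposits": 0.01386,      # fourfold odds increase over 0 -> 100%
    "bankside_trees": -0.00693,
    "macrophytes": 0.0,
    "filamentous_algae": 0.0,
    "sediment_storage": 0.0,
    "nitrate": 0.00845,            # 2 -> ~14 mg/L over 0 -> 100%
    "phosphate": 0.00477,
    "richness": 0.00232,           # ~6 extra families over 0 -> 100%
    "aspt": -0.008,
    "ffg_diversity": 0.0002,
}

_RESPONSE_NOISE_SD = {"log10chem": 0.20, "gaussian": None}
_GAUSSIAN_SD = {"aspt": 0.55, "ffg_diversity": 0.08}

#: amplitude of the covariate contribution g() per response family (link scale)
_COVARIATE_AMPLITUDE = {"binary": 0.8, "count": 0.15, "log10chem": 0.25, "gaussian": 1.0}
_GAUSSIAN_COV_AMPLITUDE = {"aspt": 0.45, "ffg_diversity": 0.05}

RHS_FEATURES = (
    "bankside_trees", "macrophytes", "filamentous_algae",
    "silt_deposits", "sediment_storage",
)

#: per-draw log-odds intercepts for spot-check counts, calibrated so the
#: dichotomized features (>=1 or >=5 of 10 spot checks) are not degenerate
_SPOTCHECK_INTERCEPTS = {
    "bankside_trees": 0.0,        # threshold >=5/10: mid prevalence
    "macrophytes": -2.2,          # thresholds >=1: rare per draw
    "filamentous_algae": -2.6,
    "silt_deposits": -2.4,
    "sediment_storage": -2.2,
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic landscape.

    ``confounding_strength`` is the target share of primary-treatment variance
    explained by the covariates; ``nonlinearity`` in [0, 1] scales quadratic
    and threshold terms in both the treatment and response links.
    """

    n_sites: int = 1000
    seed: int = 0
    confounding_strength: float = 0.76
    nonlinearity: float = 0.0
    true_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_EFFECTS))
    response_families: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_FAMILIES))
    detection_limit: float = 0.3       # mg/L, applied to monthly chemistry
    censor_fraction_target: float = 0.25
    n_families: int = 76
    n_guilds: int = 5
    planned_strata: int = 5
    treatment_mean: float = 35.0
    treatment_sd: float = 18.0

    def validate(self) -> None:
        if self.n_sites < 10 * self.planned_strata:
            raise ValueError(
                f"n_sites={self.n_sites} too small: need at least "
                f"10 per planned stratum ({10 * self.planned_strata})")
        if not 0.0 <= self.confounding_strength <= 1.0:
            raise ValueError("confounding_strength must lie in [0, 1]")
        for name in self.true_effects:
            if name not in self.response_families:
                raise ValueError(
                    f"effect map names unknown response {name!r}; known: "
                    f"{sorted(self.response_families)}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated site table."""

    true_effects: dict[str, float]
    realized_confounding_r2: float
    seed: int
    config_hash: str
    clip_fractions: dict[str, float]
    primary_treatment: str = "arable_catch"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _smooth_field(rng: np.random.Generator, east: np.ndarray, north: np.ndarray,
                  n_waves: int = 4) -> np.ndarray:
    """Standardized smooth random surface: a sum of plane waves."""
    z = np.zeros_like(east)
    for _ in range(n_waves):
        theta = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(0.5, 2.5) * 2 * np.pi / 500.0
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        z += amp * np.sin(freq * (east * np.cos(theta) + north * np.sin(theta)) + phase)
    return (z - z.mean()) / z.std()


def _blocked_classes(rng: np.random.Generator, east: np.ndarray, north: np.ndarray,
                     classes: tuple[str, ...], centers_per_class: int = 4) -> np.ndarray:
    """Spatially blocked categorical field via nearest seeded centre."""
    n_classes = len(classes)
    cx = rng.uniform(0, 500, size=n_classes * centers_per_class)
    cy = rng.uniform(0, 500, size=n_classes * centers_per_class)
    labels = np.repeat(np.arange(n_classes), centers_per_class)
    d2 = (east[:, None] - cx[None, :]) ** 2 + (north[:, None] - cy[None, :]) ** 2
    return np.asarray(classes)[labels[np.argmin(d2, axis=1)]]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _covariate_index(z: Mapping[str, np.ndarray], lith: np.ndarray, soil: np.ndarray,
                     weights: Mapping[str, float], nonlinearity: float) -> np.ndarray:
    """Linear (+ optional quadratic/threshold) combination of covariates."""
    eta = np.zeros_like(z["altitude"])
    for name, w in weights.items():
        eta += w * z[name]
    lith_eff = {"hard": -0.6, "chalk": 0.9, "limestone": 0.3,
                "sandstone": 0.1, "sedimentary": -0.2}
    soil_eff = {"loam": 0.5, "clay": 0.0, "sand": 0.2, "other": -0.5}
    eta += np.vectorize(lith_eff.get)(lith)
    eta += np.vectorize(soil_eff.get)(soil)
    if nonlinearity > 0:
        eta += nonlinearity * (
            0.6 * (z["altitude"] ** 2 - 1.0)
            + 0.8 * np.where(z["rainfall"] > 0.5, z["rainfall"] - 0.5, 0.0)
            - 0.5 * z["temperature"] * np.abs(z["temperature"])
        )
    return _zscore(eta)


def _scaled_treatment(latent: np.ndarray, mean: float, sd: float) -> tuple[np.ndarray, float]:
    raw = mean + sd * latent
    clipped = np.clip(raw, 0.0, 100.0)
    return clipped, float(np.mean((raw < 0) | (raw > 100)))


def _conditional_mean_treatment(eta: np.ndarray, s: float, mean: float, sd: float,
                                n_nodes: int = 40) -> np.ndarray:
    """E[T | covariate index] under the clipped-Gaussian treatment model
    (Gauss–Hermite quadrature over the independent noise)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    latent = np.sqrt(s) * eta[:, None] + np.sqrt(1.0 - s) * nodes[None, :]
    vals = np.clip(mean + sd * latent, 0.0, 100.0)
    return vals @ (weights / weights.sum())


def generate_sites(config: GeneratorConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a site table plus the ground truth used to create it.

    Returns a DataFrame with one row per site (covariates, the four treatment
    columns, response columns, RHS spot-check counts) and a
    :class:`SyntheticTruth` recording the true effects, the realized
    covariate->treatment R-squared and clip fractions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_sites

    east = rng.uniform(0, 500, n)
    north = rng.uniform(0, 500, n)

    fields = {name: _smooth_field(rng, east, north) for name in
              ("altitude", "slope", "rainfall", "temperature", "urban", "pasture_base")}
    noise = {name: rng.normal(0, 0.45, n) for name in fields}

    altitude = np.clip(250 + 180 * fields["altitude"] + 60 * noise["altitude"], 0, None)
    slope = np.clip(8 + 6 * fields["slope"] + 3 * noise["slope"], 0.1, None)
    rainfall = np.clip(1100 + 450 * fields["rainfall"] + 120 * noise["rainfall"], 450, None)
    temperature = 9.0 + 1.4 * fields["temperature"] + 0.4 * noise["temperature"]
    urban_pct = 100.0 / (1 + np.exp(-(fields["urban"] * 1.2 + noise["urban"] - 2.2)))

    lith = _blocked_classes(rng, east, north, LITHOLOGY_CLASSES)
    soil = _blocked_classes(rng, east, north, SOIL_CLASSES)

    z = {
        "altitude": _zscore(altitude), "slope": _zscore(slope),
        "rainfall": _zscore(rainfall), "temperature": _zscore(temperature),
        "urban_pct": _zscore(urban_pct),
    }

    s = config.confounding_strength
    clip_fracs: dict[str, float] = {}

    # pasture first (weaker covariate signal), then arable with pasture as a
    # negatively weighted "other agriculture" covariate — mirrors real
    # landscapes where the two land uses displace each other.
    pasture_weights = {"altitude": -0.5, "rainfall": 0.4, "temperature": -0.6,
                       "slope": 0.3, "urban_pct": -0.3}
    eta_pasture = _covariate_index(z, lith, soil, pasture_weights, config.nonlinearity)
    s_pasture = 0.6 * s
    lat_pasture = (np.sqrt(s_pasture) * eta_pasture
                   + np.sqrt(1 - s_pasture) * rng.normal(0, 1, n))
    pasture_catch, clip_fracs["pasture_catch"] = _scaled_treatment(
        lat_pasture, config.treatment_mean, config.treatment_sd)

    z_arable = dict(z)
    z_arable["other_agri_pct"] = _zscore(pasture_catch)
    arable_weights = {"altitude": -0.8, "rainfall": -0.7, "temperature": 0.5,
                      "slope": -0.4, "urban_pct": -0.3, "other_agri_pct": -0.5}
    eta_arable = _covariate_index(z_arable, lith, soil, arable_weights, config.nonlinearity)
    lat_arable = np.sqrt(s) * eta_arable + np.sqrt(1 - s) * rng.normal(0, 1, n)
    arable_catch, clip_fracs["arable_catch"] = _scaled_treatment(
        lat_arable, config.treatment_mean, config.treatment_sd)

    # riparian covers: strongly correlated noisy copies of the catchment values
    rho = 0.85
    for base, name in ((lat_arable, "arable_rip"), (lat_pasture, "pasture_rip")):
        lat_rip = rho * base + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, n)
        col, clip_fracs[name] = _scaled_treatment(
            lat_rip, config.treatment_mean, config.treatment_sd)
        if name == "arable_rip":
            arable_rip = col
        else:
            pasture_rip = col

    # realized covariate->treatment R^2 for the primary treatment
    cond_mean = _conditional_mean_treatment(
        eta_arable, s, config.treatment_mean, config.treatment_sd)
    var_t = arable_catch.var()
    realized_r2 = float(1.0 - np.mean((arable_catch - cond_mean) ** 2) / var_t) \
        if var_t > 0 else 0.0

    table = pd.DataFrame({
        "site_id": [f"S{i:05d}" for i in range(n)],
        "easting": east, "northing": north,
        "altitude": altitude, "slope": slope, "rainfall": rainfall,
        "temperature": temperature, "urban_pct": urban_pct,
        "lithology": lith, "soil": soil,
        "arable_catch": arable_catch, "arable_rip": arable_rip,
        "pasture_catch": pasture_catch, "pasture_rip": pasture_rip,
    })
    table["other_agri_pct"] = pasture_catch  # covariate for arable models

    treat = arable_catch
    # response covariate index aligned with the treatment index (same signs)
    # so that covariates genuinely confound the treatment-response relation
    g_base = _covariate_index(z, lith, soil,
                              {"altitude": -0.5, "rainfall": -0.4, "temperature": 0.3,
                               "slope": -0.2, "urban_pct": -0.2},
                              config.nonlinearity)

    for name, effect in config.true_effects.items():
        family, intercept = config.response_families[name]
        amp = (_GAUSSIAN_COV_AMPLITUDE.get(name, 0.3) if family == "gaussian"
               else _COVARIATE_AMPLITUDE[family])
        lin = intercept + effect * treat + amp * g_base
        if family == "binary":
            p = 1.0 / (1.0 + np.exp(-lin))
            table[name] = rng.binomial(1, p)
        elif family == "count":
            table[name] = rng.poisson(np.exp(lin))
        elif family == "log10chem":
            table[name] = lin + rng.normal(0, _RESPONSE_NOISE_SD["log10chem"], n)
        elif family == "gaussian":
            table[name] = lin + rng.normal(0, _GAUSSIAN_SD.get(name, 0.5), n)
        else:
            raise ValueError(f"unknown response family {family!r} for {name!r}")

    # RHS spot-check counts: 10 Bernoulli draws per feature per site, latent
    # per-draw log-odds sharing the binary responses' linear predictors.
    for feat in RHS_FEATURES:
        if feat in config.true_effects:
            intercept = _SPOTCHECK_INTERCEPTS[feat]
            lin = intercept + config.true_effects[feat] * treat + 0.8 * g_base
            p = 1.0 / (1.0 + np.exp(-lin))
            table[f"spotchk_{feat}"] = rng.binomial(10, p)

    truth = SyntheticTruth(
        true_effects=dict(config.true_effects),
        realized_confounding_r2=realized_r2,
        seed=config.seed,
        config_hash=config.config_hash(),
        clip_fractions=clip_fracs,
    )
    return table, truth


def generate_trait_table(n_families: int, n_guilds: int, seed: int) -> pd.DataFrame:
    """Family-level trait table: sensitivity score (1-10) and a feeding-guild
    affinity vector on the simplex.

    Columns: ``family``, ``score``, ``guild_1`` .. ``guild_G``.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if n_guilds < 2:
        raise ValueError("n_guilds must be >= 2: guild diversity is undefined "
                         "for a single guild")
    rng = np.random.default_rng(seed)
    scores = rng.integers(1, 11, size=n_families)
    affinities = rng.dirichlet(np.full(n_guilds, 0.8), size=n_families)
    out = pd.DataFrame({"family": [f"F{i:03d}" for i in range(n_families)],
                        "score": scores})
    for g in range(n_guilds):
        out[f"guild_{g + 1}"] = affinities[:, g]
    return out


def generate_censored_chemistry(n_months: int, true_median: float,
                                detection_limit: float, seed: int,
                                log_sd: float = 0.5) -> pd.DataFrame:
    """Monthly concentrations (log-normal around ``true_median``) with values
    below the detection limit reported *at* the limit and flagged censored.

    Returns columns ``value``, ``censored``, ``detection_limit``.
    """
    if n_months < 2:
        raise ValueError("need at least 2 monthly observations")
    if true_median <= 0:
        raise ValueError("true_median must be positive")
    if detection_limit < 0:
        raise ValueError("detection limit cannot be negative")
    rng = np.random.default_rng(seed)
    raw = np.exp(np.log(true_median) + rng.normal(0, log_sd, n_months))
    censored = raw < detection_limit
    values = np.where(censored, detection_limit, raw)
    return pd.DataFrame({"value": values, "censored": censored,
                         "detection_limit": detection_limit})


def generate_presence_table(sites: pd.DataFrame, traits: pd.DataFrame,
                            seed: int) -> pd.DataFrame:
    """Long-format seasonal presence records (site, season, family).

    Per site, the richness column fixes the number of distinct families in
    the spring+autumn union; families are sampled without replacement and
    assigned to spring, autumn or both, so the downstream union/richness
    computation recovers the generated count exactly.
    """
    rng = np.random.default_rng(seed)
    fams = traits["family"].to_numpy()
    records: list[tuple[str, str, str]] = []
    for site_id, rich in zip(sites["site_id"], sites["richness"]):
        r = int(min(rich, len(fams)))
        if r == 0:
            continue
        chosen = rng.choice(fams, size=r, replace=False)
        season_code = rng.integers(0, 3, size=r)  # 0 spring, 1 autumn, 2 both
        for fam, code in zip(chosen, season_code):
            if code in (0, 2):
                records.append((site_id, "spring", fam))
            if code in (1, 2):
                records.append((site_id, "autumn", fam))
    return pd.DataFrame(records, columns=["site_id", "season", "family"])


#: detection limits in mg/L, scaled to each determinand's working range
DEFAULT_DETECTION_LIMITS = {"nitrate": 0.3, "phosphate": 0.02}


def generate_chemistry_table(sites: pd.DataFrame, config: GeneratorConfig,
                             determinands: tuple[str, ...] = ("nitrate", "phosphate"),
                             n_months: int = 12,
                             detection_limits: Mapping[str, float] | None = None
                             ) -> pd.DataFrame:
    """Long-format monthly chemistry with detection-limit censoring, one
    series per site x determinand, medians centred on the site table's
    log10-concentration columns."""
    limits = dict(DEFAULT_DETECTION_LIMITS if detection_limits is None
                  else detection_limits)
    rng = np.random.default_rng(config.seed + 1)
    frames = []
    for det in determinands:
        if det not in sites.columns:
            continue
        for site_id, log10_med in zip(sites["site_id"], sites[det]):
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            series = generate_censored_chemistry(
                n_months, 10.0 ** log10_med,
                limits.get(det, config.detection_limit), sub_seed)
            series.insert(0, "month", np.arange(1, n_months + 1))
            series.insert(0, "determinand", det)
            series.insert(0, "site_id", site_id)
            frames.append(series)
    return pd.concat(frames, ignore_index=True)


def write_outputs(sites: pd.DataFrame, truth: SyntheticTruth, traits: pd.DataFrame,
                  outdir) -> None:
    """Write SiteTable/TraitTable CSVs and the truth JSON side by side."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites.to_csv(outdir / "sites.csv", index=False, float_format="%.10g")
    traits.to_csv(outdir / "traits.csv", index=False, float_format="%.10g")
    (outdir / "truth.json").write_text(truth.to_json())
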