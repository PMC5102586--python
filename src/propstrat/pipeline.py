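"""End-to-end orchestration: four treatment land covers x all responses.

For each treatment (arable / improved pasture, catchment / riparian scale)
the pipeline fits the propensity model on all sites, stratifies into k
quantile groups, reports covariate balance, fits within-group response GLMs,
pools the treatment coefficients with the stratified CI, widens limits
across the m models of each response family (Benjamini–Yekutieli), flags
significance, fits the direct whole-data comparator, and runs commonality
analysis on both arms.  A sensitivity suite reruns everything with k in
{4, 5, 6} and with the alternative habitat-feature dichotomization
thresholds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .commonality import compare_confounding, commonality_partition, group_commonality
from .effects import (ModelSpec, adjust_fcr, fit_direct_model, fit_group_models,
                      pool_estimates)
from .metrics import (ALTERNATIVE_RHS_THRESHOLDS, DEFAULT_RHS_THRESHOLDS,
                      annual_median_table, dichotomize_rhs)
from .propensity import balance_report, fit_propensity, stratify
from .synthetic import (GeneratorConfig, LITHOLOGY_CLASSES, SOIL_CLASSES,
                        generate_chemistry_table, generate_sites,
                        generate_trait_table)

TREATMENTS = ("arable_catch", "arable_rip", "pasture_catch", "pasture_rip")

#: response -> (family, adjustment family) ; chemistry enters as log10 units
DEFAULT_RESPONSES: dict[str, tuple[str, str]] = {
    "bankside_trees": ("binomial", "habitat"),
    "macrophytes": ("binomial", "habitat"),
    "filamentous_algae": ("binomial", "habitat"),
    "silt_deposits": ("binomial", "habitat"),
    "sediment_storage": ("binomial", "habitat"),
    "nitrate": ("gaussian", "biochem"),
    "phosphate": ("gaussian", "biochem"),
    "richness": ("gaussian", "biochem"),
    "aspt": ("gaussian", "biochem"),
    "ffg_diversity": ("gaussian", "biochem"),
}

BASE_COVARIATES = ["altitude", "slope", "rainfall", "temperature", "urban_pct"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    seed: int = 0
    generator: GeneratorConfig | None = None
    site_csv: str | None = None
    treatments: tuple[str, ...] = TREATMENTS
    responses: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSES))
    k: int = 5
    q: float = 0.05
    richness_family: str = "gaussian"     # or 'poisson'
    use_spotchecks: bool = True
    use_censored_chemistry: bool = False
    rhs_thresholds: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_RHS_THRESHOLDS))
    outdir: str | None = None

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.generator is None and self.site_csv is None:
            raise ValueError("either a generator config or a site CSV is required")
        for t in self.treatments:
            if t not in TREATMENTS:
                raise ValueError(f"unknown treatment {t!r}; allowed: {TREATMENTS}")


@dataclass
class RunReport:
    """All artifacts of one run, in memory."""

    results: pd.DataFrame
    balance: dict[str, pd.DataFrame]
    confounding: dict[str, object]
    propensity_fits: dict[str, dict]
    provenance: dict


def read_site_table(path) -> pd.DataFrame:
    """Read and validate a site CSV: columns, percent ranges and the
    lithology/soil class vocabularies; errors name offending rows."""
    sites = pd.read_csv(path)
    required = ["site_id", "easting", "northing"] + BASE_COVARIATES + ["lithology", "soil"]
    missing = [c for c in required if c not in sites.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    pct_cols = [c for c in sites.columns
                if c.endswith("_pct") or c in TREATMENTS]
    for c in pct_cols:
        bad = sites.index[(sites[c] < 0) | (sites[c] > 100)].tolist()
        if bad:
            raise ValueError(f"column {c!r}: percent outside [0, 100] at rows {bad[:10]}")
    for col, allowed in (("lithology", LITHOLOGY_CLASSES), ("soil", SOIL_CLASSES)):
        bad = sites.index[~sites[col].astype(str).isin(allowed)].tolist()
        if bad:
            raise ValueError(
                f"column {col!r}: unknown class at rows {bad[:10]}; "
                f"allowed classes: {', '.join(allowed)}")
    return sites


def _covariates_for(treatment: str) -> list[str]:
    """Covariate list: the opposite land use acts as 'other agriculture'."""
    other = "pasture_catch" if treatment.startswith("arable") else "arable_catch"
    return BASE_COVARIATES + [other]


def _model_spec(response: str, family: str, treatment: str,
                config: RunConfig) -> ModelSpec:
    if response == "richness":
        family = config.richness_family
    return ModelSpec(response=response, family=family, treatment=treatment,
                     continuous=_covariates_for(treatment),
                     categorical=["lithology", "soil"])


def _prepare_sites(config: RunConfig):
    if config.site_csv is not None:
        return read_site_table(config.site_csv), None
    gen = config.generator
    sites, truth = generate_sites(gen)
    if config.use_spotchecks:
        spot_cols = [c for c in sites.columns if c.startswith("spotchk_")]
        if spot_cols:
            thresholds = {f: t for f, t in config.rhs_thresholds.items()
                          if f"spotchk_{f}" in sites.columns}
            binary = dichotomize_rhs(sites, thresholds)
            for feat in binary.columns:
                sites[feat] = binary[feat]
    if config.use_censored_chemistry:
        chem = generate_chemistry_table(sites, gen)
        med = annual_median_table(chem).pivot(index="site_id", columns="determinand",
                                              values="median")
        for det in med.columns:
            sites[det] = np.log10(med.loc[sites["site_id"], det].to_numpy())
    return sites, truth


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full propensity analysis; returns the in-memory report
    and, when ``config.outdir`` is set, writes CSV/markdown/JSON artifacts."""
    config.validate()
    sites, truth = _prepare_sites(config)

    rows = []
    balance: dict[str, pd.DataFrame] = {}
    confounding: dict[str, object] = {}
    prop_fits: dict[str, dict] = {}

    for treatment in config.treatments:
        cont = _covariates_for(treatment)
        fit = fit_propensity(sites, treatment,
                             spec={"continuous": cont, "k": config.k})
        strat = stratify(fit, config.k)
        bal = balance_report(sites, treatment, strat, continuous=cont)
        balance[treatment] = bal
        prop_fits[treatment] = fit.description

        pooled_by_family: dict[str, list] = {}
        direct_by_family: dict[str, list] = {}
        prop_common: dict[str, float] = {}
        direct_common: dict[str, float] = {}
        for response, (family, adj_family) in config.responses.items():
            if response not in sites.columns:
                continue
            spec = _model_spec(response, family, treatment, config)
            try:
                groups = fit_group_models(sites, strat, spec)
                pooled = pool_estimates(groups, response=response, family=spec.family)
                direct = fit_direct_model(sites, spec)
            except Exception as err:
                raise RuntimeError(
                    f"stage failed for treatment={treatment} response={response}: {err}"
                ) from err
            pooled_by_family.setdefault(adj_family, []).append(pooled)
            direct_by_family.setdefault(adj_family, []).append(direct)
            try:
                prop_common[response] = group_commonality(sites, strat, spec)
                direct_common[response] = commonality_partition(sites, spec).common
            except Exception as err:
                warnings.warn(f"commonality skipped for {treatment}/{response}: {err}")

        for adj_family in pooled_by_family:
            m = len(pooled_by_family[adj_family]) * len(config.treatments)
            for arm, effects in (("propensity", pooled_by_family[adj_family]),
                                 ("direct", direct_by_family[adj_family])):
                for eff in adjust_fcr(effects, m=m, q=config.q):
                    lo, hi = eff.ci
                    alo, ahi = eff.adj_ci
                    rows.append({
                        "treatment": treatment, "response": eff.response,
                        "arm": arm, "scale": eff.family,
                        "estimate": eff.estimate, "se": eff.se,
                        "ci_low": lo, "ci_high": hi,
                        "adj_ci_low": alo, "adj_ci_high": ahi,
                        "odds_ratio": eff.odds_ratio,
                        "significant": eff.significant,
                        "k": eff.k, "N": eff.n, "m": m,
                    })

        if len(prop_common) >= 2:
            confounding[treatment] = compare_confounding(prop_common, direct_common)

    results = pd.DataFrame(rows)
    provenance = {
        "seed": config.seed,
        "k": config.k,
        "q": config.q,
        "n_sites": len(sites),
        "treatments": list(config.treatments),
        "version": __version__,
        "generator_hash": (config.generator.config_hash()
                           if config.generator is not None else None),
        "truth": (truth.to_json() if truth is not None else None),
    }
    report = RunReport(results=results, balance=balance, confounding=confounding,
                       propensity_fits=prop_fits, provenance=provenance)
    if config.outdir is not None:
        write_report(report, config.outdir)
    return report


def write_report(report: RunReport, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.results.to_csv(outdir / "results.csv", index=False, float_format="%.10g")
    for treatment, bal in report.balance.items():
        bal.to_csv(outdir / f"balance_{treatment}.csv", index=False,
                   float_format="%.10g")
    conf_rows = []
    for treatment, comp in report.confounding.items():
        for r, p, d in zip(comp.responses, comp.propensity_common, comp.direct_common):
            conf_rows.append({"treatment": treatment, "response": r,
                              "propensity_common": p, "direct_common": d,
                              "t": comp.t_statistic, "p_value": comp.p_value})
    if conf_rows:
        pd.DataFrame(conf_rows).to_csv(outdir / "commonality.csv", index=False,
                                       float_format="%.10g")
    (outdir / "provenance.json").write_text(
        json.dumps(report.provenance, indent=2, sort_keys=True))
    (outdir / "report.md").write_text(render_markdown(report))


def render_markdown(report: RunReport) -> str:
    """Forest-style markdown table of pooled effects per treatment."""
    lines = ["# Propensity analysis report", ""]
    res = report.results
    for treatment in res["treatment"].unique():
        lines += [f"## Treatment: {treatment}", "",
                  "| response | arm | estimate /1% | adj 95% CI | sig |",
                  "|---|---|---|---|---|"]
        sub = res[res["treatment"] == treatment]
        for _, r in sub.iterrows():
            lines.append(
                f"| {r['response']} | {r['arm']} | {r['estimate']:+.5f} | "
                f"[{r['adj_ci_low']:+.5f}, {r['adj_ci_high']:+.5f}] | "
                f"{'*' if r['significant'] else ''} |")
        bal = report.balance[treatment]
        lines += ["", f"Mean |association| reduction within groups: "
                      f"{bal.attrs['reduction']:.1%}", ""]
    return "\n".join(lines)


def sensitivity_suite(config: RunConfig, ks: tuple[int, ...] = (4, 5, 6),
                      thresholds: dict[str, tuple[int, ...]] | None = None
                      ) -> pd.DataFrame:
    """Rerun the analysis across stratum counts and alternative habitat
    dichotomization thresholds; returns estimate deltas and significance
    agreement against the base run."""
    from dataclasses import replace as dc_replace
    base = run_pipeline(config)
    base_res = base.results.set_index(["treatment", "response", "arm"])
    rows = []

    def compare(alt_res: pd.DataFrame, label: str):
        for key, r in alt_res.set_index(["treatment", "response", "arm"]).iterrows():
            if key not in base_res.index:
                continue
            b = base_res.loc[key]
            rows.append({
                "variant": label, "treatment": key[0], "response": key[1],
                "arm": key[2],
                "estimate": r["estimate"], "base_estimate": b["estimate"],
                "delta": r["estimate"] - b["estimate"],
                "significant": r["significant"],
                "agreement": bool(r["significant"] == b["significant"]),
                "same_sign": bool(np.sign(r["estimate"]) == np.sign(b["estimate"]))
                if r["estimate"] != 0 else True,
            })

    for k in ks:
        if k == config.k:
            continue
        alt = run_pipeline(dc_replace(config, k=k, outdir=None))
        compare(alt.results, f"k={k}")

    thresholds = ALTERNATIVE_RHS_THRESHOLDS if thresholds is None else thresholds
    for feat, alts in thresholds.items():
        for thr in alts:
            new_thr = dict(config.rhs_thresholds)
            new_thr[feat] = thr
            alt = run_pipeline(dc_replace(config, rhs_thresholds=new_thr, outdir=None))
            compare(alt.results[alt.results["response"] == feat],
                    f"{feat}>={thr}")
    out = pd.DataFrame(rows)
    if config.outdir is not None and not out.empty:
        Path(config.outdir).mkdir(parents=True, exist_ok=True)
        out.to_csv(Path(config.outdir) / "sensitivity.csv", index=False,
                   float_format="%.10g")
    return out
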