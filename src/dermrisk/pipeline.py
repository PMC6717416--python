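"""End-to-end assessment pipeline.

Stages, in order: ingest (read or synthesize concentrations and survey) →
censoring policy → summary statistics → per-metal distribution fitting and
selection → Monte Carlo dose simulation → risk characterization (pooled and
per brand/color stratum) → rank-correlation sensitivity.  A single
structured config drives every stage; all defaults that the dose model
needs but measurement tables cannot supply (exposure factors, iteration
count, censoring rules, the point-estimate convention) are surfaced there
rather than hidden in code.  Every run emits a JSON manifest echoing the
config, seeds, stage timings and the decisions taken, so outputs are fully
reproducible from the manifest alone.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, reference
from .data_io import (
    ConcentrationTable, LodDecision, apply_lod_policy_all, read_concentration_table,
    read_rfd_table, read_survey_table, summarize_concentrations, write_concentration_csv,
)
from .distributions import DistributionSpec, SelectionResult, fit_mle, select_best
from .exposure import DoseDistribution, ExposureFactors, simulate_dose, summarize_dose
from .risk import RiskResult, characterize, maximal_stratum, stratified_risk
from .sensitivity import SensitivityResult, sensitivity_analysis
from .synthetic import default_design, generate_concentrations, generate_survey

log = logging.getLogger("dermrisk")


class ConfigError(ValueError):
    """The run configuration is invalid."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    # 20,000 iterations for reported figures; the 2,000-iteration screening
    # preset is available as n_iter_preset: "screening"
    "n_iter": 20_000,
    "point_estimate": "median",
    "rfd_basis": "dermal",
    "lod": {"exclusion_fraction": 0.20, "substitution": "half-lod"},
    "concentrations": {"source": "synthetic"},
    "survey": {"source": "synthetic", "n": 370},
    "rfd": {"source": "packaged"},
    "exposure_factors": {
        "SA": 580.0,          # adult scalp area, cm²
        "SL": 1.45,           # product adherence, mg·cm⁻²
        "ABS": 0.001,         # absorbed fraction
        "EF": {"from": "survey"},   # applications per year; fallback 12
        "ED": 20.0,           # years of use; cancels out of the dose
        "BW": {"from": "survey"},   # kg; fallback 60
    },
    "fit": {"candidates": ["lognormal", "loggamma", "weibull", "pareto", "loglaplace"]},
}

N_ITER_PRESETS = {"reporting": 20_000, "screening": 2_000}

#: survey column backing each survey-derived factor, with its fixed fallback
_SURVEY_FACTORS = {"EF": ("frequency_per_year", 12.0), "BW": ("body_weight_kg", 60.0)}


def make_config(overrides: dict | None = None) -> dict:
    """The default config with a (possibly nested) override dict merged in."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict) and "family" not in v and "from" not in v:
                merge(dst[k], v)
            else:
                dst[k] = copy.deepcopy(v)

    if overrides:
        merge(cfg, overrides)
    preset = cfg.pop("n_iter_preset", None)
    if preset is not None:
        if preset not in N_ITER_PRESETS:
            raise ConfigError(f"unknown n_iter preset {preset!r}; choose from {sorted(N_ITER_PRESETS)}")
        cfg["n_iter"] = N_ITER_PRESETS[preset]
    if cfg["point_estimate"] not in ("median", "mean"):
        raise ConfigError("point_estimate must be 'median' or 'mean'")
    if cfg["rfd_basis"] not in ("dermal", "ingestion"):
        raise ConfigError("rfd_basis must be 'dermal' or 'ingestion'")
    if int(cfg["n_iter"]) < 1:
        raise ConfigError("n_iter must be >= 1")
    return cfg


def load_config(path: str | Path) -> dict:
    """Read a YAML (or JSON) config file and merge it over the defaults."""
    import yaml

    with open(path) as fh:
        try:
            user = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: config must be a mapping at top level")
    return make_config(user)


def _resolve_factor(name: str, spec, survey: pd.DataFrame | None):
    """Turn a config entry into a fixed value or DistributionSpec."""
    if isinstance(spec, (int, float)):
        return float(spec)
    if isinstance(spec, DistributionSpec):
        return spec
    if isinstance(spec, dict) and "family" in spec:
        return DistributionSpec(spec["family"], {k: float(v) for k, v in spec["params"].items()})
    if isinstance(spec, dict) and spec.get("from") == "survey":
        if name not in _SURVEY_FACTORS:
            raise ConfigError(f"factor {name} cannot be derived from the survey")
        column, fallback = _SURVEY_FACTORS[name]
        if survey is None or survey.empty:
            log.warning("factor %s: no survey available, falling back to fixed %s", name, fallback)
            return fallback
        values = survey[column].to_numpy(dtype=float)
        values = values[values > 0]
        return fit_mle(values, "lognormal")
    raise ConfigError(f"cannot interpret exposure factor {name}: {spec!r}")


def resolve_exposure_factors(cfg: dict, survey: pd.DataFrame | None) -> ExposureFactors:
    ef_cfg = cfg["exposure_factors"]
    return ExposureFactors(**{
        name: _resolve_factor(name, ef_cfg[name], survey)
        for name in ("SA", "SL", "ABS", "EF", "ED", "BW")
    })


@dataclass
class PipelineResult:
    """Everything one end-to-end run produced."""

    config: dict
    table: ConcentrationTable              # post-censoring-policy
    lod_decisions: list[LodDecision]
    summaries: pd.DataFrame
    fits: dict[str, SelectionResult]
    factors: ExposureFactors
    doses: dict[str, DoseDistribution]
    pooled_risk: RiskResult
    brand_risk: dict[str, RiskResult]
    color_risk: dict[str, RiskResult]
    sensitivity: dict[str, SensitivityResult]
    manifest: dict = field(default_factory=dict)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path | None = None, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full assessment and optionally write its reports to ``out_dir``."""
    if config is None:
        cfg = make_config()
    elif isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = make_config(config)

    seed = int(cfg["seed"])
    n_iter = int(cfg["n_iter"])
    if n_iter == 1:
        log.warning("n_iter=1: dose summaries will be degenerate")
    timings: dict[str, float] = {}
    digests: dict[str, str] = {}

    def stage(name):
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 4)

    # -- ingest ----------------------------------------------------------
    stage("ingest")
    conc_cfg = cfg["concentrations"]
    if conc_cfg.get("source") == "synthetic":
        table = generate_concentrations(default_design(), seed=seed)
    else:
        path = Path(conc_cfg["source"])
        if not path.exists():
            raise FileNotFoundError(f"concentration file not found: {path}")
        digests[str(path)] = _digest(path)
        table = read_concentration_table(path, conc_cfg.get("unit_map"))
    log.info("ingest: %d measurements, %d metals", len(table), len(table.metals))

    survey_cfg = cfg.get("survey") or {}
    survey = None
    if survey_cfg.get("source") == "synthetic":
        survey = generate_survey(int(survey_cfg.get("n", 370)), seed=seed + 1)
    elif survey_cfg.get("source"):
        spath = Path(survey_cfg["source"])
        digests[str(spath)] = _digest(spath)
        survey = read_survey_table(spath)

    rfd_cfg = cfg.get("rfd") or {}
    if rfd_cfg.get("source", "packaged") == "packaged":
        rfds = reference.rfd_table()
    else:
        rpath = Path(rfd_cfg["source"])
        digests[str(rpath)] = _digest(rpath)
        rfds = read_rfd_table(rpath)
    done("ingest")

    # -- censoring policy ------------------------------------------------
    stage("lod_policy")
    table, decisions = apply_lod_policy_all(
        table,
        exclusion_fraction=float(cfg["lod"]["exclusion_fraction"]),
        substitution=cfg["lod"]["substitution"],
    )
    excluded = tuple(d.metal for d in decisions if d.excluded)
    for d in decisions:
        if d.excluded:
            log.warning("censoring policy: %s excluded (%.1f%% below LOD)", d.metal, 100 * d.censored_fraction)
        elif d.n_imputed:
            log.warning("censoring policy: %s, %d value(s) imputed (%s)", d.metal, d.n_imputed, d.substitution)
    done("lod_policy")

    # -- summaries -------------------------------------------------------
    stage("summarize")
    summaries = pd.concat([
        summarize_concentrations(table),
        summarize_concentrations(table, "brand"),
        summarize_concentrations(table, "color"),
    ], ignore_index=True)
    done("summarize")

    # -- restrict assessment to metals with a reference dose ------------
    # (summaries above still cover every surviving metal)
    no_rfd = [m for m in table.metals if m not in rfds]
    if no_rfd:
        log.warning("no reference dose for %s: reported in summaries only, not assessed", no_rfd)
        table = ConcentrationTable(table.df.loc[~table.df["metal"].isin(no_rfd)])

    # -- distribution fitting -------------------------------------------
    stage("fit")
    candidates = tuple(cfg["fit"]["candidates"])
    fits = {m: select_best(table.values(m), candidates) for m in table.metals}
    for m, sel in fits.items():
        log.info("fit: %s -> %s (KS %.3f)", m, sel.best.family, sel.best.ks_stat)
    done("fit")

    # -- dose simulation -------------------------------------------------
    stage("simulate")
    factors = resolve_exposure_factors(cfg, survey)
    doses = {}
    for i, metal in enumerate(table.metals):
        doses[metal] = simulate_dose(
            fits[metal].best.spec, factors, n_iter=n_iter,
            seed=seed + 100 + i, retain_inputs=True, metal=metal,
        )
    done("simulate")

    # -- risk -------------------------------------------------------------
    stage("risk")
    point = cfg["point_estimate"]
    basis = cfg["rfd_basis"]
    pooled_doses = {m: summarize_dose(d, point) for m, d in doses.items()}
    pooled = characterize(pooled_doses, rfds, stratum="pooled", rfd_basis=basis,
                          point_estimate_used=point, excluded=excluded)
    brand_risk = stratified_risk(table, "brand", rfds, factors, n_iter=n_iter,
                                 seed=seed + 200, point_estimate=point,
                                 rfd_basis=basis, excluded=excluded)
    color_risk = stratified_risk(table, "color", rfds, factors, n_iter=n_iter,
                                 seed=seed + 300, point_estimate=point,
                                 rfd_basis=basis, excluded=excluded)
    done("risk")

    # -- sensitivity ------------------------------------------------------
    stage("sensitivity")
    sens = {m: sensitivity_analysis(d) for m, d in doses.items()}
    done("sensitivity")

    manifest = {
        "software": {"name": "dermrisk", "version": __version__},
        "config": cfg,
        "seed": seed,
        "n_iter": n_iter,
        "input_digests": digests,
        "stage_seconds": timings,
        "exposure_factors": factors.to_dict(),
        "decisions": {
            "lod": [vars(d) for d in decisions],
            "fit_winners": {m: sel.best.spec.to_dict() for m, sel in fits.items()},
            "fit_failures": {m: [vars(f) for f in sel.failures] for m, sel in fits.items() if sel.failures},
            "no_rfd": no_rfd,
            "rejections": {m: d.rejections for m, d in doses.items()},
            "maximal_brand": maximal_stratum(brand_risk),
            "maximal_color": maximal_stratum(color_risk),
        },
        "stages": ["ingest", "lod_policy", "summarize", "fit", "simulate", "risk", "sensitivity"],
    }

    result = PipelineResult(
        config=cfg, table=table, lod_decisions=decisions, summaries=summaries,
        fits=fits, factors=factors, doses=doses, pooled_risk=pooled,
        brand_risk=brand_risk, color_risk=color_risk, sensitivity=sens,
        manifest=manifest,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def fits_frame(fits: dict[str, SelectionResult]) -> pd.DataFrame:
    rows = []
    for metal in sorted(fits):
        sel = fits[metal]
        for rep in sel.reports:
            rows.append({
                "metal": metal, "family": rep.family, "rank": rep.rank,
                "params": json.dumps(rep.spec.to_dict()["params"]),
                "ks": rep.ks_stat, "ad": rep.ad_stat,
                "chi2": rep.chi2_stat, "chi2_bins": rep.chi2_bins, "status": "ok",
            })
        for f in sel.failures:
            rows.append({"metal": metal, "family": f.family, "rank": None,
                         "params": None, "ks": None, "ad": None, "chi2": None,
                         "chi2_bins": None, "status": f"failed: {f.reason}"})
    return pd.DataFrame(rows)


def doses_frame(doses: dict[str, DoseDistribution]) -> pd.DataFrame:
    rows = []
    for metal in sorted(doses):
        d = doses[metal]
        rows.append({"metal": metal, "n_iter": d.n_iter, "seed": d.seed,
                     "rejections": d.rejections, **d.summaries})
    return pd.DataFrame(rows)


def risk_frame(pooled: RiskResult, brand: dict[str, RiskResult], color: dict[str, RiskResult]) -> pd.DataFrame:
    rows = []

    def emit(kind: str, r: RiskResult) -> None:
        for metal in sorted(r.hq):
            rows.append({
                "stratum_type": kind, "stratum": r.stratum, "metal": metal,
                "dose": r.dose[metal], "rfd_basis": r.rfd_basis, "hq": r.hq[metal],
                "hi": r.hi, "hi_is_lower_bound": r.hi_is_lower_bound,
                "classification": r.classification, "note": "",
            })
        for metal in r.excluded:
            rows.append({
                "stratum_type": kind, "stratum": r.stratum, "metal": metal,
                "dose": None, "rfd_basis": r.rfd_basis, "hq": None,
                "hi": r.hi, "hi_is_lower_bound": r.hi_is_lower_bound,
                "classification": r.classification, "note": "excluded (censoring)",
            })
        if not r.assessable:
            rows.append({
                "stratum_type": kind, "stratum": r.stratum, "metal": None,
                "dose": None, "rfd_basis": r.rfd_basis, "hq": None, "hi": None,
                "hi_is_lower_bound": None, "classification": "not-assessable", "note": "",
            })

    emit("pooled", pooled)
    for key in sorted(brand):
        emit("brand", brand[key])
    for key in sorted(color):
        emit("color", color[key])
    return pd.DataFrame(rows)


def sensitivity_frame(sens: dict[str, SensitivityResult]) -> pd.DataFrame:
    rows = []
    for metal in sorted(sens):
        s = sens[metal]
        for name in s.rho:
            r = s.rho[name]
            rows.append({
                "metal": metal, "input": name,
                "rho": r,
                "abs_rank": (s.ordering.index(name) + 1) if name in s.ordering else None,
                "note": (s.notes or {}).get(name, ""),
            })
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, out_dir: str | Path, store_draws: bool = False) -> None:
    """Write the CSV reports and JSON manifest for a finished run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_concentration_csv(result.table, out / "concentrations_assessed.csv")
    result.summaries.to_csv(out / "summaries.csv", index=False)
    fits_frame(result.fits).to_csv(out / "fits.csv", index=False)
    doses_frame(result.doses).to_csv(out / "doses.csv", index=False)
    risk_frame(result.pooled_risk, result.brand_risk, result.color_risk).to_csv(
        out / "risk.csv", index=False)
    sensitivity_frame(result.sensitivity).to_csv(out / "sensitivity.csv", index=False)
    if store_draws:
        draws_dir = out / "draws"
        draws_dir.mkdir(exist_ok=True)
        for metal, d in result.doses.items():
            df = pd.DataFrame({"dose": d.draws})
            if d.inputs is not None:
                df = pd.concat([df, d.inputs], axis=1)
            df.to_csv(draws_dir / f"{metal}.csv.gz", index=False, compression="gzip")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
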