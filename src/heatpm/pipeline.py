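"""Configuration-driven orchestration of the full case-crossover analysis.

Stages: simulate (optional) -> exposure preparation (heat index, climate
percentiles, optional 3-day moving averages) -> cohort and strata -> model
menu fits (single-exposure, joint, joint-interaction; linear and spline
variants) -> OR contrasts, curves and surface -> two-stage heat->PM2.5
dependence contrast -> sensitivity refits (moving average, temporal
subcohorts). Every artifact lands under a run directory with the config and
seeds echoed; the filter ledger records counts at each cohort stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import basis as bas
from . import cohort as coh
from . import condlogit as cl
from . import dependence as dep
from . import design as dsg
from . import effects as eff
from . import heat as he
from . import synthetic as syn

logger = logging.getLogger(__name__)

MODEL_MENU = ("single-linear", "single-nonlinear", "joint-linear",
              "joint-nonlinear", "interaction-linear", "interaction-nonlinear")
_ALIASES = {"joint": "joint-nonlinear", "joint-interaction": "interaction-nonlinear"}


@dataclass
class RunConfig:
    """Everything one analysis run needs, serializable to YAML."""

    sim: syn.SimulationConfig = field(default_factory=syn.SimulationConfig)
    models: tuple[str, ...] = MODEL_MENU
    spline_df: int = 4            # single/joint nonlinear terms
    crossbasis_df: int = 3        # each margin of the interaction crossbasis
    pm_reference: float = 5.0     # ug/m3
    heat_reference: float | None = None   # percentile; None -> observed median
    pm_target: float = 10.0       # ug/m3, reported contrast level
    heat_target_pctl: float = 99.0
    moving_average_window: int | None = None   # sensitivity: e.g. 3
    subcohort_split_year: int | None = 2008    # sensitivity refit split
    resample_cases_under_truth: bool = True    # known-truth simulation mode
    mc_iterations: int = 5000
    adrd_fraction: float = 0.9
    snf_fraction: float = 0.05
    nonqualifying_source_fraction: float = 0.05
    out_dir: str | None = None

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = syn.SimulationConfig(**self.sim)
        self.models = tuple(_ALIASES.get(m, m) for m in self.models)
        unknown = set(self.models) - set(MODEL_MENU)
        if unknown:
            raise ValueError(f"unknown model menu entries: {sorted(unknown)}")
        if self.pm_reference <= 0:
            raise ValueError("PM2.5 reference must be positive")
        if (self.subcohort_split_year is not None
                and not (self.sim.date_start.year
                         < self.subcohort_split_year
                         <= self.sim.date_end.year)):
            raise ValueError("subcohort split year must fall inside the window")

    def to_yaml(self, path):
        d = asdict(self)
        d["sim"]["date_start"] = self.sim.date_start.isoformat()
        d["sim"]["date_end"] = self.sim.date_end.isoformat()
        for k in ("pm_link_coefs", "beta_true"):
            d["sim"][k] = [float(v) for v in d["sim"][k]]
        d["sim"]["panel_months"] = [int(v) for v in d["sim"]["panel_months"]]
        d["models"] = list(self.models)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


def prepare_exposures(panel: pd.DataFrame, climate: pd.DataFrame,
                      window: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Heat index, subtype percentiles and (optionally) moving averages.

    Returns the warm-season exposure table with heat_index, heat_pctl and
    pm25 columns, plus the percentile tables. Percentiles are computed on
    same-day warm-season values; when a moving-average window is requested
    both exposures are pre-averaged first (the April run-in supplies the
    early-May lags) and percentiles refer to the averaged series.
    """
    rec = panel.rename(columns={"tmax_c": "tmax", "rhmin_pct": "rhmin",
                                "pm25_ugm3": "pm25"}).copy()
    rec["date"] = pd.to_datetime(rec["date"])
    rec["heat_index"] = he.compute_heat_index(rec["tmax"].to_numpy(),
                                              rec["rhmin"].to_numpy())
    if window:
        rec = he.moving_average(rec, window=window,
                                value_cols=("heat_index", "pm25"))
    warm = rec[rec["date"].dt.month.isin(he.WARM_SEASON_MONTHS)].copy()
    tables = he.compute_percentiles(warm, climate)
    warm = warm.merge(climate[["zip", "subtype"]], on="zip", how="left")
    warm["heat_pctl"] = np.nan
    for subtype, table in tables.items():
        mask = (warm["subtype"] == subtype) & warm["heat_index"].notna()
        warm.loc[mask, "heat_pctl"] = table.percentile(
            warm.loc[mask, "heat_index"].to_numpy())
    return warm.dropna(subset=["heat_index", "pm25"]), tables


def _model_terms(name: str, heat_spec_lin, heat_spec_bs, pm_spec_lin,
                 pm_spec_bs, cb_spec):
    if name == "single-linear":
        return {"heat": [("heat_pctl", heat_spec_lin)],
                "pm": [("pm25", pm_spec_lin)]}
    if name == "single-nonlinear":
        return {"heat": [("heat_pctl", heat_spec_bs)],
                "pm": [("pm25", pm_spec_bs)]}
    if name == "joint-linear":
        return {"both": [("heat_pctl", heat_spec_lin), ("pm25", pm_spec_lin)]}
    if name == "joint-nonlinear":
        return {"both": [("heat_pctl", heat_spec_bs), ("pm25", pm_spec_bs)]}
    if name == "interaction-linear":
        return {"both": "interaction-linear"}
    if name == "interaction-nonlinear":
        return {"both": [(("heat_pctl", "pm25"), cb_spec)]}
    raise ValueError(name)


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the results bundle (dict)."""
    bundle: dict = {"config": config, "filter_ledger": {}}
    cfg = config.sim

    # -- simulate -----------------------------------------------------------
    climate = syn.gen_climate_map(cfg.n_zips, seed=cfg.rng_seed)
    panel = syn.gen_exposure_panel(climate, cfg)
    admissions = syn.gen_admissions(
        cfg, climate, adrd_fraction=config.adrd_fraction,
        snf_fraction=config.snf_fraction,
        nonqualifying_source_fraction=config.nonqualifying_source_fraction)
    bundle["climate"] = climate
    bundle["filter_ledger"]["admissions"] = len(admissions)
    bundle["filter_ledger"]["enrollees"] = admissions["enrollee_id"].nunique()

    # -- exposure preparation ----------------------------------------------
    exposures, pct_tables = prepare_exposures(
        panel, climate, window=config.moving_average_window)
    bundle["exposures"] = exposures
    bundle["percentile_tables"] = pct_tables

    # -- cohort and strata --------------------------------------------------
    events = coh.build_cohort(admissions, syn.SYNTHETIC_ADRD_CODES)
    bundle["filter_ledger"]["outcome_events"] = len(events)
    strata = coh.build_strata(events, exposures[
        ["zip", "date", "heat_index", "heat_pctl", "pm25"]])
    bundle["filter_ledger"]["strata_excluded_missing_exposure"] = (
        strata.attrs.get("n_strata_excluded", 0))
    bundle["filter_ledger"]["strata"] = strata["stratum_id"].nunique()

    bundle.update(analyze_strata(strata, config))

    if config.out_dir:
        write_bundle(bundle, Path(config.out_dir))
    return bundle


def analyze_strata(strata: pd.DataFrame, config: RunConfig) -> dict:
    """Model menu fits, contrasts, surface and two-stage analysis for an
    already-built long-format stratum table."""
    bundle: dict = {}
    cfg = config.sim
    heat_ref = (float(config.heat_reference) if config.heat_reference is not None
                else float(np.median(strata["heat_pctl"])))
    heat_lin = bas.BasisSpec(kind="linear", boundary=(0.0, 100.0),
                             reference=heat_ref)
    pm_vals = strata["pm25"].to_numpy()
    pm_lin = bas.BasisSpec.from_data(pm_vals, kind="linear",
                                     reference=config.pm_reference)
    heat_bs = bas.BasisSpec.from_data(strata["heat_pctl"].to_numpy(),
                                      df=config.spline_df, reference=heat_ref)
    pm_bs = bas.BasisSpec.from_data(pm_vals, df=config.spline_df,
                                    reference=config.pm_reference,
                                    boundary_quantiles=(0.0, 0.99))
    cb = bas.CrossbasisSpec(
        spec1=bas.BasisSpec.from_data(strata["heat_pctl"].to_numpy(),
                                      df=config.crossbasis_df,
                                      reference=heat_ref),
        spec2=bas.BasisSpec.from_data(pm_vals, df=config.crossbasis_df,
                                      reference=config.pm_reference,
                                      boundary_quantiles=(0.0, 0.99)))
    bundle["specs"] = {"heat_lin": heat_lin, "heat_bs": heat_bs,
                       "pm_lin": pm_lin, "pm_bs": pm_bs, "crossbasis": cb}

    if config.resample_cases_under_truth:
        # Known-truth simulation: re-draw the case day in each stratum under
        # the configured log-odds surface so recovery is verifiable.
        truth_terms = [("heat_pctl", heat_lin)]
        strata = syn.sample_case_days(
            strata.drop(columns="case_flag"), np.asarray(cfg.beta_true),
            lambda f: dsg.design_matrix(f, truth_terms),
            seed=int(np.random.SeedSequence([cfg.rng_seed, 4]).generate_state(1)[0]
                     % 2**31))
    bundle["strata"] = strata

    # -- fits and contrasts -------------------------------------------------
    # a 1x1 crossbasis of two linear specs is exactly (H, P, H*P)
    interaction_linear_terms = [
        (("heat_pctl", "pm25"),
         bas.CrossbasisSpec(spec1=heat_lin, spec2=pm_lin))]
    fits: dict = {}
    failures: dict = {}
    for model in config.models:
        spec_map = _model_terms(model, heat_lin, heat_bs, pm_lin, pm_bs, cb)
        for which, terms in spec_map.items():
            if terms == "interaction-linear":
                terms = interaction_linear_terms
            data = dsg.stratum_data(strata, terms)
            try:
                fits[(model, which)] = {"fit": cl.fit(data), "terms": terms}
            except cl.SeparationError as err:
                # model-level diagnostic: the cell is reported absent
                logger.warning("model %s (%s) not identifiable: %s",
                               model, which, err)
                failures[(model, which)] = str(err)
    bundle["fits"] = fits
    bundle["fit_failures"] = failures

    bundle["contrasts"] = _report_contrasts(config, fits, heat_ref,
                                            heat_lin, heat_bs, pm_lin, pm_bs, cb)

    if ("interaction-nonlinear", "both") in fits:
        f = fits[("interaction-nonlinear", "both")]["fit"]
        h_grid = np.linspace(0, 99, 34)
        p_lo, p_hi = np.quantile(pm_vals, [0.0, 0.99])
        p_grid = np.linspace(p_lo, p_hi, 34)
        bundle["surface"] = eff.surface(
            f, cb, h_grid, p_grid,
            observed_pairs=strata.rename(
                columns={"heat_pctl": "x1", "pm25": "x2"})[["x1", "x2"]],
            sparse_min_count=5)

        # -- two-stage dependence contrast ---------------------------------
        dmodel = dep.fit_dependence(strata, df=4)
        bundle["dependence"] = dmodel
        bundle["pm25_at_heat"] = dep.predict_pm25(
            dmodel, [heat_ref, config.heat_target_pctl])
        bundle["combined_or"] = dep.combined_contrast_mc(
            dmodel, f, cb, h_target=config.heat_target_pctl, h_ref=heat_ref,
            n_iter=config.mc_iterations,
            seed=int(np.random.SeedSequence([cfg.rng_seed, 5])
                     .generate_state(1)[0] % 2**31))

    # -- temporal subcohort sensitivity ------------------------------------
    if config.subcohort_split_year is not None:
        year = pd.to_datetime(
            strata.groupby("stratum_id")["date"].first()).dt.year
        split = {}
        for label, ids in (
                ("early", year.index[year < config.subcohort_split_year]),
                ("late", year.index[year >= config.subcohort_split_year])):
            sub = strata[strata["stratum_id"].isin(ids)]
            if sub["stratum_id"].nunique() < 50:
                split[label] = None
                continue
            data = dsg.stratum_data(sub, interaction_linear_terms)
            split[label] = cl.fit(data)
        bundle["subcohort_fits"] = split

    return bundle


def _report_contrasts(config, fits, heat_ref, heat_lin, heat_bs,
                      pm_lin, pm_bs, cb) -> pd.DataFrame:
    """Table-2-shaped grid: model x exposure contrast, OR with 95% CI."""
    rows = []
    for (model, which), entry in fits.items():
        f = entry["fit"]
        if model.startswith("single") or model.startswith("joint"):
            heat_spec = heat_lin if model.endswith("linear") else heat_bs
            pm_spec = pm_lin if model.endswith("linear") else pm_bs
            offset = 0
            if which in ("heat", "both"):
                cvec = np.zeros(len(f.beta))
                v = bas.contrast_vector(config.heat_target_pctl, heat_ref, heat_spec)
                cvec[offset:offset + len(v)] = v
                rows.append(_crow(model, "heat", config.heat_target_pctl,
                                  heat_ref, eff.or_contrast(f, cvec)))
            if which in ("pm", "both"):
                offset = heat_spec.df if which == "both" else 0
                cvec = np.zeros(len(f.beta))
                v = bas.contrast_vector(config.pm_target, config.pm_reference, pm_spec)
                cvec[offset:offset + len(v)] = v
                rows.append(_crow(model, "pm25", config.pm_target,
                                  config.pm_reference, eff.or_contrast(f, cvec)))
        elif model == "interaction-linear":
            # columns: heat, pm, heat (x) pm (1x1 crossbasis block)
            b3 = cl.FitResult(beta=f.beta, vcov=f.vcov, loglik=f.loglik,
                              n_strata=f.n_strata, converged=f.converged,
                              iterations=f.iterations)
            pm_med = float(pm_lin.reference)
            c_heat = eff.marginal_linear_or(
                b3, change=config.heat_target_pctl - heat_ref,
                at=pm_med, which="first")
            rows.append(_crow(model, "heat", config.heat_target_pctl,
                              heat_ref, c_heat))
            c_pm = eff.marginal_linear_or(
                b3, change=config.pm_target - config.pm_reference,
                at=heat_ref, which="second")
            rows.append(_crow(model, "pm25", config.pm_target,
                              config.pm_reference, c_pm))
        elif model == "interaction-nonlinear":
            for lab, target in (
                    ("heat", (config.heat_target_pctl, config.pm_reference)),
                    ("pm25", (heat_ref, config.pm_target)),
                    ("joint", (config.heat_target_pctl, config.pm_target))):
                c = eff.crossbasis_or(f, cb, target)
                rows.append(_crow(model, lab, target, cb.reference, c))
    return pd.DataFrame(rows)


def _crow(model, exposure, target, reference, c: eff.ORContrast) -> dict:
    lo, hi = c.ci
    return {"model": model, "exposure": exposure, "target": str(target),
            "reference": str(reference), "or": c.odds_ratio,
            "lo": lo, "hi": hi, "method": c.method}


def write_bundle(bundle: dict, out_dir: Path) -> None:
    """Persist the bundle: CSV artifacts, YAML config echo, filter ledger."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["config"].to_yaml(out_dir / "config.yaml")
    with open(out_dir / "filter_ledger.yaml", "w") as fh:
        yaml.safe_dump(bundle["filter_ledger"], fh, sort_keys=False)
    fmt = "%.10g"
    bundle["contrasts"].to_csv(out_dir / "contrasts.csv", index=False,
                               float_format=fmt)
    bundle["strata"].to_csv(out_dir / "strata.csv", index=False,
                            float_format=fmt)
    if "surface" in bundle:
        bundle["surface"].to_csv(out_dir / "surface.csv", index=False,
                                 float_format=fmt)
    if "pm25_at_heat" in bundle:
        bundle["pm25_at_heat"].to_csv(out_dir / "pm25_at_heat.csv",
                                      index=False, float_format=fmt)
    if "combined_or" in bundle:
        c = bundle["combined_or"]
        pd.DataFrame([{"or": c.odds_ratio, "lo": c.ci[0], "hi": c.ci[1],
                       "method": c.method}]).to_csv(
            out_dir / "combined_or.csv", index=False, float_format=fmt)
    fit_rows = []
    for (model, which), entry in bundle["fits"].items():
        f = entry["fit"]
        for j, (b, s) in enumerate(zip(f.beta, f.se())):
            fit_rows.append({"model": model, "submodel": which, "coef": j,
                             "beta": b, "se": s, "loglik": f.loglik,
                             "n_strata": f.n_strata})
    pd.DataFrame(fit_rows).to_csv(out_dir / "fits.csv", index=False,
                                  float_format=fmt)


def report(bundle: dict) -> pd.DataFrame:
    """Regenerate the summary OR grid from a results bundle."""
    return bundle["contrasts"].copy()
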