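"""Synthetic stand-ins for the claims and exposure inputs.

The real inputs — Medicare Part A admission records, 1-km PM2.5 surfaces and
gridMET meteorology — are restricted, so this module generates controlled
substitutes with the structural features the analysis depends on:

* warm-season daily maximum temperature with a seasonal sinusoid, a
  climate-subtype baseline and AR(1) day-to-day noise;
* right-skewed, strictly positive PM2.5 that rises with temperature
  (log-normal noise around a linear-in-temperature link), mirroring the
  summer photochemistry coupling between heat and fine particles;
* admission histories exercising every cohort filter (diagnosis-code
  position, skilled-nursing origin, admission-source codes, washout);
* case days drawn within time-stratified strata under a *known* log-odds
  surface, so parameter recovery is testable end to end.

Reproducibility: one root seed in :class:`SimulationConfig`; each operation
derives an independent child stream via ``np.random.SeedSequence([seed, k])``
with a fixed per-operation key, so modules can be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date

import numpy as np
import pandas as pd
import yaml

# The 18 Koppen-Geiger subtypes present in the contiguous US and their types.
KOPPEN_SUBTYPES: dict[str, str] = {
    "Am": "Tropical", "Aw": "Tropical",
    "BWh": "Arid", "BWk": "Arid", "BSh": "Arid", "BSk": "Arid",
    "Csa": "Temperate", "Csb": "Temperate", "Cfa": "Temperate",
    "Cfb": "Temperate",
    "Dsa": "Continental", "Dsb": "Continental", "Dsc": "Continental",
    "Dfa": "Continental", "Dfb": "Continental", "Dfc": "Continental",
    "Dwa": "Continental", "Dwb": "Continental",
}

# Warm-season baseline daily-max temperature (degC) by climate type.
_TYPE_BASELINE = {"Tropical": 31.0, "Arid": 30.0, "Temperate": 26.0,
                  "Continental": 22.0}

SYNTHETIC_ADRD_CODES: tuple[str, ...] = ("ADRD01", "ADRD02", "ADRD03")
QUALIFYING_SOURCE_CODES: tuple[str, ...] = ("1", "2", "7")
# 1 = non-healthcare facility, 2 = clinic referral, 7 = emergency room
_OTHER_SOURCE_CODES: tuple[str, ...] = ("4", "5", "6")

# per-operation child-stream keys
_STREAM_CLIMATE, _STREAM_PANEL, _STREAM_ADMISSIONS, _STREAM_CASES = 1, 2, 3, 4


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults emulate the study conditions.

    Defaults target a warm-season heat-index distribution centered near
    29 degC and a PM2.5 distribution with median near 10 ug/m3 and mean near
    12 ug/m3, the magnitudes typical of 2000-2016 US ZIP-day panels. The
    true hospitalization log-odds slope defaults to log(1.015)/49 per heat
    percentile point, i.e. an odds ratio of 1.015 for an extreme-heat
    (99th percentile) day versus the median.
    """

    n_zips: int = 100
    n_enrollees: int = 2000
    date_start: date = date(2006, 1, 1)
    date_end: date = date(2010, 12, 31)
    seasonal_amplitude: float = 8.0          # degC, peak-to-mean of sinusoid
    ar1_rho: float = 0.6                     # day-to-day noise persistence
    heat_noise_sd: float = 3.0               # degC, AR(1) innovation scale
    rh_mean: float = 45.0                    # % of daily-min relative humidity
    rh_sd: float = 15.0
    pm_link_coefs: tuple[float, ...] = (2.0, 0.30)   # ug/m3 intercept, per degC
    pm_lognoise_sd: float = 0.5              # log-ug/m3
    beta_true: tuple[float, ...] = (np.log(1.015) / 49.0,)
    panel_months: tuple[int, ...] = (4, 5, 6, 7, 8, 9)  # April run-in for lags
    rng_seed: int = 0

    def __post_init__(self):
        if isinstance(self.date_start, str):
            self.date_start = date.fromisoformat(self.date_start)
        if isinstance(self.date_end, str):
            self.date_end = date.fromisoformat(self.date_end)
        self.pm_link_coefs = tuple(float(v) for v in self.pm_link_coefs)
        self.beta_true = tuple(float(v) for v in self.beta_true)
        self.panel_months = tuple(int(v) for v in self.panel_months)
        if not -1 < self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in (-1, 1)")
        if self.pm_lognoise_sd < 0:
            raise ValueError("pm_lognoise_sd must be >= 0")
        if self.heat_noise_sd < 0:
            raise ValueError("heat_noise_sd must be >= 0")
        span_days = (self.date_end - self.date_start).days
        if span_days < 152:  # May 1 .. Sep 30
            raise ValueError("date range must span at least one full warm season")

    def child_rng(self, key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.rng_seed, key]))

    def to_yaml(self, path):
        d = asdict(self)
        d["date_start"] = self.date_start.isoformat()
        d["date_end"] = self.date_end.isoformat()
        for k in ("pm_link_coefs", "beta_true"):
            d[k] = [float(v) for v in d[k]]
        d["panel_months"] = [int(v) for v in d["panel_months"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("pm_link_coefs", "beta_true", "panel_months"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def gen_climate_map(n_zips: int, n_subtypes: int = 18, seed: int = 0) -> pd.DataFrame:
    """Assign each synthetic ZIP one Koppen-Geiger subtype.

    The first ``min(n_zips, n_subtypes)`` ZIPs get distinct subtypes so every
    requested subtype is represented whenever n_zips >= n_subtypes; remaining
    ZIPs draw uniformly. With n_zips < n_subtypes coverage is necessarily
    partial (first n_zips subtypes used), which is permitted.
    """
    if n_zips < 1:
        raise ValueError("n_zips must be >= 1")
    if not 1 <= n_subtypes <= len(KOPPEN_SUBTYPES):
        raise ValueError(f"n_subtypes must lie in [1, {len(KOPPEN_SUBTYPES)}]")
    rng = np.random.default_rng(seed)
    codes = list(KOPPEN_SUBTYPES)[:n_subtypes]
    n_fixed = min(n_zips, n_subtypes)
    assigned = codes[:n_fixed] + list(rng.choice(codes, size=n_zips - n_fixed))
    zips = [f"Z{i:05d}" for i in range(n_zips)]
    return pd.DataFrame({
        "zip": zips,
        "subtype": assigned,
        "type": [KOPPEN_SUBTYPES[s] for s in assigned],
    })


def gen_exposure_panel(climate: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    """ZIP-day panel of tmax, rhmin and PM2.5 over the configured window.

    tmax(z, t) = subtype baseline + seasonal sinusoid (peak ~July 20)
                 + AR(1) noise;  rhmin ~ Normal(rh_mean, rh_sd) clipped to
    [5, 100]; pm25 = exp(log link(tmax) + Normal(0, pm_lognoise_sd)) with the
    linear link c0 + c1*tmax (+ c2*tmax^2) floored at 0.5 ug/m3, giving a
    strictly positive right-skewed distribution that co-varies with heat.
    Only months in ``cfg.panel_months`` are emitted (the warm season plus an
    April run-in for trailing moving averages).
    """
    if climate.empty:
        raise ValueError("climate table is empty")
    rng = cfg.child_rng(_STREAM_PANEL)
    all_days = pd.date_range(cfg.date_start, cfg.date_end, freq="D")
    days = all_days[all_days.month.isin(cfg.panel_months)]
    n_days, n_zips = len(days), len(climate)

    doy = days.dayofyear.to_numpy()
    seasonal = cfg.seasonal_amplitude * np.cos(2 * np.pi * (doy - 201) / 365.25)
    base = climate["subtype"].map(
        lambda s: _TYPE_BASELINE[KOPPEN_SUBTYPES[s]]).to_numpy()

    # AR(1) noise, one chain per ZIP over the emitted days
    innov = rng.normal(0.0, cfg.heat_noise_sd, size=(n_zips, n_days))
    noise = np.empty_like(innov)
    if cfg.heat_noise_sd > 0 and abs(cfg.ar1_rho) > 0:
        stat_sd = cfg.heat_noise_sd / np.sqrt(1 - cfg.ar1_rho**2)
        noise[:, 0] = rng.normal(0.0, stat_sd, size=n_zips)
        for t in range(1, n_days):
            noise[:, t] = cfg.ar1_rho * noise[:, t - 1] + innov[:, t]
    else:
        noise = innov

    tmax = base[:, None] + seasonal[None, :] + noise
    rhmin = np.clip(rng.normal(cfg.rh_mean, cfg.rh_sd, size=(n_zips, n_days)),
                    5.0, 100.0)
    link = _pm_link(tmax, cfg.pm_link_coefs)
    pm25 = np.exp(np.log(link) + rng.normal(0.0, cfg.pm_lognoise_sd,
                                            size=(n_zips, n_days)))

    panel = pd.DataFrame({
        "zip": np.repeat(climate["zip"].to_numpy(), n_days),
        "date": np.tile(days.to_numpy(), n_zips),
        "tmax_c": tmax.ravel(),
        "rhmin_pct": rhmin.ravel(),
        "pm25_ugm3": pm25.ravel(),
    })
    return panel


def _pm_link(tmax: np.ndarray, coefs: tuple[float, ...]) -> np.ndarray:
    c = list(coefs) + [0.0, 0.0]
    link = c[0] + c[1] * tmax + c[2] * tmax**2
    return np.clip(link, 0.5, None)  # keep the log link defined


def gen_admissions(cfg: SimulationConfig, climate: pd.DataFrame,
                   adrd_fraction: float = 0.9,
                   snf_fraction: float = 0.05,
                   nonqualifying_source_fraction: float = 0.05,
                   mean_extra_admissions: float = 2.0) -> pd.DataFrame:
    """Per-enrollee admission histories spanning the study window.

    Every enrollee gets >= 1 admission; ``adrd_fraction`` of enrollees carry
    a dementia diagnosis code within the first ten billing positions of one
    admission; skilled-nursing origins and non-qualifying admission-source
    codes are injected at the given per-admission rates. Each enrollee keeps
    one residential ZIP for the whole window.
    """
    for name, frac in (("adrd_fraction", adrd_fraction),
                       ("snf_fraction", snf_fraction),
                       ("nonqualifying_source_fraction",
                        nonqualifying_source_fraction)):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = cfg.child_rng(_STREAM_ADMISSIONS)
    n = cfg.n_enrollees
    zips = rng.choice(climate["zip"].to_numpy(), size=n)
    n_adm = 1 + rng.poisson(mean_extra_admissions, size=n)
    has_adrd = rng.random(n) < adrd_fraction
    total = int(n_adm.sum())

    enrollee_idx = np.repeat(np.arange(n), n_adm)
    span = (cfg.date_end - cfg.date_start).days
    offsets = rng.integers(0, max(span - 30, 1), size=total)
    # date-sort within each enrollee block
    order = np.lexsort((offsets, enrollee_idx))
    offsets = offsets[order]
    # at most one admission per enrollee-day: nudge ties forward
    for _ in range(64):
        dup = (enrollee_idx[1:] == enrollee_idx[:-1]) & \
              (offsets[1:] <= offsets[:-1])
        if not dup.any():
            break
        offsets[1:][dup] = offsets[:-1][dup] + 1
    stays = rng.integers(1, 11, size=total)
    n_dx = rng.integers(3, 11, size=total)

    # which admission (row within block) carries the cohort code
    block_start = np.concatenate([[0], np.cumsum(n_adm)[:-1]])
    adrd_row = block_start + rng.integers(0, n_adm)  # one per enrollee
    is_adrd_row = np.zeros(total, dtype=bool)
    is_adrd_row[adrd_row[has_adrd]] = True
    adrd_code = rng.choice(SYNTHETIC_ADRD_CODES, size=total)
    adrd_pos = rng.integers(0, np.minimum(n_dx, 10))

    dx_pool = np.char.add("DX", rng.integers(100, 999, size=(total, 10))
                          .astype("U3")).astype("U6")  # room for cohort codes
    dx_codes = np.empty(total, dtype=object)
    for i in range(total):
        codes = dx_pool[i, :n_dx[i]]
        if is_adrd_row[i]:
            codes = codes.copy()
            codes[adrd_pos[i]] = adrd_code[i]
        dx_codes[i] = ";".join(codes)

    src = np.where(rng.random(total) < nonqualifying_source_fraction,
                   rng.choice(_OTHER_SOURCE_CODES, size=total),
                   rng.choice(QUALIFYING_SOURCE_CODES, size=total))
    start = pd.Timestamp(cfg.date_start)
    admit = start + pd.to_timedelta(offsets, unit="D")
    eids = np.char.add("E", np.char.zfill(np.arange(n).astype("U7"), 6))
    return pd.DataFrame({
        "enrollee_id": eids[enrollee_idx],
        "admit_date": admit,
        "discharge_date": admit + pd.to_timedelta(stays, unit="D"),
        "dx_codes": dx_codes,
        "source_code": src,
        "snf_flag": rng.random(total) < snf_fraction,
        "zip": zips[enrollee_idx],
    })


def sample_case_days(strata: pd.DataFrame, beta_true: np.ndarray,
                     design_fn, seed: int = 0) -> pd.DataFrame:
    """Draw one case day per stratum under a known log-odds surface.

    ``strata`` is long format with a ``stratum_id`` column (rows of one
    stratum contiguous) plus whatever exposure columns ``design_fn`` needs;
    ``design_fn(frame) -> (n_rows, p) array`` maps rows to the model basis.
    Within each stratum the case day is drawn with probability proportional
    to exp(x_d . beta_true); all other days become controls. Strata
    containing any non-finite design row are rejected (dropped with a
    ``n_rejected`` attribute on the result).
    """
    beta_true = np.atleast_1d(np.asarray(beta_true, dtype=float))
    frame = strata.reset_index(drop=True)
    X = np.asarray(design_fn(frame), dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ok_row = np.all(np.isfinite(X), axis=1)
    sid = frame["stratum_id"].to_numpy()
    bad = np.unique(sid[~ok_row])
    keep = ~np.isin(sid, bad)
    frame, X, sid = frame[keep].reset_index(drop=True), X[keep], sid[keep]
    if len(frame) == 0:
        raise ValueError("no stratum with complete exposures")

    change = np.flatnonzero(sid[1:] != sid[:-1]) + 1
    starts = np.concatenate([[0], change])
    sizes = np.diff(np.concatenate([starts, [len(sid)]]))
    if np.any(sizes < 2):
        raise ValueError("each stratum needs >= 2 candidate days")

    eta = X @ beta_true
    seg_max = np.maximum.reduceat(eta, starts)
    ex = np.exp(eta - np.repeat(seg_max, sizes))
    cum = np.cumsum(ex)
    tot = np.add.reduceat(ex, starts)
    rng = np.random.default_rng(seed)
    u = rng.random(len(starts)) * tot
    base = np.concatenate([[0.0], cum[starts[1:] - 1]])
    case_idx = np.searchsorted(cum, base + u, side="left")
    case_idx = np.clip(case_idx, starts, starts + sizes - 1)

    case_flag = np.zeros(len(frame), dtype=bool)
    case_flag[case_idx] = True
    out = frame.copy()
    out["case_flag"] = case_flag
    out.attrs["n_rejected"] = len(bad)
    return out
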