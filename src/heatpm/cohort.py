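"""Cohort eligibility filters and time-stratified case-crossover strata.

The cohort is defined by a *qualifying* hospitalization — the first
admission carrying a dementia-related diagnosis code within the first ten
billing positions. The *outcome* is the first warm-season (May-September)
admission occurring at least 30 days after the qualifying admission, not
originating from a skilled nursing facility, admitted from an allowed
source (non-healthcare facility, clinic referral or emergency room), and
with no further admission within 30 days of its discharge.

Control (referent) days are all calendar dates sharing the case day's
weekday, month and year — the time-stratified design — which always yields
3 or 4 controls per case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .heat import WARM_SEASON_MONTHS
from .synthetic import QUALIFYING_SOURCE_CODES

logger = logging.getLogger(__name__)


@dataclass
class EligibilityRules:
    """Configurable pieces of the outcome-selection contract."""

    washout_days: int = 30
    washout_anchor: str = "admission"   # or "discharge" of the qualifying stay
    readmission_gap_days: int = 30
    allowed_sources: tuple[str, ...] = QUALIFYING_SOURCE_CODES
    season_months: tuple[int, ...] = WARM_SEASON_MONTHS


def _split_codes(raw) -> list[str]:
    if not isinstance(raw, str):
        raise ValueError("dx_codes must be a ';'-delimited string")
    return [c.strip() for c in raw.split(";") if c.strip()]


def identify_qualifying(admissions: pd.DataFrame, adrd_codes) -> pd.DataFrame:
    """First admission per enrollee with a cohort code in the first ten
    diagnosis positions. Enrollees without one are absent from the output."""
    adrd_codes = set(adrd_codes)
    adm = admissions.sort_values(["enrollee_id", "admit_date"],
                                 kind="stable").reset_index(drop=True)
    valid = adm["dx_codes"].map(lambda c: isinstance(c, str))
    if not valid.all():
        for rec in adm[~valid].itertuples(index=False):
            logger.warning("malformed dx_codes for %s on %s; record skipped",
                           rec.enrollee_id, rec.admit_date)
    first10 = adm.loc[valid, "dx_codes"].str.split(";").map(
        lambda cs: bool({c.strip() for c in cs[:10]} & adrd_codes))
    hit = valid.copy()
    hit.loc[valid] = first10
    qual = adm[hit]
    return qual.groupby("enrollee_id", as_index=False).first()


def select_outcome(admissions: pd.DataFrame, qualifying_date,
                   rules: EligibilityRules | None = None) -> dict | None:
    """First admission of one enrollee passing every outcome filter.

    ``admissions`` holds all admissions of a single enrollee, date-sorted.
    Candidates failing any filter (off-season, inside the washout, SNF
    origin, disallowed source, or readmission within the post-discharge gap)
    are skipped and the search continues. Returns a dict with enrollee_id,
    case_date and zip, or None.
    """
    rules = rules or EligibilityRules()
    adm = admissions.sort_values("admit_date").reset_index(drop=True)
    qualifying_date = pd.Timestamp(qualifying_date)
    if rules.washout_anchor == "discharge":
        anchor_row = adm[pd.to_datetime(adm["admit_date"]) == qualifying_date]
        anchor = (pd.to_datetime(anchor_row["discharge_date"].iloc[0])
                  if len(anchor_row) else qualifying_date)
    else:
        anchor = qualifying_date
    earliest = anchor + pd.Timedelta(days=rules.washout_days)

    admit = pd.to_datetime(adm["admit_date"])
    discharge = pd.to_datetime(adm["discharge_date"])
    if (discharge < admit).any():
        logger.warning("admission with discharge before admit; flagged")
    for i in range(len(adm)):
        a, d = admit.iloc[i], discharge.iloc[i]
        if d < a:
            continue  # malformed interval: candidate rejected
        if a < earliest:
            continue
        if a.month not in rules.season_months:
            continue
        if bool(adm["snf_flag"].iloc[i]):
            continue
        if str(adm["source_code"].iloc[i]) not in rules.allowed_sources:
            continue
        # no other admission within the gap after this discharge
        gap_end = d + pd.Timedelta(days=rules.readmission_gap_days)
        later = admit[(admit > a) & (admit <= gap_end)]
        if len(later):
            continue
        return {"enrollee_id": adm["enrollee_id"].iloc[i], "case_date": a,
                "zip": adm["zip"].iloc[i]}
    return None


def build_cohort(admissions: pd.DataFrame, adrd_codes,
                 rules: EligibilityRules | None = None,
                 engine: str = "vectorized") -> pd.DataFrame:
    """identify_qualifying + outcome selection over all enrollees.

    Returns the outcome-event table (enrollee_id, case_date, zip) and logs
    the count surviving each stage. The default vectorized engine applies
    the same rules as :func:`select_outcome` (the per-enrollee reference
    path, selectable with ``engine="loop"``) in columnar form.
    """
    rules = rules or EligibilityRules()
    qual = identify_qualifying(admissions, adrd_codes)
    logger.info("enrollees with qualifying admission: %d", len(qual))
    if engine == "loop":
        events = []
        grouped = admissions.groupby("enrollee_id")
        for rec in qual.itertuples(index=False):
            ev = select_outcome(grouped.get_group(rec.enrollee_id),
                                rec.admit_date, rules)
            if ev is not None:
                events.append(ev)
        out = pd.DataFrame(events, columns=["enrollee_id", "case_date", "zip"])
    elif engine == "vectorized":
        out = _select_outcomes_vectorized(admissions, qual, rules)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    logger.info("enrollees with eligible outcome admission: %d", len(out))
    return out


def _select_outcomes_vectorized(admissions: pd.DataFrame, qual: pd.DataFrame,
                                rules: EligibilityRules) -> pd.DataFrame:
    adm = admissions.merge(
        qual[["enrollee_id", "admit_date", "discharge_date"]].rename(
            columns={"admit_date": "_qual_admit",
                     "discharge_date": "_qual_discharge"}),
        on="enrollee_id", how="inner")
    adm["admit_date"] = pd.to_datetime(adm["admit_date"])
    adm["discharge_date"] = pd.to_datetime(adm["discharge_date"])
    adm = adm.sort_values(["enrollee_id", "admit_date"],
                          kind="stable").reset_index(drop=True)
    anchor = pd.to_datetime(
        adm["_qual_discharge" if rules.washout_anchor == "discharge"
            else "_qual_admit"])
    earliest = anchor + pd.Timedelta(days=rules.washout_days)

    ok = adm["admit_date"] >= earliest
    ok &= adm["admit_date"].dt.month.isin(rules.season_months)
    ok &= ~adm["snf_flag"].astype(bool)
    ok &= adm["source_code"].astype(str).isin(rules.allowed_sources)
    ok &= adm["discharge_date"] >= adm["admit_date"]
    # readmission rule: the next admission of the same enrollee must not
    # fall within the gap after this candidate's discharge
    next_admit = adm.groupby("enrollee_id")["admit_date"].shift(-1)
    gap_end = adm["discharge_date"] + pd.Timedelta(days=rules.readmission_gap_days)
    ok &= next_admit.isna() | (next_admit > gap_end)

    first = adm[ok].groupby("enrollee_id", as_index=False).first()
    return first.rename(columns={"admit_date": "case_date"})[
        ["enrollee_id", "case_date", "zip"]]


def make_referents(case_date) -> list[pd.Timestamp]:
    """All same-weekday dates in the case's calendar month and year.

    Bidirectional: referents fall before and after the case day. Every
    month has 4 or 5 occurrences of each weekday, so there are always 3 or
    4 controls.
    """
    case = pd.Timestamp(case_date)
    month_days = pd.date_range(case.replace(day=1),
                               case.replace(day=case.days_in_month), freq="D")
    same = month_days[month_days.dayofweek == case.dayofweek]
    return [d for d in same if d != case]


def build_strata(events: pd.DataFrame, exposures: pd.DataFrame,
                 required: tuple[str, ...] = ("heat_pctl", "pm25"),
                 ) -> pd.DataFrame:
    """Attach exposures to case + referent days, long format.

    One stratum per outcome event, keyed by the event ZIP for every day in
    the stratum. Days missing any required exposure are dropped; strata
    reduced below two days (or losing their case day) are excluded, with
    counts logged.
    """
    if events.empty:
        return pd.DataFrame(columns=["stratum_id", "enrollee_id", "zip",
                                     "date", "case_flag", *required])
    case = pd.to_datetime(events["case_date"]).reset_index(drop=True)
    # same-weekday days of the case month: day-of-month f, f+7, ..., f+28
    # where f is the first occurrence of the case's weekday
    month_start = case.values.astype("datetime64[M]")
    first_dow = pd.DatetimeIndex(month_start).dayofweek.to_numpy()
    f = 1 + (case.dt.dayofweek.to_numpy() - first_dow) % 7
    dom = f[:, None] + 7 * np.arange(5)[None, :]          # (n_events, 5)
    days_in_month = case.dt.days_in_month.to_numpy()[:, None]
    valid = dom <= days_in_month
    dates = (month_start[:, None]
             + (dom - 1).astype("timedelta64[D]"))
    n_ev = len(events)
    long = pd.DataFrame({
        "stratum_id": np.repeat(np.arange(n_ev), 5)[valid.ravel()],
        "date": dates.ravel()[valid.ravel()],
    })
    long = long.merge(
        events.reset_index(drop=True).rename_axis("stratum_id").reset_index()[
            ["stratum_id", "enrollee_id", "zip", "case_date"]],
        on="stratum_id")
    long["case_flag"] = long["date"] == pd.to_datetime(long["case_date"])
    long = long.drop(columns="case_date")
    exp = exposures.copy()
    exp["date"] = pd.to_datetime(exp["date"])
    long = long.merge(exp, on=["zip", "date"], how="left")

    n0 = long["stratum_id"].nunique()
    complete = long[list(required)].notna().all(axis=1)
    long = long[complete]
    ok = long.groupby("stratum_id").agg(n=("case_flag", "size"),
                                        has_case=("case_flag", "any"))
    keep = ok.index[(ok["n"] >= 2) & ok["has_case"]]
    dropped = n0 - len(keep)
    if dropped:
        logger.info("excluded %d strata with missing exposures", dropped)
    out = long[long["stratum_id"].isin(keep)].reset_index(drop=True)
    out.attrs["n_strata_excluded"] = dropped
    return out
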