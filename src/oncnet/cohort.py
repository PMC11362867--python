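"""Cohort derivation: exclusion cascade, treatment events, analysis rows.

The study population is women with a breast biopsy followed by two cancer
diagnoses within 12 months. Exclusions are applied as a fixed cascade, each
excluded patient receiving the *first* failing rule in the documented order
so that exclusion tallies are reproducible:

1. cancer diagnosis in the 12 months before biopsy,
2. age outside 66-99 at biopsy,
3. not continuously enrolled +/-12 months around biopsy,
4. multiple primary cancers,
5. missing/invalid residential zip,
6. metastatic diagnosis within 90 days of biopsy (two-sided),
7. neoadjuvant chemo/radiotherapy before first surgery,
8. reconstructive surgery on the day of surgery,
9. no cancer-directed surgery within 12 months of biopsy.

Treatment anchors: *first* surgery (biopsy-to-surgery interval and the
operating surgeon), *last* surgery and *first* adjuvant chemo/radiotherapy
(the adjuvant interval runs from the last surgery). Delay is an interval
strictly greater than the cutoff (60 days; 90 in sensitivity analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .measures import (
    ONCOLOGIST_SPECIALTIES,
    care_density,
    degree_split,
    oncologist_supply,
)

logger = logging.getLogger(__name__)

EXCLUSION_ORDER = (
    "prior_cancer_dx",
    "age_out_of_range",
    "enrollment_gap",
    "multiple_cancers",
    "bad_zip",
    "metastatic_90d",
    "neoadjuvant",
    "same_day_reconstruction",
    "no_surgery",
)

DEPRIVATION_BINS = ("very low", "low", "medium", "high", "very high")
TERTILE_LABELS = ("low", "medium", "high")


# ---------------------------------------------------------------------------
# small pure helpers


def delay_flag(interval_days: int, cutoff: int = 60) -> bool:
    """True iff the interval strictly exceeds the cutoff ("greater than")."""
    if interval_days < 0:
        raise ValueError(f"interval_days must be >= 0, got {interval_days}")
    return interval_days > cutoff


def bin_deprivation(pct: float) -> str:
    """Zip poverty percentage -> 5-level deprivation bin (cuts 5/10/15/20)."""
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"deprivation percent must lie in [0, 100], got {pct}")
    if pct < 5.0:
        return "very low"
    if pct < 10.0:
        return "low"
    if pct < 15.0:
        return "medium"
    if pct < 20.0:
        return "high"
    return "very high"


def bin_tertiles(values) -> list[str]:
    """Nearest-rank tertiles (low/medium/high); ties go to the lower bin.

    With all-distinct values the bin sizes differ by at most one; with
    heavy ties the lower bins absorb the tied mass (all-equal input
    collapses to all "low").
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be nonempty")
    n = values.size
    ordered = np.sort(values)
    q1 = ordered[int(np.ceil(n / 3)) - 1]
    q2 = ordered[int(np.ceil(2 * n / 3)) - 1]
    return [
        "low" if v <= q1 else "medium" if v <= q2 else "high" for v in values
    ]


def bin_comorbidity(count: int) -> str:
    return "0" if count == 0 else "1" if count == 1 else ">=2"


# ---------------------------------------------------------------------------
# exclusion cascade


def apply_cohort_filters(
    patients: pd.DataFrame,
    encounters: pd.DataFrame,
    lookback_days: int = 365,
    followup_days: int = 365,
    metastatic_window: int = 90,
) -> pd.DataFrame:
    """Apply the exclusion cascade; returns patient_id/excluded/exclusion_reason.

    Violations become flags, never exceptions. Patients without a biopsy
    followed by two cancer diagnoses within ``followup_days`` do not qualify
    for the cohort at all and are dropped with a logged count.
    """
    ev = {e: g for e, g in encounters.groupby("event_class", observed=True)}

    def dates(event):
        sub = ev.get(event)
        if sub is None or sub.empty:
            return {}
        return {p: g.to_numpy() for p, g in sub.groupby("patient_id")["service_date"]}

    biopsy = dates("biopsy")
    cancer = dates("cancer_dx")
    surgery = dates("surgery")
    meta = dates("metastatic_dx")
    chemo = dates("chemotherapy")
    radio = dates("radiotherapy")
    recon = dates("reconstruction")

    age = patients.set_index("patient_id").get("age")
    pinfo = patients.set_index("patient_id")

    rows = []
    n_unqualified = 0
    for pid in patients.patient_id:
        b_dates = biopsy.get(pid)
        if b_dates is None:
            n_unqualified += 1
            continue
        b = int(b_dates.min())
        cx = cancer.get(pid, np.array([]))
        if (np.sum((cx >= b) & (cx <= b + followup_days))) < 2:
            n_unqualified += 1
            continue

        info = pinfo.loc[pid]
        sx = surgery.get(pid, np.array([]))
        sx_valid = sx[(sx >= b) & (sx <= b + followup_days)]
        first_s = int(sx_valid.min()) if sx_valid.size else None
        neo = np.concatenate([chemo.get(pid, np.array([])), radio.get(pid, np.array([]))])

        reason = "none"
        if np.any((cx >= b - lookback_days) & (cx < b)):
            reason = "prior_cancer_dx"
        elif age is not None and not 66 <= int(info["age"]) <= 99:
            reason = "age_out_of_range"
        elif not bool(info["enrolled_continuously"]):
            reason = "enrollment_gap"
        elif bool(info.get("multiple_primaries", False)):
            reason = "multiple_cancers"
        elif not isinstance(info["zip"], str) or info["zip"].strip() == "":
            reason = "bad_zip"
        elif np.any(np.abs(meta.get(pid, np.array([])) - b) <= metastatic_window):
            reason = "metastatic_90d"
        elif first_s is not None and np.any((neo >= b) & (neo < first_s)):
            reason = "neoadjuvant"
        elif first_s is not None and np.any(recon.get(pid, np.array([])) == first_s):
            reason = "same_day_reconstruction"
        elif first_s is None:
            reason = "no_surgery"
        rows.append({"patient_id": pid, "excluded": reason != "none",
                     "exclusion_reason": reason})
    if n_unqualified:
        logger.warning(
            "%d patient(s) lack a biopsy followed by 2 cancer diagnoses and were dropped",
            n_unqualified,
        )
    return pd.DataFrame(rows, columns=["patient_id", "excluded", "exclusion_reason"])


def exclusion_summary(flags: pd.DataFrame) -> pd.DataFrame:
    """Counts per exclusion reason, in cascade order (the flow-diagram table)."""
    counts = flags.exclusion_reason.value_counts()
    rows = [{"exclusion_reason": r, "n": int(counts.get(r, 0))}
            for r in (*EXCLUSION_ORDER, "none")]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# treatment events


def identify_treatments(
    encounters: pd.DataFrame,
    cohort_ids: set[str] | list[str],
    physicians: pd.DataFrame,
    network_nodes: set[str] | None = None,
    followup_days: int = 365,
) -> pd.DataFrame:
    """First/last surgery and first adjuvant therapy per cohort patient.

    Surgery must be performed by a surgeon, chemotherapy by a medical
    oncologist and radiotherapy by a radiation oncologist; when
    ``network_nodes`` is given, only physicians in the sharing network
    qualify. Patients whose earliest surgery event precedes their biopsy
    are dropped with a logged warning. The adjuvant date is the first
    qualifying event strictly after the *last* surgery.
    """
    cohort_ids = set(cohort_ids)
    spec = physicians.set_index("physician_id")["specialty"]
    enc = encounters[encounters.patient_id.isin(cohort_ids)].copy()
    enc["specialty"] = enc.physician_id.map(spec)
    if network_nodes is not None:
        in_net = enc.physician_id.isin(set(network_nodes))
    else:
        in_net = pd.Series(True, index=enc.index)

    bdates = enc[enc.event_class == "biopsy"].groupby("patient_id")["service_date"].min()

    surg = enc[(enc.event_class == "surgery") & (enc.specialty == "surgeon") & in_net]
    adjv = enc[
        ((enc.event_class == "chemotherapy") & (enc.specialty == "medical_oncologist"))
        | ((enc.event_class == "radiotherapy") & (enc.specialty == "radiation_oncologist"))
    ]
    adjv = adjv[in_net.reindex(adjv.index, fill_value=False)]

    rows = []
    n_dropped = 0
    for pid in sorted(cohort_ids):
        if pid not in bdates.index:
            continue
        b = int(bdates[pid])
        s = surg[surg.patient_id == pid]
        if s.empty:
            continue
        if int(s.service_date.min()) < b:
            n_dropped += 1
            continue
        s = s[s.service_date <= b + followup_days]
        if s.empty:
            continue
        first = s.loc[s.service_date.idxmin()]
        last_day = int(s.service_date.max())
        a = adjv[(adjv.patient_id == pid) & (adjv.service_date > last_day)]
        rows.append({
            "patient_id": pid,
            "biopsy_date": b,
            "first_surgery_date": int(first.service_date),
            "last_surgery_date": last_day,
            "surgeon_id": first.physician_id,
            "first_adjuvant_date": int(a.service_date.min()) if not a.empty else None,
        })
    if n_dropped:
        logger.warning("dropped %d patient(s) with surgery before biopsy", n_dropped)
    out = pd.DataFrame(rows, columns=[
        "patient_id", "biopsy_date", "first_surgery_date", "last_surgery_date",
        "surgeon_id", "first_adjuvant_date"])
    if len(out):
        out["first_adjuvant_date"] = out["first_adjuvant_date"].astype("Int64")
    return out


# ---------------------------------------------------------------------------
# analysis-row assembly


@dataclass
class CohortTables:
    """Analysis rows per treatment cohort plus assembly diagnostics."""

    surgery: pd.DataFrame
    adjuvant: pd.DataFrame
    exclusions: pd.DataFrame
    n_dropped_missing_measures: int = 0
    notes: dict = field(default_factory=dict)


def _teams(
    encounters: pd.DataFrame,
    bounds: pd.DataFrame,
    start_col: str,
    end_col: str,
    specialties: frozenset[str] | None,
    physician_spec: pd.Series,
) -> dict[str, set[str]]:
    """Physicians with >=1 encounter inside each patient's [start, end] window."""
    enc = encounters.merge(
        bounds[["patient_id", start_col, end_col]], on="patient_id", how="inner"
    )
    enc = enc[(enc.service_date >= enc[start_col]) & (enc.service_date <= enc[end_col])]
    if specialties is not None:
        enc = enc[enc.physician_id.map(physician_spec).isin(specialties)]
    return {p: set(g.physician_id) for p, g in enc.groupby("patient_id")}


def _visit_counts(
    encounters: pd.DataFrame, bounds: pd.DataFrame, start_col: str, end_col: str
) -> pd.Series:
    enc = encounters[encounters.event_class == "visit"].merge(
        bounds[["patient_id", start_col, end_col]], on="patient_id", how="inner"
    )
    enc = enc[(enc.service_date >= enc[start_col]) & (enc.service_date <= enc[end_col])]
    return enc.groupby("patient_id").size()


def assemble_analysis_rows(
    patients: pd.DataFrame,
    physicians: pd.DataFrame,
    encounters: pd.DataFrame,
    graph: nx.Graph,
    treatments: pd.DataFrame,
    cohort_flags: pd.DataFrame,
    linchpin: pd.DataFrame,
    over65_by_hrr: dict[str, float] | None = None,
    days_before_biopsy: int = 91,
    cutoff: int = 60,
) -> CohortTables:
    """Assemble regression-ready rows for the surgery and adjuvant cohorts.

    Surgery rows use the preoperative care density (all physicians seen from
    91 days before biopsy through first surgery, tertiled with a separate
    sole-clinician level); adjuvant rows use the postoperative care density
    (oncologists seen from last surgery through first adjuvant therapy).
    Encounter-count covariates are tallied over the same windows. Patients
    for whom a measure cannot be computed are dropped with a logged count.
    """
    included = set(cohort_flags.loc[~cohort_flags.excluded, "patient_id"])
    trt = treatments[treatments.patient_id.isin(included)].copy()
    trt = trt[trt.surgeon_id.notna()]
    pinfo = patients.set_index("patient_id")
    physician_spec = physicians.set_index("physician_id")["specialty"]

    # --- surgeon-level covariates over the cohort's surgeons -------------
    surgeons = sorted(trt.surgeon_id.unique())
    phys = physicians.set_index("physician_id")
    if over65_by_hrr is None:
        # stand-in >65 population: proportional to the generated patient
        # load of each HRR (the cohort is entirely >65)
        per_hrr = patients.groupby("hrr").size()
        over65_by_hrr = {h: float(per_hrr.get(h, 0)) * 50.0 + 1000.0
                         for h in physicians.hrr.unique()}
    supply = oncologist_supply(physicians, over65_by_hrr)

    window_enc = encounters.merge(
        trt[["patient_id", "biopsy_date"]], on="patient_id", how="inner")
    window_enc = window_enc[
        (window_enc.service_date >= window_enc.biopsy_date - days_before_biopsy)
        & (window_enc.service_date <= window_enc.biopsy_date + 365)
    ]
    volume = window_enc.drop_duplicates(["physician_id", "patient_id"]) \
        .groupby("physician_id").size()

    srows = {}
    for s in surgeons:
        if s in graph:
            ds = degree_split(graph, s)
            within, between = ds.within_hsa_degree, ds.between_hsa_degree
        else:
            within = between = 0
        srows[s] = {
            "surgeon_volume": int(volume.get(s, 0)),
            "surgeon_within_hsa_degree": within,
            "surgeon_between_hsa_degree": between,
            "surgeon_supply": float(supply.get(phys.loc[s, "hrr"], 0.0)),
            "surgeon_rurality": phys.loc[s, "rurality"],
            "surgeon_gender": phys.loc[s, "gender"],
        }
    sdf = pd.DataFrame.from_dict(srows, orient="index")
    for col, out in (("surgeon_volume", "surgeon_volume_tertile"),
                     ("surgeon_supply", "surgeon_supply_tertile"),
                     ("surgeon_within_hsa_degree", "surgeon_within_hsa_tertile"),
                     ("surgeon_between_hsa_degree", "surgeon_between_hsa_tertile")):
        sdf[out] = bin_tertiles(sdf[col]) if len(sdf) else []

    lflag = linchpin.set_index("physician_id")["is_linchpin"]

    # --- per-patient team windows ----------------------------------------
    trt["pre_start"] = trt.biopsy_date - days_before_biopsy
    pre_teams = _teams(encounters, trt, "pre_start", "first_surgery_date",
                       None, physician_spec)
    adj = trt[trt.first_adjuvant_date.notna()].copy()
    post_teams = _teams(encounters, adj, "last_surgery_date", "first_adjuvant_date",
                        ONCOLOGIST_SPECIALTIES, physician_spec)
    pre_visits = _visit_counts(encounters, trt, "biopsy_date", "first_surgery_date")
    post_visits = _visit_counts(encounters, adj, "last_surgery_date",
                                "first_adjuvant_date")

    n_dropped = 0

    def patient_covariates(pid: str) -> dict:
        info = pinfo.loc[pid]
        return {
            "age_group": info["age_group"],
            "race_ethnicity": info["race_ethnicity"],
            "comorbidity_bin": bin_comorbidity(int(info["comorbidity_count"])),
            "deprivation_bin": bin_deprivation(float(info["deprivation_pct"])),
            "patient_rurality": info["rurality"],
            "nci_affiliated": bool(info["nci_affiliated_surgery"]),
            "hrr": info["hrr"],
        }

    # surgery cohort ------------------------------------------------------
    surgery_rows = []
    for t in trt.itertuples(index=False):
        team = pre_teams.get(t.patient_id, set()) | {t.surgeon_id}
        try:
            cd = care_density(graph, team)
        except ValueError:
            n_dropped += 1
            continue
        interval = int(t.first_surgery_date - t.biopsy_date)
        surgery_rows.append({
            "patient_id": t.patient_id,
            "cohort": "surgery",
            "surgeon_id": t.surgeon_id,
            "linchpin_exposed": bool(lflag.get(t.surgeon_id, False)),
            "care_density": cd.cd,
            "sole_clinician": cd.sole_clinician,
            "team_size": cd.team_size,
            "interval_days": interval,
            "delayed": delay_flag(interval, cutoff),
            "encounter_count": int(pre_visits.get(t.patient_id, 0)),
            **patient_covariates(t.patient_id),
            **srows[t.surgeon_id],
            **{k: sdf.loc[t.surgeon_id, k] for k in (
                "surgeon_volume_tertile", "surgeon_supply_tertile",
                "surgeon_within_hsa_tertile", "surgeon_between_hsa_tertile")},
        })
    surgery_df = pd.DataFrame(surgery_rows)

    # adjuvant cohort (subset of surgery patients) ------------------------
    adjuvant_rows = []
    surgery_ids = set(surgery_df.patient_id) if len(surgery_df) else set()
    for t in adj.itertuples(index=False):
        if t.patient_id not in surgery_ids:
            continue
        team = post_teams.get(t.patient_id, set()) | {t.surgeon_id}
        try:
            cd = care_density(graph, team)
        except ValueError:
            n_dropped += 1
            continue
        interval = int(t.first_adjuvant_date - t.last_surgery_date)
        adjuvant_rows.append({
            "patient_id": t.patient_id,
            "cohort": "adjuvant",
            "surgeon_id": t.surgeon_id,
            "linchpin_exposed": bool(lflag.get(t.surgeon_id, False)),
            "care_density": cd.cd,
            "sole_clinician": cd.sole_clinician,
            "team_size": cd.team_size,
            "interval_days": interval,
            "delayed": delay_flag(interval, cutoff),
            "encounter_count": int(post_visits.get(t.patient_id, 0)),
            **patient_covariates(t.patient_id),
            **srows[t.surgeon_id],
            **{k: sdf.loc[t.surgeon_id, k] for k in (
                "surgeon_volume_tertile", "surgeon_supply_tertile",
                "surgeon_within_hsa_tertile", "surgeon_between_hsa_tertile")},
        })
    adjuvant_df = pd.DataFrame(adjuvant_rows)

    for df in (surgery_df, adjuvant_df):
        if len(df):
            df["care_density_level"] = care_density_levels(df)

    if n_dropped:
        logger.warning("dropped %d row(s) with uncomputable care density", n_dropped)
    return CohortTables(
        surgery=surgery_df,
        adjuvant=adjuvant_df,
        exclusions=exclusion_summary(cohort_flags),
        n_dropped_missing_measures=n_dropped,
    )


def care_density_levels(rows: pd.DataFrame) -> pd.Series:
    """Tertile the numeric care densities; sole-clinician keeps its own level."""
    levels = pd.Series("sole_clinician", index=rows.index, dtype=object)
    mask = ~rows.sole_clinician
    if mask.any():
        levels.loc[mask] = bin_tertiles(rows.loc[mask, "care_density"])
    return levels
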