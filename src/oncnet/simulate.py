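"""Synthetic Medicare-style claims generator with planted exposure effects.

Real fee-for-service claims are governed by data-use agreements and cannot be
shipped, so every downstream stage (network assembly, exposure measures,
cohort filters, regression) is exercised against a generator that emulates
the relevant structure of such data:

* a patient-physician encounter stream spanning 3 months before to 12 months
  after each patient's breast biopsy;
* physician specialties (medical oncologist, radiation oncologist, surgeon,
  other) placed on a zip -> HSA -> HRR geography in which rural areas have
  fewer surgeons per capita;
* treatment-delay outcomes drawn from a logistic model with configurable
  log-odds-ratio coefficients on the two network exposures (linchpin surgeon,
  care-density level) plus crossed physician and HRR random intercepts;
* configurable fractions of patients violating each cohort exclusion rule,
  so the filter cascade is testable against known counts.

Linchpin exposure is planted *structurally*: rural surgeon scarcity makes
some surgeons the only surgeon reachable from their service area, and the
network pipeline must discover this. The generator records its own notion of
the "true" flag (sole surgeon in the HSA) for validation, but recovery of
that flag by the measured score is expected only as a rank association, not
equality.

Dates are integer day indices from an arbitrary origin; "3 months" is fixed
at 91 days and "12 months" at 365 days throughout.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import ConfigError, GeneratorConfig

EVENT_CLASSES = (
    "biopsy",
    "cancer_dx",
    "surgery",
    "reconstruction",
    "chemotherapy",
    "radiotherapy",
    "metastatic_dx",
    "visit",
)

AGE_GROUPS = ("66-69", "70-74", "75-79", "80-84", ">=85")
_AGE_GROUP_P = (0.2515, 0.3190, 0.2242, 0.1280, 0.0773)
_AGE_BRACKETS = {"66-69": (66, 69), "70-74": (70, 74), "75-79": (75, 79),
                 "80-84": (80, 84), ">=85": (85, 99)}

RACE_LEVELS = ("Asian", "Black", "Hispanic", "North American Native",
               "Other", "Unknown", "White")
_RACE_P = (0.0117, 0.0609, 0.0058, 0.0031, 0.0143, 0.0147, 0.8895)

RURAL_TIERS = ("large rural", "small rural", "isolated")
_RURAL_TIER_P = (0.52, 0.275, 0.205)

SPECIALTIES = ("medical_oncologist", "radiation_oncologist", "surgeon", "other")

EXCLUSION_CLASSES = (
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

CD_LEVELS = ("low", "medium", "high")


class Population(NamedTuple):
    """Patient and physician rosters plus the zip/HSA/HRR geography map."""

    patients: pd.DataFrame
    physicians: pd.DataFrame
    geography: pd.DataFrame


@dataclass
class PlantedTruth:
    """Generative parameters of the planted delay model.

    Coefficients are log odds ratios against the reference exposure levels
    (non-linchpin surgeon; low care density). Defaults plant the effect sizes
    reported for Medicare breast-cancer treatment delay: adjuvant-phase ORs
    of 1.30 (linchpin), 0.85 (medium vs low postoperative care density) and
    0.77 (high vs low); surgical-phase ORs of 0.91, 0.96, 0.58 and 0.35
    (sole clinician vs low). The ``*_surgery`` fields override the shared
    coefficients for the biopsy-to-surgery interval; set them to ``None`` to
    use one coefficient set for both phases.
    """

    beta_linchpin: float = math.log(1.30)
    beta_caredensity_med: float = math.log(0.85)
    beta_caredensity_high: float = math.log(0.77)
    beta_caredensity_sole: float = math.log(0.35)
    sigma_npi: float = 0.25
    sigma_hrr: float = 0.15
    baseline_delay_prob: float = 0.21
    seed: int = 0
    beta_linchpin_surgery: float | None = math.log(0.91)
    beta_caredensity_med_surgery: float | None = math.log(0.96)
    beta_caredensity_high_surgery: float | None = math.log(0.58)
    baseline_delay_prob_surgery: float | None = 0.18

    @classmethod
    def null(cls, baseline_delay_prob: float = 0.2, seed: int = 0) -> "PlantedTruth":
        """A truth with no exposure effects and no cluster variation."""
        return cls(
            beta_linchpin=0.0, beta_caredensity_med=0.0,
            beta_caredensity_high=0.0, beta_caredensity_sole=0.0,
            sigma_npi=0.0, sigma_hrr=0.0,
            baseline_delay_prob=baseline_delay_prob, seed=seed,
            beta_linchpin_surgery=None, beta_caredensity_med_surgery=None,
            beta_caredensity_high_surgery=None, baseline_delay_prob_surgery=None,
        )

    def validate(self) -> None:
        if not 0.0 < self.baseline_delay_prob < 1.0:
            raise ConfigError("baseline_delay_prob must lie strictly in (0, 1)")
        if self.baseline_delay_prob_surgery is not None and not (
            0.0 < self.baseline_delay_prob_surgery < 1.0
        ):
            raise ConfigError("baseline_delay_prob_surgery must lie in (0, 1)")
        if self.sigma_npi < 0 or self.sigma_hrr < 0:
            raise ConfigError("random-intercept standard deviations must be >= 0")

    def phase_coefficients(self, phase: str) -> tuple[float, float, float, float, float]:
        """(intercept, beta_linchpin, beta_med, beta_high, beta_sole) for a phase."""
        if phase == "surgery":
            base = (self.baseline_delay_prob_surgery
                    if self.baseline_delay_prob_surgery is not None
                    else self.baseline_delay_prob)
            bl = (self.beta_linchpin_surgery
                  if self.beta_linchpin_surgery is not None else self.beta_linchpin)
            bm = (self.beta_caredensity_med_surgery
                  if self.beta_caredensity_med_surgery is not None
                  else self.beta_caredensity_med)
            bh = (self.beta_caredensity_high_surgery
                  if self.beta_caredensity_high_surgery is not None
                  else self.beta_caredensity_high)
        elif phase == "adjuvant":
            base = self.baseline_delay_prob
            bl, bm, bh = (self.beta_linchpin, self.beta_caredensity_med,
                          self.beta_caredensity_high)
        else:  # pragma: no cover - guarded by callers
            raise ValueError(f"unknown phase {phase!r}")
        return float(logit(base)), bl, bm, bh, self.beta_caredensity_sole


# ---------------------------------------------------------------------------
# population


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of `total` proportional to `weights` (sums exactly)."""
    if total <= 0 or len(weights) == 0:
        return np.zeros(len(weights), dtype=int)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    quota = total * w / w.sum()
    alloc = np.floor(quota).astype(int)
    short = total - alloc.sum()
    if short > 0:
        order = np.argsort(-(quota - alloc), kind="stable")
        alloc[order[:short]] += 1
    return alloc


def generate_population(config: GeneratorConfig, seed: int) -> Population:
    """Generate patient and physician rosters on a zip/HSA/HRR geography.

    Deterministic given ``(config, seed)``. When ``config.rural_scarcity``
    is positive, rural HSAs are allotted proportionally fewer surgeons than
    their patient load would imply, so surgeons-per-capita is lower in rural
    strata.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    # --- geography -------------------------------------------------------
    geo_rows = []
    zip_counter = 10001
    for r in range(config.n_hrrs):
        hrr = f"R{r:02d}"
        n_rural = int(round(config.rural_hsa_fraction * config.hsas_per_hrr))
        if config.rural_hsa_fraction > 0:
            n_rural = max(1, min(config.hsas_per_hrr - 1, n_rural)) \
                if config.hsas_per_hrr > 1 else n_rural
        for h in range(config.hsas_per_hrr):
            hsa = f"{hrr}H{h}"
            rural = h < n_rural
            for _ in range(config.zips_per_hsa):
                tier = (rng.choice(RURAL_TIERS, p=_RURAL_TIER_P)
                        if rural else "urban")
                geo_rows.append((f"Z{zip_counter:05d}", hsa, hrr, tier))
                zip_counter += 1
    geography = pd.DataFrame(geo_rows, columns=["zip", "hsa", "hrr", "rurality"])
    rural_zips = geography.loc[geography.rurality != "urban", "zip"].to_numpy()
    urban_zips = geography.loc[geography.rurality == "urban", "zip"].to_numpy()
    zip_info = geography.set_index("zip")

    # --- patients --------------------------------------------------------
    n = config.n_patients
    classes = ["none", *EXCLUSION_CLASSES]
    probs = np.array(
        [1.0 - sum(config.exclusion_fractions.values())]
        + [config.exclusion_fractions.get(c, 0.0) for c in EXCLUSION_CLASSES]
    )
    violation = rng.choice(classes, size=n, p=probs) if n else np.array([], dtype=object)

    rows = []
    for i in range(n):
        rural = bool(rng.random() < config.rural_patient_fraction) and len(rural_zips) > 0
        zip_code = str(rng.choice(rural_zips if rural else urban_zips))
        info = zip_info.loc[zip_code]
        group = str(rng.choice(AGE_GROUPS, p=_AGE_GROUP_P))
        lo, hi = _AGE_BRACKETS[group]
        age = int(rng.integers(lo, hi + 1))
        vio = violation[i]
        if vio == "age_out_of_range":
            age = int(rng.choice([63, 64, 65, 100, 101, 102]))
            group = AGE_GROUPS[0] if age < 66 else AGE_GROUPS[-1]
        dep_bins = ((0, 5), (5, 10), (10, 15), (15, 20), (20, 40))
        dep_p = (0.15, 0.40, 0.25, 0.12, 0.08) if rural else (0.30, 0.50, 0.13, 0.04, 0.03)
        blo, bhi = dep_bins[int(rng.choice(5, p=dep_p))]
        c = rng.random()
        comorb = 0 if c < 0.542 else 1 if c < 0.770 else 2 if c < 0.900 else \
            3 if c < 0.960 else int(4 + rng.integers(0, 3))
        rows.append({
            "patient_id": f"P{i:06d}",
            "age": age,
            "age_group": group,
            "race_ethnicity": str(rng.choice(RACE_LEVELS, p=_RACE_P)),
            "zip": "" if vio == "bad_zip" else zip_code,
            "hsa": info.hsa,
            "hrr": info.hrr,
            "rurality": info.rurality,
            "deprivation_pct": round(float(rng.uniform(blo, bhi)), 2),
            "comorbidity_count": comorb,
            "enrolled_continuously": vio != "enrollment_gap",
            "multiple_primaries": vio == "multiple_cancers",
            "nci_affiliated_surgery": bool(rng.random() < (0.03 if rural else 0.14)),
            "violation_class": vio,
        })
    patients = pd.DataFrame(rows, columns=[
        "patient_id", "age", "age_group", "race_ethnicity", "zip", "hsa", "hrr",
        "rurality", "deprivation_pct", "comorbidity_count",
        "enrolled_continuously", "multiple_primaries", "nci_affiliated_surgery",
        "violation_class",
    ])

    # --- physicians ------------------------------------------------------
    hsa_tab = geography.drop_duplicates("hsa")[["hsa", "hrr"]].reset_index(drop=True)
    hsa_rural = geography.groupby("hsa")["rurality"].agg(lambda s: (s != "urban").any())
    pat_per_hsa = (patients.groupby("hsa").size().reindex(hsa_tab.hsa, fill_value=0)
                   .to_numpy(dtype=float) if n else np.zeros(len(hsa_tab)))
    load = pat_per_hsa + 0.5  # smoothing so empty HSAs can still host physicians
    rural_mask = hsa_rural.reindex(hsa_tab.hsa).to_numpy()

    def allocate(patients_per: float, scarcity: float) -> np.ndarray:
        # expected headcount per HSA from its patient load; rural scarcity
        # shrinks the rural expectation and rounds it *down*, which is what
        # leaves many rural service areas with a single (linchpin) surgeon.
        # every HSA keeps at least one physician of each specialty so all
        # patients have a reachable clinician of the needed type.
        alloc = np.empty(len(load), dtype=int)
        for i, (ld, rural) in enumerate(zip(load, rural_mask)):
            expected = ld / patients_per
            if rural:
                alloc[i] = max(1, int(expected * max(0.0, 1.0 - scarcity)))
            else:
                alloc[i] = max(1, round(expected))
        return alloc

    scarcity = {
        "surgeon": config.rural_scarcity,
        "medical_oncologist": 0.5 * config.rural_scarcity,
        "radiation_oncologist": 0.5 * config.rural_scarcity,
        "other": 0.0,
    }
    patients_per = {
        "surgeon": config.patients_per_surgeon,
        "medical_oncologist": config.patients_per_med_onc,
        "radiation_oncologist": config.patients_per_rad_onc,
        "other": config.patients_per_other,
    }
    phys_rows = []
    npi = 100000000
    zips_by_hsa = {h: g["zip"].to_numpy() for h, g in geography.groupby("hsa")}
    for spec in SPECIALTIES:
        alloc = allocate(patients_per[spec], scarcity[spec])
        for (hsa, hrr), k in zip(hsa_tab.itertuples(index=False), alloc):
            for _ in range(int(k)):
                zp = str(rng.choice(zips_by_hsa[hsa]))
                woman = rng.random() < (0.414 if spec == "surgeon" else 0.45)
                phys_rows.append({
                    "physician_id": f"N{npi}",
                    "specialty": spec,
                    "gender": "woman" if woman else "man",
                    "zip": zp,
                    "hsa": hsa,
                    "hrr": hrr,
                    "rurality": zip_info.loc[zp, "rurality"],
                })
                npi += 1
    physicians = pd.DataFrame(phys_rows, columns=[
        "physician_id", "specialty", "gender", "zip", "hsa", "hrr", "rurality"])

    return Population(patients=patients, physicians=physicians, geography=geography)


# ---------------------------------------------------------------------------
# encounters


class _Pools:
    """Pre-indexed physician pools used while building care teams."""

    def __init__(self, physicians: pd.DataFrame, rng: np.random.Generator):
        self.rng = rng
        by = physicians.groupby("hsa")
        self.surgeons_hsa = {h: g.loc[g.specialty == "surgeon", "physician_id"].to_numpy()
                             for h, g in by}
        self.oncs_hsa = {h: g.loc[g.specialty.isin(
            ["medical_oncologist", "radiation_oncologist"]), "physician_id"].to_numpy()
            for h, g in by}
        self.others_hsa = {h: g.loc[g.specialty == "other", "physician_id"].to_numpy()
                           for h, g in by}
        self.mixed_hsa = {h: np.concatenate([self.others_hsa[h], self.oncs_hsa[h]])
                          for h in self.others_hsa}
        byr = physicians.groupby("hrr")
        self.surgeons_hrr = {h: g.loc[g.specialty == "surgeon", "physician_id"].to_numpy()
                             for h, g in byr}
        self.med_hrr = {h: g.loc[g.specialty == "medical_oncologist",
                                 "physician_id"].to_numpy() for h, g in byr}
        self.rad_hrr = {h: g.loc[g.specialty == "radiation_oncologist",
                                 "physician_id"].to_numpy() for h, g in byr}
        self.oncs_hrr = {h: g.loc[g.specialty.isin(
            ["medical_oncologist", "radiation_oncologist"]), "physician_id"].to_numpy()
            for h, g in byr}
        spec = physicians.specialty
        self.all_surgeons = physicians.loc[spec == "surgeon", "physician_id"].to_numpy()
        self.all_mixed = physicians.loc[spec != "surgeon", "physician_id"].to_numpy()
        self.all_oncs = physicians.loc[spec.isin(
            ["medical_oncologist", "radiation_oncologist"]), "physician_id"].to_numpy()
        # the sole-surgeon-in-HSA flag is the generator's structural notion
        # of linchpin truth
        self.sole_in_hsa = {
            s: len(self.surgeons_hsa[h]) == 1
            for h, surgeons in self.surgeons_hsa.items() for s in surgeons
        }
        # Zipf-style weights concentrate team choices on a few physicians,
        # which is what produces high pairwise sharing for "high" cohesion
        self._zipf = {}
        for h, pool in self.mixed_hsa.items():
            if len(pool):
                w = 1.0 / np.arange(1, len(pool) + 1)
                self._zipf[h] = w / w.sum()

    def draw_team(self, hsa: str, hrr: str, level: str, k: int,
                  oncologists_only: bool = False) -> list[str]:
        if k <= 0:
            return []
        if oncologists_only:
            local = self.oncs_hsa.get(hsa, np.array([]))
            wide = self.oncs_hrr.get(hrr, np.array([]))
            global_pool = self.all_oncs
        else:
            local = self.mixed_hsa.get(hsa, np.array([]))
            wide = local
            global_pool = self.all_mixed
        rng = self.rng
        if level == "high" and len(local):
            p = None
            if not oncologists_only and hsa in self._zipf:
                p = self._zipf[hsa]
            k_eff = min(k, len(local))
            return list(rng.choice(local, size=k_eff, replace=False, p=p)
                        if p is None or len(p) == len(local)
                        else rng.choice(local, size=k_eff, replace=False))
        if level == "medium" and len(wide):
            k_eff = min(k, len(wide))
            return list(rng.choice(wide, size=k_eff, replace=False))
        if len(global_pool):
            k_eff = min(k, len(global_pool))
            return list(rng.choice(global_pool, size=k_eff, replace=False))
        return []


def generate_encounters(
    population: Population,
    truth: PlantedTruth,
    config: GeneratorConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the encounter stream and the per-patient truth assignments.

    Returns ``(encounters, assignments)``. Encounters have columns
    ``patient_id, physician_id, service_date, event_class``; assignments
    record each patient's surgeon, true exposure levels, planted violation
    class, treatment dates and delay indicators, and are consumed by
    :func:`export_truth` and by parameter-recovery tests.
    """
    truth.validate()
    config.validate()
    rng = np.random.default_rng(seed)
    patients, physicians, _ = population
    pools = _Pools(physicians, rng)

    u_npi = dict(zip(physicians.physician_id,
                     rng.normal(0.0, truth.sigma_npi, len(physicians))))
    u_hrr = {h: rng.normal(0.0, truth.sigma_hrr)
             for h in sorted(physicians.hrr.unique())}

    a_s, bl_s, bm_s, bh_s, bsole = truth.phase_coefficients("surgery")
    a_a, bl_a, bm_a, bh_a, _ = truth.phase_coefficients("adjuvant")

    enc: list[tuple[str, str, int, int]] = []  # (patient, physician, day, class idx)
    cls = {c: i for i, c in enumerate(EVENT_CLASSES)}
    assign_rows = []

    def gap(delayed: bool) -> int:
        if delayed:
            return 60 + min(int(rng.geometric(1.0 / 25.0)), 140)
        return 15 + int(rng.integers(0, 46))

    for pat in patients.itertuples(index=False):
        pid, hsa, hrr = pat.patient_id, pat.hsa, pat.hrr
        vio = pat.violation_class
        surg_pool = pools.surgeons_hsa.get(hsa)
        if surg_pool is None or len(surg_pool) == 0:
            surg_pool = pools.surgeons_hrr.get(hrr, pools.all_surgeons)
        if len(surg_pool) == 0:
            continue  # no surgeons generated at all
        surgeon = str(rng.choice(surg_pool))
        true_linch = bool(pools.sole_in_hsa.get(surgeon, False))

        r = rng.random()
        if r < config.pre_sole_fraction:
            pre_level = "sole_clinician"
        else:
            pre_level = CD_LEVELS[int(rng.integers(0, 3))]
        post_level = CD_LEVELS[int(rng.integers(0, 3))]

        b = int(rng.integers(400, 601))
        # biopsy performed by an imaging/diagnostic clinician where available;
        # sole-clinician patients see nobody but their surgeon preoperatively,
        # so the surgeon performs their biopsy too
        others = pools.others_hsa.get(hsa, np.array([]))
        sole = pre_level == "sole_clinician"
        biopsy_doc = str(rng.choice(others)) if len(others) and not sole else surgeon
        enc.append((pid, biopsy_doc, b, cls["biopsy"]))
        enc.append((pid, surgeon, b + 3, cls["cancer_dx"]))
        enc.append((pid, surgeon, b + 10, cls["cancer_dx"]))
        if vio == "prior_cancer_dx":
            enc.append((pid, surgeon, b - 100, cls["cancer_dx"]))
        if vio == "metastatic_90d":
            enc.append((pid, surgeon, b + 30, cls["metastatic_dx"]))

        has_surgery = vio != "no_surgery"
        u = u_npi[surgeon] + u_hrr[hrr]

        first_s = last_s = adj_day = None
        delayed1 = delayed2 = None
        has_adjuvant = False
        if has_surgery:
            x_sole = pre_level == "sole_clinician"
            eta1 = (a_s + bl_s * true_linch + bm_s * (pre_level == "medium")
                    + bh_s * (pre_level == "high") + bsole * x_sole + u)
            delayed1 = bool(rng.random() < expit(eta1))
            first_s = b + gap(delayed1)
            last_s = first_s
            enc.append((pid, surgeon, first_s, cls["surgery"]))
            if rng.random() < config.two_surgery_fraction:
                last_s = first_s + 7 + int(rng.integers(0, 14))
                enc.append((pid, surgeon, last_s, cls["surgery"]))
            if vio == "same_day_reconstruction":
                enc.append((pid, surgeon, first_s, cls["reconstruction"]))
            if vio == "neoadjuvant":
                med = pools.med_hrr.get(hrr, pools.all_oncs)
                doc = str(rng.choice(med)) if len(med) else surgeon
                enc.append((pid, doc, b + 5, cls["chemotherapy"]))

        # preoperative team: surgeon plus level-dependent extras
        pre_end = (first_s if first_s is not None else b + 60)
        enc.append((pid, surgeon, b + int(rng.integers(1, 8)), cls["visit"]))
        if pre_level != "sole_clinician":
            k = 2 + int(rng.poisson(1.0))
            team = pools.draw_team(hsa, hrr, pre_level, k)
            for doc in team:
                n_vis = 1 + int(rng.random() < 0.4)
                for _ in range(n_vis):
                    day = int(rng.integers(max(b - 91, b - 60), max(pre_end, b - 59)))
                    enc.append((pid, doc, day, cls["visit"]))

        if has_surgery and rng.random() < config.adjuvant_fraction:
            has_adjuvant = True
            eta2 = (a_a + bl_a * true_linch + bm_a * (post_level == "medium")
                    + bh_a * (post_level == "high") + u)
            delayed2 = bool(rng.random() < expit(eta2))
            adj_day = last_s + gap(delayed2)
            if rng.random() < 0.5:
                pool = pools.med_hrr.get(hrr, np.array([]))
                ev = "chemotherapy"
            else:
                pool = pools.rad_hrr.get(hrr, np.array([]))
                ev = "radiotherapy"
            if len(pool) == 0:
                pool, ev = pools.rad_hrr.get(hrr, pools.all_oncs), "radiotherapy"
            if len(pool):
                adj_doc = str(rng.choice(pool))
                enc.append((pid, adj_doc, adj_day, cls[ev]))
                # postoperative oncologist team: surgeon follow-up, the
                # adjuvant oncologist, and possibly one more oncologist
                enc.append((pid, surgeon,
                            last_s + max(1, min(14, adj_day - last_s - 1)),
                            cls["visit"]))
                if adj_day - last_s > 2:
                    enc.append((pid, adj_doc,
                                int(rng.integers(last_s + 1, adj_day)), cls["visit"]))
                if rng.random() < 0.6 and adj_day - last_s > 2:
                    extra = pools.draw_team(hsa, hrr, post_level, 1,
                                            oncologists_only=True)
                    for doc in extra:
                        enc.append((pid, doc,
                                    int(rng.integers(last_s + 1, adj_day)),
                                    cls["visit"]))
            else:
                has_adjuvant, adj_day, delayed2 = False, None, None

        # longitudinal primary-care ties across phases; sole-clinician
        # patients only see their PCP well after treatment, outside the
        # preoperative window
        if len(others) and rng.random() < 0.8:
            pcp = str(rng.choice(others))
            if not sole:
                enc.append((pid, pcp, b - int(rng.integers(10, 91)), cls["visit"]))
                enc.append((pid, pcp, b + int(rng.integers(120, 300)), cls["visit"]))
            else:
                start = max(b + 210, (last_s or b) + 15)
                enc.append((pid, pcp, start + int(rng.integers(0, 60)), cls["visit"]))

        assign_rows.append({
            "patient_id": pid, "surgeon_id": surgeon, "hsa": hsa, "hrr": hrr,
            "true_linchpin": true_linch, "pre_cd_level": pre_level,
            "post_cd_level": post_level, "violation_class": vio,
            "has_surgery": has_surgery, "has_adjuvant": has_adjuvant,
            "delayed_surgery": delayed1, "delayed_adjuvant": delayed2,
            "biopsy_day": b, "first_surgery_day": first_s,
            "last_surgery_day": last_s, "adjuvant_day": adj_day,
        })

    encounters = pd.DataFrame(enc, columns=[
        "patient_id", "physician_id", "service_date", "event_class"])
    encounters["event_class"] = pd.Categorical.from_codes(
        encounters["event_class"].astype(int) if len(encounters) else [],
        categories=list(EVENT_CLASSES))
    encounters = encounters.sort_values(
        ["patient_id", "service_date", "physician_id"], kind="stable"
    ).reset_index(drop=True)
    assignments = pd.DataFrame(assign_rows)
    return encounters, assignments


# ---------------------------------------------------------------------------
# truth export


def export_truth(
    truth: PlantedTruth,
    assignments: pd.DataFrame,
    path: str | Path | None = None,
) -> dict:
    """Serialize planted parameters and per-patient truth; lossless round trip."""
    record = {
        "params": dataclasses.asdict(truth),
        "patients": assignments.replace({np.nan: None}).to_dict(orient="records"),
    }
    if path is not None:
        Path(path).write_text(json.dumps(record, indent=1))
    return record


def load_truth(path: str | Path) -> tuple[PlantedTruth, pd.DataFrame]:
    """Inverse of :func:`export_truth` (file form)."""
    record = json.loads(Path(path).read_text())
    truth = PlantedTruth(**record["params"])
    assignments = pd.DataFrame(record["patients"])
    return truth, assignments


def truth_analysis_frames(assignments: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Regression frames on the generator's *true* exposures, per phase.

    Used for parameter recovery: the planted logistic model generated the
    delay indicators from these exact exposure assignments, so fitting on
    them (rather than on measured exposures, which carry measurement noise)
    estimates the planted coefficients directly.
    """
    out = {}
    surg = assignments[assignments.delayed_surgery.notna()].copy()
    out["surgery"] = pd.DataFrame({
        "delayed": surg.delayed_surgery.astype(bool),
        "linchpin_exposed": surg.true_linchpin.astype(bool),
        "care_density_level": surg.pre_cd_level,
        "surgeon_id": surg.surgeon_id,
        "hrr": surg.hrr,
        "patient_id": surg.patient_id,
    })
    adj = assignments[assignments.delayed_adjuvant.notna()].copy()
    out["adjuvant"] = pd.DataFrame({
        "delayed": adj.delayed_adjuvant.astype(bool),
        "linchpin_exposed": adj.true_linchpin.astype(bool),
        "care_density_level": adj.post_cd_level,
        "surgeon_id": adj.surgeon_id,
        "hrr": adj.hrr,
        "patient_id": adj.patient_id,
    })
    return out


def write_population(population: Population, out_dir: str | Path) -> dict[str, Path]:
    """Write the three roster tables as tab-separated text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in zip(("patients", "physicians", "geography"), population):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths
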