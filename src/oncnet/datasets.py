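"""Bundled reference data: published bivariate counts from a national
Medicare breast-cancer cohort (56 433 surgically treated patients, 5631
linked surgeons), cross-tabulated by whether the operating surgeon was a
linchpin surgeon. These printed counts serve as ground truth for the
chi-square layer and for worked examples; columns are
(non-linchpin, linchpin).
"""

from __future__ import annotations

import pandas as pd

_PATIENT_TABLES = {
    "age_group": {
        "66-69": (12076, 2115),
        "70-74": (15169, 2835),
        "75-79": (10679, 1973),
        "80-84": (5990, 1233),
        ">=85": (3645, 718),
    },
    "race_ethnicity": {
        "Asian": (565, 94),
        "Black": (2822, 615),
        "Hispanic": (275, 53),
        "North American Native": (141, 34),
        "Other": (702, 105),
        "Unknown": (721, 106),
        "White": (42333, 7867),
    },
    "comorbidity_bin": {
        "0": (26087, 4482),
        "1": (10791, 2078),
        ">=2": (10681, 2314),
    },
    "deprivation_bin": {
        "very low": (12952, 2073),
        "low": (22816, 4234),
        "medium": (7993, 1674),
        "high": (2329, 567),
        "very high": (1469, 326),
    },
    "nci_affiliated": {
        "no": (41107, 8626),
        "yes": (6452, 248),
    },
    "patient_rurality": {
        "isolated": (1887, 506),
        "small rural": (2389, 744),
        "large rural": (4738, 1238),
        "urban": (38545, 6386),
    },
}

_SURGEON_TABLES = {
    "gender": {"woman": (1967, 353), "man": (2779, 532)},
    "patient_volume": {"low": (1450, 309), "medium": (1559, 268),
                       "high": (1737, 308)},
    "rurality": {"isolated": (35, 12), "small rural": (138, 59),
                 "large rural": (605, 165), "urban": (3968, 649)},
    "oncologist_supply": {"low": (1368, 337), "medium": (1711, 308),
                          "high": (1667, 240)},
    "within_hsa_degree": {"low": (1509, 368), "medium": (1555, 322),
                          "high": (1682, 195)},
    "between_hsa_degree": {"low": (1594, 283), "medium": (1573, 304),
                           "high": (1579, 298)},
}

COLUMNS = ("nonlinchpin", "linchpin")


def _to_frames(raw: dict) -> dict[str, pd.DataFrame]:
    return {
        name: pd.DataFrame.from_dict(levels, orient="index", columns=COLUMNS)
        for name, levels in raw.items()
    }


def patient_linchpin_tables() -> dict[str, pd.DataFrame]:
    """Patient attributes x linchpin-surgeon status contingency tables."""
    return _to_frames(_PATIENT_TABLES)


def surgeon_linchpin_tables() -> dict[str, pd.DataFrame]:
    """Surgeon attributes x linchpin status contingency tables."""
    return _to_frames(_SURGEON_TABLES)


def cohort_margins() -> dict[str, int]:
    """Published cohort margins (patients by linchpin exposure)."""
    table = patient_linchpin_tables()["age_group"].sum()
    return {
        "nonlinchpin": int(table["nonlinchpin"]),
        "linchpin": int(table["linchpin"]),
        "total": int(table.sum()),
    }
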