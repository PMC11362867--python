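"""Exposure and covariate measures on the patient-sharing graph.

Two exposure measures drive the analysis:

* **Linchpin score** of a focal physician of a given specialty: the fraction
  of the focal node's total tie weight carried by neighbors who have no tie
  to any *other* node of that specialty. A surgeon whose peers cannot reach
  another surgeon scores near 1 - they are locally unique surgical capacity.
* **Care density** of a patient's team: the sum of shared-patient edge
  weights over every unordered pair of team members divided by the number of
  pairs. A team of one has no pairs; that patient is a *sole clinician* case
  and carries its own exposure level rather than a number.

Physician-level covariates: within- vs between-HSA oncologist degree and an
HRR-level oncologist supply ratio.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import pandas as pd

ONCOLOGIST_SPECIALTIES = frozenset(
    {"medical_oncologist", "radiation_oncologist", "surgeon"}
)


@dataclass(frozen=True)
class LinchpinResult:
    physician_id: str
    score: float
    is_linchpin: bool = False


@dataclass(frozen=True)
class CareDensityResult:
    """``cd`` is None exactly when the (graph-restricted) team has one member."""

    cd: float | None
    team_size: int

    @property
    def sole_clinician(self) -> bool:
        return self.team_size == 1


@dataclass(frozen=True)
class DegreeSplit:
    physician_id: str
    within_hsa_degree: int
    between_hsa_degree: int


def _is_dependent(graph: nx.Graph, neighbor: str, focal: str, specialty: str) -> bool:
    """A neighbor is dependent on the focal node iff it has no access to the
    focal specialty other than through the focal node. A neighbor that is
    itself of the focal specialty has that capacity and is never dependent."""
    if graph.nodes[neighbor].get("specialty") == specialty:
        return False
    return not any(
        other != focal and graph.nodes[other].get("specialty") == specialty
        for other in graph.neighbors(neighbor)
    )


def linchpin_score(graph: nx.Graph, focal: str, focal_specialty: str) -> float:
    """Weight share of the focal node's ties to specialty-dependent neighbors.

    Returns 0.0 for isolated focal nodes so the score is defined for every
    physician and the top-15% threshold is computable over all of them.
    """
    if focal not in graph:
        raise KeyError(f"physician {focal!r} is not a node of the graph")
    if graph.nodes[focal].get("specialty") != focal_specialty:
        raise ValueError(
            f"physician {focal!r} has specialty "
            f"{graph.nodes[focal].get('specialty')!r}, not {focal_specialty!r}"
        )
    total = 0.0
    dependent = 0.0
    for neighbor in graph.neighbors(focal):
        w = graph.edges[focal, neighbor].get("weight", 1)
        total += w
        if _is_dependent(graph, neighbor, focal, focal_specialty):
            dependent += w
    if total == 0:
        return 0.0
    return dependent / total


def linchpin_scores(graph: nx.Graph, specialty: str = "surgeon") -> list[LinchpinResult]:
    """Linchpin score for every node of the given specialty."""
    return [
        LinchpinResult(n, linchpin_score(graph, n, specialty))
        for n in sorted(graph.nodes)
        if graph.nodes[n].get("specialty") == specialty
    ]


def flag_linchpins(
    scores: list[LinchpinResult], top_fraction: float = 0.15
) -> list[LinchpinResult]:
    """Flag physicians whose score falls in the top ``top_fraction``.

    Threshold = the m-th largest score with m = max(1, floor(top_fraction*n))
    (nearest-rank on the upper tail); every score tied with the threshold is
    flagged, so the flagged share can exceed ``top_fraction`` under ties.
    """
    if not scores:
        raise ValueError("scores must be nonempty")
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie in (0, 1)")
    n = len(scores)
    m = max(1, int(top_fraction * n + 1e-9))
    threshold = sorted((s.score for s in scores), reverse=True)[m - 1]
    return [
        LinchpinResult(s.physician_id, s.score, s.score >= threshold) for s in scores
    ]


def care_density(graph: nx.Graph, team: set[str] | list[str]) -> CareDensityResult:
    """Mean pairwise shared-patient weight over a patient's care team.

    Only team members present in the graph count (physicians dropped by the
    5-patient floor cannot contribute shared-patient weights); pairs without
    an edge contribute weight 0. A one-member team is the sole-clinician
    case (``cd`` is undefined: zero pairs).
    """
    if not team:
        raise ValueError("team must be nonempty")
    members = sorted(set(team) & set(graph.nodes))
    if not members:
        raise ValueError("no team member is present in the sharing graph")
    n = len(members)
    if n == 1:
        return CareDensityResult(cd=None, team_size=1)
    total = 0.0
    for u, v in itertools.combinations(members, 2):
        if graph.has_edge(u, v):
            total += graph.edges[u, v].get("weight", 1)
    return CareDensityResult(cd=total / (n * (n - 1) / 2), team_size=n)


def degree_split(
    graph: nx.Graph,
    physician_id: str,
    oncologist_specialties: frozenset[str] | set[str] = ONCOLOGIST_SPECIALTIES,
) -> DegreeSplit:
    """Unique oncologist ties split by HSA co-location (weights ignored)."""
    if physician_id not in graph:
        raise KeyError(f"physician {physician_id!r} is not a node of the graph")
    hsa = graph.nodes[physician_id].get("hsa")
    if hsa is None:
        raise ValueError(f"node {physician_id!r} is missing an 'hsa' attribute")
    within = between = 0
    for neighbor in graph.neighbors(physician_id):
        if graph.nodes[neighbor].get("specialty") in oncologist_specialties:
            if graph.nodes[neighbor].get("hsa") == hsa:
                within += 1
            else:
                between += 1
    return DegreeSplit(physician_id, within, between)


def oncologist_supply(
    physicians: pd.DataFrame, over65_by_hrr: dict[str, float]
) -> pd.Series:
    """Oncologists (medical, radiation, surgical) per person >65, by HRR.

    Every HRR appearing in ``physicians`` must have a positive population in
    ``over65_by_hrr``; HRRs without oncologists get supply 0.0.
    """
    counts = (
        physicians[physicians.specialty.isin(ONCOLOGIST_SPECIALTIES)]
        .groupby("hrr")
        .size()
    )
    out = {}
    for hrr in sorted(physicians.hrr.unique()):
        pop = over65_by_hrr.get(hrr)
        if pop is None or pop <= 0:
            raise ValueError(f"missing or non-positive >65 population for HRR {hrr!r}")
        out[hrr] = float(counts.get(hrr, 0)) / pop
    return pd.Series(out, name="oncologist_supply")


def linchpin_table(graph: nx.Graph, specialty: str = "surgeon",
                   top_fraction: float = 0.15) -> pd.DataFrame:
    """Scores and flags for one specialty as a tidy table."""
    flagged = flag_linchpins(linchpin_scores(graph, specialty), top_fraction)
    return pd.DataFrame(
        [(r.physician_id, r.score, r.is_linchpin) for r in flagged],
        columns=["physician_id", "linchpin_score", "is_linchpin"],
    )
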