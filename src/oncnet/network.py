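"""Patient-sharing network assembly.

Physicians are linked through the patients they both cared for during each
patient's peri-diagnostic window (by default 91 days before through 365 days
after the breast biopsy). The bipartite physician-patient incidence is then
projected onto a weighted, undirected physician graph: the weight of an edge
is the number of *unique* patients the two physicians share, edges require
at least 3 shared patients, and physicians who cared for fewer than 5
cohort patients are dropped before edges are formed.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: physician -> set of patient ids seen within the network window
BipartiteIncidence = dict[str, set[str]]


def biopsy_dates(encounters: pd.DataFrame) -> pd.Series:
    """First biopsy date per patient (patients without one are absent)."""
    biopsies = encounters[encounters.event_class == "biopsy"]
    return biopsies.groupby("patient_id")["service_date"].min()


def build_incidence(
    encounters: pd.DataFrame,
    patients: pd.DataFrame | None = None,
    window: tuple[int, int] = (91, 365),
) -> BipartiteIncidence:
    """Map each physician to the unique patients they saw within the window.

    Only encounters with ``biopsy - days_before <= service_date <=
    biopsy + days_after`` (boundaries inclusive) contribute, where the biopsy
    date is each patient's first ``biopsy`` event. If ``patients`` is given,
    encounters are first restricted to patients present in that table.
    Encounters for patients without any biopsy event are skipped with a
    logged warning.
    """
    days_before, days_after = window
    enc = encounters
    if patients is not None:
        enc = enc[enc.patient_id.isin(set(patients.patient_id))]
    bdates = biopsy_dates(enc)
    missing = set(enc.patient_id.unique()) - set(bdates.index)
    if missing:
        logger.warning(
            "skipping %d patient(s) with encounters but no biopsy event", len(missing)
        )
        enc = enc[~enc.patient_id.isin(missing)]
    if enc.empty:
        return {}
    b = enc.patient_id.map(bdates)
    in_window = (enc.service_date >= b - days_before) & (
        enc.service_date <= b + days_after
    )
    pairs = enc.loc[in_window, ["physician_id", "patient_id"]].drop_duplicates()
    return {
        doc: set(grp.patient_id)
        for doc, grp in pairs.groupby("physician_id", sort=True)
    }


def project_sharing_graph(
    incidence: BipartiteIncidence,
    min_shared: int = 3,
    min_patients: int = 5,
    physician_attrs: pd.DataFrame | None = None,
) -> nx.Graph:
    """Project the incidence onto the weighted patient-sharing graph.

    The node floor (``min_patients``) is applied before edge formation;
    pairwise shared-patient counts are unaffected by this ordering, but a
    physician kept by the floor may end up isolated. Edge weights are unique
    shared-patient counts and edges below ``min_shared`` are dropped.
    ``physician_attrs`` (indexed or keyed by ``physician_id``) attaches node
    attributes such as specialty, hsa, hrr for downstream measures.
    """
    if min_shared < 1 or min_patients < 1:
        raise ValueError("min_shared and min_patients must be >= 1")
    kept = {doc: pats for doc, pats in incidence.items() if len(pats) >= min_patients}

    graph = nx.Graph()
    graph.add_nodes_from(sorted(kept))
    by_patient: dict[str, list[str]] = {}
    for doc, pats in kept.items():
        for pat in pats:
            by_patient.setdefault(pat, []).append(doc)
    weights: Counter[tuple[str, str]] = Counter()
    for docs in by_patient.values():
        docs.sort()
        weights.update(itertools.combinations(docs, 2))
    for (u, v), w in weights.items():
        if w >= min_shared:
            graph.add_edge(u, v, weight=int(w))

    if physician_attrs is not None:
        attrs = physician_attrs
        if "physician_id" in attrs.columns:
            attrs = attrs.set_index("physician_id")
        for col in attrs.columns:
            values = attrs[col].to_dict()
            nx.set_node_attributes(
                graph, {n: values[n] for n in graph.nodes if n in values}, col
            )
    return graph


# ---------------------------------------------------------------------------
# serialization: edge list + node attribute table, exact round trip


def write_graph(graph: nx.Graph, edges_path: str | Path, nodes_path: str | Path) -> None:
    with open(edges_path, "w") as fh:
        for u, v, w in sorted(graph.edges(data="weight")):
            fh.write(f"{u}\t{v}\t{w}\n")
    rows = [{"physician_id": n, **graph.nodes[n]} for n in sorted(graph.nodes)]
    pd.DataFrame(rows).to_csv(nodes_path, sep="\t", index=False)


def read_graph(edges_path: str | Path, nodes_path: str | Path) -> nx.Graph:
    graph = nx.Graph()
    nodes = pd.read_csv(nodes_path, sep="\t", dtype={"physician_id": str})
    for row in nodes.to_dict(orient="records"):
        graph.add_node(row.pop("physician_id"), **row)
    with open(edges_path) as fh:
        for line in fh:
            u, v, w = line.rstrip("\n").split("\t")
            graph.add_edge(u, v, weight=int(w))
    return graph
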