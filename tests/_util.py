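"""Shared helpers: toy worked-example graphs and random-fixture builders."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

SPECIALTIES = ("medical_oncologist", "radiation_oncologist", "surgeon", "other")


def worked_example_linchpin_graph() -> nx.Graph:
    """The worked-example network for the linchpin score.

    Focal surgeon ``v`` has ties of weight 5, 3, 2 to three physicians with
    no tie to any other surgeon, and ties of weight 6, 4 to two physicians
    who are each tied to a second surgeon; score = (5+3+2)/(5+3+2+6+4) = 0.5.
    """
    g = nx.Graph()
    g.add_node("v", specialty="surgeon")
    g.add_node("s2", specialty="surgeon")
    for name, weight in (("a", 5), ("b", 3), ("c", 2)):
        g.add_node(name, specialty="other")
        g.add_edge("v", name, weight=weight)
    for name, weight, s2w in (("d", 6, 1), ("e", 4, 2)):
        g.add_node(name, specialty="other")
        g.add_edge("v", name, weight=weight)
        g.add_edge(name, "s2", weight=s2w)
    return g


def worked_example_team() -> tuple[nx.Graph, list[str]]:
    """The worked-example care team: 5 physicians, 10 possible pairs, four
    existing ties weighing 5 + 3 + 2 + 6 = 16; care density = 16/10 = 1.6."""
    team = ["p1", "p2", "p3", "p4", "p5"]
    g = nx.Graph()
    for n in team:
        g.add_node(n, specialty="other")
    for (u, v), w in zip((("p1", "p2"), ("p2", "p3"), ("p3", "p4"), ("p4", "p5")),
                         (5, 3, 2, 6)):
        g.add_edge(u, v, weight=w)
    return g, team


def random_specialty_graph(rng: np.random.Generator, n_nodes: int = 12,
                           edge_prob: float = 0.35,
                           max_weight: int = 8) -> nx.Graph:
    """Random weighted graph with specialty and HSA node attributes."""
    g = nx.Graph()
    for i in range(n_nodes):
        g.add_node(
            f"n{i}",
            specialty=SPECIALTIES[rng.integers(0, len(SPECIALTIES))],
            hsa=f"H{rng.integers(0, 3)}",
        )
    for u, v in itertools.combinations(list(g.nodes), 2):
        if rng.random() < edge_prob:
            g.add_edge(u, v, weight=int(rng.integers(1, max_weight + 1)))
    return g


def random_incidence(rng: np.random.Generator, n_physicians: int = 30,
                     n_patients: int = 200,
                     mean_docs_per_patient: float = 3.0) -> dict[str, set[str]]:
    """Random bipartite incidence: each patient sees a Poisson number of
    physicians."""
    incidence: dict[str, set[str]] = {f"d{i}": set() for i in range(n_physicians)}
    docs = list(incidence)
    for j in range(n_patients):
        k = min(n_physicians, 1 + rng.poisson(mean_docs_per_patient))
        for d in rng.choice(docs, size=k, replace=False):
            incidence[str(d)].add(f"p{j}")
    return incidence


def brute_force_projection(incidence: dict[str, set[str]], min_shared: int,
                           min_patients: int) -> tuple[set[str], dict]:
    """All-pairs set-intersection oracle for the sharing-graph projection."""
    nodes = {d for d, pats in incidence.items() if len(pats) >= min_patients}
    edges = {}
    for u, v in itertools.combinations(sorted(nodes), 2):
        w = len(incidence[u] & incidence[v])
        if w >= min_shared:
            edges[(u, v)] = w
    return nodes, edges


def brute_force_linchpin(g: nx.Graph, focal: str, specialty: str) -> float:
    """Exhaustive neighbor-of-neighbor oracle for the linchpin score."""
    total = dependent = 0.0
    for nb in g.neighbors(focal):
        w = g.edges[focal, nb]["weight"]
        total += w
        if g.nodes[nb].get("specialty") == specialty:
            continue
        tied_to_other = False
        for nb2 in g.neighbors(nb):
            if nb2 != focal and g.nodes[nb2].get("specialty") == specialty:
                tied_to_other = True
                break
        if not tied_to_other:
            dependent += w
    return dependent / total if total else 0.0


def brute_force_care_density(g: nx.Graph, team: list[str]) -> float | None:
    members = sorted(set(team) & set(g.nodes))
    n = len(members)
    if n < 2:
        return None
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if g.has_edge(members[i], members[j]):
                total += g.edges[members[i], members[j]]["weight"]
    return total / (n * (n - 1) / 2)
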