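"""Exposure measures: worked examples, brute-force oracles, invariants."""

import numpy as np
import pandas as pd
import pytest

from oncnet import (
    LinchpinResult,
    care_density,
    degree_split,
    flag_linchpins,
    linchpin_score,
    linchpin_scores,
    oncologist_supply,
)
from oncnet.measures import linchpin_table

from _util import (
    brute_force_care_density,
    brute_force_linchpin,
    random_specialty_graph,
    worked_example_linchpin_graph,
    worked_example_team,
)


class TestLinchpinScore:
    def test_worked_example_is_half(self, fig_linchpin_graph):
        assert linchpin_score(fig_linchpin_graph, "v", "surgeon") == pytest.approx(0.5)

    def test_all_neighbors_tied_to_other_surgeon_scores_zero(self):
        g = worked_example_linchpin_graph()
        for n in ("a", "b", "c"):
            g.add_edge(n, "s2", weight=1)
        assert linchpin_score(g, "v", "surgeon") == 0.0

    def test_no_neighbor_tied_to_other_surgeon_scores_one(self):
        g = worked_example_linchpin_graph()
        g.remove_node("s2")
        assert linchpin_score(g, "v", "surgeon") == 1.0

    def test_isolated_focal_scores_zero(self):
        g = worked_example_linchpin_graph()
        g.add_node("lonely", specialty="surgeon")
        assert linchpin_score(g, "lonely", "surgeon") == 0.0

    def test_errors(self, fig_linchpin_graph):
        with pytest.raises(KeyError):
            linchpin_score(fig_linchpin_graph, "ghost", "surgeon")
        with pytest.raises(ValueError):
            linchpin_score(fig_linchpin_graph, "a", "surgeon")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_neighbor_of_neighbor_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            g = random_specialty_graph(rng)
            for node in g.nodes:
                spec = g.nodes[node]["specialty"]
                assert linchpin_score(g, node, spec) == pytest.approx(
                    brute_force_linchpin(g, node, spec))

    def test_monotone_under_dependency_changes(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            g = random_specialty_graph(rng, n_nodes=10)
            surgeons = [n for n, d in g.nodes(data=True)
                        if d["specialty"] == "surgeon"]
            if len(surgeons) < 2:
                continue
            focal = surgeons[0]
            before = linchpin_score(g, focal, "surgeon")
            # adding a tie from any focal neighbor to another surgeon can
            # only remove weight from the dependent numerator
            nbrs = list(g.neighbors(focal))
            if nbrs:
                other = surgeons[1]
                target = nbrs[0]
                if target != other and not g.has_edge(target, other):
                    g.add_edge(target, other, weight=1)
                    assert linchpin_score(g, focal, "surgeon") <= before + 1e-12
                    g.remove_edge(target, other)
            # removing a non-focal surgeon can only enlarge the numerator
            g2 = g.copy()
            g2.remove_node(surgeons[1])
            assert linchpin_score(g2, focal, "surgeon") >= before - 1e-12


class TestFlagLinchpins:
    def test_hundred_distinct_scores_flags_fifteen(self):
        scores = [LinchpinResult(f"d{i}", i / 100.0) for i in range(100)]
        flagged = flag_linchpins(scores, 0.15)
        assert sum(r.is_linchpin for r in flagged) == 15
        assert all(r.is_linchpin == (r.score >= 0.85) for r in flagged)

    def test_all_equal_scores_all_flagged(self):
        scores = [LinchpinResult(f"d{i}", 0.4) for i in range(20)]
        assert all(r.is_linchpin for r in flag_linchpins(scores))

    def test_empty_and_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            flag_linchpins([])
        with pytest.raises(ValueError):
            flag_linchpins([LinchpinResult("d", 0.1)], top_fraction=1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_sort_and_cut_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        values = rng.choice([0.0, 0.1, 0.25, 0.5, 0.5, 0.8, 1.0], size=n)
        scores = [LinchpinResult(f"d{i}", float(v)) for i, v in enumerate(values)]
        flagged = flag_linchpins(scores, 0.15)
        m = max(1, int(0.15 * n))
        threshold = sorted(values, reverse=True)[m - 1]
        expect = {s.physician_id for s in scores if s.score >= threshold}
        got = {s.physician_id for s in flagged if s.is_linchpin}
        assert got == expect
        share = len(got) / n
        assert share >= 0.15 - 1.0 / n
        if len(set(values)) == n:  # no ties
            assert share <= 0.15 + 1.0 / n


class TestCareDensity:
    def test_worked_example_is_one_point_six(self, fig_team):
        g, team = fig_team
        result = care_density(g, team)
        assert result.cd == pytest.approx(1.6)
        assert result.team_size == 5 and not result.sole_clinician

    def test_pair_with_single_edge(self):
        g, _ = worked_example_team()
        assert care_density(g, ["p1", "p2"]).cd == pytest.approx(5.0)

    def test_sole_clinician_sentinel(self, fig_team):
        g, _ = fig_team
        result = care_density(g, ["p1"])
        assert result.sole_clinician and result.cd is None

    def test_empty_team_rejected(self, fig_team):
        g, _ = fig_team
        with pytest.raises(ValueError):
            care_density(g, [])
        with pytest.raises(ValueError):
            care_density(g, ["not-in-graph"])

    def test_members_outside_graph_do_not_count(self, fig_team):
        g, team = fig_team
        assert care_density(g, team + ["ghost"]).cd == pytest.approx(1.6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_specialty_graph(rng, n_nodes=15)
        nodes = list(g.nodes)
        for _ in range(20):
            k = int(rng.integers(2, 8))
            team = list(rng.choice(nodes, size=k, replace=False))
            assert care_density(g, team).cd == pytest.approx(
                brute_force_care_density(g, team))

    def test_invariant_to_nodes_outside_team(self, fig_team):
        g, team = fig_team
        before = care_density(g, team).cd
        g.add_node("extra", specialty="other")
        g.add_edge("extra", "p1", weight=50)
        assert care_density(g, team).cd == pytest.approx(before)


class TestDegreeSplit:
    def test_isolated_node(self):
        rng = np.random.default_rng(0)
        g = random_specialty_graph(rng, n_nodes=5, edge_prob=0.0)
        d = degree_split(g, "n0")
        assert (d.within_hsa_degree, d.between_hsa_degree) == (0, 0)

    def test_direct_count(self):
        import networkx as nx
        g = nx.Graph()
        g.add_node("s", specialty="surgeon", hsa="H1")
        g.add_node("a", specialty="medical_oncologist", hsa="H1")
        g.add_node("b", specialty="radiation_oncologist", hsa="H1")
        g.add_node("c", specialty="surgeon", hsa="H2")
        g.add_node("d", specialty="other", hsa="H1")
        for n in "abcd":
            g.add_edge("s", n, weight=3)
        d = degree_split(g, "s")
        assert (d.within_hsa_degree, d.between_hsa_degree) == (2, 1)

    def test_missing_hsa_attribute_errors(self):
        import networkx as nx
        g = nx.Graph()
        g.add_node("s", specialty="surgeon")
        with pytest.raises(ValueError):
            degree_split(g, "s")

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_filter_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_specialty_graph(rng)
        onc = {"medical_oncologist", "radiation_oncologist", "surgeon"}
        for node in g.nodes:
            d = degree_split(g, node)
            nbrs = [n for n in g.neighbors(node)
                    if g.nodes[n]["specialty"] in onc]
            within = sum(g.nodes[n]["hsa"] == g.nodes[node]["hsa"] for n in nbrs)
            assert d.within_hsa_degree == within
            assert d.within_hsa_degree + d.between_hsa_degree == len(nbrs)


class TestOncologistSupply:
    def test_direct_ratio(self):
        phys = pd.DataFrame({
            "physician_id": [f"d{i}" for i in range(6)],
            "specialty": ["surgeon", "medical_oncologist", "radiation_oncologist",
                          "other", "surgeon", "other"],
            "hrr": ["R1"] * 4 + ["R2"] * 2,
        })
        supply = oncologist_supply(phys, {"R1": 10000, "R2": 5000})
        assert supply["R1"] == pytest.approx(3 / 10000)
        assert supply["R2"] == pytest.approx(1 / 5000)

    def test_hrr_without_oncologists_is_zero(self):
        phys = pd.DataFrame({"physician_id": ["d0"], "specialty": ["other"],
                             "hrr": ["R9"]})
        assert oncologist_supply(phys, {"R9": 1000})["R9"] == 0.0

    def test_missing_population_names_hrr(self):
        phys = pd.DataFrame({"physician_id": ["d0"], "specialty": ["surgeon"],
                             "hrr": ["R7"]})
        with pytest.raises(ValueError, match="R7"):
            oncologist_supply(phys, {})

    def test_matches_group_count_oracle(self):
        rng = np.random.default_rng(4)
        phys = pd.DataFrame({
            "physician_id": [f"d{i}" for i in range(60)],
            "specialty": rng.choice(
                ["surgeon", "medical_oncologist", "radiation_oncologist", "other"],
                size=60),
            "hrr": rng.choice(["R1", "R2", "R3"], size=60),
        })
        pops = {"R1": 2000.0, "R2": 3000.0, "R3": 1000.0}
        supply = oncologist_supply(phys, pops)
        onc = phys[phys.specialty != "other"]
        for hrr, pop in pops.items():
            assert supply[hrr] == pytest.approx(
                (onc.hrr == hrr).sum() / pop)


def test_linchpin_flags_concentrate_in_rural_areas(world):
    """With rural surgeon scarcity on, measured flags should fall
    disproportionately on rural surgeons (direction only)."""
    table = linchpin_table(world.graph)
    phys = world.population.physicians.set_index("physician_id")
    table["rural"] = table.physician_id.map(phys.rurality) != "urban"
    rural_rate = table.loc[table.rural, "is_linchpin"].mean()
    urban_rate = table.loc[~table.rural, "is_linchpin"].mean()
    assert rural_rate > urban_rate


def test_measured_score_tracks_planted_scarcity(world):
    """Measured linchpin scores rank-correlate with the generator's
    structural truth (sole surgeon in HSA)."""
    from scipy.stats import spearmanr
    scores = {r.physician_id: r.score
              for r in linchpin_scores(world.graph, "surgeon")}
    asg = world.assignments
    sub = asg[asg.surgeon_id.isin(scores)]
    rho, _ = spearmanr(sub.true_linchpin.astype(int),
                       sub.surgeon_id.map(scores))
    assert rho > 0.5
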