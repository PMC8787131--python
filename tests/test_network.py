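"""Network assembly, hub ranking, dense modules and sponge triads."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernet.config import McodeParams
from cernet.network import (CeRNATriad, build_network, extract_cerna_triads,
                            hub_by_degree, mine_dense_modules,
                            restrict_by_function)


def de_frame(rows):
    """rows: (feature_id, rna_class, regulation[, significant])"""
    records = {r[0]: {"rna_class": r[1], "regulation": r[2],
                      "significant": (r[3] if len(r) > 3 else True),
                      "symbol": r[0]}
               for r in rows}
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "feature_id"
    return df


def pair_frame(pairs, target_class):
    return pd.DataFrame({
        "mirna_id": [m for m, _ in pairs],
        "target_id": [t for _, t in pairs],
        "target_symbol": [t for _, t in pairs],
        "target_class": target_class,
        "source": "test"})


# ---------------------------------------------------------------------------
# build_network
# ---------------------------------------------------------------------------

def test_gene_edge_score_cutoff_is_strict():
    de = de_frame([("m1", "miRNA", "down"), ("A", "mRNA", "up"),
                   ("B", "mRNA", "up"), ("C", "mRNA", "down")])
    edges = pd.DataFrame({"node_a": ["A", "A"], "node_b": ["B", "C"],
                          "score": [0.41, 0.39]})
    g = build_network(pair_frame([("m1", "A")], "mRNA"),
                      pair_frame([], "lncRNA"), edges, de)
    assert g.has_edge("A", "B")
    assert not g.has_edge("A", "C")


def test_network_without_gene_edges_keeps_bipartite_layers():
    de = de_frame([("m1", "miRNA", "down"), ("A", "mRNA", "up"),
                   ("L", "lncRNA", "up")])
    g = build_network(pair_frame([("m1", "A")], "mRNA"),
                      pair_frame([("m1", "L")], "lncRNA"), None, de)
    assert set(g.edges) == {("m1", "A"), ("m1", "L")} or \
        g.number_of_edges() == 2
    assert g.nodes["m1"]["rna_class"] == "miRNA"


def test_edges_to_non_differential_nodes_are_dropped():
    de = de_frame([("m1", "miRNA", "down"), ("A", "mRNA", "up"),
                   ("B", "mRNA", "up", False)])
    g = build_network(pair_frame([("m1", "A"), ("m1", "B")], "mRNA"),
                      pair_frame([], "lncRNA"), None, de)
    assert "B" not in g
    assert g.number_of_edges() == 1


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------

def test_star_center_is_hub():
    g = nx.star_graph(5)
    result = hub_by_degree(g)
    assert result.hubs == [0]
    assert result.ranking["degree"].iloc[0] == 5


def test_degree_ties_reported_lexicographically():
    g = nx.Graph([("b", "c"), ("a", "c"), ("a", "b")])  # triangle, all tied
    result = hub_by_degree(g)
    assert result.hubs == ["a", "b", "c"]
    with pytest.raises(ValueError):
        hub_by_degree(nx.Graph())


# ---------------------------------------------------------------------------
# dense modules
# ---------------------------------------------------------------------------

def test_clique_with_pendant_yields_single_haircut_module():
    g = nx.complete_graph(5)
    g.add_edge(0, "pendant")
    modules = mine_dense_modules(g, McodeParams())
    assert len(modules) == 1
    assert set(modules[0].members) == {0, 1, 2, 3, 4}
    assert modules[0].score == pytest.approx(5.0)  # density 1 x size 5


def test_two_disjoint_cliques_yield_two_modules():
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    modules = mine_dense_modules(g)
    assert len(modules) == 2
    assert sorted(len(m) for m in modules) == [4, 4]


def test_edgeless_and_tiny_graphs_yield_no_modules():
    g = nx.empty_graph(10)
    assert mine_dense_modules(g) == []
    assert mine_dense_modules(nx.complete_graph(2)) == []


def test_modules_are_denser_than_the_whole_graph():
    rng = np.random.default_rng(7)
    g = nx.gnp_random_graph(40, 0.08, seed=3)
    g = nx.disjoint_union(g, nx.complete_graph(6))
    whole = nx.density(g)
    for module in mine_dense_modules(g):
        sub = g.subgraph(module.members)
        assert nx.density(sub) > whole


# ---------------------------------------------------------------------------
# triads
# ---------------------------------------------------------------------------

def triad_graph(mirna_dir, mrna_dirs, lnc_dirs):
    rows = [("m", "miRNA", mirna_dir)]
    rows += [(f"g{i}", "mRNA", d) for i, d in enumerate(mrna_dirs)]
    rows += [(f"l{i}", "lncRNA", d) for i, d in enumerate(lnc_dirs)]
    de = de_frame(rows)
    return build_network(
        pair_frame([("m", f"g{i}") for i in range(len(mrna_dirs))], "mRNA"),
        pair_frame([("m", f"l{i}") for i in range(len(lnc_dirs))], "lncRNA"),
        None, de)


def test_opposite_directions_emit_triad():
    triads = extract_cerna_triads(triad_graph("down", ["up"], ["up"]))
    assert len(triads) == 1
    t = triads[0]
    assert (t.lncrna_id, t.mirna_id, t.mrna_id) == ("l0", "m", "g0")


def test_same_direction_mrna_blocks_triad():
    assert extract_cerna_triads(triad_graph("down", ["down"], ["up"])) == []


def test_triad_invariant_rejected_at_construction():
    with pytest.raises(ValueError):
        CeRNATriad("l", "m", "g", "down", "up", "down")


def brute_force_triads(g):
    out = set()
    for l, m, r in itertools.permutations(g.nodes, 3):
        if (g.nodes[l].get("rna_class") == "lncRNA"
                and g.nodes[m].get("rna_class") == "miRNA"
                and g.nodes[r].get("rna_class") == "mRNA"
                and g.has_edge(m, l) and g.has_edge(m, r)
                and g.nodes[m]["regulation"] != g.nodes[l]["regulation"]
                and g.nodes[m]["regulation"] != g.nodes[r]["regulation"]):
            out.add((l, m, r))
    return out


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_triads_match_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    n_m, n_g, n_l = 8, 60, 30   # up to ~100 nodes before DE filtering
    rows = ([(f"m{i}", "miRNA", rng.choice(["up", "down"]))
             for i in range(n_m)]
            + [(f"g{i}", "mRNA", rng.choice(["up", "down"]))
               for i in range(n_g)]
            + [(f"l{i}", "lncRNA", rng.choice(["up", "down"]))
               for i in range(n_l)])
    de = de_frame(rows)
    mg = [(f"m{rng.integers(n_m)}", f"g{rng.integers(n_g)}")
          for _ in range(120)]
    ml = [(f"m{rng.integers(n_m)}", f"l{rng.integers(n_l)}")
          for _ in range(60)]
    g = build_network(pair_frame(mg, "mRNA"), pair_frame(ml, "lncRNA"),
                      None, de)
    triads = extract_cerna_triads(g)
    assert {(t.lncrna_id, t.mirna_id, t.mrna_id)
            for t in triads} == brute_force_triads(g)
    # deterministic ordering and sponge consistency
    keys = [(t.mirna_id, t.lncrna_id, t.mrna_id) for t in triads]
    assert keys == sorted(keys)
    assert all(t.mirna_direction != t.mrna_direction
               and t.mirna_direction != t.lncrna_direction for t in triads)


def test_functional_restriction_filters_by_mrna_symbol():
    g = triad_graph("down", ["up", "up", "up"], ["up"])
    triads = extract_cerna_triads(g)
    assert len(triads) == 3
    kept = restrict_by_function(triads, {"g0", "g2"})
    assert sorted(t.mrna_symbol for t in kept) == ["g0", "g2"]
    assert restrict_by_function(triads, set()) == []
    assert restrict_by_function(triads, {"g0", "g1", "g2"}) == triads
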