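"""Tripartite regulatory network assembly, hubs, dense modules, triads.

The network joins three edge layers over differentially expressed
features only: miRNA->mRNA and miRNA->lncRNA target relations, and
mRNA-mRNA interactions kept when their confidence score exceeds a
cutoff (0.4 by default, the usual medium-confidence STRING setting).
ceRNA (sponge) triads are (lncRNA, miRNA, mRNA) triples in which the
miRNA's differential direction opposes both partners' directions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import pandas as pd

from .config import McodeParams

logger = logging.getLogger(__name__)

SCORE_CUTOFF = 0.4


def build_network(mirna_mrna: pd.DataFrame,
                  mirna_lncrna: pd.DataFrame,
                  gene_edges: pd.DataFrame | None,
                  de_records: pd.DataFrame,
                  score_cutoff: float = SCORE_CUTOFF) -> nx.Graph:
    """Assemble the lncRNA-miRNA-mRNA network over differential features.

    ``de_records`` is indexed by feature id and must carry ``rna_class``,
    ``regulation`` and ``significant`` columns (an optional ``symbol``
    column labels mRNA nodes for symbol-level operations). Target rows
    or interaction edges touching non-differential features are dropped
    with a logged count. Gene-gene edges are given at symbol level with
    a confidence score and kept iff ``score > score_cutoff`` (strict).
    """
    sig = de_records[de_records["significant"]]
    direction = sig["regulation"].to_dict()
    rna_class = sig["rna_class"].to_dict()
    symbols = (sig["symbol"].to_dict() if "symbol" in sig.columns else {})

    graph = nx.Graph()

    def add_node(fid: str) -> None:
        graph.add_node(fid, rna_class=rna_class[fid],
                       regulation=direction[fid],
                       symbol=symbols.get(fid, fid))

    dropped = 0
    for pairs, etype in ((mirna_mrna, "mirna-mrna"),
                         (mirna_lncrna, "mirna-lncrna")):
        if pairs is None or pairs.empty:
            continue
        for row in pairs.itertuples(index=False):
            if row.mirna_id not in direction or row.target_id not in direction:
                dropped += 1
                continue
            add_node(row.mirna_id)
            add_node(row.target_id)
            graph.add_edge(row.mirna_id, row.target_id, etype=etype)

    if gene_edges is not None and not gene_edges.empty:
        kept = gene_edges[gene_edges["score"] > score_cutoff]
        dropped += len(gene_edges) - len(kept)
        # interaction tables speak gene symbols; resolve to mRNA accessions
        by_symbol: dict[str, list[str]] = {}
        for fid in sig.index[sig["rna_class"] == "mRNA"]:
            by_symbol.setdefault(symbols.get(fid, fid), []).append(fid)
        for row in kept.itertuples(index=False):
            ids_a = by_symbol.get(row.node_a, [])
            ids_b = by_symbol.get(row.node_b, [])
            if not ids_a or not ids_b:
                dropped += 1
                continue
            for a, b in itertools.product(ids_a, ids_b):
                if a == b:
                    continue
                add_node(a)
                add_node(b)
                graph.add_edge(a, b, etype="mrna-mrna")
    if dropped:
        logger.info("dropped %d edges referencing filtered-out features",
                    dropped)
    return graph


class HubResult(NamedTuple):
    ranking: pd.DataFrame   # node, degree, rna_class; degree desc, name asc
    hubs: list[str]         # all nodes at maximum degree


def hub_by_degree(network: nx.Graph) -> HubResult:
    """Rank nodes by degree; every maximum-degree node is a hub."""
    if network.number_of_nodes() == 0:
        raise ValueError("cannot rank hubs of an empty network")
    rows = sorted(((node, deg) for node, deg in network.degree),
                  key=lambda item: (-item[1], item[0]))
    ranking = pd.DataFrame(rows, columns=["node", "degree"])
    ranking["rna_class"] = [network.nodes[n].get("rna_class", "")
                            for n in ranking["node"]]
    top = ranking["degree"].iloc[0]
    hubs = sorted(ranking.loc[ranking["degree"] == top, "node"])
    return HubResult(ranking, hubs)


# ---------------------------------------------------------------------------
# MCODE-style dense module mining
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DenseModule:
    """A dense subgraph: members, density x size score, 1-based rank."""

    members: tuple[str, ...]
    score: float
    rank: int

    def __len__(self) -> int:
        return len(self.members)


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def _vertex_weights(graph: nx.Graph, degree_cutoff: int) -> dict[str, float]:
    """Core-clustering weight: k of the neighborhood's highest k-core
    times that k-core's density; low-degree vertices weigh 0."""
    weights: dict[str, float] = {}
    for v in graph.nodes:
        if graph.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        hood = graph.subgraph(list(graph.neighbors(v)) + [v])
        core_numbers = nx.core_number(hood)
        k = max(core_numbers.values())
        top_core = hood.subgraph(
            [n for n, c in core_numbers.items() if c >= k])
        weights[v] = k * _density(top_core)
    return weights


def _haircut(graph: nx.Graph, members: set[str]) -> set[str]:
    """Iteratively strip singly-connected vertices (keep the 2-core)."""
    sub = nx.Graph(graph.subgraph(members))
    while True:
        leaves = [n for n, d in sub.degree if d < 2]
        if not leaves:
            return set(sub.nodes)
        sub.remove_nodes_from(leaves)


def mine_dense_modules(network: nx.Graph,
                       params: McodeParams | None = None) -> list[DenseModule]:
    """Greedy dense-module mining on the undirected projection.

    Vertices are weighted by the k-core number of their neighborhood's
    densest core scaled by that core's density; complexes grow from the
    highest-weight unassigned seed, absorbing neighbors whose weight is
    within ``node_score_cutoff`` of the seed's. Complexes lacking a
    ``k_core``-core are discarded; with haircut enabled the surviving
    complexes are trimmed to their 2-core. Modules are ranked by
    density x size.
    """
    params = params or McodeParams()
    if network.number_of_nodes() < 3:
        return []
    weights = _vertex_weights(network, params.degree_cutoff)
    assigned: set[str] = set()
    raw_modules: list[set[str]] = []
    for seed in sorted(network.nodes, key=lambda n: (-weights[n], n)):
        if seed in assigned or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        while frontier:
            current = frontier.pop()
            for neighbor in network.neighbors(current):
                if neighbor in members or neighbor in assigned:
                    continue
                if weights[neighbor] >= threshold:
                    members.add(neighbor)
                    frontier.append(neighbor)
        assigned |= members
        raw_modules.append(members)

    modules: list[tuple[tuple[str, ...], float]] = []
    for members in raw_modules:
        sub = network.subgraph(members)
        if not nx.k_core(sub, params.k_core):
            continue
        if params.haircut:
            members = _haircut(network, set(members))
        if len(members) < 2:
            continue
        sub = network.subgraph(members)
        modules.append((tuple(sorted(members)), _density(sub) * len(members)))
    modules.sort(key=lambda item: (-item[1], item[0]))
    return [DenseModule(members, score, rank + 1)
            for rank, (members, score) in enumerate(modules)]


# ---------------------------------------------------------------------------
# ceRNA triads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CeRNATriad:
    """One (lncRNA, miRNA, mRNA) sponge candidate with direction evidence."""

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    mirna_direction: str
    lncrna_direction: str
    mrna_direction: str
    mrna_symbol: str = ""

    def __post_init__(self) -> None:
        if (self.mirna_direction == self.mrna_direction
                or self.mirna_direction == self.lncrna_direction):
            raise ValueError(
                "sponge triad requires the miRNA direction to oppose both "
                "partners")


def extract_cerna_triads(network: nx.Graph) -> list[CeRNATriad]:
    """All sponge-consistent triads, ordered (miRNA, lncRNA, mRNA).

    For every miRNA, pairs each of its opposite-direction mRNA targets
    with each of its opposite-direction lncRNA targets.
    """
    triads: list[CeRNATriad] = []
    mirnas = sorted(n for n, d in network.nodes(data=True)
                    if d.get("rna_class") == "miRNA")
    for m in mirnas:
        m_dir = network.nodes[m]["regulation"]
        partners = {"mRNA": [], "lncRNA": []}
        for neighbor in network.neighbors(m):
            attrs = network.nodes[neighbor]
            cls = attrs.get("rna_class")
            if cls in partners and attrs["regulation"] != m_dir:
                partners[cls].append(neighbor)
        for lnc in sorted(partners["lncRNA"]):
            for mrna in sorted(partners["mRNA"]):
                triads.append(CeRNATriad(
                    lncrna_id=lnc, mirna_id=m, mrna_id=mrna,
                    mirna_direction=m_dir,
                    lncrna_direction=network.nodes[lnc]["regulation"],
                    mrna_direction=network.nodes[mrna]["regulation"],
                    mrna_symbol=network.nodes[mrna].get("symbol", mrna)))
    return triads


def restrict_by_function(triads: Sequence[CeRNATriad],
                         term_genes: Iterable[str]) -> list[CeRNATriad]:
    """Keep triads whose mRNA gene symbol belongs to a functional set.

    lncRNAs and miRNAs survive only through remaining triads, so the
    restricted set induces the functional sub-network directly.
    """
    genes = set(term_genes)
    return [t for t in triads if t.mrna_symbol in genes]


def triads_to_frame(triads: Sequence[CeRNATriad]) -> pd.DataFrame:
    cols = ["lncrna_id", "mirna_id", "mrna_id", "mrna_symbol",
            "mirna_direction", "lncrna_direction", "mrna_direction"]
    return pd.DataFrame([{c: getattr(t, c) for c in cols} for t in triads],
                        columns=cols)
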