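"""Hypergeometric over-representation analysis against a term annotation.

A generic stand-in for GO/pathway enrichment: for each term the upper
tail of the hypergeometric distribution gives the probability of
drawing at least the observed overlap when sampling the query from the
universe, and Benjamini-Hochberg adjustment is applied across terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

CATEGORIES = ("biological_process", "cellular_component",
              "molecular_function", "pathway", "custom")


@dataclass(frozen=True)
class TermAnnotation:
    """A named gene set (one GO term, pathway, or custom list)."""

    term_id: str
    term_name: str
    members: frozenset = field(default_factory=frozenset)
    category: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"term {self.term_id} has no member genes")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def enrich(query: Iterable[str],
           annotation: Sequence[TermAnnotation],
           universe: Iterable[str]) -> pd.DataFrame:
    """Per-term upper-tail hypergeometric p with BH adjustment.

    ``p = P[X >= overlap]`` for X ~ Hypergeom(universe, term, query);
    terms are first intersected with the universe and the query must be
    contained in it. Results are sorted by p-value.
    """
    query = set(query)
    universe = set(universe)
    if not query or not universe:
        raise ValueError("query and universe must be nonempty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for term in annotation:
        members = term.members & universe
        if not members:
            continue
        overlap = len(members & query)
        # sf(k-1) = P[X >= k]
        p = stats.hypergeom.sf(overlap - 1, len(universe), len(members),
                               len(query))
        rows.append({
            "term_id": term.term_id,
            "term_name": term.term_name,
            "category": term.category,
            "overlap": overlap,
            "term_size": len(members),
            "query_size": len(query),
            "universe_size": len(universe),
            "p_value": min(float(p), 1.0),
        })
    result = pd.DataFrame(rows, columns=[
        "term_id", "term_name", "category", "overlap", "term_size",
        "query_size", "universe_size", "p_value"])
    if len(result):
        result["fdr"] = bh_adjust(result["p_value"])
        result = result.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    else:
        result["fdr"] = []
    return result
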