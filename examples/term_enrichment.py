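"""Over-representation of the differential gene set in a term annotation.

The synthetic bundle carries twenty random gene sets plus one set
seeded from the planted differential genes; a hypergeometric test over
the called differential symbols should flag only that planted set.
"""

from cernet import SimulationConfig, generate_bundle, run_de
from cernet.diffexpr import significant_records
from cernet.enrichment import enrich

bundle, truth = generate_bundle(SimulationConfig(seed=3))
de = run_de(bundle.panels["mRNA"])
de["symbol"] = [bundle.symbols[f] for f in de.index]

query = sorted(significant_records(de)["symbol"])
universe = sorted(bundle.symbols.values())
result = enrich(query, bundle.terms, universe)

print(f"query: {len(query)} differential genes of {len(universe)}")
print("top terms (term, overlap/size, p, FDR):")
for row in result.head(3).itertuples(index=False):
    print(f"  {row.term_id:<9} {row.overlap}/{row.term_size}   "
          f"p={row.p_value:.3g}  fdr={row.fdr:.3g}")
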