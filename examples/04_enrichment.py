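"""Gene-set overlap enrichment of a query list.

Builds a toy universe with two reference sets, tests a query list for
over-representation (and the same overlap for depletion), and prints the
exact hypergeometric/Fisher statistics.
"""

import dielgate as dg
from dielgate.core import GeneSetCollection

universe = [f"AT{i:05d}" for i in range(500)]
cycling = set(universe[:100])          # e.g. genes cycling in diel data
stress = set(universe[400:450])        # e.g. a published stress-response list
query = universe[:40] + universe[200:220]   # 40/60 hits in "cycling"

sets = GeneSetCollection({"cycling": cycling, "stress": stress})
res = dg.fisher_overrepresentation(query, sets, universe)
print(res.table[["set_K", "query_n", "overlap_k", "expected", "p", "q"]])

dep = dg.hypergeometric_overlap(query, stress, universe, tail="depletion")
print("\ndepletion of the stress set in the query:")
print(dep.table[["overlap_k", "expected", "p"]])
# p is the exact tail probability of the observed overlap under random
# draws from the universe; q is the BH-adjusted value across the sets.
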