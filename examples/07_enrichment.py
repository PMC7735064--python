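"""Over-representation analysis of a DE parent-gene list.

Runs the one-sided hypergeometric test of a query gene list against a small
gene-set collection with an explicit background universe, BH-adjusted
across the collection.
"""

import numpy as np

from cernet.enrichment import ora_collection

rng = np.random.default_rng(0)
universe = {f"g{i:03d}" for i in range(500)}
synapse = {f"g{i:03d}" for i in range(40)}           # planted signal set
collection = {
    "synaptic_signaling": synapse,
    **{f"random_set_{j}": set(rng.choice(sorted(universe), 40, replace=False))
       for j in range(5)},
}
# query overlaps the synapse set heavily, the others only by chance
query = set(list(synapse)[:15]) | set(rng.choice(sorted(universe), 15, replace=False))

result = ora_collection(query, collection, universe)
print(result.round(4).to_string(index=False))
print("\np is the upper-tail hypergeometric probability of the observed "
      "overlap k; fold is observed/expected overlap; p_adj is BH across sets.")
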