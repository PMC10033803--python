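"""Hypergeometric over-representation of a gene list in gene sets.

A 20-gene universe contains one 5-gene set; querying exactly those 5 genes
gives the closed-form minimum p = 1 / C(20,5) = 1/15504, while a disjoint
query gives p = 1.
"""

from ffevomics import ora

universe = [f"g{i}" for i in range(20)]
sets = {
    "TARGET_SET": ("the five genes of interest", set(universe[:5])),
    "OTHER_SET": ("an unrelated set", set(universe[10:16])),
}
res = ora(universe[:5], sets, universe)
print(res.to_string(index=False))
print("\np_value is P(overlap >= k) under the hypergeometric null;"
      " 1/15504 = %.3g is the smallest possible here." % (1 / 15504))
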