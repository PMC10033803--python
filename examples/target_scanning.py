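"""Scan 3'UTRs for canonical miRNA seed sites.

Builds a small UTR library with planted sites for one miRNA, scans it, and
prints the per-gene best site class (8mer > 7mer-m8 > 7mer-A1 > 6mer) and
coordinates. Planted sites reappear at their exact positions; extra rows
are chance background matches, as in real UTR scans.
"""

from ffevomics import MatureMiRNA, gen_utr_library, predict_targets

mirna = MatureMiRNA("mir-204-like", "UUCCCUUUGUCAUCCUAUGCCU")
planted = [
    ("GENE0002", mirna.mirna_id, 40, "8mer"),
    ("GENE0005", mirna.mirna_id, 120, "7mer-m8"),
    ("GENE0008", mirna.mirna_id, 260, "6mer"),
]
utrs, truth = gen_utr_library(
    n_genes=10, utr_length=400, mirnas=[mirna], planted=planted, seed=3
)
table = predict_targets([mirna], utrs)
print(table.to_string(index=False))
print(f"\nseed (nt 2-7): {mirna.seed}; site coordinates are 1-based on the UTR")
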