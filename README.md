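# ffevomics

Integrative analysis of the miRNA and protein cargo of follicular-fluid
extracellular vesicles (FF-EVs), the kind of paired small-RNA-seq +
TMT-proteomics comparison used to profile PCOS patients against controls.
The package is aimed at computational biologists who start from a miRNA
count matrix and a PSM-level TMT reporter-intensity table and want a
reproducible path to a direction-annotated miRNA–protein network.

## What it computes

The pipeline chains five analysis stages plus a clinical-table module:

1. **Differential miRNAs** — median-of-ratios size factors, TPM
   (counts per million; mature miRNAs need no length term), a two-sided
   Welch t on log2(normalised count + 0.5) per miRNA, BH-FDR, and calls at
   |log2FC| ≥ 1 and p ≤ 0.05.
2. **TMT protein quantification** — the hierarchical median cascade: per
   replicate channel pair, PSM ratio = case/control; peptide ratio =
   median of PSM ratios; protein ratio = median of peptide ratios; combined
   ratio = median over replicate pairs. Significance is a one-sample t of
   the log2 replicate ratios against 0. Differential proteins require
   log2(FC) > median + 2·s.iqr (up) or < median − 2·s.iqr (down) **and**
   p < 0.05, where s.iqr = IQR/1.34898 is the normal-consistent robust σ.
3. **Target prediction** — canonical seed sites: the DNA reverse complement
   of miRNA nucleotides 2–7 scanned over 3′UTR sense strands, classed as
   6mer / 7mer-A1 / 7mer-m8 / 8mer. A precomputed target table (e.g. a
   database export) can be injected instead.
4. **Enrichment** — hypergeometric over-representation of a gene list in
   GMT gene sets, P(X ≥ k) under Hypergeom(N, K, n), BH-FDR across sets.
5. **Integration** — the bipartite network of DE miRNAs × DE proteins whose
   genes are predicted targets, each edge flagged *concordant* when the
   directions oppose (the repression-consistent pattern).
6. **Clinical table** — pooled-variance two-sided t-tests over the packaged
   3-vs-3 clinical characteristics table.

Seeded synthetic-data generators (negative-binomial counts with spiked fold
changes, PSM tables with known protein ratios, UTR libraries with planted
seed sites) make every stage testable end to end without downloads.

## Worked example

```bash
python examples/tmt_quantification.py
```

simulates 100 proteins (5 peptides × 3 PSMs, 3 replicate pairs, per-PSM
log2 noise 0.3; 30 proteins spiked at |log2 ratio| = 1) and prints:

```
            foldchange  p_value     fdr direction
protein_id
PROT0071        2.1650   0.0030  0.0152        up
PROT0048        2.1347   0.0010  0.0140        up
PROT0044        2.1203   0.0002  0.0109        up
...

robust cutoffs: log2FC outside [-0.216, 0.184]
called: 30 of 100 proteins (30 truly spiked)
mean log2-ratio recovery error on spiked proteins: -0.0079
```

Fold changes near 2 are the spiked proteins recovered at their true ratio;
the robust cutoffs are estimated from all 100 quantified proteins, and the
mean recovery error shows the median cascade is essentially unbiased at
this noise level. The other scripts in `examples/` demonstrate the
remaining stages; `ffevomics all --outdir run --seed 1` executes the whole
pipeline on a self-consistent simulated dataset and writes TSV results plus
a run manifest, and `ffevomics clinical` prints the clinical-table
comparison (7 of 11 variables significant, e.g. LH p = 0.0217718).

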