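# Methods

This note documents the models and procedures implemented in `ffevomics`,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the package's known limitations.

## miRNA differential expression

**Normalisation.** Size factors follow the median-of-ratios construction:
the reference profile is the per-miRNA geometric mean over samples,
restricted to miRNAs with nonzero counts in every sample, and a sample's
factor is the median of its count/reference ratios. Factors are rescaled to
geometric mean 1, which fixes the otherwise arbitrary scale without
changing any ratio. If no miRNA is expressed in all samples the function
refuses and points to the `pseudo_reference=True` fallback (a 0.5
pseudocount on all counts before forming the reference); silent fallback
would hide a data-quality problem.

**Expression scale.** TPM here is counts scaled to a per-million column
total. Mature miRNAs are 19–24 nt, so a transcript-length term would be a
near-constant factor and is omitted.

**Test.** Per miRNA, a two-sided Welch t on log2(normalised count + 0.5).
With three samples per group, fitting a full negative-binomial GLM per
feature is fragile; the log-scale Welch test is transparent and its
calibration is verified by simulation: on null NB data (2000 features,
10/group, dispersion 0.1) the fraction with p ≤ 0.05 lands in
[0.035, 0.065], and spike-ins at |log2FC| = 4 with 3/group are recalled at
≥ 80% (in practice ≈ 99%). Features with zero variance in both groups get
p = 1 (no evidence of change) rather than NaN, so BH-FDR runs over the full
tested set. The pseudocount 0.5 avoids log(0) and is configurable.

**Calls.** A miRNA is differentially expressed when |log2FC| ≥ 1 **and**
p ≤ 0.05, both boundaries inclusive, where log2FC compares pseudocounted
normalised group means. The inclusive reading keeps a feature sitting
exactly at p = 0.05 or |log2FC| = 1 callable. BH-FDR is reported but is not
part of the call rule.

## TMT quantification

**Median cascade.** Per replicate channel pair, each PSM contributes
case-intensity / control-intensity; PSMs with a missing or non-positive
intensity in either channel are dropped *for that pair only*. Medians are
taken PSM → peptide, peptide → protein, and protein ratios across replicate
pairs (the combined ratio). Medians of even counts are the mean of the two
central order statistics. The cascade is invariant to row order and to
odd-fold duplication of a peptide's PSM block, and scaling all case
channels by c scales every combined ratio by exactly c.

**Shared peptides.** A PSM whose protein field lists several accessions
(';'-separated) is assigned to the candidate with the most distinct
peptides in the table, ties broken lexicographically — the standard razor
rule, chosen for determinism.

**Significance.** One-sample two-sided t of the log2 replicate ratios
against 0 (df = n − 1). The ratio itself is the replicated quantity here,
so the one-sample form is the natural test; proteins with fewer than two
usable replicates are excluded, and zero-variance proteins are flagged
degenerate with a missing p rather than p = 0.

**Robust cutoffs.** Fold-change thresholds are median ± 2·s.iqr of all
quantified proteins' log2 combined ratios, with s.iqr = IQR/1.34898
(IQR of the standard normal is 2·Φ⁻¹(0.75) = 1.34898, so s.iqr is a
consistent robust estimate of σ and the rule is a robust analogue of
mean ± 2σ). Quartiles use linear interpolation between order statistics
(position 1 + (n−1)·q). Calls use strict inequalities — log2FC strictly
beyond a cut and p strictly below 0.05 — so a protein exactly at a cut is
not called. At least 4 finite values are required to form the cutoffs.

## Clinical-table comparisons

Each variable is compared with a two-sided Student t-test with pooled
variance (df = n₁ + n₂ − 2). Pooled rather than Welch was chosen because
it is the form whose p-values match the published table at these group
sizes (e.g. LH: t = −3.650, df 4, p = 0.02177). Degenerate inputs are
defined explicitly: two constant equal groups give t = 0, p = 1; two
constant unequal groups give p = 0 with a flag. The packaged fixture stores
the printed values verbatim, including the "<0.0001" bound for follicle
count, which is compared as a bound rather than parsed to a number.

## Target prediction

The seed is nucleotides 2–7 of the mature miRNA (5′→3′). A site is any
occurrence of the seed's DNA reverse complement on the UTR sense strand,
upgraded by two independent context checks: a match to miRNA position 8 at
the UTR base immediately 5′ of the core (7mer-m8) and an A at the base
immediately 3′ of the core (7mer-A1); both together give an 8mer. At one
locus only the best class is reported; overlapping loci at different
offsets are all reported. Coordinates are 1-based inclusive and span the
full matched word. T and U are interchangeable on input; N never matches;
other characters are rejected. The scanner is verified against a naive
all-offsets oracle on random sequences. No thermodynamic, conservation or
3′-supplementary scoring is attempted — the scanner is a transparent,
reproducible stand-in for database lookups, and a user-supplied
(mirna_id, gene_id) table can replace it wholesale.

## Enrichment

One-sided over-representation only: p = P(X ≥ k) under
Hypergeometric(N, K, n) with N the universe size, K the set size within the
universe and n the query size, BH-FDR across tested sets. The universe
defaults to all genes quantified by the calling stage (e.g. all scanned
target genes), standard ORA practice. Query genes outside the universe are
dropped and counted; sets with no member in the universe are skipped.

## Integration

An edge joins DE miRNA m to DE protein p when p's gene is in m's target
set. Genes and proteins are matched by exact symbol after uppercasing; an
explicit gene→protein map overrides. Edges are flagged concordant when the
directions oppose (up-miRNA/down-protein or down-miRNA/up-protein), the
pattern expected under miRNA-mediated repression; discordant edges are kept
because co-occurrence itself is informative, with a `concordant_only`
filter available. Output ordering is deterministic (miRNA id, protein id).

## Synthetic data

* **Counts** are negative-binomial with variance = mean + φ·mean²
  (φ = 0 degenerates to Poisson), the standard RNA-seq parameterisation.
  Spiked features split their effect symmetrically (case mean
  base·2^{+lfc/2}, control base·2^{−lfc/2}), preserving the geometric mean
  of the group means so size-factor estimation stays unbiased; spike signs
  are random unless specified. Defaults — 3 samples per group,
  dispersion 0.1, base means log-uniform on [10, 1000], library factors
  log-uniform on [0.7, 1.4] — mirror a small clinical EV small-RNA-seq
  contrast: tiny groups, moderate overdispersion, modest library-size
  spread.
* **PSM tables** draw a control intensity per PSM (log-normal around a
  protein base abundance) and set the case intensity to
  control·2^{true + N(0, σ)}, independently per PSM and replicate pair, so
  σ = 0 makes every ratio exact. The default hierarchy (5 peptides × 3
  PSMs, 3 replicate pairs, σ = 0.3) reflects a typical well-quantified TMT
  protein.
* **UTRs** are i.i.d. bases at a chosen GC fraction (default 0.45,
  roughly human 3′UTR composition) with requested sites written as the
  exact site-type word at the requested position. One flanking base on the
  unextended side(s) is constrained so a planted site cannot be upgraded by
  chance context — otherwise a planted 6mer followed by a background A
  would legitimately scan as 7mer-A1. Accidental background sites may
  exist and are deliberately not recorded as truth.

What the generators do **not** emulate: isomiRs and length heterogeneity in
the reads, channel cross-talk (isotope impurity, co-isolation interference)
in TMT, correlated peptide effects (digestion efficiency, missed
cleavages), GC or conservation structure in UTRs, and any correlation
between a miRNA's expression change and its targets' protein changes beyond
what a scenario explicitly plants. Passing tests therefore demonstrate the
*computational* correctness and calibration of each stage, not that the
pipeline's biological assumptions hold on real cohorts.

All generators take an explicit integer seed and thread a
`numpy.random.Generator` through every draw; no global state is touched and
identical seeds give byte-identical serialised outputs.

## Problem sizes and numerical choices

Simulation-based checks use 2000 features for calibration, 100 proteins for
quantifier recovery, 10⁴ draws for the robust-σ check and 1000 random UTRs
for the scanner oracle — sizes at which the Monte-Carlo error of each
statistic is comfortably below the asserted tolerance while the whole suite
runs in seconds. BH-FDR uses the exact step-up (suffix minimum of
p·m/rank); quantiles use linear interpolation; medians of even counts
average the central pair; all ratios are case/control and all logs base 2;
output coordinates are 1-based inclusive.

## Limitations

* The per-miRNA test is a calibrated proxy, not a dispersion-shrinking NB
  model; with very low counts or strong outliers an empirical-Bayes method
  will be more powerful.
* The enrichment module is annotation-agnostic: it does no GO graph
  propagation or pathway topology, and results depend entirely on the GMT
  supplied.
* Cross-plex TMT normalisation and isotope-impurity correction are out of
  scope; the PSM table is assumed to come from a single plex.
* The seed scanner ignores site context (accessibility, conservation,
  supplementary pairing), so its target sets are a superset of what
  context-aware predictors would return.
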