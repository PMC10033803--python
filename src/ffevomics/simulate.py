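"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators produce the three input kinds, each with a ground-truth
table so downstream stages can be validated end to end:

* miRNA count matrices — negative-binomial counts (variance =
  mean + dispersion * mean^2; dispersion 0 degenerates to Poisson) with a
  fraction of features carrying a spiked log2 fold change split symmetrically
  across groups, and per-sample library-size factors.
* PSM tables — TMT-style reporter intensities where each PSM's
  log2(case/control) equals the protein's true log2 ratio plus Gaussian
  noise, over a protein -> peptide -> PSM hierarchy and several replicate
  channel pairs.
* 3'UTR libraries — i.i.d. background sequence at a chosen GC content with
  seed-complementary sites planted at exact coordinates for chosen miRNAs.

All randomness flows through an explicit integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mirna_de import CountMatrix
from .targets import MatureMiRNA, site_word
from .tmt import PSMTable


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# miRNA counts

def gen_mirna_counts(
    n_features: int = 2000,
    n_per_group: int = 3,
    frac_de: float = 0.1,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.1,
    mean_range: tuple[float, float] = (10.0, 1000.0),
    lib_size_factor_range: tuple[float, float] = (0.7, 1.4),
    seed: int = 0,
    directions: list[int] | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial miRNA count matrix with spiked fold changes.

    A fraction ``frac_de`` of features carries a true log2 fold change of
    ``effect_log2fc`` with random sign (or signs from ``directions``), split
    symmetrically: the case-group mean is base * 2^(+lfc/2) and the
    control-group mean base * 2^(-lfc/2), so the marginal mean is preserved.
    Base means are drawn log-uniformly over ``mean_range`` and each sample
    gets a library factor log-uniform over ``lib_size_factor_range``.

    Returns the CountMatrix (samples ctrl_1.., case_1..) and a truth table
    indexed by feature_id with is_de, true_log2fc, base_mean, dispersion.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must be in [0, 1]")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    lo, hi = mean_range
    if not (0 < lo <= hi):
        raise ValueError("mean_range must be a positive interval")

    rng = _rng(seed)
    feature_ids = [f"mir-{i:04d}" for i in range(1, n_features + 1)]
    samples = [f"ctrl_{j + 1}" for j in range(n_per_group)] + [
        f"case_{j + 1}" for j in range(n_per_group)
    ]
    groups = pd.Series(
        ["control"] * n_per_group + ["case"] * n_per_group, index=samples, dtype=object
    )

    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_features))
    n_de = int(round(frac_de * n_features))
    de_idx = rng.choice(n_features, size=n_de, replace=False)
    sign = np.zeros(n_features)
    if directions is not None:
        if len(directions) != n_de:
            raise ValueError("directions must have one sign per spiked feature")
        sign[de_idx] = np.asarray(directions, dtype=float)
    else:
        sign[de_idx] = rng.choice([-1.0, 1.0], size=n_de)
    true_lfc = sign * effect_log2fc

    flo, fhi = lib_size_factor_range
    lib = np.exp(rng.uniform(np.log(flo), np.log(fhi), size=len(samples)))
    group_shift = np.array([-0.5] * n_per_group + [0.5] * n_per_group)
    mean = base_mean[:, None] * lib[None, :] * 2.0 ** (true_lfc[:, None] * group_shift[None, :])

    if dispersion == 0:
        counts = rng.poisson(mean)
    else:
        # NB with variance m + d m^2: shape r = 1/d, success prob r/(r+m)
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mean))

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"), columns=samples),
        groups=groups,
    )
    truth = pd.DataFrame(
        {
            "is_de": sign != 0,
            "true_log2fc": true_lfc,
            "base_mean": base_mean,
            "dispersion": dispersion,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# PSM tables

def gen_psm_table(
    n_proteins: int = 100,
    n_peptides: int = 5,
    psms_per_peptide: int = 3,
    frac_de: float = 0.2,
    effect_log2_ratio: float = 1.0,
    noise_sd: float = 0.3,
    n_replicate_pairs: int = 3,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    true_ratios: dict[str, float] | None = None,
) -> tuple[PSMTable, pd.DataFrame]:
    """TMT-style PSM table with known protein-level log2 ratios.

    Every protein has ``n_peptides`` peptides of ``psms_per_peptide`` PSMs.
    Control-channel intensities are log-normal around a protein base
    abundance; the paired case-channel intensity multiplies the control by
    2^(true_log2_ratio + Normal(0, noise_sd)), independently per PSM and
    replicate pair, so with noise_sd = 0 every PSM ratio equals the true
    ratio exactly. Spiked proteins (fraction ``frac_de``) get
    +/- ``effect_log2_ratio`` with random sign unless ``true_ratios``
    supplies explicit values per protein id.

    Returns the PSMTable (channels case_k / ctrl_k per pair) and a truth
    table indexed by protein_id.
    """
    if min(n_proteins, n_peptides, psms_per_peptide) < 1:
        raise ValueError("protein/peptide/PSM counts must be >= 1")
    if n_replicate_pairs < 1:
        raise ValueError("need at least one replicate channel pair")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = _rng(seed)
    if gene_ids is not None:
        if len(gene_ids) != n_proteins:
            raise ValueError("gene_ids must have length n_proteins")
        protein_ids = list(gene_ids)
    else:
        protein_ids = [f"PROT{i:04d}" for i in range(1, n_proteins + 1)]

    true = np.zeros(n_proteins)
    if true_ratios is not None:
        for i, p in enumerate(protein_ids):
            true[i] = true_ratios.get(p, 0.0)
    else:
        n_de = int(round(frac_de * n_proteins))
        de_idx = rng.choice(n_proteins, size=n_de, replace=False)
        true[de_idx] = rng.choice([-1.0, 1.0], size=n_de) * effect_log2_ratio

    pairing = [(f"case_{k}", f"ctrl_{k}") for k in range(1, n_replicate_pairs + 1)]
    base = np.exp(rng.uniform(np.log(1e5), np.log(1e7), size=n_proteins))

    AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    rows = []
    psm_no = 0
    for i, prot in enumerate(protein_ids):
        for j in range(n_peptides):
            pep = "".join(rng.choice(AA, size=10)) + f"{i}_{j}"
            for _ in range(psms_per_peptide):
                psm_no += 1
                row = {"psm_id": f"psm{psm_no:06d}", "peptide": pep, "protein": prot}
                for case_ch, ctrl_ch in pairing:
                    ctrl = base[i] * np.exp(rng.normal(0.0, 0.5))
                    log2_ratio = true[i] + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    row[ctrl_ch] = ctrl
                    row[case_ch] = ctrl * 2.0 ** log2_ratio
                rows.append(row)

    columns = ["psm_id", "peptide", "protein"] + [c for pair in pairing for c in pair]
    frame = pd.DataFrame(rows, columns=columns)
    truth = pd.DataFrame(
        {
            "true_log2_ratio": true,
            "n_peptides": n_peptides,
            "psms_per_peptide": psms_per_peptide,
            "noise_sd": noise_sd,
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )
    return PSMTable(frame=frame, pairing=pairing), truth


# ---------------------------------------------------------------------------
# UTR libraries

def gen_utr_library(
    n_genes: int = 50,
    utr_length: int = 500,
    mirnas: list[MatureMiRNA] | None = None,
    planted: list[tuple[str, str, int, str]] | None = None,
    gc_content: float = 0.45,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random 3'UTRs with seed-complementary sites planted at exact positions.

    ``planted`` lists (gene_id, mirna_id, start, site_type) requests with
    1-based starts; the UTR word for each request is the exact DNA reverse
    complement of the site-type-specific miRNA match sequence. Background
    bases are i.i.d. with the given GC fraction. Overlapping requests on a
    gene or positions that do not fit raise. The truth table records only
    the planted sites (accidental background sites may exist).

    Returns ({gene_id: sequence}, truth DataFrame with gene_id, mirna_id,
    start, end, site_type).
    """
    if utr_length < 8:
        raise ValueError("utr_length must be >= 8")
    if not 0 <= gc_content <= 1:
        raise ValueError("gc_content must be in [0, 1]")
    planted = planted or []
    by_id = {m.mirna_id: m for m in (mirnas or [])}

    rng = _rng(seed)
    p = np.array([(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2])
    bases = np.array(list("ACGT"))
    gene_ids = [f"GENE{i:04d}" for i in range(1, n_genes + 1)]
    seqs = {g: rng.choice(bases, size=utr_length, p=p) for g in gene_ids}

    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_ids}
    truth_rows = []
    for gene_id, mirna_id, start, site_type in planted:
        if gene_id not in seqs:
            raise ValueError(f"unknown gene {gene_id!r}")
        if mirna_id not in by_id:
            raise ValueError(f"unknown miRNA {mirna_id!r}")
        mirna = by_id[mirna_id]
        word = site_word(mirna, site_type)
        end = start + len(word) - 1
        # guard bases just outside the word keep the scanner from upgrading
        # the planted class (e.g. a chance A after a planted 6mer)
        guard_lo = start - 1 if site_type in ("6mer", "7mer-A1") else start
        guard_hi = end + 1 if site_type in ("6mer", "7mer-m8") else end
        if start < 1 or end > utr_length:
            raise ValueError(f"site {gene_id}:{start} ({site_type}) out of range")
        for s0, e0 in occupied[gene_id]:
            if guard_lo <= e0 and guard_hi >= s0:
                raise ValueError(f"overlapping planted sites on {gene_id}")
        occupied[gene_id].append((guard_lo, guard_hi))
        seqs[gene_id][start - 1 : end] = list(word)
        m8_comp = site_word(mirna, "7mer-m8")[0]
        if guard_lo == start - 1 and start >= 2 and seqs[gene_id][start - 2] == m8_comp:
            seqs[gene_id][start - 2] = "T" if m8_comp != "T" else "G"
        if guard_hi == end + 1 and end < utr_length and seqs[gene_id][end] == "A":
            seqs[gene_id][end] = "C"
        truth_rows.append(
            {"gene_id": gene_id, "mirna_id": mirna_id, "start": start, "end": end,
             "site_type": site_type}
        )

    utrs = {g: "".join(s) for g, s in seqs.items()}
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "mirna_id", "start", "end", "site_type"])
    return utrs, truth
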