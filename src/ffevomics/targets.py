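"""Seed-based miRNA target prediction over 3'UTR sequences.

A canonical target site is the Watson–Crick DNA complement of the miRNA seed
(nucleotides 2–7 of the mature sequence, 5'->3') found on the sense strand of
a 3'UTR. Sites are classed by the standard hierarchy:

* 6mer      — seed match only
* 7mer-A1   — seed match plus an A opposite miRNA position 1 (the UTR base
              immediately 3' of the seed match is A)
* 7mer-m8   — seed match plus a match to miRNA position 8 (the UTR base
              immediately 5' of the seed match pairs with nt 8)
* 8mer      — both extensions

Coordinates are 1-based inclusive on the UTR sense strand and span the whole
matched word. At a given seed-match locus only the best (most extended) class
is reported; overlapping loci at different offsets are all reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
#: efficacy hierarchy used for "best site" and minimum-type filters
SITE_RANK = {"6mer": 0, "7mer-A1": 1, "7mer-m8": 2, "8mer": 3}

_RNA_OK = set("ACGU")
_DNA_OK = set("ACGTN")
_DNA_COMP = str.maketrans("ACGT", "TGCA")
_RNA_TO_DNA_COMP = {"A": "T", "C": "G", "G": "C", "U": "A"}


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, 5'->3', RNA alphabet (T accepted, -> U)."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 8:
            raise ValueError(f"{self.mirna_id}: mature miRNA must be >= 8 nt")
        bad = set(seq) - _RNA_OK
        if bad:
            raise ValueError(f"{self.mirna_id}: invalid bases {sorted(bad)}")

    @property
    def seed(self) -> str:
        """Nucleotides 2–7 (1-based) of the mature sequence."""
        return self.sequence[1:7]


@dataclass(frozen=True)
class SeedSite:
    gene_id: str
    mirna_id: str
    start: int  # 1-based inclusive, UTR sense strand
    end: int
    site_type: str


def extract_seed(mirna: MatureMiRNA) -> str:
    """Return the 6-nt seed (positions 2–7) of a mature miRNA."""
    return mirna.seed


def seed_match_dna(mirna: MatureMiRNA) -> str:
    """DNA reverse complement of the seed: the 6mer word searched in UTRs."""
    return "".join(_RNA_TO_DNA_COMP[b] for b in reversed(mirna.seed))


def site_word(mirna: MatureMiRNA, site_type: str) -> str:
    """The exact UTR word (5'->3' DNA) for a site of the given class."""
    core = seed_match_dna(mirna)
    if site_type == "6mer":
        return core
    if site_type == "7mer-A1":
        return core + "A"
    m8 = _RNA_TO_DNA_COMP[mirna.sequence[7]]
    if site_type == "7mer-m8":
        return m8 + core
    if site_type == "8mer":
        return m8 + core + "A"
    raise ValueError(f"unknown site type {site_type!r}")


def _normalize_utr(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _DNA_OK
    if bad:
        raise ValueError(f"invalid UTR characters: {sorted(bad)}")
    return seq


def scan_utr(mirna: MatureMiRNA, gene_id: str, utr_seq: str) -> list[SeedSite]:
    """All seed-complementary sites of a miRNA in one UTR, best class per locus.

    The UTR is given 5'->3' (sense strand, DNA or RNA alphabet; N never
    matches). Returns SeedSite records with 1-based inclusive coordinates
    spanning the full matched word.
    """
    utr = _normalize_utr(utr_seq)
    core = seed_match_dna(mirna)
    m8 = _RNA_TO_DNA_COMP[mirna.sequence[7]]
    sites: list[SeedSite] = []
    i = utr.find(core)
    while i != -1:
        has_m8 = i > 0 and utr[i - 1] == m8
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            site = SeedSite(gene_id, mirna.mirna_id, i, i + 7, "8mer")
        elif has_m8:
            site = SeedSite(gene_id, mirna.mirna_id, i, i + 6, "7mer-m8")
        elif has_a1:
            site = SeedSite(gene_id, mirna.mirna_id, i + 1, i + 7, "7mer-A1")
        else:
            site = SeedSite(gene_id, mirna.mirna_id, i + 1, i + 6, "6mer")
        sites.append(site)
        i = utr.find(core, i + 1)
    return sites


def predict_targets(
    mirnas,
    utrs: dict[str, str],
    min_site_type: str = "6mer",
) -> pd.DataFrame:
    """Predicted target genes per miRNA with best site class and site count.

    ``utrs`` maps gene_id -> UTR sequence. A gene is listed for a miRNA iff
    it carries at least one site of class >= min_site_type. Returns a
    DataFrame with columns mirna_id, gene_id, best_site_type, n_sites, sites
    (semicolon list of start-end:type), sorted by (mirna_id, gene_id).
    """
    if min_site_type not in SITE_RANK:
        raise ValueError(f"unknown site type {min_site_type!r}")
    min_rank = SITE_RANK[min_site_type]
    rows = []
    for mirna in mirnas:
        for gene_id, seq in utrs.items():
            sites = [s for s in scan_utr(mirna, gene_id, seq) if SITE_RANK[s.site_type] >= min_rank]
            if not sites:
                continue
            best = max(sites, key=lambda s: SITE_RANK[s.site_type])
            rows.append(
                {
                    "mirna_id": mirna.mirna_id,
                    "gene_id": gene_id,
                    "best_site_type": best.site_type,
                    "n_sites": len(sites),
                    "sites": ";".join(f"{s.start}-{s.end}:{s.site_type}" for s in sites),
                }
            )
    cols = ["mirna_id", "gene_id", "best_site_type", "n_sites", "sites"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["mirna_id", "gene_id"]).reset_index(drop=True)


def load_target_table(path) -> pd.DataFrame:
    """Read a precomputed miRNA->gene target table (TSV: mirna_id, gene_id).

    Lets users inject database exports (e.g. miRWalk/miRDB downloads) in
    place of the internal seed scanner.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mirna_id", "gene_id"} <= set(df.columns):
        raise ValueError("target table needs columns mirna_id and gene_id")
    df = df.drop_duplicates(["mirna_id", "gene_id"])
    return df.sort_values(["mirna_id", "gene_id"]).reset_index(drop=True)
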