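"""Readers and writers for the pipeline's plain-text formats.

Counts and group maps are TSV, PSM tables CSV, channel pairings TSV, miRNA
and UTR sequences FASTA (via Biopython), gene sets GMT. Writers return the
SHA-256 checksum of the emitted file so run manifests can record input and
output identity.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mirna_de import CountMatrix
from .targets import MatureMiRNA
from .tmt import PSMTable


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# count matrix + group map

def read_count_matrix(counts_path, groups_path) -> CountMatrix:
    """Read a feature x sample count TSV plus a (sample_id, group) TSV."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    dup_cols = df.columns[df.columns.duplicated()].tolist()
    if dup_cols:
        raise ValueError(f"{counts_path}: duplicated sample column(s) {dup_cols}")
    dup_rows = df.index[df.index.duplicated()].tolist()
    if dup_rows:
        raise ValueError(f"{counts_path}: duplicated feature id(s) {dup_rows}")
    arr = df.to_numpy()
    nonint = np.argwhere(arr != np.floor(arr))
    if nonint.size:
        r, c = nonint[0]
        raise ValueError(
            f"{counts_path}: non-integer count {arr[r, c]!r} at feature "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    groups = pd.read_csv(groups_path, sep="\t", header=None, names=["sample_id", "group"])
    gmap = pd.Series(groups["group"].to_numpy(), index=groups["sample_id"], dtype=object)
    return CountMatrix(counts=df.astype(int), groups=gmap)


def write_count_matrix(matrix: CountMatrix, counts_path, groups_path) -> str:
    matrix.counts.to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"sample_id": matrix.counts.columns, "group": matrix.groups[matrix.counts.columns]}
    ).to_csv(groups_path, sep="\t", header=False, index=False)
    return sha256_of(counts_path)


# ---------------------------------------------------------------------------
# PSM table + pairing

def read_psm_table(psm_path, pairing_path) -> PSMTable:
    """Read a PSM CSV (psm_id,peptide,protein,<channels>) and a pairing TSV."""
    frame = pd.read_csv(psm_path)
    pairs = pd.read_csv(pairing_path, sep="\t", header=None, names=["case", "control"])
    pairing = [(str(r.case), str(r.control)) for r in pairs.itertuples(index=False)]
    return PSMTable(frame=frame, pairing=pairing)


def write_psm_table(psms: PSMTable, psm_path, pairing_path) -> str:
    psms.frame.to_csv(psm_path, index=False)
    with open(pairing_path, "w") as fh:
        for case_ch, ctrl_ch in psms.pairing:
            fh.write(f"{case_ch}\t{ctrl_ch}\n")
    return sha256_of(psm_path)


# ---------------------------------------------------------------------------
# sequences

def read_mirna_fasta(path) -> list[MatureMiRNA]:
    return [MatureMiRNA(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_utr_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> str:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
    return sha256_of(path)


# ---------------------------------------------------------------------------
# generic tables

def write_table(df: pd.DataFrame, path, index: bool = True) -> str:
    df.to_csv(path, sep="\t", index=index)
    return sha256_of(path)
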