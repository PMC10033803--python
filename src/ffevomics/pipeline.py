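"""End-to-end orchestration: simulate -> miRNA DE -> TMT -> targets -> enrich
-> integrate -> clinical, with a run manifest for reproducibility.

The pipeline is file-based: every stage reads the plain-text formats defined
in :mod:`ffevomics.io` and writes TSV/JSON results into the output
directory. A :class:`RunConfig` carries the stage toggles, file paths,
thresholds and the random seed; :func:`run_all` executes the enabled stages
in order and writes a manifest (config echo, input checksums, per-stage
record counts, timestamps) atomically at the end.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, clinical, enrichment, integration, io, mirna_de, simulate, targets, tmt

logger = logging.getLogger("ffevomics")

STAGES = ("simulate", "mirna_de", "tmt_quant", "targets", "enrich", "integrate", "clinical")


@dataclass
class RunConfig:
    """Configuration of a pipeline run (CLI flags > config file > defaults)."""

    outdir: str = "ffevomics_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # inputs (ignored for stages fed by the simulate stage)
    counts: str | None = None
    groups: str | None = None
    psms: str | None = None
    pairing: str | None = None
    mirna_fasta: str | None = None
    utr_fasta: str | None = None
    gmt: str | None = None
    target_table: str | None = None
    # thresholds
    alpha: float = 0.05
    lfc_min: float = 1.0
    pseudocount: float = 0.5
    min_site_type: str = "6mer"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.alpha <= 1) or self.lfc_min < 0 or self.pseudocount < 0:
            raise ValueError("thresholds out of range")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def gen_integrated_demo(seed: int = 0, outdir: str | Path | None = None) -> dict:
    """A small self-consistent scenario exercising every stage.

    300 miRNA features (6 spiked at |log2FC| = 4, named mir-demo-1..6),
    50 genes whose 3'UTRs carry planted seed sites, and a PSM table over the
    same 50 gene symbols with 12 spiked proteins (|log2 ratio| = 1.2). Each
    spiked miRNA is given planted sites in two spiked-protein genes and two
    null genes, so the true integration network is known by construction.

    Returns a dict of all inputs plus ``truth`` tables (incl. the expected
    edge set); if ``outdir`` is given, also writes the file-based inputs.
    """
    rng_offset = seed
    matrix, mir_truth = simulate.gen_mirna_counts(
        n_features=300, n_per_group=3, frac_de=0.02, effect_log2fc=4.0,
        dispersion=0.1, seed=rng_offset,
    )
    de_ids = list(mir_truth.index[mir_truth["is_de"]])
    rename = {old: f"mir-demo-{k + 1}" for k, old in enumerate(de_ids)}
    matrix.counts = matrix.counts.rename(index=rename)
    mir_truth = mir_truth.rename(index=rename)

    import numpy as np

    rng = np.random.default_rng(seed + 1)
    bases = np.array(list("ACGU"))
    mirnas = [
        targets.MatureMiRNA(f"mir-demo-{k + 1}", "".join(rng.choice(bases, size=22)))
        for k in range(len(de_ids))
    ]

    gene_ids = [f"GENE{i:04d}" for i in range(1, 51)]
    spiked_genes = gene_ids[:12]
    signs = [1.0 if i % 2 == 0 else -1.0 for i in range(12)]
    true_ratios = {g: s * 1.2 for g, s in zip(spiked_genes, signs)}
    psms, psm_truth = simulate.gen_psm_table(
        n_proteins=50, n_peptides=5, psms_per_peptide=3, noise_sd=0.2,
        n_replicate_pairs=3, seed=seed + 2, gene_ids=gene_ids, true_ratios=true_ratios,
    )

    planted = []
    expected_edges = set()
    null_genes = gene_ids[12:]
    for k, mirna in enumerate(mirnas):
        hit_genes = [spiked_genes[(2 * k) % 12], spiked_genes[(2 * k + 1) % 12]]
        miss_genes = [null_genes[(2 * k) % len(null_genes)], null_genes[(2 * k + 1) % len(null_genes)]]
        for j, g in enumerate(hit_genes + miss_genes):
            planted.append((g, mirna.mirna_id, 30 + 40 * k + 10 * j, "8mer"))
        expected_edges.update((mirna.mirna_id, g) for g in hit_genes)
    utrs, site_truth = simulate.gen_utr_library(
        n_genes=50, utr_length=500, mirnas=mirnas, planted=planted, seed=seed + 3,
    )

    gmt_sets = {
        "SPIKED_SET": ("spiked proteins", set(spiked_genes)),
        "NULL_SET": ("background genes", set(null_genes[:20])),
    }

    demo = {
        "matrix": matrix, "mir_truth": mir_truth, "mirnas": mirnas,
        "psms": psms, "psm_truth": psm_truth, "utrs": utrs,
        "site_truth": site_truth, "gmt_sets": gmt_sets,
        "expected_edges": expected_edges,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_count_matrix(matrix, outdir / "counts.tsv", outdir / "groups.tsv")
        io.write_psm_table(psms, outdir / "psms.csv", outdir / "pairing.tsv")
        io.write_fasta({m.mirna_id: m.sequence for m in mirnas}, outdir / "mirnas.fasta")
        io.write_fasta(utrs, outdir / "utrs.fasta")
        io.write_table(mir_truth, outdir / "mirna_truth.tsv")
        io.write_table(psm_truth, outdir / "psm_truth.tsv")
        io.write_table(site_truth, outdir / "site_truth.tsv", index=False)
        with open(outdir / "sets.gmt", "w") as fh:
            for name, (desc, members) in gmt_sets.items():
                fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
    return demo


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in order; return the run manifest dict.

    Aborts before running anything if an enabled stage lacks its inputs
    (inputs produced by an enabled earlier stage count as present).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s in config.stages]
    paths = {
        "counts": config.counts, "groups": config.groups, "psms": config.psms,
        "pairing": config.pairing, "mirna_fasta": config.mirna_fasta,
        "utr_fasta": config.utr_fasta, "target_table": config.target_table,
    }
    sim_dir = outdir / "sim"
    if "simulate" in enabled:
        produced = {
            "counts": sim_dir / "counts.tsv", "groups": sim_dir / "groups.tsv",
            "psms": sim_dir / "psms.csv", "pairing": sim_dir / "pairing.tsv",
            "mirna_fasta": sim_dir / "mirnas.fasta", "utr_fasta": sim_dir / "utrs.fasta",
        }
        for key, path in produced.items():
            if paths[key] is None:
                paths[key] = str(path)
        if config.gmt is None:
            config = dataclasses.replace(config, gmt=str(sim_dir / "sets.gmt"))

    _check_inputs(enabled, paths, config)

    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "started": _now(),
        "stages": {},
        "inputs": {},
    }

    if "simulate" in enabled:
        gen_integrated_demo(seed=config.seed, outdir=sim_dir)
        manifest["stages"]["simulate"] = {"outdir": str(sim_dir)}
        logger.info("stage=simulate seed=%d outdir=%s", config.seed, sim_dir)

    for key, path in paths.items():
        if path is not None and Path(path).exists():
            manifest["inputs"][key] = io.sha256_of(path)

    de_table = None
    if "mirna_de" in enabled:
        matrix = io.read_count_matrix(paths["counts"], paths["groups"])
        de_table = mirna_de.differential_mirnas(
            matrix, pseudocount=config.pseudocount, alpha=config.alpha, lfc_min=config.lfc_min
        )
        io.write_table(de_table, outdir / "mirna_de.tsv")
        n_de = int((de_table["direction"] != "ns").sum())
        manifest["stages"]["mirna_de"] = {"n_features": len(de_table), "n_de": n_de}
        logger.info("stage=mirna_de seed=%d n_features=%d n_de=%d", config.seed, len(de_table), n_de)

    dep_table = None
    if "tmt_quant" in enabled:
        psms = io.read_psm_table(paths["psms"], paths["pairing"])
        quants = tmt.protein_ratios_from_psms(psms)
        dep_table, thr = tmt.call_deps(quants, alpha=config.alpha)
        io.write_table(quants, outdir / "protein_quant.tsv")
        io.write_table(dep_table, outdir / "protein_dep.tsv")
        n_dep = int((dep_table["direction"] != "ns").sum())
        manifest["stages"]["tmt_quant"] = {
            "n_proteins": len(dep_table), "n_dep": n_dep,
            "upper_cut": thr.upper_cut, "lower_cut": thr.lower_cut,
        }
        logger.info("stage=tmt_quant seed=%d n_proteins=%d n_dep=%d", config.seed, len(dep_table), n_dep)

    target_table = None
    if "targets" in enabled:
        if paths["target_table"]:
            target_table = targets.load_target_table(paths["target_table"])
        else:
            mirnas = io.read_mirna_fasta(paths["mirna_fasta"])
            utrs = io.read_utr_fasta(paths["utr_fasta"])
            target_table = targets.predict_targets(mirnas, utrs, min_site_type=config.min_site_type)
        io.write_table(target_table, outdir / "targets.tsv", index=False)
        manifest["stages"]["targets"] = {"n_pairs": len(target_table)}
        logger.info("stage=targets seed=%d n_pairs=%d", config.seed, len(target_table))

    if "enrich" in enabled and config.gmt and Path(config.gmt).exists():
        sets = enrichment.read_gmt(config.gmt)
        if target_table is not None and de_table is not None:
            de_ids = de_table.index[de_table["direction"] != "ns"]
            query = set(target_table.loc[target_table["mirna_id"].isin(de_ids), "gene_id"])
            universe = set(target_table["gene_id"])
        else:
            query, universe = set(), set()
        if query and universe:
            ora_table = enrichment.ora(query, sets, universe)
            io.write_table(ora_table, outdir / "enrichment.tsv", index=False)
            manifest["stages"]["enrich"] = {"n_sets": len(ora_table)}
            logger.info("stage=enrich seed=%d n_sets=%d", config.seed, len(ora_table))

    if "integrate" in enabled and de_table is not None and dep_table is not None and target_table is not None:
        edges = integration.build_network(de_table, target_table, dep_table)
        io.write_table(edges, outdir / "edges.tsv", index=False)
        summary = integration.edge_summary(edges)
        with open(outdir / "edge_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        integration.to_graphml(edges, outdir / "network.graphml")
        manifest["stages"]["integrate"] = {"n_edges": summary["n_edges"]}
        logger.info("stage=integrate seed=%d n_edges=%d", config.seed, summary["n_edges"])

    if "clinical" in enabled:
        table = clinical.compare_clinical_table(alpha=config.alpha)
        io.write_table(table, outdir / "clinical.tsv", index=False)
        manifest["stages"]["clinical"] = {
            "n_variables": len(table), "n_significant": int(table["significant"].sum()),
        }
        logger.info("stage=clinical n_variables=%d", len(table))

    manifest["finished"] = _now()
    tmp = outdir / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    os.replace(tmp, outdir / "manifest.json")
    return manifest


def _check_inputs(enabled: list[str], paths: dict, config: RunConfig) -> None:
    simulated = "simulate" in enabled
    required = {
        "mirna_de": ["counts", "groups"],
        "tmt_quant": ["psms", "pairing"],
        "targets": ["target_table"] if config.target_table else ["mirna_fasta", "utr_fasta"],
    }
    for stage, keys in required.items():
        if stage not in enabled:
            continue
        for key in keys:
            path = paths.get(key)
            if path is None:
                raise FileNotFoundError(f"stage {stage!r} needs input {key!r}")
            if not simulated and not Path(path).exists():
                raise FileNotFoundError(f"stage {stage!r} input missing: {path}")


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()
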