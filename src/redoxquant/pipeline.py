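"""End-to-end orchestration: map -> annotate -> rollup -> normalize -> test ->
classify -> write, with a reproducibility manifest.

The protein branch tests log2 median-centered summed intensities with the
permutation-FDR-adjusted Student's t (calls at q), the Cys-site branch with
the raw-p Student's t plus the abundance-decoupling criterion.  Every run
writes a ``run_manifest.json`` recording config hash, input checksums, seed,
stage counts and warnings; reruns on identical inputs produce byte-identical
outputs (no timestamps anywhere).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import call_protein_abundance, call_site_redox
from .config import PipelineConfig, config_hash
from .io import (
    PeptideTable,
    SampleDesign,
    fasta_to_dict,
    read_design,
    read_fasta,
    read_peptide_table,
    write_results,
)
from .rollup import rollup_cys_sites, rollup_protein_abundance
from .stats import differential_stats, log2_median_center

logger = logging.getLogger("redoxquant")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    input_checksums: dict[str, str]
    counts: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")
        return path


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _triage_peptides(
    table: PeptideTable, database: dict[str, str], config: PipelineConfig
) -> tuple[PeptideTable, dict[str, int], list[str]]:
    """Split input peptides into used / unmapped / filtered, with warnings."""
    used = []
    n_unmapped = n_filtered = 0
    warnings: list[str] = []
    for obs in table.observations:
        known = [a for a in dict.fromkeys(obs.proteins) if a in database]
        if not known:
            n_unmapped += 1
            warnings.append(f"peptide {obs.sequence!r}: no mapped accession in database")
            continue
        if config.shared_peptide_mode == "unique_only" and len(known) > 1:
            n_filtered += 1
            continue
        if len(known) < len(set(obs.proteins)):
            dropped = sorted(set(obs.proteins) - set(known))
            warnings.append(
                f"peptide {obs.sequence!r}: accessions absent from FASTA dropped: {dropped}"
            )
        used.append(dataclasses.replace(obs, proteins=known))
    counts = {
        "n_input_peptides": len(table.observations),
        "n_used": len(used),
        "n_unmapped": n_unmapped,
        "n_filtered": n_filtered,
    }
    assert counts["n_input_peptides"] == counts["n_used"] + n_unmapped + n_filtered
    return PeptideTable(observations=used, sample_ids=table.sample_ids), counts, warnings


def analyze(
    table: PeptideTable,
    database: dict[str, str],
    design: SampleDesign,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """In-memory pipeline core.

    Returns the protein and Cys-site differential tables (output dialect
    columns plus ``tested``) and an info dict with stage counts and warnings.
    """
    config = config or PipelineConfig()
    if sorted(table.sample_ids) != sorted(design.sample_ids):
        raise ValueError(
            "peptide table and design disagree on samples: "
            f"{table.sample_ids} vs {design.sample_ids}"
        )
    table, counts, warnings = _triage_peptides(table, database, config)

    prot_matrix = rollup_protein_abundance(table, config)
    site_matrix, site_unmapped = rollup_cys_sites(table, database, config)
    for obs in site_unmapped:
        warnings.append(
            f"alkylated peptide {obs.sequence!r}: sequence not found in any mapped protein"
        )
    counts["n_proteins"] = len(prot_matrix.values)
    counts["n_cys_site_groups"] = len(site_matrix.values)
    counts["n_alkylated_unmapped"] = len(site_unmapped)

    center = config.normalization == "median_center"
    prot_stats = differential_stats(
        log2_median_center(prot_matrix, center=center), design, config, compute_q=True
    )
    prot_stats["call"] = call_protein_abundance(prot_stats, config)

    site_stats = differential_stats(
        log2_median_center(site_matrix, center=center), design, config, compute_q=False
    )
    site_stats = call_site_redox(site_stats, prot_stats, config)

    counts["n_proteins_tested"] = int(prot_stats["tested"].sum())
    counts["n_sites_tested"] = int(site_stats["tested"].sum())
    counts["n_degenerate_variance"] = int(
        prot_stats["degenerate"].sum() + site_stats["degenerate"].sum()
    )
    for msg in warnings:
        logger.warning(msg)
    for stage, n in counts.items():
        logger.info("%s = %d", stage, n)
    return prot_stats, site_stats, {"counts": counts, "warnings": warnings}


def run_pipeline(
    peptides: str | Path,
    fasta: str | Path,
    design: str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path = "redoxquant_out",
) -> tuple[pd.DataFrame, pd.DataFrame, RunManifest]:
    """File-to-file pipeline: read inputs, analyze, write result TSVs + manifest."""
    config = config or PipelineConfig()
    sample_design = read_design(design)
    entries = read_fasta(fasta)
    database = fasta_to_dict(entries)
    table = read_peptide_table(peptides, sample_design.sample_ids, config)

    prot_stats, site_stats, info = analyze(table, database, sample_design, config)

    outdir = Path(outdir)
    write_results(prot_stats, site_stats, outdir)
    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=config.seed,
        package_version=__version__,
        input_checksums={
            "peptides": _sha256(peptides),
            "fasta": _sha256(fasta),
            "design": _sha256(design),
        },
        counts=info["counts"],
        warnings=info["warnings"],
    )
    manifest.write(outdir / "run_manifest.json")
    return prot_stats, site_stats, manifest
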