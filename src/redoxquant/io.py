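"""Readers and writers for the pipeline's external tables.

Dialects
--------
* FASTA — standard, via Biopython; the first whitespace-delimited header token
  is the accession, the remainder the strain tag.
* ``peptides.tsv`` — one row per identified peptide form: ``sequence``,
  ``modifications`` (semicolon-separated ``pos:massDa``, 1-based within the
  peptide, empty = unmodified), ``proteins`` (semicolon-separated accessions),
  then one raw-intensity column per sample.
* ``design.tsv`` — ``sample_id``, ``condition``, ``replicate``; the first
  condition encountered is the reference (condition 1) of every fold change.
* ``protein_diff.tsv`` / ``cys_site_diff.tsv`` — result tables, fixed column
  order, rows sorted by feature id, "." decimal separator, ``NA`` for missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import PipelineConfig
from .sites import VALID_RESIDUES, PeptideObservation

PROTEIN_DIFF_COLUMNS = [
    "accession",
    "n_peptides",
    "mean_log2_cond1",
    "mean_log2_cond2",
    "log2fc",
    "fold_change_signed",
    "t",
    "p",
    "q",
    "call",
]

SITE_DIFF_COLUMNS = [
    "accession",
    "site_key",
    "n_peptides",
    "log2fc",
    "fold_change_signed",
    "t",
    "p",
    "protein_log2fc",
    "call",
]

_FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class ProteinEntry:
    """One FASTA record: accession, free-text strain tag, AA sequence."""

    accession: str
    sequence: str
    strain_tag: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: non-amino-acid characters {sorted(bad)}"
            )


@dataclass
class SampleDesign:
    """Ordered sample -> (condition, replicate) assignment.

    Exactly two conditions; condition 1 is the first seen in file order (the
    reference of every fold change), condition 2 the other.
    """

    samples: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        ids = [s for s, _, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in design")
        conds = list(dict.fromkeys(c for _, c, _ in self.samples))
        if len(conds) != 2:
            raise ValueError(f"need exactly 2 conditions, got {conds}")
        for c in conds:
            n = sum(1 for _, cc, _ in self.samples if cc == c)
            if n < 2:
                raise ValueError(f"condition {c!r} has {n} sample(s); need >= 2")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _, _ in self.samples]

    @property
    def conditions(self) -> tuple[str, str]:
        conds = list(dict.fromkeys(c for _, c, _ in self.samples))
        return conds[0], conds[1]

    def group_samples(self, condition: str) -> list[str]:
        return [s for s, c, _ in self.samples if c == condition]


@dataclass
class PeptideTable:
    """Parsed peptide observations plus the sample column order."""

    observations: list[PeptideObservation]
    sample_ids: list[str]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read a protein FASTA into validated entries.

    The accession is the header token before the first whitespace; duplicate
    accessions and non-amino-acid residues are rejected.
    """
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    for rec in records:
        accession = rec.id
        if accession in seen:
            raise ValueError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        strain_tag = rec.description[len(rec.id) :].strip()
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{path}: record {accession!r} has non-amino-acid "
                f"characters {sorted(bad)}"
            )
        entries.append(ProteinEntry(accession=accession, sequence=seq, strain_tag=strain_tag))
    return entries


def write_fasta(entries: list[ProteinEntry], path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(e.sequence), id=e.accession, description=e.strain_tag)
        for e in entries
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


def fasta_to_dict(entries: list[ProteinEntry]) -> dict[str, str]:
    return {e.accession: e.sequence for e in entries}


# ---------------------------------------------------------------------------
# design table


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    for col in ("sample_id", "condition", "replicate"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    samples = [
        (r.sample_id, r.condition, int(r.replicate)) for r in df.itertuples()
    ]
    return SampleDesign(samples=samples)


def write_design(design: SampleDesign, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(design.samples, columns=["sample_id", "condition", "replicate"])
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# peptide table


def format_mods(mods: list[tuple[int, float]]) -> str:
    return ";".join(f"{pos}:{mass:.4f}" for pos, mass in mods)


def parse_mods(cell: str, row: int) -> list[tuple[int, float]]:
    if not cell or (isinstance(cell, float) and math.isnan(cell)):
        return []
    mods = []
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            pos_s, mass_s = token.split(":")
            mods.append((int(pos_s), float(mass_s)))
        except ValueError as exc:
            raise ValueError(
                f"row {row}: cannot parse modification token {token!r}"
            ) from exc
    return mods


def read_peptide_table(
    path: str | Path,
    sample_ids: list[str],
    config: PipelineConfig | None = None,
) -> PeptideTable:
    """Parse ``peptides.tsv`` into observations.

    Missing intensities are empty cells or ``NaN``; a raw 0 is also treated as
    missing by default (``config.zero_is_missing``), the MaxQuant convention
    for non-detections.
    """
    config = config or PipelineConfig()
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "proteins": str})
    required = ["sequence", "modifications", "proteins", *sample_ids]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")

    observations: list[PeptideObservation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        rowd = row._asdict()
        proteins_cell = rowd["proteins"]
        if not isinstance(proteins_cell, str) or not proteins_cell.strip():
            raise ValueError(f"{path}: row {i}: no mapped protein accession")
        proteins = [p for p in proteins_cell.split(";") if p]
        intensities: dict[str, float] = {}
        for sid in sample_ids:
            v = rowd[sid]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            v = float(v)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{path}: row {i}: invalid intensity {v} for {sid}")
            if v == 0 and config.zero_is_missing:
                continue
            intensities[sid] = v
        observations.append(
            PeptideObservation(
                sequence=rowd["sequence"],
                mods=parse_mods(rowd["modifications"], i),
                proteins=proteins,
                intensities=intensities,
            )
        )
    return PeptideTable(observations=observations, sample_ids=list(sample_ids))


def write_peptide_table(table: PeptideTable, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for obs in table.observations:
        row = {
            "sequence": obs.sequence,
            "modifications": format_mods(obs.mods),
            "proteins": ";".join(obs.proteins),
        }
        for sid in table.sample_ids:
            row[sid] = obs.intensities.get(sid, float("nan"))
        rows.append(row)
    columns = ["sequence", "modifications", "proteins", *table.sample_ids]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT, na_rep="")
    return path


# ---------------------------------------------------------------------------
# result tables


def _write_table(df: pd.DataFrame, columns: list[str], sort_by: list[str], path: Path) -> None:
    out = df.reindex(columns=columns)
    if len(out):
        out = out.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT, na_rep="NA")


def write_results(
    protein_results: pd.DataFrame,
    site_results: pd.DataFrame,
    outdir: str | Path,
) -> tuple[Path, Path]:
    """Write ``protein_diff.tsv`` and ``cys_site_diff.tsv`` under ``outdir``.

    Rows are sorted by feature id and floats rendered with a fixed format so
    repeated runs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    protein_path = outdir / "protein_diff.tsv"
    site_path = outdir / "cys_site_diff.tsv"
    _write_table(protein_results, PROTEIN_DIFF_COLUMNS, ["accession"], protein_path)
    _write_table(site_results, SITE_DIFF_COLUMNS, ["accession", "site_key"], site_path)
    return protein_path, site_path


def read_results(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    outdir = Path(outdir)
    prot = pd.read_csv(outdir / "protein_diff.tsv", sep="\t", na_values=["NA"])
    site = pd.read_csv(outdir / "cys_site_diff.tsv", sep="\t", na_values=["NA"])
    return prot, site
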