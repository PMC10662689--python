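"""Synthetic proteomics experiment generator with known ground truth.

The generator emulates the measurement model of the direct-detection redox
workflow on a multi-strain consortium:

* a proteome of ``n_proteins`` families, each with ``n_strains`` homologs
  derived by per-residue copying (K, R, P and C are always preserved so that
  tryptic boundaries and Cys coordinates stay aligned across strains — the
  source of shared-peptide ambiguity in real consortium data);
* fully tryptic peptides (up to ``max_missed_cleavages``), log-normal
  intensities composed of a protein baseline, a peptide ionization efficiency
  fixed effect, a condition effect on protein abundance, and replicate noise;
* cysteine oxidation modelled as occupancy: a fraction ``occ`` of a site's
  molecules is oxidized hence NOT alkylatable, so the HPE-IAM peptide's linear
  intensity is multiplied by ``1 - occ`` for that condition.  Oxidized forms
  are not emitted as separate rows — only the reduced, alkylated form is
  measured, exactly as in the assay;
* intensity-dependent (missing-not-at-random) thinning with a random floor,
  scaled by a single ``missing_rate`` knob (0 disables all missingness).

Identical peptide forms arising from several homologs are merged into one
table row whose intensity is the sum of the sources — what a search engine
would report for a shared peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .io import (
    PeptideTable,
    ProteinEntry,
    SampleDesign,
    fasta_to_dict,
    write_design,
    write_fasta,
    write_peptide_table,
)
from .sites import CysSiteKey, PeptideIndex, PeptideObservation, digest_trypsin

# residues free to vary between homologs: everything except K/R/P (tryptic
# structure) and C (redox sites)
_VARIABLE_RESIDUES = np.array(list("ADEFGHILMNQSTVWY"))


@dataclass
class TruthAssignments:
    """Planted effects, keyed at the homolog-family level."""

    family_log2fc: dict[int, float]
    # (family, 1-based protein position) -> (occupancy cond1, occupancy cond2)
    site_occupancy: dict[tuple[int, int], tuple[float, float]]


@dataclass
class SyntheticTruth:
    """Ground-truth ledger joining every simulated feature to its effect.

    ``proteins``: accession, family, true_log2fc.
    ``sites``: accession, site_key, occupancy per condition, the attenuation
    log2 difference and the resulting true site log2 fold change.
    ``peptides``: every emitted (sequence, modifications) form with each
    generating protein and 1-based start.
    """

    proteins: pd.DataFrame
    sites: pd.DataFrame
    peptides: pd.DataFrame


@dataclass
class SimulatedDataset:
    entries: list[ProteinEntry]
    families: dict[int, list[str]]
    design: SampleDesign
    table: PeptideTable
    truth: SyntheticTruth


def _accession(family: int, strain: int) -> str:
    return f"RQ{family:04d}S{strain + 1}"


def _simulate_base_sequence(cfg: SimConfig, rng: np.random.Generator) -> str:
    """One protein as a chain of tryptic segments ending in K or R."""
    residues: list[str] = []
    while len(residues) < cfg.mean_protein_length:
        seg_len = max(2, int(rng.poisson(cfg.mean_peptide_length)))
        for i in range(seg_len - 1):
            if rng.random() < cfg.cys_frequency:
                residues.append("C")
            else:
                pool = _VARIABLE_RESIDUES
                aa = str(rng.choice(pool))
                # P immediately after K/R would suppress the upstream cleavage
                if i == 0 and aa == "P":  # pragma: no cover - P not in pool
                    aa = "A"
                residues.append(aa)
        residues.append(str(rng.choice(np.array(["K", "R"]))))
    return "".join(residues[: cfg.mean_protein_length])


def _homolog(base: str, identity: float, rng: np.random.Generator) -> str:
    out = []
    for aa in base:
        if aa in "KRPC" or rng.random() < identity:
            out.append(aa)
        else:
            choices = _VARIABLE_RESIDUES[_VARIABLE_RESIDUES != aa]
            out.append(str(rng.choice(choices)))
    return "".join(out)


def simulate_proteome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProteinEntry], dict[int, list[str]]]:
    """Generate the consortium proteome: families of strain homologs.

    Returns the FASTA entries and a map family index -> member accessions.
    Homologs preserve K/R/P/C positions, so all members of a family share
    protein length, tryptic boundaries and Cys coordinates.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    entries: list[ProteinEntry] = []
    families: dict[int, list[str]] = {}
    for fam in range(cfg.n_proteins):
        base = _simulate_base_sequence(cfg, rng)
        members = []
        for strain in range(cfg.n_strains):
            seq = base if strain == 0 else _homolog(base, cfg.homolog_identity, rng)
            acc = _accession(fam, strain)
            entries.append(
                ProteinEntry(accession=acc, sequence=seq, strain_tag=f"strain{strain + 1}")
            )
            members.append(acc)
        families[fam] = members
    return entries, families


def assign_truth(
    entries: list[ProteinEntry],
    families: dict[int, list[str]],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> TruthAssignments:
    """Plant abundance and redox effects, one draw per family.

    Effects are family-level: homologous proteins respond together, which also
    keeps shared peptides internally consistent (a peptide summed over
    homologs still scales exactly by the family fold change).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    by_acc = {e.accession: e for e in entries}
    family_log2fc: dict[int, float] = {}
    site_occupancy: dict[tuple[int, int], tuple[float, float]] = {}
    for fam, members in families.items():
        if rng.random() < cfg.frac_abundance_changed:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            family_log2fc[fam] = sign * cfg.abundance_log2fc_magnitude
        else:
            family_log2fc[fam] = 0.0
        base_seq = by_acc[members[0]].sequence
        for pos0, aa in enumerate(base_seq):
            if aa != "C":
                continue
            pos = pos0 + 1
            if rng.random() < cfg.frac_sites_redox_changed:
                occ = cfg.oxidation_occupancy
                if rng.random() < 0.5:
                    site_occupancy[(fam, pos)] = (0.0, occ)  # more oxidized in cond2
                else:
                    site_occupancy[(fam, pos)] = (occ, 0.0)  # less oxidized in cond2
            else:
                site_occupancy[(fam, pos)] = (0.0, 0.0)
    return TruthAssignments(family_log2fc=family_log2fc, site_occupancy=site_occupancy)


def make_design(cfg: SimConfig) -> SampleDesign:
    """Two conditions x n replicates; condition 1 is the reference."""
    c1, c2 = cfg.condition_names
    samples = [(f"{c1[:1].upper()}{r + 1}", c1, r + 1) for r in range(cfg.n_replicates)]
    samples += [(f"{c2[:1].upper()}{r + 1}", c2, r + 1) for r in range(cfg.n_replicates)]
    return SampleDesign(samples=samples)


def _missing_prob(log2_intensity: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if cfg.missing_rate == 0:
        return np.zeros_like(log2_intensity)
    mid = cfg.base_log2_intensity_mean + cfg.mnar_midpoint_offset * cfg.base_log2_intensity_sd
    mnar = 1.0 / (1.0 + np.exp((log2_intensity - mid) / cfg.mnar_scale))
    return cfg.missing_rate * (
        cfg.random_missing_frac + (1.0 - cfg.random_missing_frac) * mnar
    )


def simulate_peptide_table(
    entries: list[ProteinEntry],
    families: dict[int, list[str]],
    assignments: TruthAssignments,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    design: SampleDesign | None = None,
) -> tuple[PeptideTable, SyntheticTruth]:
    """Emit the peptide intensity table and its ground-truth ledger."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    design = design or make_design(cfg)
    c1, c2 = design.conditions
    sample_conditions = {sid: cond for sid, cond, _ in design.samples}
    sample_ids = design.sample_ids

    database = fasta_to_dict(entries)
    index = PeptideIndex(database)
    family_of = {acc: fam for fam, members in families.items() for acc in members}

    protein_base = {
        e.accession: rng.normal(
            cfg.base_log2_intensity_mean, cfg.base_log2_intensity_sd
        )
        for e in entries
    }
    peptide_effect: dict[str, float] = {}

    # per peptide form: linear contribution per condition, summed over sources
    contrib: dict[tuple[str, tuple[tuple[int, float], ...]], dict[str, float]] = {}
    form_sources: dict[tuple[str, tuple[tuple[int, float], ...]], set[tuple[str, int]]] = {}
    site_records: dict[str, dict] = {}

    from .config import HPEIAM_MASS

    for e in entries:
        fam = family_of[e.accession]
        fc = assignments.family_log2fc[fam]
        for pep, start in digest_trypsin(e.sequence, cfg.max_missed_cleavages):
            if not cfg.min_peptide_length <= len(pep) <= cfg.max_peptide_length:
                continue
            if pep not in peptide_effect:
                peptide_effect[pep] = rng.normal(0.0, cfg.peptide_ionization_sd)
            cys_pep_pos = [i + 1 for i, aa in enumerate(pep) if aa == "C"]
            mods = tuple((p, HPEIAM_MASS) for p in cys_pep_pos)

            base = protein_base[e.accession] + peptide_effect[pep]
            atten = {c1: 1.0, c2: 1.0}
            if cys_pep_pos:
                positions = tuple(start + p - 1 for p in cys_pep_pos)
                occ1s, occ2s = [], []
                for pos in positions:
                    o1, o2 = assignments.site_occupancy[(fam, pos)]
                    occ1s.append(o1)
                    occ2s.append(o2)
                atten[c1] = float(np.prod([1 - o for o in occ1s]))
                atten[c2] = float(np.prod([1 - o for o in occ2s]))

            form = (pep, mods)
            cond_linear = contrib.setdefault(form, {c1: 0.0, c2: 0.0})
            for cond, extra in ((c1, 0.0), (c2, fc)):
                cond_linear[cond] += 2.0 ** (base + extra) * atten[cond]
            form_sources.setdefault(form, set()).add((e.accession, start))

    observations: list[PeptideObservation] = []
    peptide_truth_rows: list[dict] = []
    for form in sorted(contrib, key=lambda f: (f[0], f[1])):
        pep, mods = form
        cond_linear = contrib[form]
        mapped = index.map_peptide(pep)
        # one truth record per site group the pipeline will derive from this
        # form; written for every mapped occurrence so pipeline features
        # always join to truth
        for acc, start in mapped:
            if not mods:
                break
            fam = family_of[acc]
            positions = tuple(start + p - 1 for p, _ in mods)
            occ1s, occ2s = zip(
                *(assignments.site_occupancy[(fam, pos)] for pos in positions)
            )
            att1 = float(np.prod([1 - o for o in occ1s]))
            att2 = float(np.prod([1 - o for o in occ2s]))
            key = CysSiteKey(accession=acc, positions=positions)
            site_records[key.feature_id] = {
                "accession": acc,
                "site_key": key.site_label,
                "occ_cond1": 1.0 - att1,
                "occ_cond2": 1.0 - att2,
                "true_log2_attenuation_diff": float(np.log2(att2) - np.log2(att1)),
                "true_site_log2fc": assignments.family_log2fc[fam]
                + float(np.log2(att2) - np.log2(att1)),
            }
        intensities: dict[str, float] = {}
        for sid in sample_ids:
            cond = sample_conditions[sid]
            log2_i = np.log2(cond_linear[cond]) + rng.normal(0.0, cfg.noise_sd)
            p_miss = float(_missing_prob(np.array(log2_i), cfg))
            if rng.random() < p_miss:
                continue
            intensities[sid] = float(2.0**log2_i)
        observations.append(
            PeptideObservation(
                sequence=pep,
                mods=list(mods),
                proteins=[acc for acc, _ in mapped],
                intensities=intensities,
            )
        )
        for acc, start in sorted(form_sources[form]):
            peptide_truth_rows.append(
                {
                    "sequence": pep,
                    "modifications": ";".join(f"{p}:{m:.4f}" for p, m in mods),
                    "accession": acc,
                    "start": start,
                }
            )

    protein_truth = pd.DataFrame(
        [
            {
                "accession": e.accession,
                "family": family_of[e.accession],
                "true_log2fc": assignments.family_log2fc[family_of[e.accession]],
            }
            for e in entries
        ]
    )
    site_truth = (
        pd.DataFrame(sorted(site_records.values(), key=lambda r: (r["accession"], r["site_key"])))
        if site_records
        else pd.DataFrame(
            columns=[
                "accession",
                "site_key",
                "occ_cond1",
                "occ_cond2",
                "true_log2_attenuation_diff",
                "true_site_log2fc",
            ]
        )
    )
    truth = SyntheticTruth(
        proteins=protein_truth,
        sites=site_truth,
        peptides=pd.DataFrame(peptide_truth_rows),
    )
    return PeptideTable(observations=observations, sample_ids=sample_ids), truth


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Full deterministic simulation from a single seed."""
    rng = np.random.default_rng(cfg.seed)
    entries, families = simulate_proteome(cfg, rng)
    assignments = assign_truth(entries, families, cfg, rng)
    design = make_design(cfg)
    table, truth = simulate_peptide_table(entries, families, assignments, cfg, rng, design)
    return SimulatedDataset(
        entries=entries, families=families, design=design, table=table, truth=truth
    )


# ---------------------------------------------------------------------------
# truth table I/O (single TSV with a `level` discriminator column)

_TRUTH_COLUMNS = [
    "level",
    "accession",
    "site_key",
    "family",
    "true_log2fc",
    "occ_cond1",
    "occ_cond2",
    "true_log2_attenuation_diff",
    "true_site_log2fc",
    "sequence",
    "modifications",
    "start",
]


def write_truth(truth: SyntheticTruth, path: str | Path) -> Path:
    path = Path(path)
    frames = []
    for level, df in (
        ("protein", truth.proteins),
        ("site", truth.sites),
        ("peptide", truth.peptides),
    ):
        part = df.copy()
        part.insert(0, "level", level)
        frames.append(part)
    out = pd.concat(frames, ignore_index=True).reindex(columns=_TRUTH_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="")
    return path


def read_truth(path: str | Path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t")
    def _part(level: str, cols: list[str]) -> pd.DataFrame:
        part = df[df["level"] == level].reindex(columns=cols).reset_index(drop=True)
        return part

    return SyntheticTruth(
        proteins=_part("protein", ["accession", "family", "true_log2fc"]),
        sites=_part(
            "site",
            [
                "accession",
                "site_key",
                "occ_cond1",
                "occ_cond2",
                "true_log2_attenuation_diff",
                "true_site_log2fc",
            ],
        ),
        peptides=_part("peptide", ["sequence", "modifications", "accession", "start"]),
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write proteome.fasta, peptides.tsv, design.tsv and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return {
        "fasta": write_fasta(ds.entries, outdir / "proteome.fasta"),
        "peptides": write_peptide_table(ds.table, outdir / "peptides.tsv"),
        "design": write_design(ds.design, outdir / "design.tsv"),
        "truth": write_truth(ds.truth, outdir / "truth.tsv"),
    }
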