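"""Peptide-to-protein mapping and cysteine-site annotation.

The coordinate frame is the protein sequence, 1-based and inclusive, so that a
site labelled ``C42`` is the cysteine at ``sequence[41]`` — the convention
used when naming residues such as Cys42/Cys47 of dihydrolipoamide
dehydrogenase.  A peptide carrying one or more HPE-IAM-alkylated cysteines is
assigned a *site group*: the exact sorted set of alkylated positions it
covers.  Peptides with the same group are aggregated together downstream;
overlapping-but-unequal groups stay distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import PipelineConfig

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
VALID_RESIDUES = AMINO_ACIDS | {"X"}

_MISSING = float("nan")


@dataclass(frozen=True)
class CysSiteKey:
    """Identity of a Cys site group: protein + sorted alkylated positions."""

    accession: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("a site key needs at least one position")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")

    @property
    def site_label(self) -> str:
        """Human-readable label, e.g. ``C42_C47``."""
        return "_".join(f"C{p}" for p in self.positions)

    @property
    def feature_id(self) -> str:
        return f"{self.accession}|{self.site_label}"


def parse_site_label(label: str) -> tuple[int, ...]:
    """Inverse of :attr:`CysSiteKey.site_label` (``"C42_C47"`` -> ``(42, 47)``)."""
    try:
        positions = tuple(int(tok[1:]) for tok in label.split("_"))
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed site label {label!r}") from exc
    return positions


@dataclass
class PeptideObservation:
    """One identified peptide form with its per-sample raw intensities.

    ``mods`` holds (position within peptide, modification mass in Da) pairs,
    1-based.  ``proteins`` lists mapped accessions as reported by the search;
    ``mappings`` (accession, 1-based start in protein) pairs are resolved
    against the sequence database.
    """

    sequence: str
    mods: list[tuple[int, float]] = field(default_factory=list)
    proteins: list[str] = field(default_factory=list)
    intensities: dict[str, float] = field(default_factory=dict)
    mappings: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for pos, _mass in self.mods:
            if not 1 <= pos <= n:
                raise ValueError(
                    f"modification position {pos} outside peptide of length {n}"
                )


def digest_trypsin(
    sequence: str, max_missed_cleavages: int = 0
) -> list[tuple[str, int]]:
    """In-silico tryptic digestion with 1-based start coordinates.

    Cleaves C-terminal to K or R unless the next residue is P.  Returns every
    peptide with at most ``max_missed_cleavages`` internal cleavage sites, as
    ``(peptide, start)`` pairs ordered by start then length.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")

    # boundaries[i] is the 0-based index at which segment i starts
    boundaries = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            boundaries.append(i + 1)
    boundaries.append(len(sequence))

    peptides: list[tuple[str, int]] = []
    n_seg = len(boundaries) - 1
    for i in range(n_seg):
        for j in range(i + 1, min(i + 1 + max_missed_cleavages + 1, n_seg + 1)):
            start, end = boundaries[i], boundaries[j]
            peptides.append((sequence[start:end], start + 1))
    return peptides


class PeptideIndex:
    """Exact-substring peptide lookup over a protein database.

    A k-mer prefix index keeps mapping linear-time for realistic peptide
    tables; peptides shorter than k fall back to a scan.
    """

    _K = 7

    def __init__(self, database: dict[str, str]):
        self.database = dict(database)
        self._index: dict[str, list[tuple[str, int]]] = {}
        for acc, seq in self.database.items():
            for i in range(len(seq) - self._K + 1):
                self._index.setdefault(seq[i : i + self._K], []).append((acc, i))

    def map_peptide(self, peptide: str) -> list[tuple[str, int]]:
        if not peptide:
            return []
        hits: list[tuple[str, int]] = []
        if len(peptide) >= self._K:
            for acc, i in self._index.get(peptide[: self._K], ()):
                if self.database[acc].startswith(peptide, i):
                    hits.append((acc, i + 1))
        else:
            for acc, seq in self.database.items():
                start = seq.find(peptide)
                while start != -1:
                    hits.append((acc, start + 1))
                    start = seq.find(peptide, start + 1)
        hits.sort()
        return hits


def map_peptide(
    peptide: str, database: dict[str, str] | PeptideIndex
) -> list[tuple[str, int]]:
    """All exact occurrences of ``peptide`` in the database.

    Returns ``(accession, start)`` pairs, 1-based, sorted by accession then
    start; an unmatched peptide yields an empty list.
    """
    if isinstance(database, PeptideIndex):
        return database.map_peptide(peptide)
    hits: list[tuple[str, int]] = []
    for acc in sorted(database):
        seq = database[acc]
        start = seq.find(peptide)
        while start != -1:
            hits.append((acc, start + 1))
            start = seq.find(peptide, start + 1)
    return hits


def hpeiam_mod_positions(
    obs: PeptideObservation, config: PipelineConfig | None = None
) -> list[int]:
    """Peptide positions (1-based) carrying the HPE-IAM alkylation mass.

    Raises
    ------
    ValueError
        If a modification within the mass window sits on a non-Cys residue —
        that indicates an inconsistent upstream search result.
    """
    config = config or PipelineConfig()
    positions = []
    for pos, mass in obs.mods:
        if abs(mass - config.hpeiam_mass) <= config.mass_tolerance:
            residue = obs.sequence[pos - 1]
            if residue != "C":
                raise ValueError(
                    f"HPE-IAM mass {mass} at position {pos} of "
                    f"{obs.sequence!r} sits on {residue!r}, not Cys"
                )
            positions.append(pos)
    return sorted(positions)


def is_hpeiam_alkylated(
    obs: PeptideObservation, config: PipelineConfig | None = None
) -> bool:
    """True iff the peptide carries >= 1 HPE-IAM-alkylated cysteine."""
    return bool(hpeiam_mod_positions(obs, config))


def annotate_site_key(
    obs: PeptideObservation,
    mapping: tuple[str, int],
    database: dict[str, str] | None = None,
    config: PipelineConfig | None = None,
) -> CysSiteKey:
    """Protein-coordinate site group of an alkylated peptide.

    ``mapping`` is an ``(accession, start)`` pair; each alkylated peptide
    position ``p`` becomes protein position ``start + p - 1``.  When the
    database is supplied, every computed position is checked to index a Cys.
    """
    pep_positions = hpeiam_mod_positions(obs, config)
    if not pep_positions:
        raise ValueError("peptide carries no HPE-IAM alkylation")
    accession, start = mapping
    positions = tuple(start + p - 1 for p in pep_positions)
    if database is not None:
        seq = database[accession]
        if seq[start - 1 : start - 1 + len(obs.sequence)] != obs.sequence:
            raise ValueError(
                f"peptide {obs.sequence!r} does not match {accession} at {start}"
            )
        for pos in positions:
            if seq[pos - 1] != "C":
                raise ValueError(
                    f"computed site {accession}:{pos} is {seq[pos - 1]!r}, not Cys"
                )
    return CysSiteKey(accession=accession, positions=positions)
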