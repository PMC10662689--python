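"""Pipeline and simulator configuration.

Two dataclasses hold every tunable of the analysis and of the synthetic-data
generator.  A single YAML file with top-level sections ``pipeline:`` and
``simulate:`` maps onto both; absent keys fall back to the defaults below.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Monoisotopic mass added by beta-(4-hydroxyphenyl)ethyl iodoacetamide
#: alkylation of a reduced cysteine thiol, in Da.
HPEIAM_MASS = 177.0790

#: Monoisotopic mass of methionine oxidation, in Da (a common dynamic
#: modification that must not be confused with the Cys alkylation).
MET_OXIDATION_MASS = 15.9949


@dataclass
class PipelineConfig:
    """Thresholds and policies of the quantification pipeline.

    Attributes
    ----------
    fc_threshold
        Minimum fold change (ratio scale, > 1) for a differential call.
    alpha_abundance
        Significance level applied to permutation-FDR q-values for
        protein-abundance calls.
    alpha_site
        Significance level applied to raw t-test p-values for Cys-site
        oxidation calls.
    decoupling_mode
        How criterion (c) — "parent protein abundance unchanged" — is read:
        ``"fold_change"`` requires |signed fold change| < ``decoupling_bound``
        (so |log2 FC| < log2 bound); ``"log2_fold_change"`` requires
        |log2 FC| < ``decoupling_bound`` directly.
    decoupling_bound
        The bound used by the decoupling test (same number, two readings).
    hpeiam_mass, mass_tolerance
        Target alkylation mass and the +/- window (Da) used to recognise it.
    min_valid_per_group
        Minimum non-missing values per condition for a feature to be tested.
    shared_peptide_mode
        ``"all_mapped"``: a shared peptide contributes its full intensity to
        every mapped protein; ``"unique_only"``: only uniquely mapped
        peptides are used.
    n_permutations
        ``"exhaustive"`` enumerates all distinct unordered label splits when
        there are at most 10 of them (the 3-vs-3 case); an integer draws that
        many random splits.
    zero_is_missing
        Treat raw intensity 0 as a non-detection (missing) rather than a
        measured zero.
    normalization
        ``"median_center"`` (default) subtracts each sample's log2 median;
        ``"none"`` applies only the log2 transform — appropriate when samples
        are already on a common loading scale, since median centering shifts
        all fold changes by the between-condition median difference.
    welch
        Use Welch's unequal-variance t-test instead of pooled Student's t.
    s0
        Fudge factor added to the denominator of the t statistic used for the
        permutation FDR (0 disables it).
    """

    fc_threshold: float = 1.5
    alpha_abundance: float = 0.05
    alpha_site: float = 0.05
    decoupling_mode: str = "fold_change"
    decoupling_bound: float = 1.5
    hpeiam_mass: float = HPEIAM_MASS
    mass_tolerance: float = 0.01
    min_valid_per_group: int = 2
    shared_peptide_mode: str = "all_mapped"
    n_permutations: int | str = "exhaustive"
    zero_is_missing: bool = True
    normalization: str = "median_center"
    welch: bool = False
    s0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must be > 1")
        for name in ("alpha_abundance", "alpha_site"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not self.mass_tolerance > 0:
            raise ValueError("mass_tolerance must be positive")
        if self.min_valid_per_group < 2:
            raise ValueError("min_valid_per_group must be >= 2")
        if self.decoupling_mode not in ("fold_change", "log2_fold_change"):
            raise ValueError(f"unknown decoupling_mode {self.decoupling_mode!r}")
        if self.normalization not in ("median_center", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.shared_peptide_mode not in ("all_mapped", "unique_only"):
            raise ValueError(
                f"unknown shared_peptide_mode {self.shared_peptide_mode!r}"
            )
        if isinstance(self.n_permutations, str) and self.n_permutations != "exhaustive":
            raise ValueError("n_permutations must be an integer or 'exhaustive'")


@dataclass
class SimConfig:
    """Parameters of the synthetic proteomics experiment.

    The generator emulates a two-condition (glucose vs lignin), three-replicate
    label-free experiment on a multi-strain consortium: log-normal peptide
    intensities, condition effects on protein abundance, per-Cys-site oxidation
    occupancy that multiplicatively attenuates the alkylated peptide signal,
    shared peptides between strain homologs, and intensity-dependent missing
    values.
    """

    n_proteins: int = 100          # protein families
    n_strains: int = 3
    homolog_identity: float = 0.9  # per-residue copy probability
    mean_protein_length: int = 300
    mean_peptide_length: int = 15  # tryptic segment target length
    cys_frequency: float = 0.02
    n_replicates: int = 3
    condition_names: tuple[str, str] = ("glucose", "lignin")
    base_log2_intensity_mean: float = 23.0
    base_log2_intensity_sd: float = 2.0
    peptide_ionization_sd: float = 1.5
    noise_sd: float = 0.25
    frac_abundance_changed: float = 0.3
    abundance_log2fc_magnitude: float = 2.0
    frac_sites_redox_changed: float = 0.1
    oxidation_occupancy: float = 0.5   # occupancy of the oxidised condition at a changed site
    missing_rate: float = 0.0          # max missingness prob; 0 disables thinning
    mnar_midpoint_offset: float = -2.0  # logistic midpoint, in SDs below base mean
    mnar_scale: float = 1.0
    random_missing_frac: float = 0.2   # share of missing_rate that is intensity-independent
    min_peptide_length: int = 6
    max_peptide_length: int = 45
    max_missed_cleavages: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "homolog_identity",
            "cys_frequency",
            "frac_abundance_changed",
            "frac_sites_redox_changed",
            "missing_rate",
            "random_missing_frac",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.oxidation_occupancy < 1:
            raise ValueError("oxidation_occupancy must lie in [0, 1)")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if len(self.condition_names) != 2:
            raise ValueError("exactly two conditions are supported")


def _filter_kwargs(cls, data: dict) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return data


def load_config(path: str | Path) -> tuple[PipelineConfig, SimConfig]:
    """Load a YAML config with optional ``pipeline`` and ``simulate`` sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    pipe = PipelineConfig(**_filter_kwargs(PipelineConfig, raw.get("pipeline", {}) or {}))
    sim_raw = raw.get("simulate", {}) or {}
    if "condition_names" in sim_raw:
        sim_raw["condition_names"] = tuple(sim_raw["condition_names"])
    sim = SimConfig(**_filter_kwargs(SimConfig, sim_raw))
    return pipe, sim


def config_hash(cfg) -> str:
    """Stable short hash of a config dataclass, for run manifests."""
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
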