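# Methods

## Quantification model

The assay blocks reduced cysteine thiols with HPE-IAM (monoisotopic addition
177.0790 Da) during lysis; oxidized thiol forms (disulfide,
S-mycothionylation, sulfinic/sulfonic acid) are not alkylated and — in this
workflow — not measured. Consequences built into the package:

- An HPE-IAM-Cys peptide's intensity is proportional to the *reduced*
  fraction of the cysteines it covers. Oxidation is inferred inversely:
  higher alkylated intensity ⇒ lower oxidation. All direction labels
  (`less_oxidized` / `more_oxidized`) follow this inversion.
- The aggregation unit for redox quantification is the **site group**: the
  exact sorted set of alkylated Cys positions (1-based protein coordinates)
  covered by a peptide. Peptides with the same group — missed-cleavage or
  charge variants — are summed; overlapping-but-unequal groups stay separate,
  because merging them would require an occupancy model the data do not
  identify. Multi-Cys peptides yield joint groups (e.g. `C42_C47`) that are
  reported jointly.
- Protein abundance is the plain sum of the MS1 intensities of all assigned
  peptides (alkylated and unmodified alike). Summation — not a
  delayed-normalization LFQ algorithm — is the package's operational
  definition of abundance; it is transparent, conservation-testable and
  adequate for the two-condition contrast. (Note this means strong oxidation
  changes bleed marginally into the protein sum through the attenuated Cys
  peptides; the decoupling criterion below bounds the practical impact.)

Modification matching uses |mass − 177.0790| ≤ 0.01 Da on a Cys residue;
an alkylation-mass modification on a non-Cys residue is treated as an
upstream search inconsistency and raised as an error, not silently dropped.
Methionine oxidation (15.9949 Da) and other modifications are ignored for
site detection.

### Shared peptides

In consortium samples the strains' proteomes are highly similar and many
peptides map to several proteins. Two policies are provided:

- `all_mapped` (default): a shared peptide's full intensity contributes to
  every mapped protein / site group — no splitting. Rollup conservation then
  holds in the multiplicity-weighted sense (column totals equal peptide
  totals weighted by each peptide's mapping count), which is what the tests
  assert.
- `unique_only`: only uniquely mapping peptides are used.

No razor-peptide or proportional-split heuristic is offered; both implemented
policies are exactly auditable.

## Statistics

1. **Normalization.** log2 transform, then per-sample median centering
   (every column median becomes 0). Centering estimates sample loading from
   the data; it shifts all fold changes by the between-condition difference
   of column medians, which is zero only when the feature population is
   mostly unchanged. `normalization: none` skips centering for inputs already
   on a common scale — the synthetic generator emits such data (it has no
   loading effects), and the exact-recovery tests run in that mode.
2. **Testing.** Two-sided Student's t with pooled variance,
   df = n1 + n2 − 2 (Welch available via `welch: true`). Features need ≥ 2
   present values per condition (`min_valid_per_group`); others are reported
   `not_tested`. Zero pooled variance with equal means gives (t = 0, p = 1);
   with unequal means the feature is flagged `degenerate` and given the
   smallest positive p — with three identical replicates this is evidence of
   a perfectly reproducible difference, not of no information.
3. **Permutation FDR (protein level).** SAM-style with s0 = 0 by default
   (`s0` exposed for sensitivity scans):
   `E_false(i) = mean over label permutations of #{j : |t_perm_j| ≥ |t_obs_i|}`,
   `q_raw(i) = E_false(i) / #{j : |t_obs_j| ≥ |t_obs_i|}`, then a monotone
   non-increasing-in-|t| envelope (step-up, as in BH) clipped at 1. For
   3-vs-3 designs the 10 distinct unordered splits are enumerated and the
   identity labelling is excluded from the null (9 permutations); larger
   designs draw `n_permutations` distinct random splits from the config seed.
4. **Calls.** Strict inequalities throughout (thresholds are written as
   `>` / `<`). Protein: q < `alpha_abundance` (0.05) and |signed fold| >
   `fc_threshold` (1.5). Site: raw p < `alpha_site` (0.05), |signed fold| >
   1.5, **and** decoupling — the parent protein's abundance unchanged.
   Signed fold change is `2^log2fc` for increases and `−2^(−log2fc)` for
   decreases, so its magnitude is always ≥ 1.

### The decoupling criterion, two readings

"Protein abundance unchanged" can be read on the ratio scale
(|protein fold| < 1.5, i.e. |log2fc| < log2 1.5 ≈ 0.585) or on the log2 scale
(|log2fc| < 1.5, i.e. fold < 2.83). Both are implemented
(`decoupling_mode: fold_change | log2_fold_change`); the ratio-scale reading
is the default because it matches the 1.5-fold convention used everywhere
else in the criteria. The log2 reading is strictly looser, so its call set is
a superset (a tested invariant). `recount_published` tabulates counts under
both modes rather than guessing which produced any previously published
tally.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions and are not tuned per test.

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 100 | homolog families |
| `n_strains` | 3 | strain homologs per family |
| `homolog_identity` | 0.9 | per-residue copy probability |
| `mean_protein_length` | 300 | residues |
| `mean_peptide_length` | 15 | tryptic segment target |
| `cys_frequency` | 0.02 | per-residue Cys probability |
| `n_replicates` | 3 | per condition (glucose, lignin) |
| `base_log2_intensity_mean/sd` | 23 / 2 | protein baseline, log2 |
| `peptide_ionization_sd` | 1.5 | fixed per-sequence effect, log2 |
| `noise_sd` | 0.25 | replicate noise, log2 |
| `frac_abundance_changed` | 0.3 | families with a planted ±2 log2 effect |
| `frac_sites_redox_changed` | 0.1 | Cys positions with occupancy change |
| `oxidation_occupancy` | 0.5 | oxidized fraction at a changed site |
| `missing_rate` | 0.0 | max missingness probability (0 = none) |
| `max_missed_cleavages` | 2 | digestion depth |

Mechanics worth knowing:

- Homologs preserve K/R/P/C positions, so all members of a family share
  length, tryptic boundaries and Cys coordinates; substitutions never
  introduce those residues. This reproduces the consortium's shared-peptide
  structure while keeping coordinates aligned.
- Abundance and occupancy effects are planted **per family** — homologous
  proteins respond together. A shared peptide summed over homologs then
  still scales exactly by the family fold change, which is what makes exact
  noiseless recovery well-defined.
- Oxidation multiplies the alkylated peptide's linear intensity by
  `Π (1 − occ)` over its covered sites, per condition; oxidized forms are
  not emitted as separate rows (the assay does not measure them).
- Identical peptide forms from several proteins are merged into one table
  row with summed intensity — what a search engine reports.
- Missingness is missing-not-at-random: a logistic function of log2
  intensity (midpoint 2 SD below the baseline mean) plus a 20% random floor,
  all scaled by `missing_rate` so 0 disables thinning entirely.

What the simulator does **not** emulate: retention-time/charge-state
structure, interference and co-isolation, non-tryptic cleavage,
search-engine FDR, inter-sample loading differences, and biological
covariance between proteins. Passing recovery and calibration tests
therefore validates the pipeline's arithmetic and statistics, not its
robustness to those real-data phenomena.

## Numerical and design notes

- Raw intensity 0 is treated as missing by default (non-detection
  convention); configurable via `zero_is_missing`.
- A rollup cell is missing iff all contributing peptide intensities are
  missing in that sample (`min_count=1` semantics).
- Median centering leaves an even-count column's median within ~1 ulp of 0
  (the median of an even count averages two floats); odd counts are exact.
- With centering on, noiseless estimates differ from planted truth by one
  global constant (the column-median shift) — asserted as a shift-invariance
  test; exact recovery tests run with `normalization: none` (see above).
- Result TSVs are written with a fixed column order, "%.10g" floats, `NA`
  for missing, rows sorted by feature id: reruns are byte-identical, and the
  run manifest intentionally contains no timestamps.
- Coordinates are 1-based and inclusive on the protein sequence throughout
  (`C42` is `sequence[41]`), matching conventional site naming.
- I/L ambiguity is not collapsed in mapping: the upstream search already
  resolved peptide identity, and collapsing would create spurious shared
  peptides.

## Problem sizes used in the checks

The bundled verification (`scripts/acceptance.py`, test suite) uses
scaled-down but structurally complete experiments chosen as the smallest
sizes at which the measured properties are statistically meaningful: a
150-family × 3-strain main run (≈ 450 proteins, ≈ 3 000 site groups), a
500-protein single-strain null simulation for calibration, 25-family
noiseless runs for exact recovery, and 1 000 random 3-vs-3 draws for the
t-test reference comparison.

## Known limitations

- The permutation FDR is the SAM-style estimator defined above; other tools'
  permutation FDR implementations (and any nonzero s0 default) can give
  different q-values, so externally published counts are *recounted and
  tabulated*, never asserted, by `recount_published`.
- Summed-intensity abundance is not MaxLFQ; absolute comparisons across very
  different peptide complements are out of scope.
- No missing-value imputation, moderated variance estimation, PTM
  localization scoring, or multi-condition designs.
- `all_mapped` shared-peptide handling double-counts shared signal at the
  feature level (by design, for auditability); interpret consortium-level
  protein sums accordingly.
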