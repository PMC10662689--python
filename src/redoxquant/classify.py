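"""Differential-abundance and abundance-decoupled redox calls.

Protein abundance call (condition 2 vs condition 1):
  ``up``   — q < alpha_abundance and signed fold change >  fc_threshold
  ``down`` — q < alpha_abundance and signed fold change < -fc_threshold
  ``ns``   — tested but not both criteria;  ``not_tested`` otherwise.
All comparisons are strict.

Cys-site redox call: the site's HPE-IAM-Cys intensity reports the *reduced*
thiol fraction, so direction labels are inverted — an intensity increase means
the site became LESS oxidized, a decrease MORE oxidized.  A site is called
only when (a) raw p < alpha_site, (b) |signed fold change| > fc_threshold, and
(c) the parent protein's own abundance is not substantially changed (the
decoupling criterion), so that a redox call cannot be a disguised expression
change.  Criterion (c) has two readings, both implemented:

* ``fold_change`` (default): |protein signed fold change| < decoupling_bound,
  i.e. |protein log2 FC| < log2(bound);
* ``log2_fold_change``: |protein log2 FC| < decoupling_bound directly —
  a much looser gate for the same nominal bound of 1.5.

Sites failing (c) are ``excluded_abundance_coupled``; sites whose parent
protein was never quantified are ``excluded_no_protein``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig

PROTEIN_CALLS = ("up", "down", "ns", "not_tested")
SITE_CALLS = (
    "less_oxidized",
    "more_oxidized",
    "ns",
    "excluded_abundance_coupled",
    "excluded_no_protein",
    "not_tested",
)


def call_protein_abundance(
    results: pd.DataFrame, config: PipelineConfig | None = None
) -> pd.Series:
    """Vectorized abundance call for a protein differential table."""
    config = config or PipelineConfig()
    q = results["q"].to_numpy(dtype=float)
    fcs = results["fold_change_signed"].to_numpy(dtype=float)
    tested = results["tested"].to_numpy(dtype=bool)

    call = np.where(tested, "ns", "not_tested").astype(object)
    sig = tested & (q < config.alpha_abundance)
    call[sig & (fcs > config.fc_threshold)] = "up"
    call[sig & (fcs < -config.fc_threshold)] = "down"
    return pd.Series(call, index=results.index, name="call")


def _decoupled(
    protein_log2fc: np.ndarray, config: PipelineConfig
) -> np.ndarray:
    """Criterion (c): parent protein abundance not substantially changed."""
    if config.decoupling_mode == "fold_change":
        bound = np.log2(config.decoupling_bound)
    else:
        bound = config.decoupling_bound
    return np.abs(protein_log2fc) < bound


def call_site_redox(
    site_results: pd.DataFrame,
    protein_results: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Redox calls for a Cys-site differential table.

    Returns the site table with two added columns: ``protein_log2fc`` (the
    parent protein's log2 fold change, NaN when the protein was not
    quantified/tested) and ``call``.
    """
    config = config or PipelineConfig()
    tested_prot = protein_results[protein_results["tested"].astype(bool)]
    accessions = (
        tested_prot["accession"]
        if "accession" in tested_prot.columns
        else pd.Series(tested_prot.index, index=tested_prot.index)
    )
    by_acc = pd.Series(tested_prot["log2fc"].values, index=accessions.values)

    protein_log2fc = (
        site_results["accession"].map(by_acc).to_numpy(dtype=float)
        if len(site_results)
        else np.array([], dtype=float)
    )

    p = site_results["p"].to_numpy(dtype=float)
    fcs = site_results["fold_change_signed"].to_numpy(dtype=float)
    tested = site_results["tested"].to_numpy(dtype=bool)

    call = np.full(len(site_results), "ns", dtype=object)
    call[~tested] = "not_tested"
    no_protein = tested & np.isnan(protein_log2fc)
    call[no_protein] = "excluded_no_protein"

    candidate = (
        tested
        & ~no_protein
        & (p < config.alpha_site)
        & (np.abs(fcs) > config.fc_threshold)
    )
    with np.errstate(invalid="ignore"):
        passes_c = _decoupled(protein_log2fc, config)
    call[candidate & ~passes_c] = "excluded_abundance_coupled"
    call[candidate & passes_c & (fcs > 0)] = "less_oxidized"
    call[candidate & passes_c & (fcs < 0)] = "more_oxidized"

    out = site_results.copy()
    out["protein_log2fc"] = protein_log2fc
    out["call"] = call
    return out
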