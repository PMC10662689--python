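"""Peptide-to-feature intensity rollups.

Two aggregations, both plain sums of raw MS1 intensities:

* protein abundance — every peptide assigned to a protein contributes,
  alkylated or not;
* Cys-site oxidation — only HPE-IAM-alkylated peptides contribute, grouped by
  their exact site group (protein accession + sorted alkylated positions).

A cell is missing iff every contributing peptide intensity is missing in that
sample.  Shared peptides follow ``config.shared_peptide_mode``: ``all_mapped``
adds the full intensity to every mapped protein (no splitting), while
``unique_only`` drops peptides with more than one mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import PeptideTable
from .sites import CysSiteKey, PeptideObservation, annotate_site_key, is_hpeiam_alkylated


@dataclass
class QuantMatrix:
    """Feature-by-sample intensity matrix with per-feature metadata.

    ``values`` is indexed by feature id (protein accession, or
    ``accession|C..`` for site groups) with one column per sample; missing
    cells are NaN.  ``feature_meta`` shares the index and carries at least
    ``accession`` and ``n_peptides``.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    kind: str = "protein"  # or "site"
    scale: str = "raw"  # or "log2" after normalization

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.feature_meta.index):
            raise ValueError("values and feature_meta must share an index")
        if self.scale == "raw":
            present = self.values.to_numpy(dtype=float)
            if np.any(present[~np.isnan(present)] < 0):
                raise ValueError("raw intensities must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _empty_matrix(sample_ids: list[str], meta_cols: list[str], kind: str) -> QuantMatrix:
    idx = pd.Index([], name="feature_id", dtype=object)
    return QuantMatrix(
        values=pd.DataFrame(columns=sample_ids, index=idx, dtype=float),
        feature_meta=pd.DataFrame(columns=meta_cols, index=idx),
        kind=kind,
    )


def _peptide_frame(
    rows: list[tuple[str, PeptideObservation]], sample_ids: list[str]
) -> pd.DataFrame:
    data = {
        "feature_id": [fid for fid, _ in rows],
    }
    for sid in sample_ids:
        data[sid] = [obs.intensities.get(sid, np.nan) for _, obs in rows]
    return pd.DataFrame(data)


def rollup_protein_abundance(
    table: PeptideTable, config: PipelineConfig | None = None
) -> QuantMatrix:
    """Sum peptide intensities per mapped protein per sample."""
    config = config or PipelineConfig()
    rows: list[tuple[str, PeptideObservation]] = []
    for obs in table.observations:
        accessions = list(dict.fromkeys(obs.proteins))
        if config.shared_peptide_mode == "unique_only" and len(accessions) != 1:
            continue
        for acc in accessions:
            rows.append((acc, obs))
    if not rows:
        return _empty_matrix(table.sample_ids, ["accession", "n_peptides"], "protein")

    df = _peptide_frame(rows, table.sample_ids)
    grouped = df.groupby("feature_id", sort=True)
    values = grouped[table.sample_ids].sum(min_count=1)
    meta = pd.DataFrame(
        {"accession": values.index, "n_peptides": grouped.size()},
        index=values.index,
    )
    values.index.name = meta.index.name = "feature_id"
    return QuantMatrix(values=values, feature_meta=meta, kind="protein")


def rollup_cys_sites(
    table: PeptideTable,
    database: dict[str, str],
    config: PipelineConfig | None = None,
) -> tuple[QuantMatrix, list[PeptideObservation]]:
    """Sum HPE-IAM-Cys peptide intensities per Cys site group per sample.

    Non-alkylated peptides are excluded entirely.  An alkylated peptide whose
    sequence cannot be located in any of its mapped proteins is excluded and
    returned in the unmapped list for the caller to log.
    """
    config = config or PipelineConfig()
    rows: list[tuple[str, PeptideObservation]] = []
    meta_rows: dict[str, CysSiteKey] = {}
    unmapped: list[PeptideObservation] = []

    for obs in table.observations:
        if not is_hpeiam_alkylated(obs, config):
            continue
        accessions = list(dict.fromkeys(obs.proteins))
        if config.shared_peptide_mode == "unique_only" and len(accessions) != 1:
            continue
        mappings: list[tuple[str, int]] = []
        for acc in accessions:
            seq = database.get(acc)
            if seq is None:
                continue
            start = seq.find(obs.sequence)
            while start != -1:
                mappings.append((acc, start + 1))
                start = seq.find(obs.sequence, start + 1)
        if not mappings:
            unmapped.append(obs)
            continue
        for mapping in mappings:
            key = annotate_site_key(obs, mapping, database=database, config=config)
            rows.append((key.feature_id, obs))
            meta_rows[key.feature_id] = key

    if not rows:
        return (
            _empty_matrix(
                table.sample_ids, ["accession", "site_key", "n_peptides"], "site"
            ),
            unmapped,
        )

    df = _peptide_frame(rows, table.sample_ids)
    grouped = df.groupby("feature_id", sort=True)
    values = grouped[table.sample_ids].sum(min_count=1)
    meta = pd.DataFrame(
        {
            "accession": [meta_rows[fid].accession for fid in values.index],
            "site_key": [meta_rows[fid].site_label for fid in values.index],
            "n_peptides": grouped.size(),
        },
        index=values.index,
    )
    values.index.name = meta.index.name = "feature_id"
    return QuantMatrix(values=values, feature_meta=meta, kind="site"), unmapped
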