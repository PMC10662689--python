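"""Scoring pipeline output against ground truth, and recounting calls from
externally supplied per-sample intensity tables.

``score_against_truth`` joins pipeline results to a
:class:`~redoxquant.simulate.SyntheticTruth` ledger and reports detection
power, empirical false-discovery rate, and log2-fold-change RMSE at both the
protein and the Cys-site level, plus call-by-truth confusion tables.

``recount_published`` re-applies the call criteria to any protein / site
table that carries per-sample raw intensities in the package's column
dialects (a column mapping adapts foreign layouts), returning the number of
up- and downregulated proteins and of differentially oxidized sites under
both readings of the abundance-decoupling criterion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import call_protein_abundance, call_site_redox
from .config import PipelineConfig
from .io import SampleDesign
from .rollup import QuantMatrix
from .simulate import SyntheticTruth
from .stats import differential_stats, log2_median_center


@dataclass
class EvalReport:
    abundance: dict
    redox: dict
    confusion: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _score_level(
    merged: pd.DataFrame,
    changed: np.ndarray,
    direction_true: np.ndarray,
    positive_calls: dict[str, int],
) -> tuple[dict, dict]:
    """Shared power/FDR/RMSE arithmetic for one feature level.

    ``positive_calls`` maps the two directional call labels to the sign
    (+1/-1) of the truth direction they claim.
    """
    call = merged["call"].astype(str).to_numpy()
    called = np.isin(call, list(positive_calls))
    claimed_sign = np.zeros(len(merged))
    for label, sign in positive_calls.items():
        claimed_sign[call == label] = sign

    tp = called & changed & (claimed_sign == direction_true)
    fp = called & ~tp
    fn = changed & ~tp

    n_changed = int(changed.sum())
    tested = merged["tested"].astype(bool).to_numpy()
    est = merged["log2fc"].to_numpy(dtype=float)
    true = merged["_true_log2fc"].to_numpy(dtype=float)
    resid = est[tested] - true[tested]
    metrics = {
        "power": float(tp.sum() / n_changed) if n_changed else float("nan"),
        "empirical_fdr": float(fp.sum() / max(1, tp.sum() + fp.sum())),
        "log2fc_rmse": float(np.sqrt(np.mean(resid**2))) if len(resid) else float("nan"),
        "n_true_positive": int(tp.sum()),
        "n_false_positive": int(fp.sum()),
        "n_false_negative": int(fn.sum()),
        "n_truly_changed": n_changed,
        "n_tested": int(tested.sum()),
    }
    confusion = (
        pd.crosstab(merged["call"], pd.Series(changed, index=merged.index, name="truly_changed"))
        .astype(int)
        .to_dict()
    )
    confusion = {str(k): v for k, v in confusion.items()}
    return metrics, confusion


def score_against_truth(
    protein_results: pd.DataFrame,
    site_results: pd.DataFrame,
    truth: SyntheticTruth,
) -> EvalReport:
    """Score called results against the simulator's ground-truth ledger.

    Every feature in the results must join to exactly one truth record;
    unmatched ids raise with the offending list.  A protein true positive is
    an ``up``/``down`` call on a truly changed protein in the true direction;
    a site true positive is a ``less_oxidized``/``more_oxidized`` call on a
    site with truly changed occupancy, again in the true direction (higher
    alkylated intensity = less oxidized).
    """
    prot = protein_results.reset_index(drop=True).merge(
        truth.proteins.rename(columns={"true_log2fc": "_true_log2fc"}),
        on="accession",
        how="left",
        validate="many_to_one",
    )
    missing = prot.loc[prot["_true_log2fc"].isna(), "accession"].tolist()
    if missing:
        raise ValueError(f"protein features without truth records: {missing[:10]}")
    p_metrics, p_conf = _score_level(
        prot,
        changed=(prot["_true_log2fc"] != 0).to_numpy(),
        direction_true=np.sign(prot["_true_log2fc"].to_numpy(dtype=float)),
        positive_calls={"up": 1, "down": -1},
    )

    strue = truth.sites.rename(
        columns={
            "true_site_log2fc": "_true_log2fc",
            "true_log2_attenuation_diff": "_atten_diff",
        }
    )
    site = site_results.reset_index(drop=True).merge(
        strue, on=["accession", "site_key"], how="left", validate="many_to_one"
    )
    missing = site.loc[site["_atten_diff"].isna()]
    if len(missing):
        ids = (missing["accession"] + "|" + missing["site_key"]).tolist()
        raise ValueError(f"site features without truth records: {ids[:10]}")
    s_metrics, s_conf = _score_level(
        site,
        changed=(site["_atten_diff"] != 0).to_numpy(),
        direction_true=np.sign(site["_atten_diff"].to_numpy(dtype=float)),
        positive_calls={"less_oxidized": 1, "more_oxidized": -1},
    )
    return EvalReport(
        abundance=p_metrics,
        redox=s_metrics,
        confusion={"protein": p_conf, "site": s_conf},
    )


# ---------------------------------------------------------------------------
# recount from per-sample intensity tables


def _matrix_from_frame(
    df: pd.DataFrame,
    design: SampleDesign,
    kind: str,
    config: PipelineConfig,
    column_map: dict[str, str] | None,
    table_name: str,
) -> QuantMatrix:
    column_map = column_map or {}

    def col(name: str) -> str:
        return column_map.get(name, name)

    missing_samples = [s for s in design.sample_ids if col(s) not in df.columns]
    if missing_samples:
        raise ValueError(
            f"{table_name}: no per-sample intensity columns for {missing_samples}; "
            "only summary-level reporting is possible for this table"
        )
    id_cols = ["accession"] + (["site_key"] if kind == "site" else [])
    for c in id_cols:
        if col(c) not in df.columns:
            raise ValueError(f"{table_name}: missing required column {col(c)!r}")

    values = df[[col(s) for s in design.sample_ids]].astype(float).copy()
    values.columns = design.sample_ids
    if config.zero_is_missing:
        values = values.mask(values == 0)
    if kind == "site":
        index = df[col("accession")].astype(str) + "|" + df[col("site_key")].astype(str)
        meta = pd.DataFrame(
            {
                "accession": df[col("accession")].astype(str).values,
                "site_key": df[col("site_key")].astype(str).values,
                "n_peptides": np.nan,
            }
        )
    else:
        index = df[col("accession")].astype(str)
        meta = pd.DataFrame(
            {"accession": df[col("accession")].astype(str).values, "n_peptides": np.nan}
        )
    values.index = pd.Index(index.values, name="feature_id")
    meta.index = values.index
    return QuantMatrix(values=values, feature_meta=meta, kind=kind)


def recount_published(
    protein_table_path: str | Path,
    site_table_path: str | Path | None,
    design: SampleDesign,
    config: PipelineConfig | None = None,
    column_map: dict[str, str] | None = None,
    s0_grid: tuple[float, ...] = (0.0,),
) -> dict:
    """Apply the call criteria to externally supplied intensity tables.

    The protein table needs ``accession`` plus one raw-intensity column per
    design sample; the site table additionally needs ``site_key``
    (``C42_C47``-style labels).  Returns the up/down protein counts (per
    ``s0``) and the redox-site count under both decoupling modes.
    """
    config = config or PipelineConfig()
    prot_df = pd.read_csv(protein_table_path, sep="\t")
    prot_matrix = _matrix_from_frame(
        prot_df, design, "protein", config, column_map, str(protein_table_path)
    )
    center = config.normalization == "median_center"
    norm_prot = log2_median_center(prot_matrix, center=center)

    result: dict = {"s0_scan": {}}
    prot_results = None
    for s0 in s0_grid:
        cfg = dataclasses.replace(config, s0=s0)
        res = differential_stats(norm_prot, design, cfg, compute_q=True)
        res["call"] = call_protein_abundance(res, cfg)
        counts = {
            "n_up": int((res["call"] == "up").sum()),
            "n_down": int((res["call"] == "down").sum()),
        }
        result["s0_scan"][s0] = counts
        if s0 == config.s0 or prot_results is None:
            prot_results = res
            result.update(counts)

    result["n_redox_sites"] = {}
    if site_table_path is not None:
        site_df = pd.read_csv(site_table_path, sep="\t")
        site_matrix = _matrix_from_frame(
            site_df, design, "site", config, column_map, str(site_table_path)
        )
        norm_site = log2_median_center(site_matrix, center=center)
        site_stats = differential_stats(norm_site, design, config, compute_q=False)
        for mode in ("fold_change", "log2_fold_change"):
            cfg = dataclasses.replace(config, decoupling_mode=mode)
            called = call_site_redox(site_stats, prot_results, cfg)
            result["n_redox_sites"][mode] = int(
                called["call"].isin(["less_oxidized", "more_oxidized"]).sum()
            )
    return result
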