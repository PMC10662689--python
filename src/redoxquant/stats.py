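"""Normalization, two-sample testing and permutation-based FDR.

The statistical model is the one standard in label-free proteomics: intensities
are log2-transformed and median-centered per sample, features are compared
between the two conditions with a two-sided Student's t-test (pooled variance,
df = n1 + n2 - 2; Welch available behind a flag), and protein-level p-values
are adjusted with a SAM-style permutation FDR:

    E_false(i) = mean over label permutations of #{j : |t_perm_j| >= |t_obs_i|}
    q_raw(i)   = E_false(i) / #{j : |t_obs_j| >= |t_obs_i|}
    q(i)       = min(1, monotone non-increasing-in-|t| envelope of q_raw)

For a 3-vs-3 design the 10 distinct unordered group splits are enumerated
exhaustively (the identity split is excluded from the null set, leaving 9
permutations); larger designs fall back to random splits.  An optional SAM
fudge factor ``s0`` is added to the denominator of the statistic used for the
permutation comparison; the reported t and p always use s0 = 0.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig
from .io import SampleDesign
from .rollup import QuantMatrix

_TINY_P = np.nextafter(0.0, 1.0)

#: random splits used when exhaustive enumeration is not available
DEFAULT_N_PERMUTATIONS = 250


# ---------------------------------------------------------------------------
# normalization


def log2_median_center(matrix: QuantMatrix, center: bool = True) -> QuantMatrix:
    """log2-transform and subtract each sample's median (over present cells).

    Every output column has median exactly 0.  Raises on nonpositive present
    values — those cannot come from a raw intensity rollup.  With
    ``center=False`` only the log2 transform is applied (for inputs already on
    a common loading scale, e.g. simulated data without sample effects;
    median centering shifts every fold change by the between-condition
    difference of column medians, which is nonzero whenever the feature
    population genuinely changes).
    """
    values = matrix.values.to_numpy(dtype=float)
    present = ~np.isnan(values)
    if np.any(values[present] <= 0):
        raise ValueError("log2 transform requires strictly positive intensities")
    logged = np.full_like(values, np.nan)
    logged[present] = np.log2(values[present])
    if center and logged.size:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            medians = np.nanmedian(logged, axis=0)
        medians = np.where(np.isnan(medians), 0.0, medians)
        logged = logged - medians
    centered = pd.DataFrame(
        logged, index=matrix.values.index, columns=matrix.values.columns
    )
    return QuantMatrix(
        values=centered,
        feature_meta=matrix.feature_meta,
        kind=matrix.kind,
        scale="log2",
    )


# ---------------------------------------------------------------------------
# t statistics (vectorised over feature rows)


def _row_t(
    X1: np.ndarray,
    X2: np.ndarray,
    min_valid: int,
    welch: bool = False,
    s0: float = 0.0,
) -> dict[str, np.ndarray]:
    """Row-wise two-sample t over matrices with NaN missing values.

    Returns arrays: t (NaN where untested), p, df, mean1, mean2, n1, n2,
    tested (bool), degenerate (bool: zero variance with unequal means).
    The t sign follows mean2 - mean1.
    """
    n1 = np.sum(~np.isnan(X1), axis=1)
    n2 = np.sum(~np.isnan(X2), axis=1)
    tested = (n1 >= min_valid) & (n2 >= min_valid)

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(X1, axis=1)
        m2 = np.nanmean(X2, axis=1)
        v1 = np.nanvar(X1, axis=1, ddof=1)
        v2 = np.nanvar(X2, axis=1, ddof=1)
        diff = m2 - m1
        if welch:
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = sp2 * (1.0 / n1 + 1.0 / n2)
            df = (n1 + n2 - 2).astype(float)
        se = np.sqrt(se2)
        t = diff / (se + s0)

    with np.errstate(invalid="ignore"):
        zero_se = tested & (se + s0 == 0)
        degenerate = zero_se & (diff != 0)
        t = np.where(zero_se & (diff == 0), 0.0, t)
        t = np.where(degenerate, np.sign(diff) * np.inf, t)

    with np.errstate(all="ignore"):
        p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(degenerate, _TINY_P, p)
    p = np.where(zero_se & (diff == 0), 1.0, p)

    nan = ~tested
    for arr in (t, p, df):
        arr[nan] = np.nan
    return {
        "t": t,
        "p": p,
        "df": df,
        "mean1": np.where(n1 > 0, m1, np.nan),
        "mean2": np.where(n2 > 0, m2, np.nan),
        "n1": n1,
        "n2": n2,
        "tested": tested,
        "degenerate": degenerate,
    }


def student_t_test(
    group1, group2, config: PipelineConfig | None = None
) -> tuple[float, float]:
    """Two-sided Student's t for two small samples (pooled variance).

    Degenerate inputs: zero pooled variance with equal means gives
    ``(0.0, 1.0)``; with unequal means the p-value is the smallest positive
    float and t is signed infinity.
    """
    config = config or PipelineConfig()
    x1 = np.asarray(group1, dtype=float)[None, :]
    x2 = np.asarray(group2, dtype=float)[None, :]
    res = _row_t(x1, x2, min_valid=config.min_valid_per_group, welch=config.welch)
    if not res["tested"][0]:
        raise ValueError(
            f"need >= {config.min_valid_per_group} present values per group"
        )
    return float(res["t"][0]), float(res["p"][0])


def fold_change_signed(log2fc: np.ndarray) -> np.ndarray:
    """Signed ratio convention: 2**log2fc for up, -(2**-log2fc) for down.

    Magnitude is always >= 1; downregulation is reported as a negative fold,
    matching the "fold-change > 1.5 or < -1.5" phrasing of the call criteria.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    with np.errstate(over="ignore"):
        out = np.where(log2fc >= 0, 2.0**log2fc, -(2.0 ** (-log2fc)))
    return np.where(np.isnan(log2fc), np.nan, out)


# ---------------------------------------------------------------------------
# permutation FDR


def _exhaustive_splits(n1: int, n2: int) -> list[tuple[int, ...]]:
    """All distinct unordered splits of n1+n2 columns into sizes (n1, n2).

    Each split is the tuple of column positions assigned to group 1.  When
    n1 == n2 a split and its complement are the same unordered split; keeping
    only those containing column 0 enumerates each pair once.  The identity
    split (the observed labelling) is included; callers drop it from the null.
    """
    cols = range(n1 + n2)
    splits = [tuple(c) for c in combinations(cols, n1)]
    if n1 == n2:
        splits = [s for s in splits if 0 in s]
    return splits


def n_distinct_splits(n1: int, n2: int) -> int:
    from math import comb

    total = comb(n1 + n2, n1)
    return total // 2 if n1 == n2 else total


def permutation_fdr(
    t_obs: np.ndarray,
    X: np.ndarray,
    idx1: np.ndarray,
    idx2: np.ndarray,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """SAM-style permutation q-values for row-wise two-sample t statistics.

    Parameters
    ----------
    t_obs
        Observed statistics (NaN marks untested features; they get q = NaN).
    X
        Feature-by-sample matrix on the normalized log2 scale (NaN missing).
    idx1, idx2
        Column positions of the two condition groups within ``X``.

    Notes
    -----
    With every feature constant the null and observed statistics are all zero
    and every tested feature gets q = 1.
    """
    config = config or PipelineConfig()
    t_obs = np.asarray(t_obs, dtype=float)
    idx1 = np.asarray(idx1)
    idx2 = np.asarray(idx2)
    n1, n2 = len(idx1), len(idx2)
    cols = np.concatenate([idx1, idx2])
    Xc = X[:, cols]  # columns 0..n1-1 are group 1 in the observed labelling

    identity = frozenset(range(n1))
    use_exhaustive = (
        config.n_permutations == "exhaustive" and n_distinct_splits(n1, n2) <= 10
    )
    if use_exhaustive:
        splits = [
            s
            for s in _exhaustive_splits(n1, n2)
            if frozenset(s) not in (identity, frozenset(range(n1, n1 + n2)))
        ]
    else:
        n_perm = (
            int(config.n_permutations)
            if config.n_permutations != "exhaustive"
            else DEFAULT_N_PERMUTATIONS
        )
        rng = np.random.default_rng(config.seed)
        seen: set[frozenset[int]] = set()
        splits = []
        total = n1 + n2
        attempts = 0
        while len(splits) < n_perm and attempts < 50 * n_perm:
            attempts += 1
            s = tuple(sorted(rng.choice(total, size=n1, replace=False)))
            key = frozenset(s)
            comp = frozenset(set(range(total)) - key) if n1 == n2 else None
            if key == identity or (n1 == n2 and key == frozenset(range(n1, total))):
                continue
            if key in seen or (comp is not None and comp in seen):
                continue
            seen.add(key)
            splits.append(s)
    if not splits:
        raise ValueError("no non-identity label permutations exist")

    null_stats: list[np.ndarray] = []
    for s in splits:
        g1 = list(s)
        g2 = [c for c in range(n1 + n2) if c not in s]
        res = _row_t(
            Xc[:, g1],
            Xc[:, g2],
            min_valid=config.min_valid_per_group,
            welch=config.welch,
            s0=config.s0,
        )
        null_stats.append(np.abs(res["t"]))

    tested = ~np.isnan(t_obs)
    abs_obs = np.abs(t_obs[tested])
    pooled = np.concatenate(null_stats)
    pooled = np.sort(pooled[~np.isnan(pooled)])

    # exceedance counts via sorted search; side="left" makes the count >=
    n_ge_null = len(pooled) - np.searchsorted(pooled, abs_obs, side="left")
    e_false = n_ge_null / len(splits)
    sorted_obs = np.sort(abs_obs)
    n_ge_obs = len(sorted_obs) - np.searchsorted(sorted_obs, abs_obs, side="left")
    q_raw = e_false / n_ge_obs

    # monotone envelope: q must be non-increasing in |t| (step-up, as in BH)
    order = np.argsort(-abs_obs, kind="mergesort")
    q_sorted = q_raw[order]
    q_env = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_mono = np.empty_like(q_raw)
    q_mono[order] = np.minimum(q_env, 1.0)

    q = np.full_like(t_obs, np.nan)
    q[tested] = q_mono
    return q


# ---------------------------------------------------------------------------
# full differential table


def differential_stats(
    matrix: QuantMatrix,
    design: SampleDesign,
    config: PipelineConfig | None = None,
    compute_q: bool = False,
) -> pd.DataFrame:
    """Per-feature differential statistics between the two conditions.

    ``matrix`` must be on the normalized log2 scale.  The log2 fold change is
    mean(condition 2) - mean(condition 1); with ``compute_q`` the permutation
    FDR is run (protein-level analysis), otherwise ``q`` is NaN (site-level
    analysis uses raw p).
    """
    config = config or PipelineConfig()
    if matrix.scale != "log2":
        raise ValueError("differential_stats expects a log2-scale matrix")
    cond1, cond2 = design.conditions
    samples = list(matrix.values.columns)
    idx1 = np.array([samples.index(s) for s in design.group_samples(cond1)])
    idx2 = np.array([samples.index(s) for s in design.group_samples(cond2)])

    X = matrix.values.to_numpy(dtype=float)
    res = _row_t(
        X[:, idx1], X[:, idx2], min_valid=config.min_valid_per_group, welch=config.welch
    )
    log2fc = np.where(res["tested"], res["mean2"] - res["mean1"], np.nan)

    if compute_q and len(X):
        q = permutation_fdr(res["t"], X, idx1, idx2, config)
    else:
        q = np.full(len(X), np.nan)

    out = pd.DataFrame(
        {
            "feature_id": matrix.values.index,
            "n_valid_1": res["n1"],
            "n_valid_2": res["n2"],
            "mean_log2_cond1": res["mean1"],
            "mean_log2_cond2": res["mean2"],
            "log2fc": log2fc,
            "fold_change_signed": fold_change_signed(log2fc),
            "t": res["t"],
            "p": res["p"],
            "q": q,
            "tested": res["tested"],
            "degenerate": res["degenerate"],
        }
    ).set_index("feature_id")
    return matrix.feature_meta.join(out)
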