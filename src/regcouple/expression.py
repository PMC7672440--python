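"""Expression normalization, pair correlation, active-TF selection, labeling.

A TF is called *active* when the mean all-against-all Pearson correlation of
its target genes' expression exceeds the 97.5th percentile of the same
statistic computed on size-matched random non-target gene sets pooled over
all TFs.  Pairs of active TFs are then labeled correlated (r > 0.4),
uncorrelated (-0.1 < r < 0.1) or excluded (strict inequalities throughout).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def quantile_normalize(matrix: pd.DataFrame, log_transform: bool = False) -> pd.DataFrame:
    """Quantile-normalize columns (samples) of a genes x samples matrix.

    After normalization every column holds the same multiset of values: the
    column-wise mean of order statistics.  Tied values within a column
    receive the mean of their tied order-statistic means.  ``log_transform``
    applies the natural log first (for raw-scale inputs).
    """
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    values = matrix.to_numpy(dtype=float)
    if log_transform:
        if (values <= 0).any():
            raise ValueError("log transform requires positive values")
        values = np.log(values)
    n, m = values.shape
    order = np.argsort(values, axis=0, kind="mergesort")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        idx = order[:, j]
        assigned = np.empty(n)
        assigned[idx] = reference
        # average reference values over runs of tied input values
        sv = col[idx]
        boundaries = np.flatnonzero(np.diff(sv) != 0) + 1
        groups = np.split(idx, boundaries)
        for grp in groups:
            if len(grp) > 1:
                assigned[grp] = assigned[grp].mean()
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def pair_correlation(expr: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Fill ``pearson_r`` for every pair; drop pairs with unusable genes.

    Pairs whose TF or TG is absent from the matrix, or whose profile has zero
    variance, are dropped (counts logged).
    """
    present = pairs["tf_id"].isin(expr.index) & pairs["tg_id"].isin(expr.index)
    if (~present).any():
        log.info("dropping %d pairs with genes absent from expression", int((~present).sum()))
    kept = pairs.loc[present].copy()
    values = expr.to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(expr.index)}
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    ti = kept["tf_id"].map(idx).to_numpy()
    gi = kept["tg_id"].map(idx).to_numpy()
    denom = norms[ti] * norms[gi]
    ok = denom > 0
    if (~ok).any():
        log.info("dropping %d pairs with zero-variance profiles", int((~ok).sum()))
    kept = kept.loc[ok]
    r = (centered[ti[ok]] * centered[gi[ok]]).sum(axis=1) / denom[ok]
    kept["pearson_r"] = np.clip(r, -1.0, 1.0)
    return kept.reset_index(drop=True)


def _mean_pairwise_r(values: np.ndarray) -> float:
    """Mean off-diagonal Pearson correlation among rows."""
    k = len(values)
    if k < 2:
        return np.nan
    sd = values.std(axis=1)
    keep = sd > 0
    values = values[keep]
    k = len(values)
    if k < 2:
        return np.nan
    c = np.corrcoef(values)
    iu = np.triu_indices(k, 1)
    return float(c[iu].mean())


def select_active_tfs(
    expr: pd.DataFrame,
    pairs: pd.DataFrame,
    percentile: float = 97.5,
    tg_cap: int = 3000,
    n_draws: int = 1,
    seed: int = 0,
    pooled: bool = True,
    threshold_override: float | None = None,
) -> pd.DataFrame:
    """Resampling-null selection of TFs with evidence of activity.

    Per TF the statistic is the mean all-against-all pairwise correlation of
    its target genes (subsampled to ``tg_cap`` when larger).  The null draws
    size-matched sets of non-targets (excluding the TF itself); the activity
    threshold is the ``percentile``-th percentile of the null means pooled
    over all TFs (or per-TF with ``pooled=False``).  TFs with fewer than two
    usable targets are reported inactive by default.  ``threshold_override``
    replaces the recomputed threshold with a fixed, data-set-specific value.
    """
    rng = np.random.default_rng(seed)
    idx = {g: i for i, g in enumerate(expr.index)}
    values = expr.to_numpy(dtype=float)
    all_genes = np.array(expr.index)

    rows = []
    null_means: dict[str, list[float]] = {}
    for tf, grp in pairs.groupby("tf_id", sort=True):
        tgs = [g for g in grp["tg_id"].unique() if g in idx]
        if len(tgs) < 2:
            log.info("TF %s has <2 usable targets; inactive by default", tf)
            rows.append((tf, np.nan, len(tgs), False))
            null_means[tf] = []
            continue
        if len(tgs) > tg_cap:
            tgs = list(rng.choice(tgs, size=tg_cap, replace=False))
        obs = _mean_pairwise_r(values[[idx[g] for g in tgs]])
        non_tg = np.setdiff1d(all_genes, np.append(grp["tg_id"].unique(), tf))
        size = min(len(tgs), len(non_tg))
        if size < len(tgs):
            log.warning("TF %s: only %d non-targets available", tf, size)
        draws = []
        for _ in range(n_draws):
            pick = rng.choice(non_tg, size=size, replace=False)
            draws.append(_mean_pairwise_r(values[[idx[g] for g in pick]]))
        null_means[tf] = draws
        rows.append((tf, obs, len(tgs), True))

    result = pd.DataFrame(
        rows, columns=["tf_id", "mean_tg_pairwise_r", "n_tgs_used", "_eligible"]
    )
    pooled_null = [v for vs in null_means.values() for v in vs if np.isfinite(v)]
    global_thr = float(np.percentile(pooled_null, percentile)) if pooled_null else np.nan
    thresholds = []
    for tf in result["tf_id"]:
        if threshold_override is not None:
            thresholds.append(threshold_override)
        elif pooled:
            thresholds.append(global_thr)
        else:
            vs = [v for v in null_means[tf] if np.isfinite(v)]
            thresholds.append(float(np.percentile(vs, percentile)) if vs else np.nan)
    result["null_percentile_threshold"] = thresholds
    result["is_active"] = (
        result["_eligible"]
        & result["mean_tg_pairwise_r"].gt(result["null_percentile_threshold"])
    )
    return result.drop(columns="_eligible")


def label_pairs(
    pairs: pd.DataFrame,
    active: pd.DataFrame | None = None,
    hi: float = 0.4,
    band: tuple[float, float] = (-0.1, 0.1),
    require_active: bool = True,
) -> pd.DataFrame:
    """Assign correlated / uncorrelated / excluded labels (strict inequalities).

    When an active-TF table is given, only pairs of active TFs are retained.
    """
    out = pairs.copy()
    if require_active and active is not None:
        keep = set(active.loc[active["is_active"], "tf_id"])
        out = out[out["tf_id"].isin(keep)].copy()
    r = out["pearson_r"]
    lo_b, hi_b = band
    out["label"] = np.select(
        [r > hi, (r > lo_b) & (r < hi_b)], ["correlated", "uncorrelated"], default="excluded"
    )
    return out.reset_index(drop=True)


def concordance(r_a: np.ndarray, r_b: np.ndarray) -> float:
    """Correlation of per-pair correlation vectors from two expression sources."""
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    if r_a.shape != r_b.shape:
        raise ValueError(f"length mismatch: {r_a.shape} vs {r_b.shape}")
    if len(r_a) < 3:
        raise ValueError("need at least 3 pairs")
    return float(np.corrcoef(r_a, r_b)[0, 1])
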