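"""Feature clustering, univariate screening and categorical enrichment.

Features are z-scored and merged into clusters wherever pairwise Pearson
correlation exceeds 0.85 (connected components, so merging is transitive and
order-independent); each cluster is represented by the mean of its z-scored
members.  The univariate screen contrasts correlated vs uncorrelated pairs
with a two-sided Wilcoxon-Mann-Whitney test, Benjamini-Hochberg FDR and
Cohen's D.  Enrichment of categorical labels (TF families, GO terms) uses
one-tailed Fisher tests on pair-based 2x2 tables.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def zscore_columns(X: pd.DataFrame) -> pd.DataFrame:
    """Standardize columns to mean 0, SD 1; constant columns become all-zero."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        log.warning("%d zero-variance columns kept as constant 0", int(zero_var.sum()))
    return (X - mean) / sd.where(~zero_var, 1.0)


def cluster_features(
    X: pd.DataFrame, r_threshold: float = 0.85
) -> tuple[list[dict], pd.DataFrame]:
    """Merge correlated features into connected components.

    Returns (clusters, clustered matrix).  Each cluster dict has
    ``cluster_id``, ``members`` and ``name`` (the first member for
    singletons, ``member1+member2+...`` otherwise).  Cluster values are the
    mean of the z-scored member columns.
    """
    Z = zscore_columns(X)
    cols = list(Z.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(Z.to_numpy(dtype=float).T)
    corr = np.nan_to_num(corr, nan=0.0)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(cols)))
    hi = np.argwhere(np.triu(corr > r_threshold, k=1))
    graph.add_edges_from(map(tuple, hi))
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: c[0])
    clusters = []
    data = {}
    for k, comp in enumerate(comps):
        members = [cols[i] for i in comp]
        name = members[0] if len(members) == 1 else "+".join(members)
        clusters.append({"cluster_id": k, "members": members, "name": name})
        data[name] = Z.iloc[:, comp].mean(axis=1)
    return clusters, pd.DataFrame(data, index=X.index)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """(mean(a) - mean(b)) / pooled SD with (n1-1, n2-1) weighting."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    v1 = a.var(ddof=1) if n1 > 1 else 0.0
    v2 = b.var(ddof=1) if n2 > 1 else 0.0
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / max(n1 + n2 - 2, 1)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


def univariate_screen(
    X: pd.DataFrame,
    labels: pd.Series,
    positive: str = "correlated",
    negative: str = "uncorrelated",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Wilcoxon-Mann-Whitney + BH FDR + Cohen's D per feature/cluster.

    D is signed correlated-minus-uncorrelated.  The exact null distribution
    is used for small groups (<= 50 per class, no ties handled by scipy's
    exact path), the continuity-corrected normal approximation otherwise.
    """
    pos = X.loc[labels == positive]
    neg = X.loc[labels == negative]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("both classes need at least 2 observations")
    method = "exact" if max(len(pos), len(neg)) <= 50 else "asymptotic"
    rows = []
    for col in X.columns:
        a, b = pos[col].to_numpy(), neg[col].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            rows.append((col, 1.0, 0.0))
            continue
        use = method
        if method == "exact" and (len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)):
            use = "asymptotic"  # ties: exact null unavailable
        res = sps.mannwhitneyu(a, b, alternative=alternative, method=use)
        rows.append((col, float(res.pvalue), cohens_d(a, b)))
    out = pd.DataFrame(rows, columns=["feature", "wilcoxon_p", "cohens_d"])
    out["p_fdr"] = multipletests(out["wilcoxon_p"], method="fdr_bh")[1]
    return out[["feature", "wilcoxon_p", "p_fdr", "cohens_d"]]


def fisher_enrichment(
    pair_labels: pd.Series,
    pair_categories: pd.DataFrame,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-category one-tailed Fisher test on pair-based 2x2 tables.

    ``pair_categories`` is long-form with columns ``pair_id`` and
    ``category`` (a pair may carry several categories).  For category c:
    n11 = correlated pairs with c, n12 = correlated without, n21 =
    uncorrelated with, n22 = uncorrelated without.  The odds ratio is the
    unconditional sample OR n11*n22 / (n12*n21); ``alternative='less'``
    runs the symmetric depletion test.
    """
    labels = pair_labels[pair_labels.isin(["correlated", "uncorrelated"])]
    n_corr = int((labels == "correlated").sum())
    n_unc = int((labels == "uncorrelated").sum())
    cat = pair_categories[pair_categories["pair_id"].isin(labels.index)]
    rows = []
    for category, grp in cat.groupby("category", sort=True):
        ids = grp["pair_id"].unique()
        lab = labels.reindex(ids)
        n11 = int((lab == "correlated").sum())
        n21 = int((lab == "uncorrelated").sum())
        n12, n22 = n_corr - n11, n_unc - n21
        if n11 + n21 == 0 or min(n12, n22) < 0:
            log.info("category %s skipped (zero margin)", category)
            continue
        _, p = sps.fisher_exact([[n11, n12], [n21, n22]], alternative=alternative)
        odds = (n11 * n22) / (n12 * n21) if n12 * n21 > 0 else (np.inf if n11 * n22 > 0 else 0.0)
        rows.append((category, n11, n12, n21, n22, odds, float(p)))
    out = pd.DataFrame(
        rows, columns=["category", "n11", "n12", "n21", "n22", "odds_ratio", "p_one_tailed"]
    )
    if len(out):
        out["p_fdr"] = multipletests(out["p_one_tailed"], method="fdr_bh")[1]
    else:
        out["p_fdr"] = []
    return out
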