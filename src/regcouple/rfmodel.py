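"""Random-forest classification under component-disjoint cross-validation.

The classifier separates correlated from uncorrelated pairs.  Splits are
*component-disjoint*: TFs and TGs are partitioned 80/20 and every pair whose
members straddle the partition is discarded, so no TF or TG identifier is
shared between training and test.  Training data are balanced by
undersampling the majority class; test sets stay imbalanced.  Importance is
permutation-based mean decrease in accuracy (MDA); feature interactions are
read off the forest as conditional depths: how shallowly a second feature
splits inside the subtree rooted at a conditioning feature's
closest-to-root split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score

log = logging.getLogger(__name__)

POSITIVE = "correlated"
NEGATIVE = "uncorrelated"


def _pair_members(pair_ids) -> tuple[np.ndarray, np.ndarray]:
    tf, tg = zip(*(p.split("|", 1) for p in pair_ids))
    return np.array(tf), np.array(tg)


@dataclass
class SplitSpec:
    train_tf_ids: set
    train_tg_ids: set
    test_tf_ids: set
    test_tg_ids: set
    train_pairs: np.ndarray
    test_pairs: np.ndarray
    dropped_cross_pairs: int

    def check(self) -> None:
        assert not (self.train_tf_ids & self.test_tf_ids)
        assert not (self.train_tg_ids & self.test_tg_ids)


def component_disjoint_split(
    pair_ids: np.ndarray,
    labels: pd.Series,
    train_frac: float = 0.8,
    seed: int = 0,
    max_attempts: int = 50,
) -> SplitSpec:
    """Partition TFs and TGs at ``train_frac`` and drop straddling pairs.

    An identifier appearing both as TF and as TG is assigned once, so the
    partition is disjoint at the entity level.  If either side misses one of
    the classes, the split is redrawn with a derived seed (up to
    ``max_attempts``).
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    pair_ids = np.asarray(pair_ids)
    tf_of, tg_of = _pair_members(pair_ids)
    tfs = np.unique(tf_of)
    tgs = np.unique(tg_of)
    if len(tfs) < 2 or len(tgs) < 2:
        raise ValueError("need at least 2 TFs and 2 TGs")
    lab = labels.reindex(pair_ids).to_numpy()

    for attempt in range(max_attempts):
        rng = np.random.default_rng((seed + 7919 * attempt) % (2**31))
        train_entities = set()
        # TFs first; TGs that are also TFs inherit the TF assignment
        picked = rng.permutation(tfs)[: max(1, int(round(train_frac * len(tfs))))]
        train_entities.update(picked)
        pure_tgs = np.array([g for g in tgs if g not in set(tfs)])
        picked_tg = rng.permutation(pure_tgs)[: max(1, int(round(train_frac * len(pure_tgs))))]
        train_entities.update(picked_tg)

        tf_in_train = np.isin(tf_of, list(train_entities))
        tg_in_train = np.isin(tg_of, list(train_entities))
        train_mask = tf_in_train & tg_in_train
        test_mask = ~tf_in_train & ~tg_in_train
        dropped = int((~train_mask & ~test_mask).sum())
        spec = SplitSpec(
            train_tf_ids=set(tf_of[train_mask]),
            train_tg_ids=set(tg_of[train_mask]),
            test_tf_ids=set(tf_of[test_mask]),
            test_tg_ids=set(tg_of[test_mask]),
            train_pairs=pair_ids[train_mask],
            test_pairs=pair_ids[test_mask],
            dropped_cross_pairs=dropped,
        )
        classes_ok = (
            len(set(lab[train_mask]) & {POSITIVE, NEGATIVE}) == 2
            and len(set(lab[test_mask]) & {POSITIVE, NEGATIVE}) == 2
        )
        if classes_ok:
            spec.check()
            return spec
    raise RuntimeError(f"no valid split in {max_attempts} attempts (degenerate classes)")


def undersample_majority(pair_ids: np.ndarray, labels: pd.Series, seed: int = 0) -> np.ndarray:
    """Balance classes by sampling the majority down to the minority size."""
    pair_ids = np.asarray(pair_ids)
    lab = labels.reindex(pair_ids).to_numpy()
    pos = pair_ids[lab == POSITIVE]
    neg = pair_ids[lab == NEGATIVE]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    if len(pos) > len(neg):
        pos = rng.choice(pos, size=len(neg), replace=False)
    elif len(neg) > len(pos):
        neg = rng.choice(neg, size=len(pos), replace=False)
    out = np.concatenate([pos, neg])
    return out[np.argsort(out)]


def default_vars_per_split(n_features: int) -> int:
    """0.5 * sqrt(number of feature clusters), rounded, at least 1."""
    return max(1, int(round(0.5 * np.sqrt(n_features))))


def train_forest(
    X: pd.DataFrame,
    y: np.ndarray,
    n_trees: int = 3000,
    vars_per_split: int | None = 5,
    min_node: int = 150,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit the forest with the study's hyperparameters.

    ``vars_per_split`` is the number of candidate variables per split (the
    randomForest ``mtry`` convention); ``min_node`` is the minimal terminal
    node size.  ``vars_per_split=None`` applies the 0.5*sqrt(p) default.
    """
    if min_node > len(X):
        raise ValueError(f"min_node ({min_node}) exceeds training size ({len(X)})")
    if 0.632 * len(X) < 2 * min_node:
        # bootstrap leaves ~63% unique rows per tree; below 2*min_node of
        # those no split is admissible and every tree is a constant
        log.warning(
            "training size %d is too small for terminal nodes of %d: "
            "trees will rarely split", len(X), min_node,
        )
    mtry = vars_per_split if vars_per_split is not None else default_vars_per_split(X.shape[1])
    if mtry > X.shape[1]:
        raise ValueError("vars_per_split exceeds feature count")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=min_node,
        random_state=seed % (2**31),
        n_jobs=1,
    )
    forest.fit(X.to_numpy(dtype=float), (np.asarray(y) == POSITIVE).astype(int))
    return forest


def evaluate(forest, X: pd.DataFrame, y: np.ndarray) -> tuple[float, float]:
    """ROC-AUC and PR-AUC (average precision) on a test set."""
    y01 = (np.asarray(y) == POSITIVE).astype(int)
    if len(np.unique(y01)) < 2:
        raise ValueError("test set must contain both classes")
    score = forest.predict_proba(X.to_numpy(dtype=float))[:, 1]
    return float(roc_auc_score(y01, score)), float(average_precision_score(y01, score))


def permutation_importance_mda(
    forest,
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    n_permutations: int = 5,
) -> pd.Series:
    """Mean decrease of accuracy after permuting each test column.

    Accuracy uses the 0.5 probability cutoff; the drop is averaged over
    ``n_permutations`` independent permutations per feature.
    """
    rng = np.random.default_rng(seed)
    y01 = (np.asarray(y) == POSITIVE).astype(int)
    mat = X.to_numpy(dtype=float)
    base = ((forest.predict_proba(mat)[:, 1] >= 0.5).astype(int) == y01).mean()
    mda = {}
    for j, col in enumerate(X.columns):
        accs = []
        for _ in range(n_permutations):
            perm = mat.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            pred = (forest.predict_proba(perm)[:, 1] >= 0.5).astype(int)
            accs.append((pred == y01).mean())
        mda[col] = float(base - np.mean(accs))
    return pd.Series(mda, name="mda")


# ---------------------------------------------------------------- interactions


def _tree_min_depths(tree) -> dict[int, int]:
    """Minimal depth of each splitting feature from the tree root."""
    depths: dict[int, int] = {}
    stack = [(0, 0)]
    while stack:
        node, d = stack.pop()
        f = tree.feature[node]
        if f < 0:
            continue
        if f not in depths or d < depths[f]:
            depths[f] = d
        stack.append((tree.children_left[node], d + 1))
        stack.append((tree.children_right[node], d + 1))
    return depths


def _subtree_min_depths(tree, root: int) -> dict[int, int]:
    depths: dict[int, int] = {}
    stack = [(root, 0)]
    while stack:
        node, d = stack.pop()
        f = tree.feature[node]
        if f < 0:
            continue
        if f not in depths or d < depths[f]:
            depths[f] = d
        stack.append((tree.children_left[node], d + 1))
        stack.append((tree.children_right[node], d + 1))
    return depths


def _highest_split(tree, feature: int) -> int | None:
    best, best_d = None, None
    stack = [(0, 0)]
    while stack:
        node, d = stack.pop()
        f = tree.feature[node]
        if f < 0:
            continue
        if f == feature and (best_d is None or d < best_d):
            best, best_d = node, d
        stack.append((tree.children_left[node], d + 1))
        stack.append((tree.children_right[node], d + 1))
    return best


def interaction_depths(
    forest, feature_names: list[str], top_k: int = 30
) -> pd.DataFrame:
    """Conditional-depth interaction statistics over all trees.

    For an ordered feature pair (v, w): in each tree where v splits, take
    v's closest-to-root split; if w splits within that subtree, record w's
    minimal depth measured from the subtree root.  ``tree_frequency`` counts
    such trees, ``mean_conditional_depth`` averages the recorded depths, and
    ``unconditional_mean_depth`` is w's mean minimal root depth over the
    trees in which w appears at all.
    """
    estimators = getattr(forest, "estimators_", None)
    trees = [e.tree_ for e in estimators] if estimators is not None else [forest.tree_]
    pair_depth_sum: dict[tuple[int, int], float] = {}
    pair_count: dict[tuple[int, int], int] = {}
    w_depth_sum: dict[int, float] = {}
    w_count: dict[int, int] = {}
    for tree in trees:
        root_depths = _tree_min_depths(tree)
        for w, d in root_depths.items():
            w_depth_sum[w] = w_depth_sum.get(w, 0.0) + d
            w_count[w] = w_count.get(w, 0) + 1
        for v in root_depths:
            top = _highest_split(tree, v)
            sub = _subtree_min_depths(tree, top)
            for w, d in sub.items():
                if w == v and d == 0:
                    continue  # the conditioning split itself
                key = (v, w)
                pair_depth_sum[key] = pair_depth_sum.get(key, 0.0) + d
                pair_count[key] = pair_count.get(key, 0) + 1
    rows = []
    for (v, w), cnt in pair_count.items():
        rows.append(
            (
                feature_names[v],
                feature_names[w],
                cnt,
                pair_depth_sum[(v, w)] / cnt,
                w_depth_sum[w] / w_count[w],
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "conditioning_feature",
            "second_feature",
            "tree_frequency",
            "mean_conditional_depth",
            "unconditional_mean_depth",
        ],
    )
    out = out.sort_values(
        ["tree_frequency", "mean_conditional_depth"], ascending=[False, True]
    ).reset_index(drop=True)
    return out.head(top_k) if top_k else out


# ---------------------------------------------------------------- CV driver


@dataclass
class CVResult:
    roc_aucs: list[float] = field(default_factory=list)
    pr_aucs: list[float] = field(default_factory=list)
    mda: pd.DataFrame | None = None  # features x repeats
    interactions: pd.DataFrame | None = None
    dropped_fractions: list[float] = field(default_factory=list)

    def median_roc_auc(self) -> float:
        return float(np.median(self.roc_aucs))

    def median_pr_auc(self) -> float:
        return float(np.median(self.pr_aucs))

    def mean_mda(self) -> pd.Series:
        return self.mda.mean(axis=1).sort_values(ascending=False)

    def summary(self) -> dict:
        return {
            "repeats": len(self.roc_aucs),
            "median_roc_auc": self.median_roc_auc(),
            "sd_roc_auc": float(np.std(self.roc_aucs, ddof=1)) if len(self.roc_aucs) > 1 else 0.0,
            "median_pr_auc": self.median_pr_auc(),
            "sd_pr_auc": float(np.std(self.pr_aucs, ddof=1)) if len(self.pr_aucs) > 1 else 0.0,
        }


def cross_validate(
    X: pd.DataFrame,
    labels: pd.Series,
    repeats: int = 20,
    train_frac: float = 0.8,
    n_trees: int = 3000,
    vars_per_split: int | None = 5,
    min_node: int = 150,
    seed: int = 0,
    permute_labels: bool = False,
    compute_mda: bool = True,
    compute_interactions: bool = False,
    mda_permutations: int = 5,
) -> CVResult:
    """Repeat {split, undersample, train, evaluate, MDA} ``repeats`` times.

    Only labeled (correlated/uncorrelated) pairs enter.  With
    ``permute_labels=True`` the labels are shuffled once per repeat (after
    splitting, within each side) to provide the permuted-label baseline on
    identical splits.
    """
    keep = labels.isin([POSITIVE, NEGATIVE])
    X = X.loc[keep.reindex(X.index, fill_value=False)]
    labels = labels.loc[keep]
    pair_ids = np.asarray(X.index)
    result = CVResult(mda=pd.DataFrame(index=X.columns))
    inter_frames = []
    rng = np.random.default_rng(seed % (2**31))
    for rep in range(repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        split = component_disjoint_split(pair_ids, labels, train_frac, seed=rep_seed)
        split.check()
        result.dropped_fractions.append(split.dropped_cross_pairs / len(pair_ids))
        lab = labels.copy()
        if permute_labels:
            prng = np.random.default_rng(rep_seed + 1)
            for side in (split.train_pairs, split.test_pairs):
                lab.loc[side] = prng.permutation(lab.loc[side].to_numpy())
        train_ids = undersample_majority(split.train_pairs, lab, seed=rep_seed + 2)
        forest = train_forest(
            X.loc[train_ids],
            lab.loc[train_ids].to_numpy(),
            n_trees=n_trees,
            vars_per_split=vars_per_split,
            min_node=min_node,
            seed=rep_seed + 3,
        )
        roc, pr = evaluate(forest, X.loc[split.test_pairs], lab.loc[split.test_pairs].to_numpy())
        result.roc_aucs.append(roc)
        result.pr_aucs.append(pr)
        if compute_mda:
            result.mda[f"rep{rep}"] = permutation_importance_mda(
                forest,
                X.loc[split.test_pairs],
                lab.loc[split.test_pairs].to_numpy(),
                seed=rep_seed + 4,
                n_permutations=mda_permutations,
            )
        if compute_interactions:
            inter_frames.append(interaction_depths(forest, list(X.columns), top_k=0))
    if inter_frames:
        allint = pd.concat(inter_frames)
        grouped = allint.groupby(["conditioning_feature", "second_feature"]).agg(
            tree_frequency=("tree_frequency", "sum"),
            mean_conditional_depth=("mean_conditional_depth", "mean"),
            unconditional_mean_depth=("unconditional_mean_depth", "mean"),
        )
        result.interactions = (
            grouped.sort_values("tree_frequency", ascending=False).reset_index().head(30)
        )
    return result
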