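"""Feature importance and backward elimination.

Two importance views are combined: permutation (accuracy) importance — the
out-of-bag accuracy lost when a feature column is shuffled — and Gini
importance — the total node-size-weighted impurity decrease credited to the
feature across every split of every tree, left unnormalized.  Because the
two live on very different scales, features are ranked by their geometric
mean, the combined score.  Backward elimination then greedily drops the
feature whose removal most improves cross-validated G-mean until no removal
helps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import EnsembleModel, cross_validate, train_dtb, train_rusboost
from .graph_io import GeneSet
from .resampling import LabeledDataset, smote

logger = logging.getLogger("nettop")

__all__ = [
    "ImportanceRecord",
    "gini_importance",
    "accuracy_importance",
    "combined_score",
    "importance_table",
    "backward_elimination",
]


@dataclass(frozen=True)
class ImportanceRecord:
    feature: str
    accuracy_importance: float
    gini_importance: float
    combined_score: float


def _tree_gini_credit(tree, n_features: int) -> np.ndarray:
    """Per-feature sum of node-size-weighted Gini impurity decreases.

    For each internal node: n_node * impurity - n_left * impurity_left -
    n_right * impurity_right, credited to the split feature.  Node sizes are
    the tree's (weighted) training sample counts; nothing is divided out, so
    a single pure root split on 2n rows scores n.
    """
    t = tree.tree_
    credit = np.zeros(n_features)
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        drop = (
            t.weighted_n_node_samples[node] * t.impurity[node]
            - t.weighted_n_node_samples[left] * t.impurity[left]
            - t.weighted_n_node_samples[right] * t.impurity[right]
        )
        credit[t.feature[node]] += drop
    return credit


def gini_importance(model: EnsembleModel) -> dict[str, float]:
    """Total impurity-decrease credit per feature, summed over all trees."""
    trees = model.trees
    if not trees:
        raise ValueError("model has no fitted trees")
    n = len(model.feature_names)
    total = np.zeros(n)
    for tree in trees:
        total += _tree_gini_credit(tree, n)
    return dict(zip(model.feature_names, total.tolist()))


def accuracy_importance(
    model: EnsembleModel,
    data: LabeledDataset,
    seed: int = 0,
    n_repeats: int = 10,
) -> dict[str, float]:
    """Mean decrease in accuracy when a feature's column is permuted.

    For bagged models the decrease is measured per tree on that tree's
    out-of-bag rows and averaged over trees and ``n_repeats`` permutations.
    Models without bootstrap structure (RUSBoost) fall back to permutation
    on the supplied data as a held-out set, with a warning.
    """
    rng = np.random.default_rng(seed)
    x = data.X[model.feature_names].to_numpy(dtype=float)
    y = data.y.to_numpy(dtype=int)
    n_feat = len(model.feature_names)
    drops = np.zeros(n_feat)

    if model.family == "dtb":
        bag = model.estimator
        n_rows = len(y)
        n_used = 0
        for tree, sample_idx in zip(bag.estimators_, bag.estimators_samples_):
            oob = np.setdiff1d(np.arange(n_rows), sample_idx, assume_unique=False)
            if len(oob) == 0:
                continue
            n_used += 1
            x_oob, y_oob = x[oob], y[oob]
            baseline = float(np.mean(tree.predict(x_oob) == y_oob))
            # stack all (feature, repeat) variants into one predict call
            m = len(oob)
            blocks = np.tile(x_oob, (n_feat * n_repeats, 1))
            for f in range(n_feat):
                for r in range(n_repeats):
                    rows = slice((f * n_repeats + r) * m, (f * n_repeats + r + 1) * m)
                    blocks[rows, f] = x_oob[rng.permutation(m), f]
            acc = (tree.predict(blocks) == np.tile(y_oob, n_feat * n_repeats)).reshape(
                n_feat, n_repeats, m
            ).mean(axis=(1, 2))
            drops += baseline - acc
        if n_used == 0:
            raise ValueError("no tree has out-of-bag rows")
        drops /= n_used * n_repeats
    else:
        logger.warning(
            "model family %r has no bootstrap structure; measuring permutation "
            "importance on the supplied data as a held-out set",
            model.family,
        )
        baseline = float(np.mean((model.predict_scores(x) >= 0.5) == (y == 1)))
        for f in range(n_feat):
            for _ in range(n_repeats):
                x_perm = x.copy()
                x_perm[:, f] = x[rng.permutation(len(y)), f]
                acc = float(np.mean((model.predict_scores(x_perm) >= 0.5) == (y == 1)))
                drops[f] += baseline - acc
        drops /= n_repeats
    return dict(zip(model.feature_names, drops.tolist()))


def combined_score(accuracy_importance: float, gini_importance: float) -> float:
    """Geometric mean sqrt(a * g) of the two importance scores."""
    if accuracy_importance < 0 or gini_importance < 0:
        raise ValueError(
            "combined score requires nonnegative inputs, got "
            f"({accuracy_importance}, {gini_importance})"
        )
    return math.sqrt(accuracy_importance * gini_importance)


def importance_table(
    model: EnsembleModel, data: LabeledDataset, seed: int = 0, n_repeats: int = 10
) -> pd.DataFrame:
    """Accuracy, Gini and combined scores per feature, sorted by combined
    score descending.  Negative permutation importances (pure-noise
    features) are floored at 0 before combining."""
    acc = accuracy_importance(model, data, seed=seed, n_repeats=n_repeats)
    gini = gini_importance(model)
    rows = []
    for f in model.feature_names:
        a = max(acc[f], 0.0)
        rows.append(
            {
                "feature": f,
                "accuracy": acc[f],
                "gini": gini[f],
                "combined": combined_score(a, gini[f]),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("combined", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def backward_elimination(
    table: pd.DataFrame,
    signature: GeneSet,
    model_family: str = "dtb",
    k_folds: int = 10,
    seed: int = 0,
    use_smote: bool = True,
    n_trees: int = 100,
    smote_k: int = 5,
) -> tuple[list[str], list[dict]]:
    """Greedy backward elimination maximizing mean cross-validated G-mean.

    Starting from all features, repeatedly drop the feature whose removal
    gives the largest mean G-mean over ``k_folds`` stratified folds
    (fold-honest SMOTE inside); stop once the best possible removal would
    strictly reduce the score.  A removal that ties the current score still
    proceeds — the feature demonstrably carried no information (e.g. a
    zero-variance column can never change a split).  Ties between candidate
    removals are broken by the lower combined importance score.  Returns the
    surviving features (in the table's column order) and a per-step trace.
    """
    features = list(table.columns)
    if len(features) < 2:
        raise ValueError("backward elimination needs at least 2 features")

    def cv_gmean(feats: list[str]) -> float:
        res = cross_validate(
            table[feats],
            signature,
            model_family=model_family,
            k_folds=k_folds,
            use_smote=use_smote,
            seed=seed,
            n_trees=n_trees,
            smote_k=smote_k,
        )
        return res.mean("Gm")

    # combined scores once, on the full feature set, for tie-breaking
    from .resampling import label_dataset  # local: keep module import graph flat

    full = label_dataset(table, signature)
    if use_smote and model_family != "rusboost":
        full_train = smote(full, k_neighbors=smote_k, seed=seed)
    else:
        full_train = full
    trainer = train_dtb if model_family == "dtb" else train_rusboost
    model = trainer(full_train, n_trees, seed)
    ranking = importance_table(model, full_train, seed=seed)
    tie_rank = dict(zip(ranking["feature"], ranking["combined"]))

    current = list(features)
    score = cv_gmean(current)
    trace: list[dict] = [{"removed": None, "score": score, "remaining": list(current)}]
    while len(current) > 1:
        best_feat, best_score = None, -np.inf
        for f in current:
            trial = [g for g in current if g != f]
            s = cv_gmean(trial)
            if s > best_score or (
                s == best_score and tie_rank.get(f, 0) < tie_rank.get(best_feat, 0)
            ):
                best_feat, best_score = f, s
        if best_score < score:
            break
        current = [g for g in current if g != best_feat]
        score = best_score
        trace.append({"removed": best_feat, "score": score, "remaining": list(current)})
        logger.info(
            "eliminated %s (G-mean %.4f, %d features left)",
            best_feat, score, len(current),
        )
    return current, trace
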