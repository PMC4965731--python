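"""Ensemble classifiers, confusion-based metrics, ROC/AUC, cross-validation.

Two tree ensembles are supported: a bagged Gini decision-tree classifier
(DTB) whose score is the fraction of per-tree positive votes, and RUSBoost,
a boosting loop in which each round's training set keeps every minority row
and draws an equally sized majority sample without replacement according to
the current boosting weights.  Evaluation follows the confusion-matrix
metrics ACC, PPV, SN, SP, F, Gm plus ROC/AUC, and k-fold cross-validation
reports each metric as mean +/- 1.96 * standard error (a 95 % normal CI).
SMOTE, when requested, is applied inside each training fold only, so no
synthetic row can reach a test fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .graph_io import GeneSet
from .resampling import LabeledDataset, label_dataset, smote

logger = logging.getLogger("nettop")

Z95 = 1.96  # normal quantile for the 95 % confidence interval

METRIC_NAMES = ("ACC", "PPV", "SN", "SP", "F", "Gm", "AUC")

__all__ = [
    "Z95",
    "METRIC_NAMES",
    "ConfusionCounts",
    "MetricReport",
    "RocCurve",
    "CvResult",
    "EnsembleModel",
    "train_dtb",
    "train_rusboost",
    "evaluate",
    "metrics",
    "roc_auc",
    "rank_auc",
    "cross_validate",
]


# ---------------------------------------------------------------------------
# metric containers


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricReport:
    """ACC, PPV, SN, SP, F, Gm and (when scores are supplied) AUC.

    ``degenerate`` lists metrics whose defining ratio was 0/0 and was
    reported as 0.
    """

    ACC: float
    PPV: float
    SN: float
    SP: float
    F: float
    Gm: float
    AUC: float = float("nan")
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class RocCurve:
    """Threshold sweep of (1 - SP, SN) points, from (0, 0) to (1, 1)."""

    points: np.ndarray  # shape (m, 2): columns FPR, TPR

    def auc(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return float(np.trapezoid(y, x))


# ---------------------------------------------------------------------------
# models


class _RusBoost:
    """SAMME-style two-class boosting with per-round random undersampling.

    Each round trains an unpruned Gini tree on all minority rows plus an
    equal number of majority rows sampled without replacement with
    probability proportional to the current boosting weights; rounds are
    combined by weighted vote.  Boosting stops early if a round's weighted
    training error reaches 0.5.
    """

    def __init__(self, n_rounds: int, seed: int) -> None:
        self.n_rounds = n_rounds
        self.seed = seed
        self.trees: list[DecisionTreeClassifier] = []
        self.alphas: list[float] = []

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_RusBoost":
        rng = np.random.default_rng(self.seed)
        n = len(y)
        counts = np.bincount(y, minlength=2)
        minority = int(np.argmin(counts))
        idx_min = np.flatnonzero(y == minority)
        idx_maj = np.flatnonzero(y != minority)
        w = np.full(n, 1.0 / n)
        for t in range(self.n_rounds):
            if len(idx_maj) > len(idx_min):
                p = w[idx_maj] / w[idx_maj].sum()
                take = rng.choice(idx_maj, size=len(idx_min), replace=False, p=p)
                sel = np.concatenate([idx_min, take])
            else:
                sel = np.arange(n)  # balanced input: plain boosting
            tree = DecisionTreeClassifier(
                criterion="gini", random_state=int(rng.integers(2**31))
            )
            sw = w[sel] / w[sel].sum()
            tree.fit(x[sel], y[sel], sample_weight=sw)
            pred = tree.predict(x)
            miss = pred != y
            err = float(w[miss].sum())
            if err >= 0.5:
                if not self.trees:
                    raise RuntimeError("first boosting round no better than chance")
                logger.info("boosting stopped early at round %d (err=%.3f)", t, err)
                break
            err = max(err, 1e-10)
            alpha = 0.5 * math.log((1.0 - err) / err)
            self.trees.append(tree)
            self.alphas.append(alpha)
            w = w * np.exp(alpha * np.where(miss, 1.0, -1.0))
            w /= w.sum()
        return self

    def score_samples(self, x: np.ndarray) -> np.ndarray:
        votes = np.zeros(len(x))
        total = sum(self.alphas)
        for tree, alpha in zip(self.trees, self.alphas):
            votes += alpha * (tree.predict(x) == 1)
        return votes / total


@dataclass
class EnsembleModel:
    """A fitted tree ensemble ("dtb" or "rusboost") scoring in [0, 1]."""

    family: str
    estimator: object
    feature_names: list[str]
    n_trees: int
    seed: int
    training_frame: pd.DataFrame = field(repr=False, default=None)

    def predict_scores(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            x = x[self.feature_names].to_numpy(dtype=float)
        else:
            x = np.asarray(x, dtype=float)
        if x.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {x.shape[1]}"
            )
        if self.family == "dtb":
            votes = np.zeros(len(x))
            for tree in self.estimator.estimators_:
                votes += tree.predict(x) == 1
            return votes / len(self.estimator.estimators_)
        return self.estimator.score_samples(x)

    @property
    def trees(self) -> list[DecisionTreeClassifier]:
        if self.family == "dtb":
            return list(self.estimator.estimators_)
        return list(self.estimator.trees)


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")


def train_dtb(data: LabeledDataset, n_trees: int = 100, seed: int = 0) -> EnsembleModel:
    """Bagged Gini decision trees: each tree fits an independent bootstrap
    replica of size N; the model score is the mean per-tree positive vote."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    x = data.X.to_numpy(dtype=float)
    y = data.y.to_numpy(dtype=int)
    _check_two_classes(y)
    bag = BaggingClassifier(
        estimator=DecisionTreeClassifier(criterion="gini"),
        n_estimators=n_trees,
        bootstrap=True,
        max_samples=1.0,
        random_state=seed % 2**31,
    ).fit(x, y)
    return EnsembleModel("dtb", bag, data.feature_names, n_trees, seed, data.frame)


def train_rusboost(
    data: LabeledDataset, n_rounds: int = 100, seed: int = 0
) -> EnsembleModel:
    """RUSBoost: boosting with per-round majority undersampling."""
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    x = data.X.to_numpy(dtype=float)
    y = data.y.to_numpy(dtype=int)
    _check_two_classes(y)
    booster = _RusBoost(n_rounds, seed % 2**31).fit(x, y)
    return EnsembleModel("rusboost", booster, data.feature_names, n_rounds, seed, data.frame)


# ---------------------------------------------------------------------------
# metrics


def evaluate(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts with score >= threshold predicting the positive class."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts, scores=None, labels=None) -> MetricReport:
    """ACC, PPV, SN, SP, F, Gm from the confusion counts; AUC from scores.

    Any 0/0 ratio is reported as 0 and flagged in ``degenerate``.
    """
    if c.N == 0:
        raise ValueError("empty confusion table")
    deg: list[str] = []
    acc = (c.TP + c.TN) / c.N
    ppv = _ratio(c.TP, c.TP + c.FP, "PPV", deg)
    sn = _ratio(c.TP, c.TP + c.FN, "SN", deg)
    sp = _ratio(c.TN, c.TN + c.FP, "SP", deg)
    f = _ratio(2.0 * sn * ppv, sn + ppv, "F", deg)
    gm = math.sqrt(sn * sp)
    auc = float("nan")
    if scores is not None and labels is not None:
        _, auc = roc_auc(scores, labels)
    return MetricReport(acc, ppv, sn, sp, f, gm, auc, tuple(deg))


def roc_auc(scores, labels) -> tuple[RocCurve, float]:
    """ROC curve by threshold sweep over the unique scores, and its
    trapezoid area (equal to the Mann-Whitney statistic of the scores)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    pts = [(0.0, 0.0)]
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        pts.append((fp / n_neg, tp / n_pos))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    curve = RocCurve(np.array(pts))
    return curve, curve.auc()


def rank_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney U statistic (average ranks for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CvResult:
    """Per-fold metric reports plus mean +/- Z95 * SEM summaries."""

    folds: list[MetricReport]
    fold_test_ids: list[list[str]]
    fold_train_synthetic_ids: list[list[str]]
    selected_features: list[list[str]]

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(m, metric) for m in self.folds]))

    def sem(self, metric: str) -> float:
        vals = [getattr(m, metric) for m in self.folds]
        return float(np.std(vals, ddof=1) / math.sqrt(len(vals)))

    def interval(self, metric: str) -> tuple[float, float]:
        """(mean, half-width) of the 95 % CI: M +/- Z95 * sigma_M."""
        return self.mean(metric), Z95 * self.sem(metric)

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name in METRIC_NAMES:
            m, half = self.interval(name)
            rows[name] = {"mean": m, "sem": self.sem(name), "ci95_half_width": half}
        return pd.DataFrame(rows).T


def _fit_family(family: str, data: LabeledDataset, n_trees: int, seed: int) -> EnsembleModel:
    if family == "dtb":
        return train_dtb(data, n_trees=n_trees, seed=seed)
    if family == "rusboost":
        return train_rusboost(data, n_rounds=n_trees, seed=seed)
    raise ValueError(f"unknown model family {family!r}")


def cross_validate(
    table: pd.DataFrame,
    signature: GeneSet,
    model_family: str = "dtb",
    k_folds: int = 10,
    use_smote: bool = True,
    select_features: bool = False,
    seed: int = 0,
    n_trees: int = 100,
    smote_k: int = 5,
    threshold: float = 0.5,
    select_inner_folds: int = 3,
) -> CvResult:
    """Stratified k-fold cross-validation with fold-honest preprocessing.

    Feature selection (backward elimination) and SMOTE both see the
    training partition only; the held-out fold is evaluated untouched.
    RUSBoost performs its own undersampling and is refused in combination
    with SMOTE.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if model_family == "rusboost" and use_smote:
        raise ValueError(
            "RUSBoost undersamples internally; combining it with SMOTE would "
            "make the two sampling schemes fight — disable one of them"
        )
    data = label_dataset(table, signature)
    y = data.y.to_numpy(dtype=int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed % 2**31)
    folds: list[MetricReport] = []
    test_ids: list[list[str]] = []
    synth_ids: list[list[str]] = []
    selected: list[list[str]] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_vertices = list(table.index[train_idx])
        test_vertices = list(table.index[test_idx])
        feats = list(table.columns)
        if select_features:
            from .importance import backward_elimination  # deferred: cyclic module pair

            feats, _ = backward_elimination(
                table.loc[train_vertices],
                signature,
                model_family=model_family,
                k_folds=select_inner_folds,
                seed=seed + 1000 + fold,
                use_smote=use_smote,
                n_trees=n_trees,
            )
        fold_train = LabeledDataset(data.frame.loc[train_vertices, feats + ["label", "provenance"]])
        if use_smote:
            fold_train = smote(fold_train, k_neighbors=smote_k, seed=seed + fold)
        model = _fit_family(model_family, fold_train, n_trees, seed + fold)
        test_frame = data.frame.loc[test_vertices]
        scores = model.predict_scores(test_frame[feats])
        y_test = test_frame["label"].to_numpy(dtype=int)
        report = metrics(evaluate(scores, y_test, threshold), scores, y_test)
        logger.info(
            "fold %d/%d: ACC=%.3f SN=%.3f SP=%.3f Gm=%.3f",
            fold + 1, k_folds, report.ACC, report.SN, report.SP, report.Gm,
        )
        folds.append(report)
        test_ids.append(test_vertices)
        synth_ids.append(
            list(fold_train.frame.index[fold_train.provenance == "synthetic"])
        )
        selected.append(feats)
    return CvResult(folds, test_ids, synth_ids, selected)
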