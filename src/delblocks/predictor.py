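"""Binder prediction from per-position building-block productivity.

Two evaluation protocols mirror two practical questions.  A random compound
split (90/10, with test building blocks constrained to appear in training)
asks whether P(bind) alone predicts binding for *new combinations of tested
building blocks*.  A building-block holdout (remove 5% of building blocks
per position and every trisynthon containing them) asks the harder design
question: can binding be predicted for *untested building blocks*, whose
P(bind) must first be imputed from their similarity cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .chemspace import ChemSpace
from .distances import DistanceMatrix
from .productivity import compute_pbind

__all__ = [
    "IMPUTATION_STRATEGIES",
    "split_random",
    "split_bb_holdout",
    "impute_pbind",
    "imputation_mae_study",
    "BinderClassifier",
    "EvalReport",
    "evaluate",
    "run_holdout_workflow",
]

POSITIONS = (1, 2, 3)

#: Ways to estimate P(bind) of an untested building block from its cluster.
IMPUTATION_STRATEGIES = ("cluster_median", "cluster_mean", "cluster_random", "cluster_nearest")


# -- data splits -----------------------------------------------------------


@dataclass
class RandomSplit:
    train: pd.DataFrame
    test: pd.DataFrame
    n_moved: int  # test rows moved to train to close building-block leakage


def split_random(records: pd.DataFrame, test_fraction: float = 0.10, seed: int = 0) -> RandomSplit:
    """Random compound split with the constraint that every building block
    in the test set also occurs in the training set.

    Test rows violating the constraint (e.g. containing a building block
    that occurs only once) are moved into training and counted in
    ``n_moved``, so test trisynthons are strictly new combinations of
    already-tested building blocks.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    n = len(records)
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    test_pos = set(perm[:n_test].tolist())

    cols = [records[f"bb{p}"].to_numpy() for p in POSITIONS]
    train_counts: list[dict] = [{}, {}, {}]
    for i in range(n):
        if i not in test_pos:
            for p in range(3):
                bb = cols[p][i]
                train_counts[p][bb] = train_counts[p].get(bb, 0) + 1

    moved = 0
    # Moving rows to train only adds coverage, so one ordered pass suffices.
    for i in sorted(test_pos):
        if any(cols[p][i] not in train_counts[p] for p in range(3)):
            test_pos.discard(i)
            moved += 1
            for p in range(3):
                bb = cols[p][i]
                train_counts[p][bb] = train_counts[p].get(bb, 0) + 1

    test_mask = np.zeros(n, dtype=bool)
    test_mask[list(test_pos)] = True
    achieved = test_mask.mean()
    if abs(achieved - test_fraction) > 0.01:
        warnings.warn(
            f"test fraction {achieved:.3f} deviates from target {test_fraction} "
            f"after moving {moved} leaking rows into training",
            stacklevel=2,
        )
    return RandomSplit(
        records.loc[~test_mask].reset_index(drop=True),
        records.loc[test_mask].reset_index(drop=True),
        moved,
    )


@dataclass
class HoldoutSplit:
    train: pd.DataFrame
    holdout: pd.DataFrame
    held_out: dict[int, list]  # position -> held-out building-block IDs


def split_bb_holdout(records: pd.DataFrame, bb_fraction: float = 0.05, seed: int = 0) -> HoldoutSplit:
    """Hold out a fraction of building blocks at each position together with
    every trisynthon containing any of them.

    The training set then mimics an initial screen over a limited
    building-block set; the holdout set mimics proposed follow-up compounds
    that each contain at least one untested building block.
    """
    if not 0 <= bb_fraction < 1:
        raise ValueError(f"bb_fraction must be in [0, 1), got {bb_fraction}")
    rng = np.random.default_rng(seed)

    def _pick():
        held: dict[int, list] = {}
        for p in POSITIONS:
            bbs = np.sort(records[f"bb{p}"].unique())
            k = int(round(len(bbs) * bb_fraction))
            held[p] = sorted(rng.choice(bbs, size=k, replace=False).tolist()) if k else []
        return held

    held = _pick()
    mask = np.zeros(len(records), dtype=bool)
    for p in POSITIONS:
        mask |= records[f"bb{p}"].isin(held[p]).to_numpy()
    if bb_fraction > 0 and not mask.any():
        warnings.warn("holdout selection hit no compounds; resampling once", stacklevel=2)
        held = _pick()
        mask = np.zeros(len(records), dtype=bool)
        for p in POSITIONS:
            mask |= records[f"bb{p}"].isin(held[p]).to_numpy()
    return HoldoutSplit(
        records.loc[~mask].reset_index(drop=True),
        records.loc[mask].reset_index(drop=True),
        held,
    )


# -- imputation ------------------------------------------------------------


def impute_pbind(
    coords: np.ndarray,
    labels: np.ndarray,
    model: ChemSpace,
    pbind: pd.Series,
    strategy: str,
    seed: int = 0,
    input_distances: np.ndarray | None = None,
    nearest_metric: str = "embedding",
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate P(bind) for projected building blocks from their clusters.

    Strategies: ``cluster_median`` / ``cluster_mean`` summarize the member
    P(bind) values; ``cluster_random`` copies one uniformly drawn member
    (seeded); ``cluster_nearest`` copies the closest member — by embedding
    Euclidean distance (default), or by the raw similarity-derived distance
    when ``nearest_metric="input"`` and ``input_distances`` (rows aligned
    with ``coords``, columns with the model's training order) is given.
    Noise-assigned points fall back to the global training median and are
    flagged.

    Returns ``(estimates, noise_flags)`` aligned with ``coords`` rows.
    """
    if strategy not in IMPUTATION_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {IMPUTATION_STRATEGIES}")
    if nearest_metric not in ("embedding", "input"):
        raise ValueError(f"nearest_metric must be 'embedding' or 'input', got {nearest_metric!r}")
    if nearest_metric == "input" and input_distances is None:
        raise ValueError("nearest_metric='input' requires input_distances")
    coords = np.atleast_2d(coords)
    labels = np.asarray(labels)
    values = pbind.reindex(model.ids_).to_numpy(dtype=float)
    if np.isnan(values).any():
        raise KeyError("every training building block needs a computed P(bind)")
    global_median = float(np.median(values))
    rng = np.random.default_rng(seed)
    est = np.empty(len(coords))
    noise = labels < 0
    for i in range(len(coords)):
        if noise[i]:
            est[i] = global_median
            continue
        member_idx = np.flatnonzero(model.labels_ == labels[i])
        member_vals = values[member_idx]
        if strategy == "cluster_median":
            est[i] = float(np.median(member_vals))
        elif strategy == "cluster_mean":
            est[i] = float(np.mean(member_vals))
        elif strategy == "cluster_random":
            est[i] = float(member_vals[rng.integers(len(member_vals))])
        elif nearest_metric == "input":
            d = np.atleast_2d(input_distances)[i, member_idx]
            est[i] = float(member_vals[int(np.argmin(d))])
        else:
            d = np.linalg.norm(model.embedding_[member_idx] - coords[i], axis=1)
            est[i] = float(member_vals[int(np.argmin(d))])
    return est, noise


def imputation_mae_study(
    records: pd.DataFrame,
    distance_matrices: dict[int, DistanceMatrix],
    strategies=IMPUTATION_STRATEGIES,
    n_trials: int = 20,
    bb_fraction: float = 0.05,
    seed: int = 0,
    chemspace_params: dict | None = None,
    nearest_metric: str = "input",
) -> dict[str, float]:
    """Mean absolute error of each imputation strategy on held-out building
    blocks, pooled over positions and resampled holdouts.

    Per trial: hold out building blocks, fit a chemical space per position on
    the training ones, project the held-out ones, impute their P(bind) with
    each strategy, and compare against the P(bind) computed from the full
    record set (the value the holdout would reveal).
    """
    from .chemspace import ChemSpace as _ChemSpace  # local alias for clarity
    from .productivity import compute_pbind as _compute_pbind

    rng = np.random.default_rng(seed)
    trial_seeds = rng.integers(0, 2**31 - 1, size=n_trials)
    full_pbind = {p: _compute_pbind(records, p)["pbind"] for p in POSITIONS}
    errors: dict[str, list[float]] = {s: [] for s in strategies}
    for tseed in trial_seeds:
        split = split_bb_holdout(records, bb_fraction=bb_fraction, seed=int(tseed))
        for p in POSITIONS:
            train_bbs = sorted(split.train[f"bb{p}"].unique())
            train_pbind = _compute_pbind(split.train, p)["pbind"]
            model = _ChemSpace(**(chemspace_params or {}))
            model.fit(distance_matrices[p].subset(train_bbs))
            new_bbs = sorted(set(split.holdout[f"bb{p}"].unique()) - set(train_bbs))
            if not new_bbs:
                continue
            rect = distance_matrices[p].rectangular(new_bbs, train_bbs)
            coords = model.transform(rect)
            labels = model.predict(rect)
            truth = full_pbind[p].reindex(new_bbs).to_numpy()
            for s in strategies:
                est, _ = impute_pbind(
                    coords, labels, model, train_pbind, s, seed=int(tseed),
                    input_distances=rect, nearest_metric=nearest_metric,
                )
                errors[s].extend(np.abs(est - truth).tolist())
    return {s: float(np.mean(errs)) for s, errs in errors.items()}


# -- classifier ------------------------------------------------------------


class BinderClassifier(BaseEstimator, ClassifierMixin):
    """Decision tree over per-position P(bind) (and optional cluster) features.

    The maximum depth is selected by stratified K-fold cross-validation
    maximizing mean precision-recall AUC (ties resolved toward the shallower
    tree), then the tree is refit on the full training set.  Balanced class
    weights are the default because binders are typically a percent-level
    minority.

    Attributes (after ``fit``): ``tree_`` (the fitted sklearn tree),
    ``max_depth_`` (selected depth), ``cv_scores_`` (depth -> mean CV PR-AUC).
    """

    def __init__(
        self,
        max_depth_grid: tuple = tuple(range(1, 11)),
        cv: int = 5,
        class_weight: str | None = "balanced",
        random_state: int = 0,
    ):
        self.max_depth_grid = max_depth_grid
        self.cv = cv
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y) -> "BinderClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class; cannot fit")
        self.classes_ = classes
        splitter = StratifiedKFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        folds = list(splitter.split(X, y))
        self.cv_scores_ = {}
        for depth in self.max_depth_grid:
            scores = []
            for tr, va in folds:
                tree = DecisionTreeClassifier(
                    max_depth=depth,
                    class_weight=self.class_weight,
                    random_state=self.random_state,
                )
                tree.fit(X[tr], y[tr])
                scores.append(average_precision_score(y[va], tree.predict_proba(X[va])[:, 1]))
            self.cv_scores_[depth] = float(np.mean(scores))
        # argmax over the grid; ties go to the shallower tree (grid order).
        self.max_depth_ = max(self.max_depth_grid, key=lambda d: (self.cv_scores_[d], -d))
        self.tree_ = DecisionTreeClassifier(
            max_depth=self.max_depth_,
            class_weight=self.class_weight,
            random_state=self.random_state,
        )
        self.tree_.fit(X, y)
        return self

    def predict(self, X):
        return self.tree_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return self.tree_.predict_proba(np.asarray(X, dtype=float))

    def to_dict(self) -> dict:
        """JSON-ready tree structure: feature, threshold, children, leaf counts."""
        t = self.tree_.tree_
        def node(i):
            if t.children_left[i] == -1:
                return {"leaf": True, "value": t.value[i][0].tolist(), "n": int(t.n_node_samples[i])}
            return {
                "leaf": False,
                "feature": int(t.feature[i]),
                "threshold": float(t.threshold[i]),
                "n": int(t.n_node_samples[i]),
                "left": node(t.children_left[i]),
                "right": node(t.children_right[i]),
            }
        return {"max_depth": int(self.max_depth_), "root": node(0)}


def build_features(
    records: pd.DataFrame,
    pbind_maps: dict[int, pd.Series],
    cluster_maps: dict[int, pd.Series] | None = None,
) -> np.ndarray:
    """Feature matrix: P(bind) at p1..p3 (and, optionally, cluster IDs)."""
    cols = []
    for p in POSITIONS:
        mapped = records[f"bb{p}"].map(pbind_maps[p])
        if mapped.isna().any():
            missing = records.loc[mapped.isna(), f"bb{p}"].unique()
            raise KeyError(f"no P(bind) for building blocks at p{p}: {missing[:5]}")
        cols.append(mapped.to_numpy(dtype=float))
    if cluster_maps is not None:
        for p in POSITIONS:
            cols.append(records[f"bb{p}"].map(cluster_maps[p]).to_numpy(dtype=float))
    return np.column_stack(cols)


# -- evaluation ------------------------------------------------------------


@dataclass
class EvalReport:
    """Confusion counts and derived metrics for one evaluation.

    precision = TP/(TP+FP); recall = TP/(TP+FN); baseline is the test-set
    hit rate, which is also the PR-AUC of a random-guessing classifier.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    pr_auc: float = float("nan")

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def baseline(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.fn) / total if total else float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "pr_auc": self.pr_auc,
            "baseline": self.baseline,
        }


def evaluate(y_true, y_pred, y_score=None) -> EvalReport:
    """Confusion counts, precision, recall, baseline hit rate and PR-AUC.

    PR-AUC uses the step-wise precision-recall summation over unique score
    thresholds (average precision); it requires ``y_score``.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if len(y_true) == 0:
        raise ValueError("cannot evaluate on an empty test set")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    auc = float("nan")
    if y_score is not None and y_true.min() != y_true.max():
        auc = float(average_precision_score(y_true, np.asarray(y_score, dtype=float)))
    return EvalReport(tp, fp, fn, tn, auc)


# -- end-to-end holdout workflow ------------------------------------------


@dataclass
class WorkflowResult:
    """Per-strategy evaluation of the building-block holdout workflow."""

    reports: dict[str, list[EvalReport]]
    mean_pr_auc: dict[str, float]
    baseline: float  # mean holdout hit rate over trials
    n_trials: int
    trial_seeds: list[int] = field(default_factory=list)


def run_holdout_workflow(
    records: pd.DataFrame,
    distance_matrices: dict[int, DistanceMatrix],
    strategies=IMPUTATION_STRATEGIES,
    n_trials: int = 1,
    bb_fraction: float = 0.05,
    seed: int = 0,
    chemspace_params: dict | None = None,
    classifier_params: dict | None = None,
    nearest_metric: str = "input",
) -> WorkflowResult:
    """Full out-of-sample protocol, repeated over resampled holdouts.

    Per trial: hold out building blocks; compute training P(bind) per
    position; fit a ChemSpace per position on the training building blocks;
    project the held-out ones and assign clusters; train the decision tree
    on training-set P(bind) features; then, for each imputation strategy,
    evaluate on the holdout trisynthons with held-out building blocks'
    P(bind) replaced by the strategy's estimate.
    """
    if "binder" not in records.columns:
        raise ValueError("records must be labeled before running the workflow")
    rng = np.random.default_rng(seed)
    trial_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_trials)]
    reports: dict[str, list[EvalReport]] = {s: [] for s in strategies}
    baselines: list[float] = []

    for trial, tseed in enumerate(trial_seeds):
        try:
            split = split_bb_holdout(records, bb_fraction=bb_fraction, seed=tseed)
            pbind_maps = {p: compute_pbind(split.train, p)["pbind"] for p in POSITIONS}

            imputed: dict[str, dict[int, pd.Series]] = {s: {} for s in strategies}
            for p in POSITIONS:
                train_bbs = sorted(split.train[f"bb{p}"].unique())
                model = ChemSpace(**(chemspace_params or {}))
                model.fit(distance_matrices[p].subset(train_bbs))
                new_bbs = sorted(
                    set(split.holdout[f"bb{p}"].unique()) - set(train_bbs)
                )
                if new_bbs:
                    rect = distance_matrices[p].rectangular(new_bbs, train_bbs)
                    coords = model.transform(rect)
                    labels = model.predict(rect)
                else:
                    rect = np.empty((0, len(train_bbs)))
                    coords = np.empty((0, 2))
                    labels = np.empty(0, dtype=int)
                for s in strategies:
                    est, _ = impute_pbind(
                        coords, labels, model, pbind_maps[p], s, seed=tseed,
                        input_distances=rect, nearest_metric=nearest_metric,
                    )
                    combined = pd.concat(
                        [pbind_maps[p], pd.Series(est, index=new_bbs, dtype=float)]
                    )
                    imputed[s][p] = combined

            X_train = build_features(split.train, pbind_maps)
            clf = BinderClassifier(**(classifier_params or {}))
            clf.fit(X_train, split.train["binder"].to_numpy())

            y_true = split.holdout["binder"].to_numpy()
            baselines.append(float(y_true.mean()))
            for s in strategies:
                X_hold = build_features(split.holdout, imputed[s])
                report = evaluate(
                    y_true, clf.predict(X_hold), clf.predict_proba(X_hold)[:, 1]
                )
                reports[s].append(report)
        except Exception as exc:
            raise RuntimeError(f"holdout workflow failed at trial {trial}") from exc

    mean_auc = {s: float(np.mean([r.pr_auc for r in reports[s]])) for s in strategies}
    return WorkflowResult(reports, mean_auc, float(np.mean(baselines)), n_trials, trial_seeds)
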