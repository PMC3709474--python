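"""Leave-one-run-out cross-validated pattern classification.

Binary decoding uses a linear soft-margin support vector machine (libsvm
via scikit-learn); multiclass decoding combines the six pairwise binary
classifiers by majority voting over their predictions for each test trial.
Accuracy is the fraction of correct guesses on held-out runs, averaged
with equal weight over the cross-validation folds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .preprocess import TrialPatternSet
from .simulate import FunctionalDataset

TieBreak = str  # "random" | "lowest-index"


@dataclass
class WeightVector:
    """Per-voxel weights and bias of one binary linear decision rule.

    The rule predicts ``classes[1]`` when ``weights @ x + bias > 0`` and
    ``classes[0]`` otherwise (classes in sorted label order, following the
    fitted estimator).
    """

    weights: np.ndarray
    bias: float
    classes: tuple[str, str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.bias):
            raise ValueError("weights must be finite")

    def predict(self, X: np.ndarray) -> np.ndarray:
        score = np.asarray(X) @ self.weights + self.bias
        return np.where(score > 0, self.classes[1], self.classes[0])


@dataclass
class DecodingResult:
    """Cross-validated accuracies and confusion counts for one task."""

    task: str
    fold_accuracies: np.ndarray
    confusion: pd.DataFrame  # rows: guesses, columns: targets
    weights: list[WeightVector] | None = None
    per_subject: pd.DataFrame | None = None

    mean_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=float)
        if np.any((self.fold_accuracies < 0) | (self.fold_accuracies > 1)):
            raise ValueError("fold accuracies must lie in [0, 1]")
        self.mean_accuracy = float(self.fold_accuracies.mean())

    @property
    def pooled_accuracy(self) -> float:
        """Trace over total of the confusion matrix (trial-weighted)."""
        m = self.confusion.to_numpy()
        return float(np.trace(m) / m.sum())


def make_fold_plan(runs: np.ndarray) -> list[tuple[tuple[int, ...], int]]:
    """Leave-one-run-out split plan: each run is the test set exactly once."""
    uniq = sorted(int(r) for r in np.unique(runs))
    if len(uniq) < 2:
        raise ValueError("cross-validation needs at least 2 runs")
    return [(tuple(r for r in uniq if r != test), test) for test in uniq]


def fit_linear_classifier(X: np.ndarray, y: np.ndarray,
                          C: float = 1.0) -> tuple[WeightVector, SVC]:
    """Fit a linear soft-margin SVM on a two-class training set."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(
            f"binary classifier needs exactly 2 classes, got {list(classes)}"
        )
    clf = SVC(kernel="linear", C=C)
    clf.fit(np.asarray(X, dtype=float), y)
    wv = WeightVector(weights=clf.coef_[0], bias=float(clf.intercept_[0]),
                      classes=(str(clf.classes_[0]), str(clf.classes_[1])))
    return wv, clf


def _check_conditions_per_run(labels, runs, conditions) -> None:
    for run in np.unique(runs):
        present = set(labels[runs == run])
        missing = [c for c in conditions if c not in present]
        if missing:
            raise ValueError(
                f"run {int(run)} lacks conditions {missing}; every run must "
                "contain every decoded condition"
            )


def crossvalidate_two_way(patterns: TrialPatternSet,
                          pair: tuple[str, str],
                          C: float = 1.0,
                          train_labels: np.ndarray | None = None,
                          keep_weights: bool = False) -> DecodingResult:
    """Two-way leave-one-run-out decoding of one condition pair.

    ``train_labels``, when given, replaces the true labels for classifier
    training only; held-out trials are always scored against the true
    labels (used by the train-only permutation mode).
    """
    a, b = pair
    if a == b:
        raise ValueError("pair must contain two distinct conditions")
    sel = np.isin(patterns.labels, list(pair))
    X, y, runs = patterns.X[sel], patterns.labels[sel], patterns.runs[sel]
    ty = np.asarray(train_labels)[sel] if train_labels is not None else y
    _check_conditions_per_run(y, runs, pair)

    order = [a, b]
    counts = np.zeros((2, 2), dtype=int)
    accs, weights = [], []
    for train_runs, test_run in make_fold_plan(runs):
        tr = np.isin(runs, train_runs)
        te = runs == test_run
        wv, clf = fit_linear_classifier(X[tr], ty[tr], C=C)
        pred = clf.predict(X[te])
        accs.append(float(np.mean(pred == y[te])))
        for g, t in zip(pred, y[te]):
            counts[order.index(g), order.index(t)] += 1
        if keep_weights:
            weights.append(wv)
    confusion = pd.DataFrame(counts, index=order, columns=order)
    return DecodingResult(task=f"{a} vs {b}", fold_accuracies=np.array(accs),
                          confusion=confusion,
                          weights=weights if keep_weights else None)


def tally_votes(votes, conditions, tie_break: TieBreak = "random",
                rng: np.random.Generator | None = None) -> str:
    """Resolve pairwise-vote lists into one predicted label.

    The label predicted most often across the pairwise contests wins; ties
    are broken uniformly at random (seeded ``rng`` required) or, in
    ``lowest-index`` mode, by position in ``conditions``.
    """
    counts = {c: 0 for c in conditions}
    for v in votes:
        counts[v] += 1
    top = max(counts.values())
    winners = [c for c in conditions if counts[c] == top]
    if len(winners) == 1:
        return winners[0]
    if tie_break == "lowest-index":
        return winners[0]
    if tie_break == "random":
        if rng is None:
            raise ValueError("random tie-breaking requires a seeded rng")
        return winners[int(rng.integers(len(winners)))]
    raise ValueError(f"unknown tie_break {tie_break!r}")


def crossvalidate_four_way(patterns: TrialPatternSet,
                           C: float = 1.0,
                           tie_break: TieBreak = "random",
                           seed: int | None = 0,
                           train_labels: np.ndarray | None = None,
                           conditions: tuple[str, ...] | None = None
                           ) -> DecodingResult:
    """Multiclass decoding by pairwise voting under leave-one-run-out CV.

    For each fold, one binary classifier is trained per condition pair; a
    test trial's predicted label is the one endorsed by most of the
    pairwise classifiers.  Works for any number >= 2 of conditions (named
    for the four-condition design it serves).
    """
    conds = tuple(conditions) if conditions else patterns.conditions
    if len(conds) < 2:
        raise ValueError("need at least two conditions")
    X, y, runs = patterns.X, patterns.labels, patterns.runs
    ty = np.asarray(train_labels) if train_labels is not None else y
    _check_conditions_per_run(y, runs, conds)
    rng = np.random.default_rng(seed) if tie_break == "random" else None

    pairs = list(itertools.combinations(conds, 2))
    counts = np.zeros((len(conds), len(conds)), dtype=int)
    accs = []
    for train_runs, test_run in make_fold_plan(runs):
        tr = np.isin(runs, train_runs)
        te = runs == test_run
        clfs = {}
        for pair in pairs:
            sub = tr & np.isin(ty, list(pair))
            _, clfs[pair] = fit_linear_classifier(X[sub], ty[sub], C=C)
        preds = []
        pair_votes = {pair: clfs[pair].predict(X[te]) for pair in pairs}
        for i in range(int(te.sum())):
            votes = [str(pair_votes[pair][i]) for pair in pairs]
            preds.append(tally_votes(votes, conds, tie_break, rng))
        true = y[te]
        accs.append(float(np.mean(np.asarray(preds) == true)))
        for g, t in zip(preds, true):
            counts[conds.index(g), conds.index(t)] += 1
    confusion = pd.DataFrame(counts, index=list(conds), columns=list(conds))
    return DecodingResult(task="four-way" if len(conds) == 4 else
                          f"{len(conds)}-way",
                          fold_accuracies=np.array(accs), confusion=confusion)


def timecourse_decoding(data: FunctionalDataset,
                        events: pd.DataFrame,
                        roi: np.ndarray,
                        pair: tuple[str, str],
                        k_range=range(0, 7),
                        normalization: str = "both",
                        C: float = 1.0,
                        roi_name: str = "roi") -> dict[int, DecodingResult]:
    """Repeat the two-way decoding at each post-stimulus volume offset.

    Returns one result per ``k``; k=0 is the pre/at-onset volume, and the
    profile across k traces how decodable information follows the
    hemodynamic response.
    """
    from .preprocess import extract_patterns

    out: dict[int, DecodingResult] = {}
    for k in k_range:
        pset = extract_patterns(data, events, roi, k=k,
                                normalization=normalization,
                                roi_name=roi_name)
        out[k] = crossvalidate_two_way(pset, pair, C=C)
    return out
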