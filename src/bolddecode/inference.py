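"""Group-level statistics for decoding accuracies.

The central tool is a permutation test of the group-average cross-validated
accuracy: condition labels are shuffled within each subject and each run
(preserving run-level exchangeability under leave-one-run-out), the entire
decoding is recomputed, and the observed accuracy is compared against the
null sample.  Paired comparisons between tasks use the Wilcoxon
signed-rank test; the saliency control uses Spearman rank correlation with
a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .decode import crossvalidate_four_way, crossvalidate_two_way
from .preprocess import TrialPatternSet

PERMUTATION_MODES = ("both", "train-only")
P_CONVENTIONS = ("count", "add-one")


@dataclass
class PermutationResult:
    """Observed group accuracy, its permutation null and p-value.

    With the default counting convention ``p = #(null >= observed) / n``;
    when no permutation reaches the observed value the p-value is reported
    as the upper bound ``< 1/n`` (``p_value`` is then set to ``1/n`` and
    ``is_upper_bound`` flags it).
    """

    observed: float
    null: np.ndarray
    n_permutations: int
    p_value: float
    p_report: str
    seed: int
    is_upper_bound: bool = False

    def __post_init__(self) -> None:
        self.null = np.asarray(self.null, dtype=float)
        if len(self.null) != self.n_permutations:
            raise ValueError("null sample length must equal n_permutations")
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must lie in (0, 1]")


@dataclass
class SubjectDecoding:
    """One subject's re-runnable decoding problem.

    ``task`` is either a condition pair (two-way) or the string
    ``"four-way"``.  For a pair task the pattern set is restricted to the
    pair's trials at construction; label permutations then shuffle exactly
    those trials' labels within run.
    """

    patterns: TrialPatternSet
    task: tuple[str, str] | str
    C: float = 1.0

    def __post_init__(self) -> None:
        if not isinstance(self.task, str):
            self.task = tuple(self.task)
            sel = np.isin(self.patterns.labels, list(self.task))
            self.patterns = self.patterns.subset(sel)
        from .decode import make_fold_plan

        runs = self.patterns.runs
        self._folds = [(np.isin(runs, tr), runs == te)
                       for tr, te in make_fold_plan(runs)]
        self._X = np.ascontiguousarray(self.patterns.X, dtype=float)
        self._run_idx = [np.flatnonzero(runs == r) for r in np.unique(runs)]
        if not isinstance(self.task, str):
            self._y01 = self.patterns.labels == sorted(self.task)[1]

    def _cv01(self, train_y: np.ndarray, test_y: np.ndarray) -> float:
        """Fold-mean accuracy with boolean labels (pair tasks only)."""
        from sklearn.svm import SVC

        acc = 0.0
        for tr, te in self._folds:
            clf = SVC(kernel="linear", C=self.C).fit(
                self._X[tr], train_y[tr].astype(np.uint8))
            pred = (self._X[te] @ clf.coef_[0] + clf.intercept_[0]) > 0
            acc += float(np.mean(pred == test_y[te]))
        return acc / len(self._folds)

    def _shuffle01(self, rng: np.random.Generator) -> np.ndarray:
        y = self._y01.copy()
        for idx in self._run_idx:
            y[idx] = y[idx[rng.permutation(len(idx))]]
        return y

    def accuracy(self, train_labels: np.ndarray | None = None,
                 labels: np.ndarray | None = None,
                 seed: int | None = 0) -> float:
        pset = (self.patterns.with_labels(labels)
                if labels is not None else self.patterns)
        if isinstance(self.task, str):
            res = crossvalidate_four_way(pset, C=self.C, seed=seed,
                                         train_labels=train_labels)
        else:
            res = crossvalidate_two_way(pset, self.task, C=self.C,
                                        train_labels=train_labels)
        return res.mean_accuracy

    def _fast_accuracy(self, labels: np.ndarray,
                       train_labels: np.ndarray | None = None,
                       seed: int | None = 0) -> float:
        """Same computation as :meth:`accuracy` for pair tasks, without
        result-object construction (used inside permutation loops)."""
        if isinstance(self.task, str):
            return self.accuracy(train_labels=train_labels, labels=labels,
                                 seed=seed)
        from sklearn.svm import SVC

        pos = sorted(self.task)[1]
        y = labels == pos
        ty = (np.asarray(train_labels) == pos) if train_labels is not None else y
        accs = []
        for tr, te in self._folds:
            clf = SVC(kernel="linear", C=self.C).fit(self._X[tr],
                                                     ty[tr].astype(np.uint8))
            pred = (self._X[te] @ clf.coef_[0] + clf.intercept_[0]) > 0
            accs.append(float(np.mean(pred == y[te])))
        return float(np.mean(accs))

    def shuffled_labels(self, rng: np.random.Generator) -> np.ndarray:
        """Labels permuted within each run (never across runs/subjects)."""
        labels = self.patterns.labels.copy()
        runs = self.patterns.runs
        for run in np.unique(runs):
            idx = np.flatnonzero(runs == run)
            labels[idx] = labels[idx[rng.permutation(len(idx))]]
        return labels


def permutation_test(subjects: list[SubjectDecoding],
                     n_permutations: int = 10000,
                     seed: int = 0,
                     mode: str = "both",
                     convention: str = "count") -> PermutationResult:
    """Permutation null for the group-average decoding accuracy.

    For every permutation, each subject's condition labels are shuffled
    within run and the full cross-validated decoding is recomputed; the
    group average of the permuted accuracies forms one null draw.  Mode
    ``both`` relabels training and test trials alike; ``train-only``
    shuffles the labels the classifiers are trained on while held-out
    trials keep their true labels for scoring.
    """
    if not subjects:
        raise ValueError("at least one subject required")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if mode not in PERMUTATION_MODES:
        raise ValueError(f"unknown permutation mode {mode!r}")
    if convention not in P_CONVENTIONS:
        raise ValueError(f"unknown p-value convention {convention!r}")

    rng = np.random.default_rng(seed)
    tie_seed = int(rng.integers(2 ** 31))
    import sklearn

    pair_only = all(not isinstance(s.task, str) for s in subjects)
    with sklearn.config_context(assume_finite=True,
                                skip_parameter_validation=True):
        if pair_only:
            observed = float(np.mean([s._cv01(s._y01, s._y01)
                                      for s in subjects]))
        else:
            observed = float(np.mean([
                s._fast_accuracy(s.patterns.labels, seed=tie_seed)
                for s in subjects]))
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            acc = 0.0
            for s in subjects:
                if pair_only:
                    perm01 = s._shuffle01(rng)
                    if mode == "both":
                        acc += s._cv01(perm01, perm01)
                    else:
                        acc += s._cv01(perm01, s._y01)
                else:
                    perm = s.shuffled_labels(rng)
                    if mode == "both":
                        acc += s._fast_accuracy(perm, seed=tie_seed)
                    else:
                        acc += s._fast_accuracy(s.patterns.labels,
                                                train_labels=perm,
                                                seed=tie_seed)
            null[i] = acc / len(subjects)

    count = int(np.sum(null >= observed))
    if convention == "add-one":
        p = (count + 1) / (n_permutations + 1)
        return PermutationResult(observed=observed, null=null,
                                 n_permutations=n_permutations, p_value=p,
                                 p_report=f"{p:.4g}", seed=seed)
    if count == 0:
        bound = 1.0 / n_permutations
        return PermutationResult(observed=observed, null=null,
                                 n_permutations=n_permutations,
                                 p_value=bound, p_report=f"<{bound:.4g}",
                                 seed=seed, is_upper_bound=True)
    p = count / n_permutations
    return PermutationResult(observed=observed, null=null,
                             n_permutations=n_permutations, p_value=p,
                             p_report=f"{p:.4g}", seed=seed)


@dataclass
class GroupComparison:
    """Paired signed-rank comparison of two per-subject value lists."""

    a: np.ndarray
    b: np.ndarray
    statistic: float
    p_value: float
    n_used: int
    alternative: str


def wilcoxon_paired(a, b, alternative: str = "greater") -> GroupComparison:
    """Paired Wilcoxon signed-rank test of per-subject accuracies.

    Zero differences are discarded (Wilcoxon's rule); the exact
    distribution is enumerated for up to 25 informative pairs, the normal
    approximation is used beyond.  All-zero differences carry no
    information and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D arrays")
    if len(a) < 5:
        raise ValueError("at least 5 pairs required")
    diffs = a - b
    nonzero = diffs != 0
    if not nonzero.any():
        raise ValueError("all paired differences are zero; no information")
    n_used = int(nonzero.sum())
    method = "exact" if n_used <= 25 else "approx"
    res = stats.wilcoxon(a[nonzero], b[nonzero], zero_method="wilcox",
                         alternative=alternative, method=method)
    return GroupComparison(a=a, b=b, statistic=float(res.statistic),
                           p_value=float(res.pvalue), n_used=n_used,
                           alternative=alternative)


def saliency_accuracy_correlation(saliency_diffs, accuracies,
                                  n_permutations: int = 10000,
                                  seed: int = 0):
    """Spearman correlation with a permutation p-value (two-sided).

    Tests whether per-task differences in stimulus saliency ratings
    predict the corresponding classification accuracies; ranks use
    midranks for ties.  Returns ``(rho, p_value, p_report)``.
    """
    x = np.asarray(saliency_diffs, dtype=float)
    y = np.asarray(accuracies, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if len(x) < 4:
        raise ValueError("at least 4 observations required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector; correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        r = stats.spearmanr(x, rng.permutation(y)).statistic
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    if count == 0:
        bound = 1.0 / n_permutations
        return rho, bound, f"<{bound:.4g}"
    p = count / n_permutations
    return rho, p, f"{p:.4g}"
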