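"""Linear SVM decoding, fold plans, pairwise voting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

import bolddecode as bd
from conftest import make_noise_patterns


def svm_qp_oracle(X, y, C=1.0):
    """Reference soft-margin linear SVM via the dual quadratic program."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    Q = (y[:, None] * y[None, :]) * (X @ X.T)

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    cons = {"type": "eq", "fun": lambda a: a @ y}
    res = minimize(neg_dual, np.full(n, C / 2), bounds=[(0, C)] * n,
                   constraints=cons, method="SLSQP",
                   options={"ftol": 1e-12, "maxiter": 500})
    a = res.x
    w = (a * y) @ X
    free = (a > 1e-6) & (a < C - 1e-6)
    e = y - X @ w
    if free.any():
        b = float(np.mean(e[free]))
    else:
        # bias interval from the KKT conditions; libsvm takes the midpoint
        at_c = a >= C - 1e-6
        at_0 = a <= 1e-6
        lo = np.max(e[(at_0 & (y > 0)) | (at_c & (y < 0))])
        hi = np.min(e[(at_0 & (y < 0)) | (at_c & (y > 0))])
        b = float((lo + hi) / 2)
    return w, b


class TestFitLinearClassifier:
    def test_separable_pair_boundary_at_zero(self):
        X = np.array([[-1.0], [1.0]])
        wv, clf = bd.fit_linear_classifier(X, np.array(["A", "B"]))
        # boundary where w*x + b = 0
        assert -wv.bias / wv.weights[0] == pytest.approx(0.0, abs=1e-9)
        assert list(clf.predict(X)) == ["A", "B"]

    def test_matches_qp_oracle_on_nonseparable_data(self):
        # perturbed XOR layout: linearly non-separable, non-degenerate
        X = np.array([[0.0, 0.0], [1.0, 1.2], [0.0, 1.0], [1.0, 0.1]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        w_o, b_o = svm_qp_oracle(X, y, C=1.0)
        labels = np.where(y > 0, "pos", "neg")
        wv, clf = bd.fit_linear_classifier(X, labels, C=1.0)
        # sklearn orients the rule by sorted class order: neg < pos, so the
        # positive decision side corresponds to "pos" = y +1
        oracle_acc = np.mean(np.sign(X @ w_o + b_o) == y)
        ours_acc = np.mean(clf.predict(X) == labels)
        assert ours_acc == pytest.approx(oracle_acc)
        np.testing.assert_allclose(wv.weights, w_o, atol=1e-4)
        np.testing.assert_allclose(wv.bias, b_o, atol=1e-4)

    def test_duplicating_training_trials_keeps_rule(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(-3, 0.3, (6, 3)),
                       rng.normal(3, 0.3, (6, 3))])
        y = np.repeat(["a", "b"], 6)
        wv1, _ = bd.fit_linear_classifier(X, y)
        wv2, _ = bd.fit_linear_classifier(np.vstack([X, X]),
                                          np.concatenate([y, y]))
        np.testing.assert_allclose(wv1.weights, wv2.weights, atol=1e-8)
        assert wv1.bias == pytest.approx(wv2.bias, abs=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            bd.fit_linear_classifier(np.zeros((3, 2)), np.array(["a"] * 3))


class TestFoldPlan:
    def test_each_run_tested_exactly_once(self):
        runs = np.repeat([0, 1, 2, 3], 4)
        plan = bd.make_fold_plan(runs)
        assert len(plan) == 4
        tested = [test for _, test in plan]
        assert sorted(tested) == [0, 1, 2, 3]
        for train, test in plan:
            assert test not in train
            assert set(train) | {test} == {0, 1, 2, 3}

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match="2 runs"):
            bd.make_fold_plan(np.zeros(8))


@pytest.fixture(scope="module")
def separable_patterns(small_geometry):
    """Noiseless simulation with little response overlap: condition
    patterns are exactly recoverable."""
    _, rois = small_geometry
    design = bd.DesignSpec(n_per_condition_per_run=2, isi_min=10.0,
                           isi_max=12.0, max_consecutive_same=2)
    acq = bd.AcquisitionParams(tr=3.0, n_volumes_per_run=36, n_runs=4)
    events = bd.generate_design(design, acq, seed=21)
    patterns = bd.random_patterns(rois, design.conditions,
                                  effect_size=1.0, seed=22)
    noise = bd.NoiseModel(white_sd=0.0, drift_slope_sd=0.0, seed=23)
    ds = bd.simulate_dataset(events, patterns, noise, acq, rois)
    return bd.extract_patterns(ds, events, rois["roi"], k=2)


class TestCrossvalidation:
    def test_four_folds_every_trial_tested_once(self, separable_patterns):
        res = bd.crossvalidate_two_way(separable_patterns, ("touch", "pain"))
        assert len(res.fold_accuracies) == 4
        n_pair_trials = int(np.isin(separable_patterns.labels,
                                    ["touch", "pain"]).sum())
        assert res.confusion.to_numpy().sum() == n_pair_trials

    def test_separable_limit_reaches_perfect_accuracy(self,
                                                      separable_patterns):
        res = bd.crossvalidate_two_way(separable_patterns, ("touch", "pain"))
        assert res.mean_accuracy == 1.0
        res4 = bd.crossvalidate_four_way(separable_patterns, seed=0)
        assert res4.mean_accuracy == 1.0
        off_diag = res4.confusion.to_numpy().copy()
        np.fill_diagonal(off_diag, 0)
        assert off_diag.sum() == 0

    def test_confusion_columns_sum_to_target_counts(self, separable_patterns):
        res4 = bd.crossvalidate_four_way(separable_patterns, seed=0)
        col_sums = res4.confusion.sum(axis=0)
        for cond in separable_patterns.conditions:
            assert col_sums[cond] == int(
                (separable_patterns.labels == cond).sum())

    def test_trial_order_invariance(self, separable_patterns):
        rng = np.random.default_rng(0)
        perm = rng.permutation(separable_patterns.n_trials)
        shuffled = separable_patterns.subset(perm)
        a = bd.crossvalidate_two_way(separable_patterns, ("touch", "vision"))
        b = bd.crossvalidate_two_way(shuffled, ("touch", "vision"))
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)

    def test_missing_condition_in_run_reported(self):
        rng = np.random.default_rng(5)
        pset = make_noise_patterns(rng)
        keep = ~((pset.runs == 2) & (pset.labels == "b"))
        with pytest.raises(ValueError, match="run 2"):
            bd.crossvalidate_two_way(pset.subset(keep), ("a", "b"))

    def test_two_way_agrees_with_pairwise_vote_on_two_conditions(self):
        rng = np.random.default_rng(6)
        pset = make_noise_patterns(rng, conditions=("a", "b"))
        res2 = bd.crossvalidate_two_way(pset, ("a", "b"))
        res_multi = bd.crossvalidate_four_way(pset, conditions=("a", "b"),
                                              seed=0)
        np.testing.assert_array_equal(res2.fold_accuracies,
                                      res_multi.fold_accuracies)

    def test_regularization_sweep_keeps_separable_accuracy(
            self, separable_patterns):
        for C in (0.1, 1.0, 10.0):
            res = bd.crossvalidate_two_way(separable_patterns,
                                           ("pain", "audition"), C=C)
            assert res.mean_accuracy == 1.0


class TestVoting:
    CONDS = ("w", "x", "y", "z")
    PAIRS = list(itertools.combinations(CONDS, 2))

    def vote_oracle(self, votes):
        """Brute-force tally; returns the set of modal labels."""
        tally = {c: votes.count(c) for c in self.CONDS}
        top = max(tally.values())
        return [c for c in self.CONDS if tally[c] == top]

    def test_all_64_vote_patterns_match_tally_oracle(self):
        rng = np.random.default_rng(9)
        for choice in itertools.product([0, 1], repeat=6):
            votes = [pair[c] for pair, c in zip(self.PAIRS, choice)]
            modal = self.vote_oracle(votes)
            assert bd.tally_votes(votes, self.CONDS,
                                  tie_break="lowest-index") == modal[0]
            assert bd.tally_votes(votes, self.CONDS, tie_break="random",
                                  rng=rng) in modal

    def test_winner_of_all_own_contests_always_wins(self):
        # 'x' wins its three contests; remaining three split arbitrarily
        votes = ["x", "x", "x", "y", "z", "w"]
        assert bd.tally_votes(votes, self.CONDS,
                              tie_break="lowest-index") == "x"

    def test_random_tie_break_needs_rng(self):
        with pytest.raises(ValueError, match="rng"):
            bd.tally_votes(["w", "x", "w", "x", "y", "z"][:6], self.CONDS)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(("w", "x", "y", "z")), min_size=1,
                    max_size=9))
    def test_winner_always_has_maximal_vote_count(self, votes):
        winner = bd.tally_votes(votes, self.CONDS, tie_break="lowest-index")
        counts = {c: votes.count(c) for c in self.CONDS}
        assert counts[winner] == max(counts.values())


class TestTimecourse:
    def test_profile_peaks_at_hrf_peak_volume(self, fast_design,
                                              small_geometry):
        acq = bd.AcquisitionParams(tr=3.0, n_volumes_per_run=30, n_runs=4)
        design = bd.DesignSpec(n_per_condition_per_run=2, isi_min=8.0,
                               isi_max=10.0, max_consecutive_same=2)
        _, rois = small_geometry
        events = bd.generate_design(design, acq, seed=31)
        patterns = bd.random_patterns(rois, design.conditions,
                                      effect_size=3.0, seed=32)
        noise = bd.NoiseModel(white_sd=1.0, drift_slope_sd=0.01, seed=33)
        ds = bd.simulate_dataset(events, patterns, noise, acq, rois)
        prof = bd.timecourse_decoding(ds, events, rois["roi"],
                                      ("touch", "pain"), k_range=range(3))
        accs = {k: r.mean_accuracy for k, r in prof.items()}
        assert accs[2] == max(accs.values())
        assert accs[2] > 0.8
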