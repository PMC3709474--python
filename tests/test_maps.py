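"""Group F-maps, map dissimilarity and univariate GLM characterization."""

import numpy as np
import pandas as pd
import pytest

import bolddecode as bd
from bolddecode.maps import SensitivityMap


def smap(values, task="t", level="subject"):
    return SensitivityMap(values=np.asarray(values, float), task=task,
                          level=level)


class TestGroupFMap:
    def test_f_equals_squared_t_oracle(self):
        rng = np.random.default_rng(0)
        W = rng.normal(0.3, 1.0, size=(14, 50))
        gmap = bd.group_f_map([smap(w) for w in W])
        t = W.mean(axis=0) / (W.std(axis=0, ddof=1) / np.sqrt(14))
        np.testing.assert_allclose(gmap.values, t ** 2, atol=1e-10)
        assert gmap.df == (1, 13)

    def test_critical_value_for_14_subjects(self):
        assert round(bd.f_critical(14), 2) == 4.67

    def test_degenerate_voxels_flagged(self):
        W = np.ones((4, 3))
        W[:, 0] = 0.0            # zero in every subject -> undefined
        W[:, 2] = [1, 2, 3, 4]   # ordinary voxel
        with pytest.warns(UserWarning):
            gmap = bd.group_f_map([smap(w) for w in W])
        assert np.isnan(gmap.values[0])
        assert np.isinf(gmap.values[1])  # nonzero mean, zero variance
        assert np.isfinite(gmap.values[2])
        assert not gmap.significant[0]

    def test_invariant_under_global_rescaling_only(self):
        rng = np.random.default_rng(1)
        W = rng.standard_normal((8, 30)) + 0.2
        base = bd.group_f_map([smap(w) for w in W]).values
        scaled = bd.group_f_map([smap(3.5 * w) for w in W]).values
        np.testing.assert_allclose(scaled, base, rtol=1e-10)
        # per-subject rescaling changes the statistic
        factors = rng.uniform(0.5, 2.0, size=8)
        per_subj = bd.group_f_map(
            [smap(f * w) for f, w in zip(factors, W)]).values
        assert not np.allclose(per_subj, base)


class TestDistanceMatrix:
    def test_self_negation_orthogonal(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(40)
        u = rng.standard_normal(40)
        u -= (u - u.mean()) @ (v - v.mean()) / ((v - v.mean()) @
                                                (v - v.mean())) * (v - v.mean())
        maps = {"a": smap(v, level="group"), "b": smap(-v, level="group"),
                "c": smap(u, level="group")}
        D = bd.distance_matrix(maps)
        assert D.loc["a", "a"] == 0.0
        assert D.loc["a", "b"] == pytest.approx(2.0)
        assert D.loc["a", "c"] == pytest.approx(1.0, abs=1e-10)

    def test_valid_dissimilarity_on_random_maps(self):
        rng = np.random.default_rng(3)
        maps = {f"t{i}": smap(rng.standard_normal(25), level="group")
                for i in range(4)}
        D = bd.distance_matrix(maps)
        np.testing.assert_allclose(D.to_numpy(), D.to_numpy().T)
        assert np.all(np.diag(D.to_numpy()) == 0)
        assert D.to_numpy().min() >= 0 and D.to_numpy().max() <= 2

    def test_nan_voxels_excluded_pairwise(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        w = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        D = bd.distance_matrix({"a": smap(v), "b": smap(w)})
        assert D.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bd.distance_matrix({"a": smap(np.ones(10)),
                                "b": smap(np.arange(10.0))})

    def test_disjoint_patterns_are_most_dissimilar(self, fast_acq,
                                                   small_geometry):
        # tasks over non-overlapping modality pairs should sit farther
        # apart than tasks sharing a modality, across seeds
        _, rois = small_geometry
        design = bd.DesignSpec(n_per_condition_per_run=2, isi_min=8.0,
                               isi_max=10.0, max_consecutive_same=2)
        acq = bd.AcquisitionParams(tr=3.0, n_volumes_per_run=30, n_runs=4)
        d_disjoint, d_overlap = [], []
        n_seeds = 20
        for seed in range(n_seeds):
            # subjects share the condition patterns (registered to a common
            # space) and differ in stimulus sequences and noise
            pat = bd.random_patterns(rois, design.conditions,
                                     effect_size=3.0, seed=7000 + seed)
            subjects = []
            for subj in range(3):
                s = 1000 * seed + 10 * subj
                events = bd.generate_design(design, acq, seed=s)
                ds = bd.simulate_dataset(
                    events, pat, bd.NoiseModel(white_sd=1.0, seed=s + 2),
                    acq, rois)
                subjects.append(bd.extract_patterns(ds, events, rois["roi"],
                                                    k=2))
            smaps = {}
            for pair in [("touch", "pain"), ("audition", "vision"),
                         ("touch", "audition")]:
                per_subj = [
                    bd.subject_sensitivity_map(
                        bd.crossvalidate_two_way(pset, pair,
                                                 keep_weights=True))
                    for pset in subjects]
                smaps[f"{pair[0]} vs {pair[1]}"] = bd.group_f_map(per_subj)
            D = bd.distance_matrix(smaps)
            d_disjoint.append(D.loc["touch vs pain", "audition vs vision"])
            d_overlap.append(D.loc["touch vs pain", "touch vs audition"])
        wins = np.sum(np.asarray(d_disjoint) > np.asarray(d_overlap))
        assert np.mean(d_disjoint) > np.mean(d_overlap)
        assert wins > n_seeds / 2


class TestGlm:
    def _single_voxel_dataset(self, scale=2.0, cond="a"):
        acq = bd.AcquisitionParams(tr=2.0, n_volumes_per_run=25, n_runs=2)
        events = pd.DataFrame({
            "run": [0, 0, 1, 1], "onset": [4.0, 20.0, 6.0, 24.0],
            "condition": ["a", "b", "b", "a"]})
        X = bd.glm_design(events, acq, ["a", "b"])
        data = np.zeros((2, 2, 2, 50))
        data[0, 0, 0] = scale * X[f"cond:{cond}"].to_numpy()
        run_index = np.repeat([0, 1], 25)
        ds = bd.FunctionalDataset(data=data, run_index=run_index,
                                  acquisition=acq)
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = True
        return ds, events, mask

    def test_exact_recovery_of_injected_amplitude(self):
        ds, events, mask = self._single_voxel_dataset(scale=2.0, cond="a")
        summary = bd.glm_betas(ds, events, mask, conditions=["a", "b"])
        assert summary.betas.iloc[0]["a"] == pytest.approx(2.0, abs=1e-8)
        assert summary.betas.iloc[0]["b"] == pytest.approx(0.0, abs=1e-8)

    def test_negative_response_has_negative_beta(self):
        ds, events, mask = self._single_voxel_dataset(scale=-1.5, cond="b")
        summary = bd.glm_betas(ds, events, mask, conditions=["a", "b"])
        assert summary.betas.iloc[0]["b"] < 0
        assert summary.sign_proportions.loc["b", "negative"] == 1.0

    def test_betas_match_pseudoinverse_oracle(self):
        rng = np.random.default_rng(4)
        acq = bd.AcquisitionParams(tr=2.0, n_volumes_per_run=30, n_runs=2)
        spec = bd.DesignSpec(conditions=("a", "b"), n_per_condition_per_run=2,
                             isi_min=6.0, isi_max=9.0)
        events = bd.generate_design(spec, acq, seed=5)
        data = rng.standard_normal((3, 2, 2, 60))
        ds = bd.FunctionalDataset(data=data,
                                  run_index=np.repeat([0, 1], 30),
                                  acquisition=acq)
        mask = np.ones((3, 2, 2), dtype=bool)
        summary = bd.glm_betas(ds, events, mask, conditions=["a", "b"])
        X = bd.glm_design(events, acq, ["a", "b"]).to_numpy()
        oracle = np.linalg.pinv(X) @ data.reshape(-1, 60).T
        np.testing.assert_allclose(summary.betas.to_numpy(), oracle[:2].T,
                                   atol=1e-10)
        assert np.allclose(
            summary.sign_proportions.sum(axis=1).to_numpy(), 1.0)

    def test_collinear_design_named(self):
        acq = bd.AcquisitionParams(tr=2.0, n_volumes_per_run=20, n_runs=2)
        events = pd.DataFrame({
            "run": [0, 0, 1, 1], "onset": [4.0, 4.0, 6.0, 6.0],
            "condition": ["a", "b", "a", "b"]})  # identical regressors
        data = np.zeros((2, 2, 2, 40))
        ds = bd.FunctionalDataset(data=data,
                                  run_index=np.repeat([0, 1], 20),
                                  acquisition=acq)
        mask = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(ValueError, match="cond:"):
            bd.glm_betas(ds, events, mask, conditions=["a", "b"])
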