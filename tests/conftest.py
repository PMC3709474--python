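import numpy as np
import pytest

import bolddecode as bd


@pytest.fixture(scope="session")
def fast_acq():
    """Short acquisition for unit tests (full-scale runs live in the
    calibration/acceptance checks)."""
    return bd.AcquisitionParams(tr=3.0, n_volumes_per_run=24, n_runs=4)


@pytest.fixture(scope="session")
def fast_design():
    return bd.DesignSpec(n_per_condition_per_run=2, isi_min=4.0, isi_max=6.0,
                         max_consecutive_same=2)


@pytest.fixture(scope="session")
def small_geometry():
    shape = (10, 10, 8)
    brain = np.zeros(shape, dtype=bool)
    brain[1:9, 1:9, 1:7] = True
    roi = np.zeros(shape, dtype=bool)
    roi[2:6, 2:6, 2:6] = True
    return brain, {"roi": roi}


@pytest.fixture(scope="session")
def strong_subject(fast_design, fast_acq, small_geometry):
    """One simulated subject with strong, clearly decodable patterns."""
    _, rois = small_geometry
    events = bd.generate_design(fast_design, fast_acq, seed=11)
    patterns = bd.random_patterns(rois, fast_design.conditions,
                                  effect_size=4.0, pattern_sparsity=0.5,
                                  seed=12)
    noise = bd.NoiseModel(white_sd=0.5, drift_slope_sd=0.01, seed=13)
    dataset = bd.simulate_dataset(events, patterns, noise, fast_acq, rois)
    return events, dataset, patterns, rois


@pytest.fixture(scope="session")
def strong_patterns(strong_subject):
    events, dataset, _, rois = strong_subject
    return bd.extract_patterns(dataset, events, rois["roi"], k=2)


def make_noise_patterns(rng, n_runs=4, n_per=4, n_vox=16,
                        conditions=("a", "b")):
    """TrialPatternSet of pure noise: labels carry no information."""
    from bolddecode.preprocess import TrialPatternSet

    n_run = n_per * len(conditions)
    X = rng.standard_normal((n_runs * n_run, n_vox))
    labels = np.tile(np.repeat(list(conditions), n_per), n_runs)
    runs = np.repeat(np.arange(n_runs), n_run)
    return TrialPatternSet(X=X, labels=labels, runs=runs, roi="toy",
                           volume_offset=2)
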