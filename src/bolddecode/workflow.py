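"""End-to-end orchestration of the two simulated experiments.

Experiment 1 decodes the modality of four stimulus types (touch, pain,
audition, vision) from each sensory ROI: all six two-way tasks, the
four-way pairwise-voting task, permutation inference on group-average
accuracies, the pertinent-vs-non-pertinent comparison, sensitivity maps
with group F-thresholding and their dissimilarity matrix, an out-of-brain
control ROI, and the accuracy time-course across post-stimulus volumes.

Experiment 2 uses four conditions structured as two modalities x two
locations and decodes (a) location within each modality and (b) modality
with locations pooled.

Every random choice derives from the single ``seed`` of the
:class:`StudyConfig`, so identical configs reproduce identical reports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .decode import (crossvalidate_four_way, crossvalidate_two_way,
                     timecourse_decoding)
from .inference import (PermutationResult, SubjectDecoding, permutation_test,
                        wilcoxon_paired)
from .maps import distance_matrix, group_f_map, subject_sensitivity_map
from .preprocess import extract_patterns, pool_labels
from .simulate import (AcquisitionParams, DEFAULT_CONDITIONS, DesignSpec,
                       NoiseModel, generate_design, make_control_roi,
                       random_patterns, simulate_dataset)

EXP2_CONDITIONS = ("touch1", "touch2", "vision1", "vision2")
EXP2_MODALITIES = {"touch": ("touch1", "touch2"),
                   "vision": ("vision1", "vision2")}


@dataclass
class StudyConfig:
    """All knobs of a simulated study in one reproducible record."""

    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_per_condition_per_run: int = 8
    isi_min: float = 10.0
    isi_max: float = 19.0
    max_consecutive_same: int = 2
    tr: float = 3.0
    n_volumes_per_run: int = 210
    n_runs: int = 4
    n_subjects: int = 6
    effect_size: float = 1.0
    pattern_sparsity: float = 0.5
    white_sd: float = 1.0
    drift_slope_sd: float = 0.01
    k: int = 2
    k_range: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)
    n_permutations: int = 1000
    svm_c: float = 1.0
    normalization: str = "both"
    seed: int = 0
    grid_shape: tuple[int, int, int] = (14, 14, 10)
    roi_principal: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"S1": ("touch", "pain"),
                                 "A1": ("audition",),
                                 "V1": ("vision",)})
    modalities: dict[str, tuple[str, ...]] | None = None
    run_timecourse: bool = True
    run_maps: bool = True

    @property
    def design(self) -> DesignSpec:
        return DesignSpec(conditions=tuple(self.conditions),
                          n_per_condition_per_run=self.n_per_condition_per_run,
                          isi_min=self.isi_min, isi_max=self.isi_max,
                          max_consecutive_same=self.max_consecutive_same)

    @property
    def acquisition(self) -> AcquisitionParams:
        return AcquisitionParams(tr=self.tr,
                                 n_volumes_per_run=self.n_volumes_per_run,
                                 n_runs=self.n_runs)


def apply_profile(config: StudyConfig, profile: str) -> StudyConfig:
    """``ci``: 6 subjects / 1,000 permutations; ``paper``: 14 / 10,000."""
    if profile == "ci":
        return replace(config, n_subjects=6, n_permutations=1000)
    if profile == "paper":
        return replace(config, n_subjects=14, n_permutations=10000)
    raise ValueError(f"unknown profile {profile!r}")


def config_from_mapping(mapping: dict) -> StudyConfig:
    known = {f.name for f in StudyConfig.__dataclass_fields__.values()}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("conditions", "k_range", "grid_shape"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    for key in ("roi_principal", "modalities"):
        if kwargs.get(key):
            kwargs[key] = {k: tuple(v) for k, v in kwargs[key].items()}
    return StudyConfig(**kwargs)


def default_geometry(shape=(14, 14, 10)) -> tuple[np.ndarray,
                                                  dict[str, np.ndarray]]:
    """Synthetic brain mask with three cubic sensory ROIs inside it.

    The brain is a central block, leaving an out-of-brain shell from which
    the control ROI can be drawn; the ROIs are disjoint 4x4x4 cubes.
    """
    brain = np.zeros(shape, dtype=bool)
    brain[1:shape[0] - 1, 1:shape[1] - 1, 1:shape[2] - 1] = True
    rois = {}
    spots = {"S1": (2, 2, 2), "A1": (8, 2, 2), "V1": (2, 8, 2)}
    for name, (x, y, z) in spots.items():
        m = np.zeros(shape, dtype=bool)
        m[x:x + 4, y:y + 4, z:z + 4] = True
        if not (m & brain).sum() == m.sum():
            raise ValueError("ROI extends outside the synthetic brain")
        rois[name] = m
    return brain, rois


def simulate_group(config: StudyConfig,
                   roi_masks: dict[str, np.ndarray] | None = None):
    """Simulate one group: per subject (events, dataset); shared geometry.

    Each subject gets an independent stimulus sequence and an independent
    set of condition patterns (idiosyncratic fine-grained maps, as across
    real brains), all derived from the config seed.
    """
    brain, rois = (None, roi_masks)
    if roi_masks is None:
        brain, rois = default_geometry(config.grid_shape)
    rng = np.random.default_rng(config.seed)
    subjects = []
    for _ in range(config.n_subjects):
        s_events, s_pat, s_noise = (int(x) for x in
                                    rng.integers(2 ** 31, size=3))
        events = generate_design(config.design, config.acquisition, s_events)
        patterns = random_patterns(rois, config.conditions,
                                   effect_size=config.effect_size,
                                   pattern_sparsity=config.pattern_sparsity,
                                   seed=s_pat)
        noise = NoiseModel(white_sd=config.white_sd,
                           drift_slope_sd=config.drift_slope_sd,
                           seed=s_noise)
        dataset = simulate_dataset(events, patterns, noise,
                                   config.acquisition, rois)
        subjects.append((events, dataset))
    return brain, rois, subjects


def _extract_all(config: StudyConfig, subjects, rois):
    """Per (subject, roi) TrialPatternSets at the default volume offset."""
    psets: dict[str, list] = {name: [] for name in rois}
    for events, dataset in subjects:
        for name, mask in rois.items():
            psets[name].append(
                extract_patterns(dataset, events, mask, k=config.k,
                                 normalization=config.normalization,
                                 roi_name=name))
    return psets


def _accuracy_table(psets, tasks, config: StudyConfig, seed: int):
    rows = []
    for roi_name, subject_sets in psets.items():
        for subj, pset in enumerate(subject_sets):
            for task in tasks:
                if task == "four-way":
                    res = crossvalidate_four_way(pset, C=config.svm_c,
                                                 seed=seed)
                else:
                    res = crossvalidate_two_way(pset, task, C=config.svm_c)
                for fold, acc in enumerate(res.fold_accuracies):
                    rows.append((subj, roi_name, res.task, fold, acc))
    return pd.DataFrame(rows, columns=["subject", "roi", "task", "fold",
                                       "accuracy"])


def _permutation_table(psets, tasks, config: StudyConfig, seed: int):
    rows = []
    results: dict[tuple[str, str], PermutationResult] = {}
    for roi_name, subject_sets in psets.items():
        for task in tasks:
            task_name = task if task == "four-way" else f"{task[0]} vs {task[1]}"
            subs = [SubjectDecoding(patterns=p, task=task, C=config.svm_c)
                    for p in subject_sets]
            res = permutation_test(subs, n_permutations=config.n_permutations,
                                   seed=seed)
            results[(roi_name, task_name)] = res
            rows.append((roi_name, task_name, res.observed, res.p_value,
                         res.p_report))
    table = pd.DataFrame(rows, columns=["roi", "task", "observed_accuracy",
                                        "p_value", "p_report"])
    return table, results


def _pertinence_comparison(accuracies: pd.DataFrame,
                           config: StudyConfig) -> pd.DataFrame:
    """Paired Wilcoxon: pertinent vs non-pertinent task accuracies per ROI.

    A two-way task is pertinent to an ROI when at least one of its
    conditions is a principal modality of that ROI.
    """
    rows = []
    pairs = list(itertools.combinations(config.conditions, 2))
    for roi_name, principal in config.roi_principal.items():
        pert = [f"{a} vs {b}" for a, b in pairs
                if a in principal or b in principal]
        nonp = [f"{a} vs {b}" for a, b in pairs
                if a not in principal and b not in principal]
        if not pert or not nonp:
            continue
        sub = accuracies[accuracies["roi"] == roi_name]
        mean_acc = sub.groupby(["subject", "task"])["accuracy"].mean()
        a = mean_acc.unstack()[pert].mean(axis=1).to_numpy()
        b = mean_acc.unstack()[nonp].mean(axis=1).to_numpy()
        try:
            comp = wilcoxon_paired(a, b, alternative="greater")
            stat, p = comp.statistic, comp.p_value
        except ValueError:
            # all paired differences zero (e.g. ceiling accuracies):
            # no information, reported as such rather than failing the run
            stat, p = float("nan"), float("nan")
        rows.append((roi_name, float(a.mean()), float(b.mean()), stat, p))
    return pd.DataFrame(rows, columns=["roi", "pertinent_mean",
                                       "non_pertinent_mean", "statistic",
                                       "p_value"])


def _sensitivity_analysis(psets, pairs, config: StudyConfig):
    group_maps: dict[str, dict[str, object]] = {}
    distances: dict[str, pd.DataFrame] = {}
    for roi_name, subject_sets in psets.items():
        per_task = {}
        for pair in pairs:
            smaps = []
            for pset in subject_sets:
                res = crossvalidate_two_way(pset, pair, C=config.svm_c,
                                            keep_weights=True)
                smaps.append(subject_sensitivity_map(
                    res, voxel_indices=pset.voxel_indices))
            per_task[f"{pair[0]} vs {pair[1]}"] = group_f_map(smaps)
        group_maps[roi_name] = per_task
        distances[roi_name] = distance_matrix(per_task)
    return group_maps, distances


def _timecourse_table(config: StudyConfig, subjects, rois, pair):
    rows = []
    for roi_name, mask in rois.items():
        for subj, (events, dataset) in enumerate(subjects):
            res = timecourse_decoding(dataset, events, mask, pair,
                                      k_range=config.k_range,
                                      normalization=config.normalization,
                                      C=config.svm_c, roi_name=roi_name)
            for k, r in res.items():
                rows.append((subj, roi_name, f"{pair[0]} vs {pair[1]}", k,
                             r.mean_accuracy))
    return pd.DataFrame(rows, columns=["subject", "roi", "task",
                                       "volume_offset", "accuracy"])


def chance_calibration(n_replicates: int = 50, n_subjects: int = 6,
                       seed: int = 1,
                       config: StudyConfig | None = None,
                       pair: tuple[str, str] | None = None) -> pd.DataFrame:
    """Group-average accuracy of the full pipeline on pure-noise data.

    Generates ``n_replicates`` independent groups with zero
    condition-specific signal (the full design, simulation, extraction and
    decoding chain otherwise unchanged), decodes one condition pair
    (two-way) and all conditions (pairwise-voting multiclass) in a single
    compact ROI, and returns one row per replicate with the group-mean
    accuracies.  Their grand means estimate the pipeline's empirical
    chance levels (1/2 and 1/4 for the four-condition design).
    """
    if config is None:
        config = StudyConfig()
    config = replace(config, effect_size=0.0, n_subjects=n_subjects)
    if pair is None:
        pair = tuple(config.conditions[:2])
    # one small cubic ROI inside a compact brain block: the null carries no
    # spatial structure, so a single ROI suffices and keeps replicates cheap
    shape = (8, 8, 6)
    roi = np.zeros(shape, dtype=bool)
    roi[2:6, 2:6, 1:5] = True
    rois = {"roi": roi}
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        rep_cfg = replace(config, seed=int(rng.integers(2 ** 31)))
        _, _, subjects = simulate_group(rep_cfg, roi_masks=rois)
        two, four = [], []
        for events, dataset in subjects:
            pset = extract_patterns(dataset, events, roi, k=rep_cfg.k,
                                    normalization=rep_cfg.normalization,
                                    roi_name="roi")
            two.append(crossvalidate_two_way(pset, pair,
                                             C=rep_cfg.svm_c).mean_accuracy)
            four.append(crossvalidate_four_way(
                pset, C=rep_cfg.svm_c, seed=rep_cfg.seed).mean_accuracy)
        rows.append((rep, float(np.mean(two)), float(np.mean(four))))
    return pd.DataFrame(rows, columns=["replicate", "two_way_accuracy",
                                       "multiway_accuracy"])


def run_experiment1(config: StudyConfig, out_dir=None) -> dict:
    """Four-modality study: all decoding, inference and map stages.

    Returns a report bundle (dict of tables and result objects); when
    ``out_dir`` is given, writes tab-separated tables, NIfTI maps and a
    JSON sidecar echoing the configuration.
    """
    if len(config.conditions) != 4:
        raise ValueError("the four-modality experiment needs 4 conditions")
    rng = np.random.default_rng(config.seed + 1)
    seed_perm, seed_tie, seed_ctrl = (int(x) for x in
                                      rng.integers(2 ** 31, size=3))
    brain, rois, subjects = simulate_group(config)
    control = make_control_roi(brain, rois, seed=seed_ctrl)
    rois_all = dict(rois)
    rois_all["control"] = control

    psets = _extract_all(config, subjects, rois_all)
    pairs = list(itertools.combinations(config.conditions, 2))
    tasks = pairs + ["four-way"]

    accuracies = _accuracy_table(psets, tasks, config, seed_tie)
    perm_table, perm_results = _permutation_table(psets, tasks, config,
                                                  seed_perm)
    wilcoxon = _pertinence_comparison(accuracies, config)

    confusions = {}
    for roi_name, subject_sets in psets.items():
        mats = [crossvalidate_four_way(p, C=config.svm_c,
                                       seed=seed_tie).confusion
                for p in subject_sets]
        confusions[roi_name] = sum(m.to_numpy() for m in mats) / len(mats)
        confusions[roi_name] = pd.DataFrame(confusions[roi_name],
                                            index=list(config.conditions),
                                            columns=list(config.conditions))

    group_maps, distances = ({}, {})
    if config.run_maps:
        group_maps, distances = _sensitivity_analysis(
            {n: psets[n] for n in rois}, pairs, config)

    timecourse = None
    if config.run_timecourse:
        timecourse = _timecourse_table(config, subjects, rois, pairs[0])

    report = {
        "config": config,
        "accuracies": accuracies,
        "permutation": perm_table,
        "permutation_results": perm_results,
        "wilcoxon_pertinence": wilcoxon,
        "confusion": confusions,
        "group_maps": group_maps,
        "distance": distances,
        "timecourse": timecourse,
        "rois": rois_all,
    }
    if out_dir is not None:
        _write_report(report, out_dir, config)
    return report


def run_experiment2(config: StudyConfig | None = None, out_dir=None) -> dict:
    """Two-modality x two-location study: location and pooled-modality
    decoding with permutation inference."""
    if config is None:
        config = StudyConfig(conditions=EXP2_CONDITIONS,
                             modalities=EXP2_MODALITIES)
    modalities = config.modalities or EXP2_MODALITIES
    if len(modalities) < 2:
        raise ValueError("experiment 2 needs at least two modalities")
    for mod, locs in modalities.items():
        if len(locs) < 2:
            raise ValueError(
                f"modality {mod!r} has {len(locs)} location(s); >= 2 required"
            )
        if not set(locs) <= set(config.conditions):
            raise ValueError(f"locations of {mod!r} missing from conditions")
    rng = np.random.default_rng(config.seed + 2)
    seed_perm = int(rng.integers(2 ** 31))
    _, rois, subjects = simulate_group(config)
    psets = _extract_all(config, subjects, rois)

    pool_map = {loc: mod for mod, locs in modalities.items() for loc in locs}
    rows = []
    perm_results = {}
    for roi_name, subject_sets in psets.items():
        tasks = []
        # location decoding within each modality
        for mod, locs in modalities.items():
            for pair in itertools.combinations(locs, 2):
                tasks.append((f"{pair[0]} vs {pair[1]}", pair, subject_sets))
        # modality decoding with locations pooled
        pooled_sets = [pool_labels(p, pool_map) for p in subject_sets]
        for pair in itertools.combinations(sorted(modalities), 2):
            tasks.append((f"{pair[0]} vs {pair[1]} (pooled)", pair,
                          pooled_sets))
        for task_name, pair, sets in tasks:
            subs = [SubjectDecoding(patterns=p, task=tuple(pair),
                                    C=config.svm_c) for p in sets]
            res = permutation_test(subs, n_permutations=config.n_permutations,
                                   seed=seed_perm)
            perm_results[(roi_name, task_name)] = res
            rows.append((roi_name, task_name, res.observed, res.p_value,
                         res.p_report))
    table = pd.DataFrame(rows, columns=["roi", "task", "observed_accuracy",
                                        "p_value", "p_report"])
    report = {"config": config, "permutation": table,
              "permutation_results": perm_results, "rois": rois}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_table(table, out / "permutation.tsv")
        io.save_sidecar(config, out / "config.json")
    return report


def _write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(str(path), sep="\t", index=False, float_format="%.6g")


def _write_report(report: dict, out_dir, config: StudyConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_table(report["accuracies"], out / "accuracies.tsv")
    _write_table(report["permutation"], out / "permutation.tsv")
    _write_table(report["wilcoxon_pertinence"], out / "wilcoxon.tsv")
    for roi_name, mat in report["confusion"].items():
        mat.to_csv(out / f"confusion_{roi_name}.tsv", sep="\t",
                   float_format="%.6g")
    for roi_name, d in report["distance"].items():
        d.to_csv(out / f"distance_{roi_name}.tsv", sep="\t",
                 float_format="%.6g")
    if report["timecourse"] is not None:
        _write_table(report["timecourse"], out / "timecourse.tsv")
    for roi_name, per_task in report["group_maps"].items():
        for task, smap in per_task.items():
            safe = task.replace(" ", "_")
            io.save_map(smap.values, smap.voxel_indices, config.grid_shape,
                        out / f"fmap_{roi_name}_{safe}.nii.gz")
    for roi_name, mask in report["rois"].items():
        io.save_mask(mask, out / f"roi_{roi_name}.nii.gz")
    io.save_sidecar(config, out / "config.json")
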