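"""Synthetic event-related BOLD data generation.

This module builds complete synthetic fMRI datasets whose statistical
structure mirrors a slow event-related multi-condition design: balanced
pseudo-random stimulus sequences with a bounded inter-stimulus interval and
a cap on consecutive same-condition events, condition-specific multivoxel
spatial patterns confined to regions of interest, a double-gamma
hemodynamic impulse response, per-run linear drift and white measurement
noise.  Every stage of the decoding pipeline can therefore be exercised and
validated without any human data.

The default design parameters correspond to a four-condition experiment
acquired in four runs of 32 events each (8 per condition), with an ISI
drawn uniformly from 10-19 s, at most two consecutive events of the same
condition, and a repetition time of 3 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ("run", "onset", "condition")

#: default condition labels of the four-modality design
DEFAULT_CONDITIONS = ("touch", "pain", "audition", "vision")


@dataclass(frozen=True)
class AcquisitionParams:
    """Scanner timing: volumes are acquired every ``tr`` seconds.

    Volume ``k`` of a run covers the half-open interval ``[k*tr, (k+1)*tr)``
    seconds from run start; its sample instant is taken at ``k*tr``.
    """

    tr: float = 3.0
    n_volumes_per_run: int = 210
    n_runs: int = 4

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.n_volumes_per_run < 1:
            raise ValueError("n_volumes_per_run must be >= 1")
        if self.n_runs < 2:
            raise ValueError(
                "n_runs must be >= 2 (leave-one-run-out needs at least two runs)"
            )

    @property
    def run_duration(self) -> float:
        return self.tr * self.n_volumes_per_run

    @property
    def n_volumes_total(self) -> int:
        return self.n_volumes_per_run * self.n_runs


@dataclass(frozen=True)
class DesignSpec:
    """Stimulation design of one run, replicated over runs.

    ``max_consecutive_same`` bounds the length of same-condition streaks;
    the default of 2 forbids three consecutive events of one condition.
    """

    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_per_condition_per_run: int = 8
    isi_min: float = 10.0
    isi_max: float = 19.0
    max_consecutive_same: int = 2

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if not self.conditions:
            raise ValueError("at least one condition required")
        if self.n_per_condition_per_run < 1:
            raise ValueError("n_per_condition_per_run must be >= 1")
        if self.isi_min > self.isi_max:
            raise ValueError(
                f"isi_min ({self.isi_min}) must not exceed isi_max ({self.isi_max})"
            )
        if self.isi_min <= 0:
            raise ValueError("isi_min must be positive")
        if self.max_consecutive_same < 1:
            raise ValueError("max_consecutive_same must be >= 1")

    @property
    def n_events_per_run(self) -> int:
        return self.n_per_condition_per_run * len(self.conditions)


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise: white Gaussian noise plus a per-run linear drift.

    ``white_sd`` is in signal units per volume sample; ``drift_slope_sd``
    is the standard deviation of the per-voxel drift slope in signal units
    per volume.  All randomness derives from ``seed``.
    """

    white_sd: float = 1.0
    drift_slope_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_sd < 0:
            raise ValueError("white_sd must be >= 0")
        if self.drift_slope_sd < 0:
            raise ValueError("drift_slope_sd must be >= 0")


@dataclass
class PatternSpec:
    """Condition-specific multivoxel response patterns.

    ``maps[roi][condition]`` holds the unitless response amplitude of each
    ROI voxel (1-D, ordered as ``np.flatnonzero`` of the ROI mask).  The
    injected response of a voxel to an event is
    ``effect_size * amplitude * hrf(t - onset)``.
    """

    maps: dict[str, dict[str, np.ndarray]]
    effect_size: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0 (0 = pure-noise dataset)")

    def scaled(self, factor: float) -> "PatternSpec":
        return replace(self, effect_size=self.effect_size * factor)


@dataclass
class FunctionalDataset:
    """A 4-D voxel grid over time with contiguous run blocks.

    ``data`` has shape ``(x, y, z, time)``; ``run_index`` assigns each
    volume to its acquisition run.
    """

    data: np.ndarray
    run_index: np.ndarray
    acquisition: AcquisitionParams
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be a 4-D (x, y, z, time) array")
        if self.data.shape[3] != self.acquisition.n_volumes_total:
            raise ValueError(
                "time axis length must equal n_runs * n_volumes_per_run "
                f"({self.acquisition.n_volumes_total}), got {self.data.shape[3]}"
            )
        self.run_index = np.asarray(self.run_index)
        if self.run_index.shape != (self.data.shape[3],):
            raise ValueError("run_index must have one entry per volume")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_runs(self) -> int:
        return self.acquisition.n_runs

    def run_slice(self, run: int) -> slice:
        idx = np.flatnonzero(self.run_index == run)
        if idx.size == 0:
            raise ValueError(f"no volumes for run {run}")
        return slice(int(idx[0]), int(idx[-1]) + 1)


def validate_events(events: pd.DataFrame, spec: DesignSpec | None = None) -> None:
    """Raise ``ValueError`` if the event table violates its invariants."""
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    for run, grp in events.groupby("run"):
        onsets = grp["onset"].to_numpy()
        if not np.all(np.diff(onsets) > 0):
            raise ValueError(f"onsets must be strictly increasing within run {run}")
        if spec is not None:
            counts = grp["condition"].value_counts()
            for cond in spec.conditions:
                if counts.get(cond, 0) != spec.n_per_condition_per_run:
                    raise ValueError(
                        f"run {run}: condition {cond!r} has {counts.get(cond, 0)} "
                        f"events, expected {spec.n_per_condition_per_run}"
                    )
            seq = grp["condition"].to_list()
            if _max_streak(seq) > spec.max_consecutive_same:
                raise ValueError(
                    f"run {run}: more than {spec.max_consecutive_same} consecutive "
                    "same-condition events"
                )


def _max_streak(seq) -> int:
    best = cur = 1
    for a, b in zip(seq, seq[1:]):
        cur = cur + 1 if a == b else 1
        best = max(best, cur)
    return best


def _condition_sequence(spec: DesignSpec, rng: np.random.Generator,
                        max_retries: int = 200) -> list[str]:
    """Balanced pseudo-random condition sequence with bounded streaks.

    Rejection-samples random permutations of the balanced multiset; after
    ``max_retries`` failures falls back to a greedy scheduler that places,
    at each position, a random condition with maximal remaining count among
    those that do not extend a forbidden streak.
    """
    pool = [c for c in spec.conditions for _ in range(spec.n_per_condition_per_run)]
    if len(spec.conditions) == 1:
        if spec.n_per_condition_per_run > spec.max_consecutive_same:
            raise ValueError(
                "single-condition design cannot satisfy max_consecutive_same="
                f"{spec.max_consecutive_same} with "
                f"{spec.n_per_condition_per_run} events"
            )
        return pool
    for _ in range(max_retries):
        perm = list(rng.permutation(pool))
        if _max_streak(perm) <= spec.max_consecutive_same:
            return perm
    # constructive fallback: largest-remaining-count greedy
    remaining = {c: spec.n_per_condition_per_run for c in spec.conditions}
    seq: list[str] = []
    streak_cond, streak_len = None, 0
    for _ in range(len(pool)):
        allowed = [c for c, n in remaining.items()
                   if n > 0 and not (c == streak_cond
                                     and streak_len >= spec.max_consecutive_same)]
        if not allowed:
            raise ValueError(
                "no condition sequence satisfies max_consecutive_same="
                f"{spec.max_consecutive_same} for this design"
            )
        top = max(remaining[c] for c in allowed)
        candidates = [c for c in allowed if remaining[c] == top]
        choice = candidates[int(rng.integers(len(candidates)))]
        seq.append(choice)
        remaining[choice] -= 1
        if choice == streak_cond:
            streak_len += 1
        else:
            streak_cond, streak_len = choice, 1
    return seq


def generate_design(spec: DesignSpec, acq: AcquisitionParams,
                    seed: int) -> pd.DataFrame:
    """Generate a balanced pseudo-random event table for all runs.

    Onsets start after a lead-in drawn like an ISI and are spaced by ISIs
    drawn uniformly from ``[isi_min, isi_max]``, independently per event.
    Returns a DataFrame with columns ``run``, ``onset``, ``condition``.
    """
    n_events = spec.n_events_per_run
    # feasibility at the minimum ISI: lead-in + (n-1) gaps + one volume tail
    min_span = spec.isi_min * n_events + acq.tr
    if min_span > acq.run_duration:
        raise ValueError(
            f"run too short: {n_events} events need at least {min_span:.1f} s "
            f"at isi_min={spec.isi_min}, run lasts {acq.run_duration:.1f} s"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(acq.n_runs):
        seq = _condition_sequence(spec, rng)
        for _ in range(1000):
            isis = rng.uniform(spec.isi_min, spec.isi_max, size=n_events)
            onsets = np.cumsum(isis)
            if onsets[-1] + acq.tr <= acq.run_duration:
                break
        else:
            raise ValueError(
                "could not place events within the run: run duration "
                f"{acq.run_duration:.1f} s is too short for the sampled ISIs"
            )
        for onset, cond in zip(onsets, seq):
            rows.append((run, float(onset), cond))
    events = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    validate_events(events, spec)
    return events


# ---------------------------------------------------------------------------
# Hemodynamic response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HrfParams:
    """Double-gamma impulse response; defaults peak at ~5 s.

    The response is ``gampdf(t; peak_shape, peak_scale) -
    undershoot_ratio * gampdf(t; undershoot_shape, undershoot_scale)``,
    rescaled so its maximum is 1.
    """

    peak_shape: float = 6.0
    peak_scale: float = 1.0
    undershoot_shape: float = 16.0
    undershoot_scale: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        for name in ("peak_shape", "peak_scale", "undershoot_shape",
                     "undershoot_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be >= 0")


DEFAULT_HRF = HrfParams()

_peak_cache: dict[HrfParams, float] = {}


def _hrf_raw(t: np.ndarray, p: HrfParams) -> np.ndarray:
    return (_gamma_dist.pdf(t, p.peak_shape, scale=p.peak_scale)
            - p.undershoot_ratio
            * _gamma_dist.pdf(t, p.undershoot_shape, scale=p.undershoot_scale))


def hrf(t, params: HrfParams = DEFAULT_HRF):
    """Canonical double-gamma hemodynamic response, peak-normalized to 1.

    Zero for ``t <= 0`` (causality); a single positive peak near 5 s is
    followed by a shallow undershoot that returns to baseline by ~30 s.
    Accepts scalars or arrays.
    """
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if params not in _peak_cache:
        grid = np.arange(0.0, 40.0, 1e-3)
        _peak_cache[params] = float(_hrf_raw(grid, params).max())
    peak = _peak_cache[params]
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = _hrf_raw(t[pos], params) / peak
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Dataset synthesis
# ---------------------------------------------------------------------------

def random_patterns(roi_masks: dict[str, np.ndarray],
                    conditions,
                    effect_size: float = 1.0,
                    pattern_sparsity: float = 0.5,
                    seed: int = 0) -> PatternSpec:
    """Draw independent condition patterns for each ROI.

    For every (ROI, condition) pair a random subset of ``pattern_sparsity``
    of the ROI voxels receives a standard-normal amplitude; the rest stay
    silent.  Distinct conditions get independent draws, so their patterns
    are distinguishable in expectation but spatially interleaved.
    """
    if not 0 < pattern_sparsity <= 1:
        raise ValueError("pattern_sparsity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    maps: dict[str, dict[str, np.ndarray]] = {}
    for roi_name, mask in roi_masks.items():
        n_vox = int(np.count_nonzero(mask))
        n_active = max(1, int(round(pattern_sparsity * n_vox)))
        maps[roi_name] = {}
        for cond in conditions:
            amp = np.zeros(n_vox)
            active = rng.choice(n_vox, size=n_active, replace=False)
            amp[active] = rng.standard_normal(n_active)
            maps[roi_name][cond] = amp
    return PatternSpec(maps=maps, effect_size=effect_size)


def _condition_regressors(events_run: pd.DataFrame, conditions,
                          acq: AcquisitionParams,
                          hrf_params: HrfParams) -> dict[str, np.ndarray]:
    """HRF response of each condition sampled at the run's volume times."""
    t = np.arange(acq.n_volumes_per_run) * acq.tr
    regs = {c: np.zeros(acq.n_volumes_per_run) for c in conditions}
    for onset, cond in zip(events_run["onset"], events_run["condition"]):
        if cond in regs:
            regs[cond] += hrf(t - onset, hrf_params)
    return regs


def simulate_dataset(events: pd.DataFrame,
                     patterns: PatternSpec,
                     noise: NoiseModel,
                     acq: AcquisitionParams,
                     roi_masks: dict[str, np.ndarray],
                     hrf_params: HrfParams = DEFAULT_HRF,
                     affine: np.ndarray | None = None) -> FunctionalDataset:
    """Synthesize a 4-D dataset from events, patterns and a noise model.

    Each voxel's time series is the superposition of HRF-shaped responses
    (one per event of each condition the voxel's ROI pattern responds to),
    scaled by ``patterns.effect_size``, plus a per-run linear drift and
    white Gaussian noise.  Runs are generated from independent random
    streams derived from ``noise.seed``, so the dataset is bit-reproducible
    and run blocks are statistically independent.
    """
    shapes = {m.shape for m in roi_masks.values()}
    if len(shapes) > 1:
        raise ValueError("all ROI masks must share one grid shape")
    if not shapes:
        raise ValueError("at least one ROI mask required")
    shape = shapes.pop()
    for name, mask in roi_masks.items():
        if name in patterns.maps:
            n_vox = int(np.count_nonzero(mask))
            for cond, amp in patterns.maps[name].items():
                if len(amp) != n_vox:
                    raise ValueError(
                        f"pattern map for ROI {name!r}, condition {cond!r} has "
                        f"{len(amp)} amplitudes but the mask has {n_vox} voxels"
                    )
    missing_rois = set(patterns.maps) - set(roi_masks)
    if missing_rois:
        raise ValueError(f"patterns reference unknown ROIs: {sorted(missing_rois)}")

    validate_events(events)
    nv = acq.n_volumes_per_run
    data = np.zeros(shape + (acq.n_volumes_total,))
    run_index = np.repeat(np.arange(acq.n_runs), nv)
    flat = data.reshape(-1, acq.n_volumes_total)

    for run in range(acq.n_runs):
        rng = np.random.default_rng([int(noise.seed), run])
        sl = slice(run * nv, (run + 1) * nv)
        ev_run = events[events["run"] == run]
        if (ev_run["onset"] + acq.tr > acq.run_duration).any():
            raise ValueError(f"run {run}: events extend beyond the run end")
        if patterns.effect_size > 0:
            for roi_name, cond_maps in patterns.maps.items():
                vox = np.flatnonzero(roi_masks[roi_name].reshape(-1))
                regs = _condition_regressors(ev_run, list(cond_maps), acq,
                                             hrf_params)
                for cond, amp in cond_maps.items():
                    flat[vox, sl] += (patterns.effect_size
                                      * np.outer(amp, regs[cond]))
        if noise.drift_slope_sd > 0:
            slopes = rng.normal(0.0, noise.drift_slope_sd, size=flat.shape[0])
            ramp = np.arange(nv) - (nv - 1) / 2.0
            flat[:, sl] += np.outer(slopes, ramp)
        if noise.white_sd > 0:
            flat[:, sl] += rng.normal(0.0, noise.white_sd,
                                      size=(flat.shape[0], nv))

    return FunctionalDataset(
        data=data, run_index=run_index, acquisition=acq,
        affine=np.eye(4) if affine is None else affine,
    )


def make_control_roi(brain_mask: np.ndarray,
                     roi_masks: dict[str, np.ndarray],
                     seed: int) -> np.ndarray:
    """Random out-of-brain control region matched in size to the ROIs.

    Selects, without replacement, out-of-brain voxels equal in number to
    the rounded mean voxel count of the supplied ROIs.  The returned mask
    never intersects the brain mask.
    """
    if not roi_masks:
        raise ValueError("at least one ROI required to define the target size")
    sizes = [int(np.count_nonzero(m)) for m in roi_masks.values()]
    n_target = int(round(float(np.mean(sizes))))
    outside = np.flatnonzero(~brain_mask.astype(bool).reshape(-1))
    if outside.size < n_target:
        raise ValueError(
            f"only {outside.size} out-of-brain voxels available, "
            f"{n_target} needed"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(outside, size=n_target, replace=False)
    control = np.zeros(brain_mask.size, dtype=bool)
    control[chosen] = True
    return control.reshape(brain_mask.shape)
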