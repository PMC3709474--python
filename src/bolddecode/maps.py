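"""Sensitivity maps, group F-statistics, map dissimilarity, GLM betas.

A subject's sensitivity map assigns every ROI voxel its linear-SVM weight
for one binary task (averaged over cross-validation folds).  Group maps
test each voxel's weight against zero with a one-sample F-test across
subjects; dissimilarity between two tasks' group maps is 1 - r with r the
Pearson correlation over shared voxels.  A conventional univariate GLM
(HRF-convolved condition regressors, per-run intercept and linear drift)
characterizes whether contributing voxels carry signal increases or
decreases.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decode import DecodingResult
from .simulate import DEFAULT_HRF, FunctionalDataset, HrfParams, hrf

logger = logging.getLogger(__name__)


@dataclass
class SensitivityMap:
    """Per-voxel values for one task, at subject or group level.

    Subject-level values are raw classifier weights; group-level values
    are F-statistics.  ``voxel_indices`` (flat grid indices) tie the
    vector back to the common voxel grid.
    """

    values: np.ndarray
    task: str
    level: str  # "subject" | "group"
    voxel_indices: np.ndarray | None = None
    df: tuple[int, int] | None = None
    critical_value: float | None = None
    significant: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.level not in ("subject", "group"):
            raise ValueError("level must be 'subject' or 'group'")


def subject_sensitivity_map(result: DecodingResult,
                            voxel_indices: np.ndarray | None = None
                            ) -> SensitivityMap:
    """Average the per-fold SVM weight vectors into one subject map."""
    if not result.weights:
        raise ValueError(
            "decoding result carries no weights; rerun with keep_weights=True"
        )
    stacked = np.vstack([w.weights for w in result.weights])
    return SensitivityMap(values=stacked.mean(axis=0), task=result.task,
                          level="subject", voxel_indices=voxel_indices)


def f_critical(n_subjects: int, alpha: float = 0.05) -> float:
    """Critical value of F(1, n-1) at significance level ``alpha``."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    return float(stats.f.ppf(1 - alpha, 1, n_subjects - 1))


def group_f_map(subject_maps: list[SensitivityMap],
                alpha: float = 0.05) -> SensitivityMap:
    """Test each voxel's weight against zero across subjects.

    Per voxel, F = t^2 of the one-sample t-test, with (1, n-1) degrees of
    freedom; voxels exceeding the alpha critical value form the
    significant-contribution mask.  Voxels that are zero in every subject
    are undefined and excluded (NaN); nonzero-mean voxels with zero
    between-subject variance get a +inf sentinel, both with a warning.
    """
    if len(subject_maps) < 2:
        raise ValueError("need at least 2 subjects")
    lengths = {len(m.values) for m in subject_maps}
    if len(lengths) != 1:
        raise ValueError("subject maps must share one voxel grid")
    W = np.vstack([m.values for m in subject_maps])
    n = W.shape[0]
    mean = W.mean(axis=0)
    var = W.var(axis=0, ddof=1)
    F = np.empty(W.shape[1])
    zero_var = var == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        F[~zero_var] = n * mean[~zero_var] ** 2 / var[~zero_var]
    all_zero = zero_var & (mean == 0)
    degenerate = zero_var & (mean != 0)
    F[all_zero] = np.nan
    F[degenerate] = np.inf
    if all_zero.any():
        warnings.warn(f"{int(all_zero.sum())} voxels are zero in every "
                      "subject; excluded from the group map", stacklevel=2)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} voxels have zero "
                      "between-subject variance; F set to +inf", stacklevel=2)
    crit = f_critical(n, alpha)
    sig = np.zeros_like(F, dtype=bool)
    ok = ~np.isnan(F)
    sig[ok] = F[ok] > crit
    return SensitivityMap(values=F, task=subject_maps[0].task, level="group",
                          voxel_indices=subject_maps[0].voxel_indices,
                          df=(1, n - 1), critical_value=crit,
                          significant=sig)


def distance_matrix(group_maps: dict[str, SensitivityMap]) -> pd.DataFrame:
    """Pairwise 1 - r dissimilarity between group-level maps.

    r is the Pearson correlation over voxels finite in both maps (zero
    weights are informative and kept; NaN voxels are excluded pairwise).
    The result is symmetric with a zero diagonal, entries in [0, 2].
    """
    tasks = list(group_maps)
    if len(tasks) < 2:
        raise ValueError("need at least 2 maps")
    D = pd.DataFrame(0.0, index=tasks, columns=tasks)
    for a, b in itertools.combinations(tasks, 2):
        va, vb = group_maps[a].values, group_maps[b].values
        if len(va) != len(vb):
            raise ValueError(f"maps {a!r} and {b!r} differ in voxel count")
        ok = np.isfinite(va) & np.isfinite(vb)
        if ok.sum() < 3:
            raise ValueError(f"maps {a!r} and {b!r} share too few voxels")
        if np.ptp(va[ok]) == 0 or np.ptp(vb[ok]) == 0:
            raise ValueError(
                f"constant map in pair ({a!r}, {b!r}); correlation undefined"
            )
        r = float(np.corrcoef(va[ok], vb[ok])[0, 1])
        D.loc[a, b] = D.loc[b, a] = 1.0 - r
    return D


@dataclass
class BetaSummary:
    """GLM beta estimates for a set of contributing voxels.

    ``betas`` is voxels x conditions; ``sign_proportions`` gives, per
    condition, the fractions of voxels with positive, negative and zero
    response amplitude (summing to 1).
    """

    betas: pd.DataFrame
    sign_proportions: pd.DataFrame
    design_columns: list[str]


def glm_design(events: pd.DataFrame, acq, conditions,
               hrf_params: HrfParams = DEFAULT_HRF) -> pd.DataFrame:
    """Design matrix: HRF-convolved condition regressors + per-run
    intercept and linear drift columns, sampled at volume times."""
    nv = acq.n_volumes_per_run
    t = np.arange(nv) * acq.tr
    cols: dict[str, np.ndarray] = {}
    for cond in conditions:
        reg = np.zeros(nv * acq.n_runs)
        for run in range(acq.n_runs):
            ev = events[(events["run"] == run) & (events["condition"] == cond)]
            block = np.zeros(nv)
            for onset in ev["onset"]:
                block += hrf(t - onset, hrf_params)
            reg[run * nv:(run + 1) * nv] = block
        cols[f"cond:{cond}"] = reg
    for run in range(acq.n_runs):
        ind = np.zeros(nv * acq.n_runs)
        ind[run * nv:(run + 1) * nv] = 1.0
        cols[f"intercept:run{run}"] = ind
        drift = np.zeros(nv * acq.n_runs)
        drift[run * nv:(run + 1) * nv] = np.linspace(-1, 1, nv)
        cols[f"drift:run{run}"] = drift
    return pd.DataFrame(cols)


def glm_betas(data: FunctionalDataset, events: pd.DataFrame,
              voxels: np.ndarray, conditions=None,
              hrf_params: HrfParams = DEFAULT_HRF) -> BetaSummary:
    """Ordinary-least-squares betas for each voxel of a mask.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    conds = (list(conditions) if conditions is not None
             else sorted(events["condition"].unique()))
    X = glm_design(events, data.acquisition, conds, hrf_params)
    Xm = X.to_numpy()
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # pinpoint columns whose removal restores full rank
        collinear = [c for i, c in enumerate(X.columns)
                     if np.linalg.matrix_rank(np.delete(Xm, i, axis=1)) == rank]
        raise ValueError(f"rank-deficient design matrix; collinear columns: "
                         f"{collinear}")
    vox = np.flatnonzero(np.asarray(voxels, dtype=bool).reshape(-1))
    if vox.size == 0:
        raise ValueError("empty voxel mask")
    Y = data.data.reshape(-1, data.data.shape[3])[vox].T  # time x voxels
    beta, *_ = np.linalg.lstsq(Xm, Y, rcond=None)
    betas = pd.DataFrame(beta.T, columns=X.columns,
                         index=[int(v) for v in vox])[
        [f"cond:{c}" for c in conds]]
    betas.columns = conds
    props = pd.DataFrame(
        {c: {"positive": float(np.mean(betas[c] > 0)),
             "negative": float(np.mean(betas[c] < 0)),
             "zero": float(np.mean(betas[c] == 0))} for c in conds}
    ).T[["positive", "negative", "zero"]]
    return BetaSummary(betas=betas, sign_proportions=props,
                       design_columns=list(X.columns))
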