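"""Task-design GLM: build HRF-convolved design matrices and regress them out.

Used to check whether spectral features of task runs survive removal of the
task-evoked component: each trial (or condition) becomes a boxcar sampled on
the TR grid, convolved with the canonical HRF; ordinary least squares then
returns the residual time series for downstream spectral/complexity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sp_linalg

from .containers import RoiTimeSeries, TaskDesign
from .exceptions import ValidationError
from .hrf import hrf_convolve


@dataclass
class DesignMatrix:
    """Time × regressor matrix with an intercept (and optional drift)."""

    columns: np.ndarray
    names: list[str]
    tr: float

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2:
            raise ValidationError("columns must be 2-D")
        if len(self.names) != self.columns.shape[1]:
            raise ValidationError("name count does not match column count")
        if "intercept" not in self.names:
            raise ValidationError("design must include an intercept column")
        if self.columns.shape[1] >= self.columns.shape[0]:
            raise ValidationError("more regressors than time points")
        norms = np.abs(self.columns).max(axis=0)
        if (norms == 0).any():
            bad = [n for n, z in zip(self.names, norms == 0) if z]
            raise ValidationError(f"all-zero regressor(s): {bad}")

    @property
    def n_time(self) -> int:
        return self.columns.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.columns.shape[1]


def _boxcar(onset: float, duration: float, n_time: int, tr: float) -> np.ndarray:
    frame_times = np.arange(n_time) * tr
    return ((frame_times >= onset)
            & (frame_times < onset + duration)).astype(float)


def build_design(
    design: TaskDesign,
    n_time: int,
    trialwise: bool = True,
    drift: bool = True,
) -> DesignMatrix:
    """HRF-convolved task design plus intercept (and linear drift) columns.

    ``trialwise=True`` gives one regressor per trial; otherwise trials of a
    condition share one regressor. Trials extending past ``n_time`` volumes
    are truncated with a warning; a trial entirely past the end is dropped.
    An empty design yields nuisance columns only.
    """
    if n_time < 2:
        raise ValidationError("n_time must be ≥ 2")
    run_end = n_time * design.tr
    task_cols: list[np.ndarray] = []
    task_names: list[str] = []

    for label, trials in design.conditions:
        per_condition = np.zeros(n_time)
        for t_idx, (onset, duration) in enumerate(trials):
            if onset >= run_end:
                warnings.warn(
                    f"trial {t_idx} of {label!r} starts past the run end; "
                    "dropped", RuntimeWarning)
                continue
            if onset + duration > run_end + 1e-9:
                warnings.warn(
                    f"trial {t_idx} of {label!r} extends past the run end; "
                    "truncated", RuntimeWarning)
            box = _boxcar(onset, duration, n_time, design.tr)
            if trialwise:
                reg = hrf_convolve(box, design.tr)
                if np.abs(reg).max() == 0:
                    warnings.warn(
                        f"trial {t_idx} of {label!r} produced an empty "
                        "regressor; dropped", RuntimeWarning)
                    continue
                task_cols.append(reg)
                task_names.append(f"{label}_trial{t_idx}")
            else:
                per_condition += box
        if not trialwise:
            reg = hrf_convolve(per_condition, design.tr)
            if np.abs(reg).max() > 0:
                task_cols.append(reg)
                task_names.append(label)
            else:
                warnings.warn(f"condition {label!r} produced an empty "
                              "regressor; dropped", RuntimeWarning)

    cols = [np.ones(n_time)]
    names = ["intercept"]
    if drift:
        cols.append(np.linspace(-0.5, 0.5, n_time))
        names.append("drift")
    cols.extend(task_cols)
    names.extend(task_names)
    return DesignMatrix(columns=np.column_stack(cols), names=names,
                        tr=design.tr)


def _drop_collinear(columns: np.ndarray, names: list[str],
                    tol: float = 1e-10) -> tuple[np.ndarray, list[str]]:
    """Remove columns that are numerically linear combinations of earlier ones."""
    _, r, piv = sp_linalg.qr(columns, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * diag.max()).sum())
    if rank == columns.shape[1]:
        return columns, names
    keep = np.sort(piv[:rank])
    dropped = [names[i] for i in piv[rank:]]
    warnings.warn(f"design is rank-deficient; dropped collinear column(s): "
                  f"{dropped}", RuntimeWarning)
    return columns[:, keep], [names[i] for i in keep]


def regress_out(data: RoiTimeSeries, dm: DesignMatrix) -> RoiTimeSeries:
    """Column-wise OLS residuals of the data against the design matrix."""
    if dm.n_time != data.n_time:
        raise ValidationError(
            f"design has {dm.n_time} rows but data has {data.n_time}")
    if abs(dm.tr - data.tr) > 1e-9:
        raise ValidationError("design TR does not match data TR")
    cols, _ = _drop_collinear(dm.columns, list(dm.names))
    coef, *_ = np.linalg.lstsq(cols, data.values, rcond=None)
    residuals = data.values - cols @ coef
    return data.copy_with(residuals)
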