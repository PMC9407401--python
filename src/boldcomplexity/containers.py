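"""Shared in-memory containers for parcellated fMRI analysis.

The pipeline operates on three plain-text-backed objects: an ROI time-series
matrix (time × region, with its repetition time), a structural connectome
(symmetric non-negative region × region weight matrix), and a task design
(condition-labelled trial onsets/durations in seconds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ValidationError


def _default_labels(n: int, prefix: str = "roi") -> list[str]:
    width = len(str(max(n - 1, 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


@dataclass
class RoiTimeSeries:
    """Parcellated BOLD data: one column per region of interest.

    Parameters
    ----------
    values : (n_time, n_roi) float array
        Mean BOLD signal per ROI at each volume.
    tr : float
        Repetition time in seconds (volume sampling interval).
    roi_labels : sequence of str, optional
        Unique region labels; auto-generated when omitted.
    """

    values: np.ndarray
    tr: float
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D (time × ROI) array")
        if not np.isfinite(self.values).all():
            raise ValidationError("values contain non-finite entries")
        if self.tr <= 0:
            raise ValidationError(f"tr must be positive, got {self.tr}")
        if not self.roi_labels:
            self.roi_labels = _default_labels(self.n_roi)
        self.roi_labels = [str(l) for l in self.roi_labels]
        if len(self.roi_labels) != self.n_roi:
            raise ValidationError(
                f"{len(self.roi_labels)} labels for {self.n_roi} ROIs"
            )
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValidationError("roi_labels must be unique")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_roi(self) -> int:
        return self.values.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each volume in seconds."""
        return np.arange(self.n_time) * self.tr

    def copy_with(self, values: np.ndarray) -> "RoiTimeSeries":
        """New object with the same TR/labels but different values."""
        return RoiTimeSeries(values=np.array(values, dtype=float),
                             tr=self.tr, roi_labels=list(self.roi_labels))


@dataclass
class StructuralConnectome:
    """Symmetric non-negative anatomical weight matrix with zero diagonal."""

    weights: np.ndarray
    roi_labels: list[str] = field(default_factory=list)

    _SYM_TOL = 1e-10

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError("weights must be a square matrix")
        if not np.isfinite(w).all():
            raise ValidationError("weights contain non-finite entries")
        if np.abs(w - w.T).max(initial=0.0) > self._SYM_TOL:
            raise ValidationError("weights must be symmetric to 1e-10")
        if (w < 0).any():
            raise ValidationError("weights must be non-negative")
        if np.abs(np.diag(w)).max(initial=0.0) > 0:
            raise ValidationError("diagonal must be zero")
        self.weights = (w + w.T) / 2.0
        if not self.roi_labels:
            self.roi_labels = _default_labels(self.n_roi)
        self.roi_labels = [str(l) for l in self.roi_labels]
        if len(self.roi_labels) != self.n_roi:
            raise ValidationError("label count does not match matrix size")

    @property
    def n_roi(self) -> int:
        return self.weights.shape[0]

    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def is_connected(self) -> bool:
        from scipy.sparse import csgraph

        n_comp, _ = csgraph.connected_components(self.weights, directed=False)
        return int(n_comp) == 1


Trial = tuple[float, float]  # (onset seconds, duration seconds)


@dataclass
class TaskDesign:
    """Block/event task timing: per-condition trial onsets and durations."""

    tr: float
    n_time: int
    conditions: list[tuple[str, list[Trial]]]

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValidationError("tr must be positive")
        if self.n_time < 1:
            raise ValidationError("n_time must be positive")
        labels = [label for label, _ in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValidationError("condition labels must be unique")
        run_end = self.n_time * self.tr
        for label, trials in self.conditions:
            for onset, duration in trials:
                if onset < 0:
                    raise ValidationError(
                        f"negative onset {onset} in condition {label!r}")
                if duration <= 0:
                    raise ValidationError(
                        f"non-positive duration {duration} in {label!r}")
                if onset + duration > run_end + 1e-9:
                    raise ValidationError(
                        f"trial ({onset}, {duration}) in {label!r} extends "
                        f"past run end {run_end:.3f}s")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_trials(self) -> int:
        return sum(len(trials) for _, trials in self.conditions)

    def to_dict(self) -> dict:
        return {
            "tr": self.tr,
            "n_time": self.n_time,
            "conditions": [
                {"label": label, "trials": [[float(o), float(d)] for o, d in trials]}
                for label, trials in self.conditions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskDesign":
        return cls(
            tr=float(d["tr"]),
            n_time=int(d["n_time"]),
            conditions=[
                (c["label"], [(float(o), float(dur)) for o, dur in c["trials"]])
                for c in d["conditions"]
            ],
        )
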