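"""Group-level detection testing of complexity maps.

Each subject's per-ROI statistic (complexity index by default) is compared
against its surrogate null with a one-sided empirical p-value; thresholding
at alpha_subj gives a binary detection map per subject. At the group level
the number of detections per ROI is tested against Binomial(n_subj,
alpha_subj): an ROI is suprathreshold when its detection count reaches the
smallest n whose exact upper-tail probability is below alpha_group divided
by the number of comparisons (Bonferroni). With 100 subjects, alpha_subj =
0.01, alpha_group = 0.001 and 360 × 6 comparisons this threshold is 10
detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError


def empirical_pvalues(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """One-sided (high statistic) add-one empirical p-values per ROI.

    p = (1 + #{null ≥ observed}) / (1 + n_surr); the add-one form guarantees
    validity (p is never 0) and means a detection at alpha ≤ 1/(n_surr+1)
    requires the observed statistic to exceed every surrogate. Ties count
    against significance. NaN null entries are ignored per ROI; a NaN
    observation yields p = 1.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    null = np.asarray(null, dtype=float)
    if null.ndim != 2:
        raise ValidationError("null must be n_surr × n_roi")
    n_surr, n_roi = null.shape
    if n_surr == 0:
        raise ValidationError("n_surr must be ≥ 1")
    if n_roi != observed.size:
        raise ValidationError("null ROI count does not match observed")
    pvals = np.ones(observed.size)
    for j in range(observed.size):
        if not np.isfinite(observed[j]):
            continue
        nj = null[:, j]
        nj = nj[np.isfinite(nj)]
        exceed = int((nj >= observed[j]).sum())
        # undefined surrogate statistics count against significance too:
        # the denominator keeps the full ensemble size
        exceed += int(np.isnan(null[:, j]).sum())
        pvals[j] = (1 + exceed) / (1 + n_surr)
    return pvals


def binomial_threshold(n_subj: int, alpha_subj: float, alpha_group: float,
                       n_comparisons: int = 1) -> int:
    """Smallest detection count n with P(X ≥ n) ≤ alpha_group/n_comparisons.

    X ~ Binomial(n_subj, alpha_subj); the upper tail is evaluated by exact
    summation of the probability mass function.
    """
    if n_subj < 1:
        raise ValidationError("n_subj must be ≥ 1")
    if not 0 < alpha_subj < 1:
        raise ValidationError("alpha_subj must be in (0,1)")
    if not 0 < alpha_group <= 1:
        raise ValidationError("alpha_group must be in (0,1]")
    if n_comparisons < 1:
        raise ValidationError("n_comparisons must be ≥ 1")
    corrected = alpha_group / n_comparisons
    pmf = stats.binom.pmf(np.arange(n_subj + 1), n_subj, alpha_subj)
    # exact upper-tail sums P(X ≥ n), accumulated from the top
    upper_tail = np.cumsum(pmf[::-1])[::-1]
    meets = np.flatnonzero(upper_tail <= corrected)
    meets = meets[meets >= 1]
    if meets.size == 0:
        raise ValidationError(
            f"no detection count ≤ {n_subj} reaches corrected level "
            f"{corrected:.3g}")
    return int(meets[0])


@dataclass
class GroupDetectionMap:
    """Per-ROI detection counts, binomial p-values and suprathreshold flags."""

    roi_labels: list[str]
    detection_count: np.ndarray
    n_subj: int
    threshold_n: int
    alpha_subj: float
    alpha_group: float
    n_comparisons: int
    binomial_p: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.detection_count = np.asarray(self.detection_count, dtype=int)
        if self.detection_count.min(initial=0) < 0 or \
                self.detection_count.max(initial=0) > self.n_subj:
            raise ValidationError("detection counts out of [0, n_subj]")
        if not 1 <= self.threshold_n <= self.n_subj:
            raise ValidationError("threshold_n must be in [1, n_subj]")
        if self.binomial_p is None:
            pmf = stats.binom.pmf(np.arange(self.n_subj + 1),
                                  self.n_subj, self.alpha_subj)
            upper = np.cumsum(pmf[::-1])[::-1]
            self.binomial_p = upper[self.detection_count]

    @property
    def suprathreshold(self) -> np.ndarray:
        return self.detection_count >= self.threshold_n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi": self.roi_labels,
            "detections": self.detection_count,
            "binomial_p": self.binomial_p,
            "suprathreshold": self.suprathreshold.astype(int),
        })


def threshold_subject(observed: np.ndarray, null: np.ndarray,
                      alpha_subj: float) -> np.ndarray:
    """Binary subject map: empirical p ≤ alpha_subj per ROI."""
    return empirical_pvalues(observed, null) <= alpha_subj


def group_map(subject_maps: np.ndarray | Sequence[np.ndarray],
              alpha_subj: float, alpha_group: float,
              n_comparisons: int = 1,
              roi_labels: Sequence[str] | None = None) -> GroupDetectionMap:
    """Binomial group test on stacked binary subject maps (n_subj × n_roi)."""
    maps = np.asarray(subject_maps)
    if maps.ndim != 2:
        raise ValidationError("subject_maps must be n_subj × n_roi")
    if not np.isin(maps, [0, 1]).all():
        raise ValidationError("subject maps must be binary")
    n_subj, n_roi = maps.shape
    counts = maps.sum(axis=0).astype(int)
    thr = binomial_threshold(n_subj, alpha_subj, alpha_group, n_comparisons)
    labels = (list(roi_labels) if roi_labels is not None
              else [f"roi{j}" for j in range(n_roi)])
    if len(labels) != n_roi:
        raise ValidationError("label count does not match map width")
    return GroupDetectionMap(
        roi_labels=labels, detection_count=counts, n_subj=n_subj,
        threshold_n=thr, alpha_subj=alpha_subj, alpha_group=alpha_group,
        n_comparisons=n_comparisons)


def rsn_percentages(detection: GroupDetectionMap,
                    partition: dict[str, str],
                    denominator: str = "network") -> pd.DataFrame:
    """Percentage of suprathreshold ROIs per network.

    ``denominator="network"`` (default) normalises by each network's ROI
    count; ``"total"`` normalises by the whole-brain ROI count. Networks in
    the partition with no ROIs present are omitted with a warning.
    """
    if denominator not in ("network", "total"):
        raise ValidationError("denominator must be 'network' or 'total'")
    missing = [l for l in detection.roi_labels if l not in partition]
    if missing:
        raise ValidationError(
            f"{len(missing)} ROI labels missing from partition")
    df = pd.DataFrame({
        "network": [partition[l] for l in detection.roi_labels],
        "supra": detection.suprathreshold.astype(int),
    })
    grouped = df.groupby("network")["supra"].agg(["sum", "count"])
    empty = set(partition.values()) - set(grouped.index)
    if empty:
        warnings.warn(f"network(s) with no ROIs omitted: {sorted(empty)}",
                      RuntimeWarning)
    denom = grouped["count"] if denominator == "network" else len(df)
    out = pd.DataFrame({
        "network": grouped.index,
        "n_roi": grouped["count"].astype(int).values,
        "n_suprathreshold": grouped["sum"].astype(int).values,
        "percent": (100.0 * grouped["sum"] / denom).values,
    }).reset_index(drop=True)
    return out
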