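"""Per-ROI temporal-complexity estimation.

Three estimators characterise how far a BOLD time series sits from white
noise on the order–disorder axis:

* the Hurst exponent H from detrended fluctuation analysis (DFA) — the
  slope of log RMS fluctuation of the mean-centred cumulative profile vs
  log window size; H = 0.5 for memoryless noise, H > 0.5 for persistent,
  long-memory dynamics;
* the spectral exponent β from a log-log least-squares fit to the Welch
  power spectral density inside a low-frequency band (default 0.01–0.2 Hz);
  for fractional Brownian motion β = 2H + 1;
* the multiscale-entropy (MSE) curve — sample entropy of successively
  coarse-grained copies of the signal — summarised by its area under the
  curve, the complexity index (CI). White noise starts high and decays
  rapidly with scale (small CI); 1/f-like signals stay flat or rise
  (larger CI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal as sp_signal

from .containers import RoiTimeSeries
from .exceptions import DegenerateSeriesError, ValidationError

DEFAULT_BAND = (0.01, 0.2)  # Hz
DEFAULT_SCALES = tuple(range(1, 11))
DEFAULT_M = 2
DEFAULT_R_FRAC = 0.15
MIN_COARSE_LENGTH_FACTOR = 10  # coarse series must keep ≥ 10·(m+1) samples


# ---------------------------------------------------------------------------
# DFA
# ---------------------------------------------------------------------------

def dfa_window_sizes(n: int, window_range: Optional[tuple[int, int]] = None,
                     n_windows: int = 15) -> np.ndarray:
    """Log-spaced, de-duplicated integer window sizes (default 10 .. n/4)."""
    lo, hi = window_range if window_range is not None else (10, n // 4)
    if lo < 4:
        raise ValidationError("minimum window size must be ≥ 4")
    if hi > n // 4:
        raise ValidationError(f"window_max {hi} exceeds n/4 = {n // 4}")
    if n < 4 * lo:
        raise ValidationError(f"series length {n} < 4·window_min {4 * lo}")
    sizes = np.unique(np.round(
        np.logspace(np.log10(lo), np.log10(hi), n_windows)).astype(int))
    return sizes


def _dfa_fluctuations(columns: np.ndarray, sizes: np.ndarray,
                      detrend_order: int) -> np.ndarray:
    """F(s) per column for an (n_time × n_col) matrix; one fit per size."""
    n, p = columns.shape
    profile = np.cumsum(columns - columns.mean(axis=0), axis=0)
    fluct = np.empty((len(sizes), p))
    for idx, s in enumerate(sizes):
        k = n // s
        # (s, k·p): every window of every column as one projection RHS
        segments = profile[: k * s].reshape(k, s, p).transpose(1, 0, 2)
        segments = segments.reshape(s, k * p)
        # polynomial basis on t scaled to [-1, 1] keeps the normal
        # equations well conditioned at every window size
        t = np.linspace(-1.0, 1.0, s)
        design = np.vander(t, detrend_order + 1)
        resid = segments - design @ (np.linalg.pinv(design) @ segments)
        fluct[idx] = np.sqrt((resid**2).reshape(s, k, p).mean(axis=(0, 1)))
    return fluct


def dfa_hurst_batch(
    values: np.ndarray,
    window_range: Optional[tuple[int, int]] = None,
    n_windows: int = 15,
    detrend_order: int = 1,
) -> np.ndarray:
    """DFA Hurst exponent of every column of an (n_time × n_col) matrix.

    Same estimator as :func:`dfa_hurst`, vectorised across columns (all
    windows of one size are solved in a single least-squares call), which is
    what makes surrogate-ensemble nulls affordable. Columns with zero
    fluctuation at any window size yield NaN instead of raising.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("values must be 2-D (time × columns)")
    n = values.shape[0]
    sizes = dfa_window_sizes(n, window_range, n_windows)
    fluct = _dfa_fluctuations(values, sizes, detrend_order)
    hurst = np.full(values.shape[1], np.nan)
    ok = (fluct > 0).all(axis=0)
    if ok.any():
        log_s = np.log10(sizes)
        design = np.column_stack([log_s, np.ones_like(log_s)])
        coef, *_ = np.linalg.lstsq(design, np.log10(fluct[:, ok]), rcond=None)
        hurst[ok] = coef[0]
    return hurst


def dfa_hurst(
    series: np.ndarray,
    window_range: Optional[tuple[int, int]] = None,
    n_windows: int = 15,
    detrend_order: int = 1,
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Hurst exponent by detrended fluctuation analysis.

    The mean-centred series is integrated into a profile; in non-overlapping
    windows of each (log-spaced) size s an order-``detrend_order`` polynomial
    is removed and the pooled RMS residual F(s) recorded; H is the
    least-squares slope of log10 F(s) against log10 s.

    Returns ``(H, (sizes, F))`` so the fluctuation curve can be inspected.

    Raises :class:`DegenerateSeriesError` when the series has no fluctuation
    about an order-``detrend_order`` trend (e.g. a constant, or a pure ramp
    at order 1): no scaling exponent exists for such input.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    sizes = dfa_window_sizes(n, window_range, n_windows)

    # reject series that are exactly a low-order polynomial: zero fluctuation
    t = np.arange(n, dtype=float)
    trend_coef = np.polynomial.polynomial.polyfit(t, x, detrend_order)
    resid_global = x - np.polynomial.polynomial.polyval(t, trend_coef)
    scale = max(np.abs(x).max(), 1.0)
    if np.sqrt(np.mean(resid_global**2)) < 1e-12 * scale:
        raise DegenerateSeriesError(
            f"series is an order-{detrend_order} polynomial; "
            "no detrended fluctuation")

    fluctuations = _dfa_fluctuations(x[:, None], sizes, detrend_order)[:, 0]
    if not (fluctuations > 0).all():
        raise DegenerateSeriesError("zero fluctuation at some window size")
    slope, _ = np.polyfit(np.log10(sizes), np.log10(fluctuations), 1)
    return float(slope), (sizes, fluctuations)


# ---------------------------------------------------------------------------
# spectral exponent
# ---------------------------------------------------------------------------

def welch_psd(
    series: np.ndarray,
    tr: float,
    normalize: bool = False,
    detrend: str = "linear",
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density (Hann window, 50% overlap).

    Segment length is min(n, 128). Per-segment linear detrending is the
    default: BOLD-like 1/f^β signals with β near or above 2 are effectively
    nonstationary over a segment, and removing the segment drift keeps the
    low-frequency log-log slope unbiased (mean-only detrending inflates β
    by up to ≈0.3 at β ≈ 2.7). With ``normalize`` the power is divided by
    its maximum so curves from different runs are comparable on one plot.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 32:
        raise ValidationError(f"need ≥ 32 samples for Welch PSD, got {x.size}")
    if tr <= 0:
        raise ValidationError("tr must be positive")
    nperseg = min(x.size, 128)
    freqs, power = sp_signal.welch(
        x, fs=1.0 / tr, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend=detrend)
    if normalize:
        peak = power.max()
        if peak > 0:
            power = power / peak
    return freqs, power


def spectral_exponent(
    frequencies: np.ndarray,
    power: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
) -> float:
    """β = negated slope of the log10-log10 PSD inside ``band``.

    Zero-power bins are dropped before fitting; at least 5 positive bins
    must remain inside the band.
    """
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(power, dtype=float)
    lo, hi = band
    mask = (f >= lo) & (f <= hi) & (f > 0)
    if mask.sum() < 5:
        raise ValidationError(
            f"only {int(mask.sum())} frequency bins inside band {band}")
    f, p = f[mask], p[mask]
    positive = p > 0
    if positive.sum() < 5:
        raise ValidationError("fewer than 5 positive-power bins in band")
    slope, _ = np.polyfit(np.log10(f[positive]), np.log10(p[positive]), 1)
    return float(-slope)


# ---------------------------------------------------------------------------
# sample entropy / multiscale entropy
# ---------------------------------------------------------------------------

@njit(cache=True)
def _count_template_matches(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Unordered template-pair counts (A: length m+1, B: length m).

    Richman–Moorman convention: both counts range over the first n−m
    template start points; matches use the Chebyshev norm with a strict
    ``< r`` criterion; self-pairs are excluded.
    """
    n = x.shape[0]
    n_templates = n - m
    a = 0
    b = 0
    for i in range(n_templates - 1):
        for j in range(i + 1, n_templates):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) >= r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) < r:
                    a += 1
    return a, b


def sample_entropy(series: np.ndarray, m: int = DEFAULT_M,
                   r_abs: float = 0.0) -> float:
    """Sample entropy −ln(A/B) in nats with absolute tolerance ``r_abs``.

    A and B count template pairs (excluding self-matches) of lengths m+1 and
    m whose Chebyshev distance is strictly below ``r_abs``. When either
    count is zero the entropy is undefined and NaN is returned (callers
    record the undefined marker rather than raising).
    """
    x = np.ascontiguousarray(series, dtype=float).ravel()
    if m < 1:
        raise ValidationError("m must be ≥ 1")
    if x.size <= m + 1:
        raise ValidationError(f"series length {x.size} must exceed m+1 = {m + 1}")
    if r_abs <= 0:
        raise ValidationError("r_abs must be positive")
    a, b = _count_template_matches(x, m, r_abs)
    if a == 0 or b == 0:
        return math.nan
    return float(-math.log(a / b))


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block means of length ``tau`` (tail dropped)."""
    x = np.asarray(series, dtype=float).ravel()
    if tau < 1:
        raise ValidationError("tau must be ≥ 1")
    if tau == 1:
        return x.copy()
    n_blocks = x.size // tau
    if n_blocks < 1:
        raise ValidationError(f"series too short to coarse-grain at tau={tau}")
    return x[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


@dataclass
class MseCurve:
    """Multiscale-entropy curve with per-scale undefined markers.

    ``entropy[i]`` is the sample entropy of the scale-``scales[i]``
    coarse-grained series; NaN where undefined (no template matches or the
    coarse series fell below the minimum-length floor). ``defined`` mirrors
    this as a boolean mask. The tolerance r is a fraction of the original
    (un-coarsened) series SD and is held fixed across scales.
    """

    scales: np.ndarray
    entropy: np.ndarray
    m: int
    r_frac: float
    r_abs: float

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=int)
        self.entropy = np.asarray(self.entropy, dtype=float)
        if self.scales.ndim != 1 or self.scales.shape != self.entropy.shape:
            raise ValidationError("scales and entropy must be 1-D, same length")
        if (np.diff(self.scales) <= 0).any():
            raise ValidationError("scales must be strictly increasing")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.entropy)


def mse_curve(
    series: np.ndarray,
    scales: Sequence[int] = DEFAULT_SCALES,
    m: int = DEFAULT_M,
    r_frac: float = DEFAULT_R_FRAC,
) -> MseCurve:
    """Multiscale entropy with tolerance fixed from the original series SD."""
    x = np.asarray(series, dtype=float).ravel()
    scales = np.asarray(list(scales), dtype=int)
    if scales.size == 0 or scales[0] < 1:
        raise ValidationError("scales must start at ≥ 1")
    if r_frac <= 0:
        raise ValidationError("r_frac must be positive")
    sd = x.std()
    if sd == 0:
        # constant signal: every template matches at every scale → entropy 0
        return MseCurve(scales=scales, entropy=np.zeros(scales.size),
                        m=m, r_frac=r_frac, r_abs=0.0)
    r_abs = r_frac * sd
    min_len = MIN_COARSE_LENGTH_FACTOR * (m + 1)
    entropy = np.full(scales.size, np.nan)
    for idx, tau in enumerate(scales):
        coarse = coarse_grain(x, int(tau))
        if coarse.size < min_len:
            continue  # undefined at this scale
        entropy[idx] = sample_entropy(coarse, m=m, r_abs=r_abs)
    return MseCurve(scales=scales, entropy=entropy, m=m,
                    r_frac=r_frac, r_abs=r_abs)


def complexity_index(curve: MseCurve) -> float:
    """Trapezoidal area under the leading defined run of the MSE curve.

    Integration is over scale index; NaN when fewer than two leading scales
    are defined (an undefined scale truncates the integration range rather
    than being silently skipped).
    """
    defined = curve.defined
    n_lead = int(np.argmin(defined)) if not defined.all() else defined.size
    if n_lead < 2:
        return math.nan
    return float(np.trapezoid(curve.entropy[:n_lead], curve.scales[:n_lead]))


# ---------------------------------------------------------------------------
# whole-map estimation and summaries
# ---------------------------------------------------------------------------

@dataclass
class ComplexityMap:
    """Per-ROI complexity estimates plus the parameters that produced them."""

    roi_labels: list[str]
    hurst: np.ndarray
    spectral_exponent: np.ndarray
    complexity_index: np.ndarray
    mse: list[MseCurve]
    metadata: dict = field(default_factory=dict)

    H_RANGE = (0.0, 1.5)

    @property
    def n_roi(self) -> int:
        return len(self.roi_labels)

    def out_of_range_hurst(self) -> np.ndarray:
        lo, hi = self.H_RANGE
        return (self.hurst < lo) | (self.hurst > hi) | ~np.isfinite(self.hurst)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi": self.roi_labels,
            "hurst": self.hurst,
            "beta": self.spectral_exponent,
            "complexity_index": self.complexity_index,
        })

    def mse_frame(self) -> pd.DataFrame:
        rows = []
        for label, curve in zip(self.roi_labels, self.mse):
            for tau, h in zip(curve.scales, curve.entropy):
                rows.append({"roi": label, "scale": int(tau), "entropy": h})
        return pd.DataFrame(rows)


def complexity_map(
    data: RoiTimeSeries,
    window_range: Optional[tuple[int, int]] = None,
    n_windows: int = 15,
    detrend_order: int = 1,
    band: tuple[float, float] = DEFAULT_BAND,
    scales: Sequence[int] = DEFAULT_SCALES,
    m: int = DEFAULT_M,
    r_frac: float = DEFAULT_R_FRAC,
) -> ComplexityMap:
    """Column-wise H, β and MSE/CI for every ROI of a run."""
    if data.n_time < 64:
        raise ValidationError("need ≥ 64 volumes for complexity estimation")
    n = data.n_roi
    hurst = np.full(n, np.nan)
    beta = np.full(n, np.nan)
    ci = np.full(n, np.nan)
    curves: list[MseCurve] = []
    for j in range(n):
        col = data.values[:, j]
        try:
            hurst[j], _ = dfa_hurst(col, window_range, n_windows, detrend_order)
        except DegenerateSeriesError:
            pass
        try:
            freqs, power = welch_psd(col, data.tr)
            beta[j] = spectral_exponent(freqs, power, band)
        except ValidationError:
            pass
        curve = mse_curve(col, scales=scales, m=m, r_frac=r_frac)
        curves.append(curve)
        ci[j] = complexity_index(curve)
    meta = {
        "tr": data.tr,
        "n_time": data.n_time,
        "dfa": {"window_range": list(window_range) if window_range else
                [10, data.n_time // 4],
                "n_windows": n_windows, "detrend_order": detrend_order},
        "psd_band_hz": list(band),
        "mse": {"scales": [int(s) for s in scales], "m": m, "r_frac": r_frac},
    }
    return ComplexityMap(roi_labels=list(data.roi_labels), hurst=hurst,
                         spectral_exponent=beta, complexity_index=ci,
                         mse=curves, metadata=meta)


def map_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation across ROIs, pairwise-complete over NaNs."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValidationError("maps must have the same length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValidationError("fewer than 3 complete ROI pairs")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def rsn_summary(values: np.ndarray, roi_labels: Sequence[str],
                partition: dict[str, str]) -> pd.DataFrame:
    """Per-network mean and SD of an ROI map.

    ``partition`` maps ROI label → network label; networks with no ROIs in
    the map are simply absent from the output.
    """
    values = np.asarray(values, dtype=float).ravel()
    if len(roi_labels) != values.size:
        raise ValidationError("label count does not match value count")
    missing = [l for l in roi_labels if l not in partition]
    if missing:
        raise ValidationError(
            f"{len(missing)} ROI labels missing from partition "
            f"(first: {missing[0]!r})")
    df = pd.DataFrame({
        "network": [partition[l] for l in roi_labels],
        "value": values,
    })
    out = (df.groupby("network")["value"].agg(["mean", "std", "count"])
             .reset_index()
             .rename(columns={"count": "n_roi"}))
    out["n_roi"] = out["n_roi"].astype(int)
    return out
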