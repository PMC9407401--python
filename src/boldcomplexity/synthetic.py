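"""Synthetic scale-free BOLD, connectomes and populations.

Everything downstream of this module is testable without real data: the
generators produce (i) exact fractional Gaussian noise (fGn) of known Hurst
exponent via circulant embedding, (ii) power-law (coloured) noise of known
spectral exponent, (iii) distance-decay random connectomes, and (iv)
multi-ROI, multi-subject BOLD whose functional connectivity is coupled to a
structural connectome by heat-kernel graph smoothing, with optional
HRF-convolved task blocks.

Defaults emulate the study conditions this pipeline targets: runs of a few
hundred volumes at TR = 0.72 s, regional Hurst exponents in roughly
0.5–0.9, and 100-subject populations with between-subject variability.

Seeding scheme
--------------
All generators accept either an integer or a sequence of integers, fed to
``numpy.random.default_rng``. Composite structures derive child seeds by
appending counters to the master seed: subject ``i`` of a population uses
``(master_seed, i)``; within a subject, ``(seed, 0)`` draws the Hurst
jitter and ``(seed, 1, roi_index)`` drives each ROI's fGn. Any subject or
ROI stream is therefore regenerable in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csgraph
from scipy.spatial.distance import pdist, squareform

from .containers import RoiTimeSeries, StructuralConnectome, TaskDesign
from .exceptions import SimulationError, ValidationError
from .hrf import hrf_convolve

SeedLike = int | Sequence[int] | None

DEFAULT_TR = 0.72          # seconds
DEFAULT_DECAY_LENGTH = 0.3  # distance-decay scale in the unit cube
DEFAULT_EDGE_NOISE_SD = 0.5  # lognormal sigma on edge weights
_HURST_CLIP = (0.05, 0.95)


def _seed_tuple(seed: SeedLike) -> tuple[int, ...]:
    if seed is None:
        raise ValidationError("an explicit seed is required for reproducibility")
    if np.isscalar(seed):
        return (int(seed),)
    return tuple(int(s) for s in seed)


def _rng(seed: SeedLike, *counters: int) -> np.random.Generator:
    return np.random.default_rng(_seed_tuple(seed) + tuple(counters))


# ---------------------------------------------------------------------------
# univariate scale-free signals
# ---------------------------------------------------------------------------

def fgn_autocovariance(h: float, max_lag: int) -> np.ndarray:
    """Autocovariance γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}), k=0..max_lag."""
    k = np.arange(max_lag + 1, dtype=float)
    two_h = 2.0 * h
    return 0.5 * (np.abs(k + 1) ** two_h - 2 * np.abs(k) ** two_h
                  + np.abs(k - 1) ** two_h)


def gen_fgn(h: float, n: int, seed: SeedLike) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding.

    Stationary, unit-variance, with the fGn autocovariance for Hurst
    exponent ``h``. The circulant embedding of the fGn covariance is
    non-negative definite for all h in (0,1); should a pathological
    combination still break it numerically, the generator falls back to
    spectral synthesis at the equivalent exponent β = 2H − 1 with a warning.
    """
    if not 0.0 < h < 1.0:
        raise ValidationError(f"h must be in (0,1), got {h}")
    if n < 16:
        raise ValidationError(f"n must be ≥ 16, got {n}")

    gamma = fgn_autocovariance(h, n)
    first_row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    lam = np.fft.fft(first_row).real
    if lam.min() < -1e-8 * lam.max():
        warnings.warn(
            "circulant embedding not non-negative definite; "
            "falling back to spectral synthesis", RuntimeWarning)
        return gen_colored_noise(max(2 * h - 1, 0.0), n, seed)
    lam = np.clip(lam, 0.0, None)

    m = 2 * n
    rng = _rng(seed)
    z = rng.standard_normal(m)
    w = np.empty(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * z[0]
    w[n] = np.sqrt(lam[n] / m) * z[1]
    u = z[2: n + 1]
    v = z[n + 1: 2 * n]
    scale = np.sqrt(lam[1:n] / (2 * m))
    w[1:n] = scale * (u + 1j * v)
    w[n + 1:] = np.conj(w[n - 1:0:-1])
    x = np.fft.fft(w).real[:n]
    return x


def gen_fbm(h: float, n: int, seed: SeedLike) -> np.ndarray:
    """Fractional Brownian motion: zero-anchored cumulative sum of fGn.

    Returns a length-``n`` path starting at exactly 0 whose increments
    ``np.diff`` reproduce ``gen_fgn(h, n - 1, seed)`` bit-for-bit.
    """
    if n < 17:
        raise ValidationError(f"n must be ≥ 17, got {n}")
    increments = gen_fgn(h, n - 1, seed)
    return np.concatenate([[0.0], np.cumsum(increments)])


def gen_colored_noise(beta: float, n: int, seed: SeedLike) -> np.ndarray:
    """Gaussian 1/f^β noise by spectral synthesis, standardised.

    I.i.d. complex-Gaussian Fourier coefficients are scaled by f^{−β/2}
    (zero-frequency term set to 0), inverse-transformed, and standardised
    to zero mean / unit SD. β = 0 gives white noise, β = 1 pink, β = 2
    brown-like.
    """
    if beta < 0:
        raise ValidationError(f"beta must be ≥ 0, got {beta}")
    if n < 16:
        raise ValidationError(f"n must be ≥ 16, got {n}")
    rng = _rng(seed)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    n_half = len(freqs)
    coeff = amp * (rng.standard_normal(n_half) + 1j * rng.standard_normal(n_half))
    coeff[0] = 0.0
    if n % 2 == 0:
        coeff[-1] = coeff[-1].real
    x = np.fft.irfft(coeff, n=n)
    sd = x.std()
    if sd == 0:
        raise SimulationError("degenerate spectral synthesis (zero variance)")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# connectomes
# ---------------------------------------------------------------------------

def gen_connectome(
    n_roi: int,
    density: float,
    seed: SeedLike,
    decay_length: float = DEFAULT_DECAY_LENGTH,
    edge_noise_sd: float = DEFAULT_EDGE_NOISE_SD,
) -> StructuralConnectome:
    """Distance-decay random connectome on points in the unit cube.

    ROIs are placed uniformly at random in [0,1]³; candidate weights are
    exp(−distance/decay_length) with multiplicative lognormal noise; the
    strongest edges are kept to reach the target density; the graph is
    symmetrised with zero diagonal. If thresholding disconnects the graph,
    the strongest discarded edges bridging distinct components are restored
    (with a warning), so the result is always connected.
    """
    if n_roi < 2:
        raise ValidationError("n_roi must be ≥ 2")
    if not 0.0 < density <= 1.0:
        raise ValidationError(f"density must be in (0,1], got {density}")
    rng = _rng(seed)
    points = rng.uniform(0.0, 1.0, size=(n_roi, 3))
    dist = pdist(points)
    noise = rng.lognormal(mean=0.0, sigma=edge_noise_sd, size=dist.shape)
    raw = np.exp(-dist / decay_length) * noise

    n_pairs = len(raw)
    n_keep = int(round(density * n_pairs))
    n_keep = max(n_keep, 1)
    order = np.argsort(raw)[::-1]
    keep = np.zeros(n_pairs, dtype=bool)
    keep[order[:n_keep]] = True

    weights = squareform(np.where(keep, raw, 0.0))
    n_comp, labels = csgraph.connected_components(weights, directed=False)
    n_bridges = 0
    while n_comp > 1:
        # strongest discarded edge joining two different components
        cand = squareform(np.where(keep, 0.0, raw))
        cross = labels[:, None] != labels[None, :]
        cand[~cross] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= 0:
            raise SimulationError("cannot bridge components (no cross edges)")
        weights[i, j] = weights[j, i] = cand[i, j]
        flat = squareform(weights) > 0
        keep = flat
        n_bridges += 1
        n_comp, labels = csgraph.connected_components(weights, directed=False)
    if n_bridges:
        warnings.warn(
            f"density {density} disconnected the graph; restored "
            f"{n_bridges} bridging edge(s)", RuntimeWarning)
    return StructuralConnectome(weights=weights)


# ---------------------------------------------------------------------------
# multi-ROI subjects and populations
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Study-design parameters for one synthetic cohort.

    ``hurst_map`` holds the population-level per-ROI Hurst targets; each
    subject jitters them by N(0, subject_sd²), clipped to (0.05, 0.95).
    ``coupling_strength`` is the diffusion time t of the heat-kernel graph
    smoothing exp(−t·L_norm) applied to every frame; 0 leaves ROIs
    independent. Task blocks (if any) are HRF-convolved boxcars scaled by
    ``task_amplitude`` (in SD units of the pre-standardised noise) and added
    to ``task_rois`` (default: every ROI).
    """

    n_roi: int
    n_time: int = 399
    tr: float = DEFAULT_TR
    hurst_map: Optional[np.ndarray] = None
    coupling_strength: float = 0.0
    task_design: Optional[TaskDesign] = None
    task_amplitude: float = 1.0
    task_rois: Optional[Sequence[int]] = None
    subject_sd: float = 0.05
    roi_amplitude_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roi < 1:
            raise ValidationError("n_roi must be ≥ 1")
        if self.n_time < 64:
            raise ValidationError("n_time must be ≥ 64")
        if self.tr <= 0:
            raise ValidationError("tr must be positive")
        if self.coupling_strength < 0:
            raise ValidationError("coupling_strength must be ≥ 0")
        if self.subject_sd < 0:
            raise ValidationError("subject_sd must be ≥ 0")
        if self.roi_amplitude_sd < 0:
            raise ValidationError("roi_amplitude_sd must be ≥ 0")
        if self.hurst_map is None:
            # default regional spread mirrors the 0.5–0.9 range of BOLD
            self.hurst_map = np.linspace(0.5, 0.9, self.n_roi)
        self.hurst_map = np.asarray(self.hurst_map, dtype=float)
        if self.hurst_map.shape != (self.n_roi,):
            raise ValidationError(
                f"hurst_map length {self.hurst_map.shape} != n_roi {self.n_roi}")
        if ((self.hurst_map <= 0) | (self.hurst_map >= 1)).any():
            raise ValidationError("all Hurst targets must lie in (0,1)")
        if self.task_design is not None:
            if self.task_design.n_time != self.n_time:
                raise ValidationError("task_design.n_time must match n_time")
            if abs(self.task_design.tr - self.tr) > 1e-9:
                raise ValidationError("task_design.tr must match tr")
        if self.task_rois is not None:
            rois = np.asarray(self.task_rois, dtype=int)
            if rois.size and (rois.min() < 0 or rois.max() >= self.n_roi):
                raise ValidationError("task_rois out of range")

    def to_dict(self) -> dict:
        return {
            "n_roi": self.n_roi,
            "n_time": self.n_time,
            "tr": self.tr,
            "hurst_map": [float(h) for h in self.hurst_map],
            "coupling_strength": self.coupling_strength,
            "task_design": (None if self.task_design is None
                            else self.task_design.to_dict()),
            "task_amplitude": self.task_amplitude,
            "task_rois": (None if self.task_rois is None
                          else [int(i) for i in self.task_rois]),
            "subject_sd": self.subject_sd,
            "roi_amplitude_sd": self.roi_amplitude_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if d.get("hurst_map") is not None:
            d["hurst_map"] = np.asarray(d["hurst_map"], dtype=float)
        if d.get("task_design") is not None:
            d["task_design"] = TaskDesign.from_dict(d["task_design"])
        return cls(**d)


def _diffusion_operator(connectome: StructuralConnectome, t: float) -> np.ndarray:
    """Heat kernel exp(−t·L_norm) of the symmetric normalised Laplacian."""
    from .surrogates import normalized_laplacian

    lap = normalized_laplacian(connectome)
    evals, evecs = np.linalg.eigh(lap)
    return (evecs * np.exp(-t * evals)) @ evecs.T


def task_regressor(design: TaskDesign, amplitude: float = 1.0) -> np.ndarray:
    """Summed HRF-convolved boxcar of every trial, sampled at TR."""
    frame_times = np.arange(design.n_time) * design.tr
    box = np.zeros(design.n_time)
    for _, trials in design.conditions:
        for onset, duration in trials:
            box += ((frame_times >= onset)
                    & (frame_times < onset + duration)).astype(float)
    return amplitude * hrf_convolve(box, design.tr)


def gen_subject(
    spec: SyntheticSpec,
    connectome: Optional[StructuralConnectome] = None,
    seed: SeedLike = None,
) -> RoiTimeSeries:
    """One subject's ROI time series under the given study design.

    Pipeline: per-ROI fGn with jittered Hurst targets → per-frame heat-kernel
    smoothing on the connectome (if coupling_strength > 0) → additive task
    component (if a design is present) → column standardisation.
    """
    if seed is None:
        seed = spec.seed
    if spec.coupling_strength > 0 and connectome is None:
        raise ValidationError("coupling_strength > 0 requires a connectome")
    if connectome is not None and connectome.n_roi != spec.n_roi:
        raise ValidationError("connectome size does not match n_roi")

    jitter_rng = _rng(seed, 0)
    h_subject = np.clip(
        spec.hurst_map + spec.subject_sd * jitter_rng.standard_normal(spec.n_roi),
        *_HURST_CLIP)

    x = np.empty((spec.n_time, spec.n_roi))
    base = _seed_tuple(seed)
    for i in range(spec.n_roi):
        x[:, i] = gen_fgn(h_subject[i], spec.n_time, base + (1, i))

    if spec.roi_amplitude_sd > 0:
        # regional variance heterogeneity: makes the spatial covariance
        # non-diagonal in the connectome-harmonic basis, so surrogate
        # sign-randomisation has functional connectivity to randomise
        amp_rng = _rng(seed, 2)
        x *= amp_rng.lognormal(0.0, spec.roi_amplitude_sd, spec.n_roi)

    if spec.coupling_strength > 0 and connectome is not None:
        kernel = _diffusion_operator(connectome, spec.coupling_strength)
        x = x @ kernel  # kernel is symmetric; smooths each time frame

    if spec.task_design is not None:
        evoked = task_regressor(spec.task_design, spec.task_amplitude)
        rois = (np.arange(spec.n_roi) if spec.task_rois is None
                else np.asarray(spec.task_rois, dtype=int))
        x[:, rois] += evoked[:, None]

    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x /= sd
    labels = (connectome.roi_labels if connectome is not None else None)
    return RoiTimeSeries(values=x, tr=spec.tr,
                         roi_labels=list(labels) if labels else [])


def gen_population(
    spec: SyntheticSpec,
    connectome: Optional[StructuralConnectome] = None,
    n_subj: int = 100,
    seed: SeedLike = None,
) -> list[RoiTimeSeries]:
    """Independent subjects; subject ``i`` is seeded by (master_seed, i)."""
    if n_subj < 0:
        raise ValidationError("n_subj must be ≥ 0")
    if seed is None:
        seed = spec.seed
    base = _seed_tuple(seed)
    return [gen_subject(spec, connectome, seed=base + (i,))
            for i in range(n_subj)]
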