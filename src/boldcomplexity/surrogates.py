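"""Connectome harmonics and sign-randomised graph surrogates.

The structural connectome's symmetric normalised Laplacian provides an
orthonormal basis of spatial harmonics. Projecting each fMRI frame onto the
harmonics (the graph Fourier transform, GFT) and flipping the sign of each
harmonic's coefficient by an i.i.d. Rademacher vector — one vector per
surrogate, constant over time — yields null datasets that

* (i) preserve the temporal Gram matrix X Xᵀ exactly (the flip operator
  U diag(s) Uᵀ is orthogonal), hence all second-order temporal statistics;
* (ii) randomise functional connectivity between ROIs;
* (iii) randomise where on the cortex scale-free dynamics live, per ROI;
* (iv) randomise the spatial pattern of pairwise scale-free coupling;

while keeping the per-harmonic graph spectral power untouched. Subject-level
complexity statistics are compared against the ensemble of surrogate
statistics to obtain empirical p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .complexity import MseCurve, complexity_index, mse_curve
from .complexity import DEFAULT_M, DEFAULT_R_FRAC, DEFAULT_SCALES
from .containers import RoiTimeSeries, StructuralConnectome
from .exceptions import ValidationError

_EIG_TOL = 1e-10


def normalized_laplacian(connectome: StructuralConnectome,
                         variant: str = "normalized") -> np.ndarray:
    """Graph Laplacian of the connectome.

    ``variant="normalized"`` (default): L = I − D^{−1/2} A D^{−1/2}, whose
    spectrum lies in [0, 2]. ``variant="combinatorial"``: L = D − A.
    Isolated nodes (zero degree) are rejected — they make the normalised
    form undefined and the graph basis meaningless for surrogate testing.
    """
    a = connectome.weights
    deg = connectome.degrees()
    if (deg <= 0).any():
        isolated = [connectome.roi_labels[i] for i in np.flatnonzero(deg <= 0)]
        raise ValidationError(f"isolated node(s): {isolated}")
    if variant == "combinatorial":
        return np.diag(deg) - a
    if variant != "normalized":
        raise ValidationError(f"unknown Laplacian variant {variant!r}")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = -a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    np.fill_diagonal(lap, 1.0)
    return (lap + lap.T) / 2.0


@dataclass
class GraphBasis:
    """Orthonormal Laplacian eigenbasis with a fixed sign/ordering convention.

    Columns of ``eigenvectors`` are the spatial harmonics, in ascending
    eigenvalue order. Each eigenvector's sign is fixed so its
    largest-magnitude entry is positive; within numerically degenerate
    eigenvalue groups columns are ordered lexicographically. The convention
    makes repeated decompositions of the same matrix identical.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    roi_labels: list[str] = field(default_factory=list)
    sign_convention: str = "largest-magnitude entry positive"

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        n = self.eigenvalues.size
        if self.eigenvectors.shape != (n, n):
            raise ValidationError("eigenvector matrix must be square n × n")
        if (np.diff(self.eigenvalues) < -_EIG_TOL).any():
            raise ValidationError("eigenvalues must be ascending")
        gram = self.eigenvectors.T @ self.eigenvectors
        if np.abs(gram - np.eye(n)).max() > 1e-8:
            raise ValidationError("eigenvectors are not orthonormal to 1e-8")

    @property
    def n_roi(self) -> int:
        return self.eigenvalues.size


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def graph_basis(laplacian: np.ndarray,
                roi_labels: Optional[Sequence[str]] = None) -> GraphBasis:
    """Deterministic eigendecomposition of a symmetric Laplacian."""
    lap = np.asarray(laplacian, dtype=float)
    if lap.ndim != 2 or lap.shape[0] != lap.shape[1]:
        raise ValidationError("Laplacian must be square")
    if np.abs(lap - lap.T).max() > 1e-10:
        raise ValidationError("Laplacian must be symmetric")
    evals, evecs = np.linalg.eigh(lap)
    evecs = _fix_signs(evecs)

    # canonical order inside degenerate groups: lexicographic by entries
    order = np.arange(evals.size)
    start = 0
    while start < evals.size:
        stop = start + 1
        while stop < evals.size and evals[stop] - evals[start] <= _EIG_TOL:
            stop += 1
        if stop - start > 1:
            block = order[start:stop]
            lex = np.lexsort(evecs[::-1, block])
            order[start:stop] = block[lex]
        start = stop
    evals = evals[order]
    evecs = evecs[:, order]
    return GraphBasis(eigenvalues=evals, eigenvectors=evecs,
                      roi_labels=list(roi_labels) if roi_labels else [])


def basis_from_connectome(connectome: StructuralConnectome,
                          variant: str = "normalized") -> GraphBasis:
    """Convenience: harmonics of a connectome's (normalised) Laplacian."""
    if not connectome.is_connected():
        raise ValidationError("connectome must be connected for a graph basis")
    lap = normalized_laplacian(connectome, variant=variant)
    return graph_basis(lap, roi_labels=connectome.roi_labels)


def gft(basis: GraphBasis, data: RoiTimeSeries | np.ndarray) -> np.ndarray:
    """Graph Fourier transform: time × harmonic coefficient matrix."""
    values = data.values if isinstance(data, RoiTimeSeries) else np.asarray(data)
    if values.shape[1] != basis.n_roi:
        raise ValidationError("data ROI count does not match basis size")
    return values @ basis.eigenvectors


def igft(basis: GraphBasis, coefficients: np.ndarray) -> np.ndarray:
    """Inverse GFT; ``igft(basis, gft(basis, x)) == x``."""
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape[1] != basis.n_roi:
        raise ValidationError("coefficient count does not match basis size")
    return coefficients @ basis.eigenvectors.T


def graph_psd(coefficients: np.ndarray, normalize: bool = False) -> np.ndarray:
    """Time-averaged squared GFT coefficient per harmonic.

    With ``normalize`` the curve is scaled to a maximum of 1 for plotting
    several runs on a common axis.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    power = (coefficients**2).mean(axis=0)
    if normalize:
        peak = power.max()
        if peak > 0:
            power = power / peak
    return power


def make_surrogate(data: RoiTimeSeries, basis: GraphBasis,
                   sign_vector: np.ndarray) -> RoiTimeSeries:
    """Sign-randomised reconstruction X · (U diag(s) Uᵀ).

    The flip operator is symmetric, orthogonal and involutory: applying the
    same sign vector twice returns the original data.
    """
    s = np.asarray(sign_vector, dtype=float).ravel()
    if s.size != basis.n_roi:
        raise ValidationError("sign vector length does not match basis size")
    if not np.all(np.abs(s) == 1.0):
        raise ValidationError("sign vector entries must be ±1")
    operator = (basis.eigenvectors * s) @ basis.eigenvectors.T
    return data.copy_with(data.values @ operator)


@dataclass
class SurrogateEnsemble:
    """Seeded family of sign vectors; surrogates materialise on demand.

    Surrogate ``i`` uses the Rademacher vector drawn from
    ``default_rng((master_seed, i))`` with the first harmonic's sign pinned
    to +1 (a global sign flip is statistically vacuous), so any single
    surrogate is regenerable from (master_seed, index) alone.
    """

    data: RoiTimeSeries
    basis: GraphBasis
    n_surr: int
    master_seed: int
    sign_vectors: np.ndarray

    def __post_init__(self) -> None:
        self.sign_vectors = np.asarray(self.sign_vectors, dtype=float)
        if self.sign_vectors.shape != (self.n_surr, self.basis.n_roi):
            raise ValidationError("sign_vectors must be n_surr × n_roi")
        if not np.all(np.abs(self.sign_vectors) == 1.0):
            raise ValidationError("sign vectors must be ±1")

    def __len__(self) -> int:
        return self.n_surr

    def surrogate(self, index: int) -> RoiTimeSeries:
        if not 0 <= index < self.n_surr:
            raise IndexError(index)
        return make_surrogate(self.data, self.basis, self.sign_vectors[index])

    def __iter__(self):
        return (self.surrogate(i) for i in range(self.n_surr))


def rademacher_signs(n_roi: int, n_surr: int, master_seed: int) -> np.ndarray:
    """The ensemble's sign vectors; row i from default_rng((master_seed, i))."""
    signs = np.empty((n_surr, n_roi))
    for i in range(n_surr):
        rng = np.random.default_rng((int(master_seed), i))
        signs[i] = rng.choice([-1.0, 1.0], size=n_roi)
        signs[i, 0] = 1.0
    return signs


def surrogate_ensemble(data: RoiTimeSeries, basis: GraphBasis,
                       n_surr: int = 100,
                       master_seed: int = 0) -> SurrogateEnsemble:
    """Reproducible ensemble of sign-randomised surrogates."""
    if n_surr < 1:
        raise ValidationError("n_surr must be ≥ 1")
    if data.n_roi != basis.n_roi:
        raise ValidationError("data ROI count does not match basis size")
    signs = rademacher_signs(basis.n_roi, n_surr, master_seed)
    return SurrogateEnsemble(data=data, basis=basis, n_surr=n_surr,
                             master_seed=int(master_seed), sign_vectors=signs)


def harmonic_complexity(
    coefficients: np.ndarray,
    scales: Sequence[int] = DEFAULT_SCALES,
    m: int = DEFAULT_M,
    r_frac: float = DEFAULT_R_FRAC,
) -> tuple[list[MseCurve], np.ndarray]:
    """MSE curve and complexity index of each harmonic's coefficient series."""
    coefficients = np.asarray(coefficients, dtype=float)
    curves: list[MseCurve] = []
    ci = np.full(coefficients.shape[1], np.nan)
    for j in range(coefficients.shape[1]):
        curve = mse_curve(coefficients[:, j], scales=scales, m=m, r_frac=r_frac)
        curves.append(curve)
        ci[j] = complexity_index(curve)
    return curves, ci


def knee_point(values: np.ndarray,
               flat_tol: float = 1e-9) -> Optional[int]:
    """Index of maximal perpendicular distance to the first–last chord.

    Standard geometric knee detection on a per-harmonic profile. Returns
    ``None`` (flagged "no knee") when every point lies on the chord to
    within ``flat_tol`` of the profile's scale; ties break to the smallest
    index.
    """
    y = np.asarray(values, dtype=float).ravel()
    if y.size < 3:
        raise ValidationError("need at least 3 points for knee detection")
    x = np.arange(y.size, dtype=float)
    x0, y0 = x[0], y[0]
    dx, dy = x[-1] - x0, y[-1] - y0
    chord = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x0) - dx * (y - y0)) / chord
    scale = max(np.abs(y).max(), 1.0)
    if dist.max() <= flat_tol * scale:
        return None
    return int(np.argmax(dist))
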