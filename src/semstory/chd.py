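"""Connectome Harmonic Decomposition.

The template vertex connectome combines long-range links (vertex pairs whose
regions are connected in a donor-averaged, symmetrised, mean-thresholded
region matrix) with local links (vertex pairs closer than 10 mm).  Harmonics
are the eigenvectors of the symmetric normalised graph Laplacian

    Delta_G = D^{-1/2} (D - A) D^{-1/2}

ordered by ascending eigenvalue (spatial frequency); a signal over vertices
is decomposed as F_t = sum_k w_k(t) phi_k with w_k(t) = <F_t, phi_k>.
Windowed energies along the spatial-frequency axis (window 4% of the basis,
step 2% by default) are the features fed to the decoding stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .dataset import ValidationError

__all__ = ["StructuralConnectome", "HarmonicBasis", "HarmonicWeights",
           "HarmonicSpectrum", "build_template_adjacency", "compute_harmonics",
           "project_signal", "harmonic_windows"]


@dataclass
class StructuralConnectome:
    """Binary symmetric vertex adjacency with coordinates and region labels."""

    adjacency: np.ndarray
    coords: np.ndarray
    region_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValidationError("adjacency diagonal must be zero")
        if not np.isin(A, (0, 1)).all():
            raise ValidationError("adjacency must be binary")
        coords = np.asarray(self.coords, float)
        if coords.shape != (A.shape[0], 3):
            raise ValidationError("coords must be n x 3 (mm)")
        n_comp, labels = connected_components(A, directed=False)
        if n_comp != 1:
            sizes = np.bincount(labels)
            raise ValidationError(
                f"graph is disconnected: {n_comp} components of sizes "
                f"{sizes.tolist()}")
        self.adjacency = A.astype(np.uint8)
        self.coords = coords

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(float)


def build_template_adjacency(region_matrix: np.ndarray,
                             vertex_labels: np.ndarray,
                             coords: np.ndarray,
                             local_radius_mm: float = 10.0) -> StructuralConnectome:
    """Template vertex connectome from a region-level tract matrix.

    ``region_matrix`` is region x region non-negative weights, or a stack
    (donor x region x region) averaged first.  The matrix is symmetrised as
    (M + M^T)/2 and binarised at the mean of all its entries; vertex pairs
    in connected regions are linked (long-range), as are vertex pairs closer
    than ``local_radius_mm`` (local).  The result must be connected.
    """
    M = np.asarray(region_matrix, float)
    if M.ndim == 3:
        M = M.mean(axis=0)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or M.size == 0:
        raise ValidationError("region matrix must be square and non-empty")
    if np.any(M < 0):
        raise ValidationError("region matrix must be non-negative")
    sym = (M + M.T) / 2
    threshold = sym.mean()
    binarized = (sym > threshold).astype(np.uint8)

    vertex_labels = np.asarray(vertex_labels)
    coords = np.asarray(coords, float)
    n = len(vertex_labels)
    if coords.shape != (n, 3):
        raise ValidationError("coords must be n x 3")
    labeled = vertex_labels >= 0
    A = np.zeros((n, n), dtype=np.uint8)
    li = vertex_labels[labeled]
    A[np.ix_(labeled, labeled)] = binarized[np.ix_(li, li)]
    dist = cdist(coords, coords)
    A[dist < local_radius_mm] = 1
    np.fill_diagonal(A, 0)
    A = np.maximum(A, A.T)
    return StructuralConnectome(adjacency=A, coords=coords,
                                region_labels=vertex_labels)


@dataclass
class HarmonicBasis:
    """Orthonormal eigenvectors (columns) and ascending eigenvalues of the
    symmetric normalised connectome Laplacian."""

    eigenvectors: np.ndarray   # (n, n), column k is phi_k
    eigenvalues: np.ndarray    # (n,), ascending, in [0, 2]
    degrees: np.ndarray

    @property
    def n(self) -> int:
        return self.eigenvectors.shape[0]

    def save(self, path) -> None:
        np.savez(path, eigenvectors=self.eigenvectors,
                 eigenvalues=self.eigenvalues, degrees=self.degrees)

    @classmethod
    def load(cls, path) -> "HarmonicBasis":
        data = np.load(path)
        return cls(eigenvectors=data["eigenvectors"],
                   eigenvalues=data["eigenvalues"], degrees=data["degrees"])


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: first entry of magnitude > 1e-12
    of each eigenvector is positive."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            out[:, k] = -col
    return out


def compute_harmonics(connectome: StructuralConnectome) -> HarmonicBasis:
    """Full eigendecomposition of the symmetric normalised Laplacian.

    D_ii = sum_j A_ij; L = D - A; Delta_G = D^{-1/2} L D^{-1/2}.  The
    smallest eigenvalue of a connected graph is 0 (eigenvector proportional
    to D^{1/2} 1) and all eigenvalues are at most 2.
    """
    deg = connectome.degrees
    if np.any(deg == 0):
        raise ValidationError("isolated vertex: degree 0 breaks D^{-1/2}")
    A = connectome.adjacency.astype(float)
    d_isqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(connectome.n) - (d_isqrt[:, None] * A) * d_isqrt[None, :]
    lap = (lap + lap.T) / 2
    eigenvalues, eigenvectors = np.linalg.eigh(lap)
    order = np.argsort(eigenvalues, kind="stable")
    eigenvalues = eigenvalues[order]
    eigenvectors = _fix_signs(eigenvectors[:, order])
    return HarmonicBasis(eigenvectors=eigenvectors, eigenvalues=eigenvalues,
                         degrees=deg)


@dataclass
class HarmonicWeights:
    """Harmonic weights w_k(t): volumes x n, ordered like the eigenvalues."""

    weights: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_volumes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_harmonics(self) -> int:
        return self.weights.shape[1]


def project_signal(F: np.ndarray, basis: HarmonicBasis) -> HarmonicWeights:
    """Project a volumes x n vertex signal onto the harmonic basis.

    w_k(t) = <F_t, phi_k>; with the full orthonormal basis the reconstruction
    W Phi^T reproduces F and Parseval holds (sum_k w_k(t)^2 = ||F_t||^2).
    """
    F = np.atleast_2d(np.asarray(F, float))
    if F.shape[1] != basis.n:
        raise ValidationError(
            f"signal width {F.shape[1]} != basis size {basis.n}")
    return HarmonicWeights(weights=F @ basis.eigenvectors,
                           eigenvalues=basis.eigenvalues)


def reconstruct_signal(weights: HarmonicWeights, basis: HarmonicBasis) -> np.ndarray:
    return weights.weights @ basis.eigenvectors.T


@dataclass
class HarmonicSpectrum:
    """Windowed harmonic energy: volumes x windows, ascending spatial frequency."""

    energies: np.ndarray
    window_bounds: list[tuple[int, int]]
    energy_mode: str

    @property
    def n_windows(self) -> int:
        return self.energies.shape[1]


_ENERGY_MODES = {
    "mean_abs": lambda w, lam: np.abs(w).mean(axis=1),
    "mean_square": lambda w, lam: (w ** 2).mean(axis=1),
    "lambda_weighted": lambda w, lam: (np.abs(w) * lam[None, :]).mean(axis=1),
}


def harmonic_windows(weights: HarmonicWeights, window_frac: float = 0.04,
                     step_frac: float = 0.02,
                     energy_mode: str = "mean_abs") -> HarmonicSpectrum:
    """Sliding-window energy spectrum along the spatial-frequency axis.

    Window length = round(window_frac * n), step = round(step_frac * n)
    (at least 1); the number of windows is floor((n - window)/step) + 1.
    For n = 5124 at 4% the window length is 205.
    """
    if not (0 < step_frac <= window_frac <= 1):
        raise ValidationError("need 0 < step_frac <= window_frac <= 1")
    if energy_mode not in _ENERGY_MODES:
        raise ValidationError(f"unknown energy mode {energy_mode!r}")
    n = weights.n_harmonics
    window = max(1, round(window_frac * n))
    step = max(1, round(step_frac * n))
    if window > n:
        raise ValidationError("window longer than harmonic basis")
    agg = _ENERGY_MODES[energy_mode]
    bounds = [(start, start + window)
              for start in range(0, n - window + 1, step)]
    energies = np.column_stack(
        [agg(weights.weights[:, lo:hi], weights.eigenvalues[lo:hi])
         for lo, hi in bounds])
    return HarmonicSpectrum(energies=energies, window_bounds=bounds,
                            energy_mode=energy_mode)


def window_length(n_harmonics: int, window_frac: float = 0.04) -> int:
    """Window length in harmonics for a basis of ``n_harmonics`` modes."""
    return max(1, round(window_frac * n_harmonics))
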