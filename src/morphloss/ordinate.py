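"""Cailliez correction and principal coordinates analysis.

Dissimilarity matrices computed under missing data are generally
non-Euclidean: the double-centred Gram matrix has negative eigenvalues and
classical scaling would place taxa on imaginary axes.  The Cailliez
construction finds the smallest constant c such that adding c to every
off-diagonal dissimilarity makes the matrix Euclidean; PCoA (classical
multidimensional scaling) then embeds the corrected distances exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .core import TipStatus
from .distance import DistanceMatrixResult

__all__ = ["OrdinationResult", "cailliez_constant", "apply_cailliez", "pcoa"]

#: Relative eigenvalue tolerance: axes with eigenvalue <= tol * max are dropped.
EIGEN_TOL = 1e-8


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return D


def _double_centre(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * (J @ X @ J)


def cailliez_constant(dm: DistanceMatrixResult | np.ndarray) -> float:
    """Smallest c >= 0 making ``D + c`` (off-diagonal) Euclidean.

    Computed as the largest real eigenvalue of the 2n x 2n block companion
    matrix of the Cailliez (1983) construction,

        [[ 0,  2 * delta1],
         [-I, -4 * delta2]]

    with delta1 the double-centred ``-D**2 / 2`` and delta2 the
    double-centred ``-D / 2``.  Returns 0 for matrices that are already
    Euclidean (including any 2-taxon matrix).
    """
    D = dm.D if isinstance(dm, DistanceMatrixResult) else dm
    D = _check_distance_matrix(D)
    n = D.shape[0]
    if n <= 2:
        return 0.0
    delta1 = _double_centre(D**2)
    delta2 = _double_centre(D)
    upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    eigvals = scipy.linalg.eigvals(np.vstack([upper, lower]))
    real = eigvals.real[np.abs(eigvals.imag) <= 1e-8 * np.abs(eigvals).max()]
    if real.size == 0:
        return 0.0
    c = float(max(real.max(), 0.0))
    # eigenvalue noise: treat constants far below the distance scale as zero
    if c <= 1e-8 * max(D.max(), 1.0):
        return 0.0
    return c


def apply_cailliez(
    dm: DistanceMatrixResult, c: float | None = None
) -> DistanceMatrixResult:
    """Add the Cailliez constant to every off-diagonal entry.

    When ``c`` is omitted it is computed from the matrix.  The constant is
    recorded on the result so downstream ordinations are traceable.
    """
    if c is None:
        c = cailliez_constant(dm)
    if c < 0:
        raise ValueError("Cailliez constant must be >= 0")
    D = dm.D + c
    np.fill_diagonal(D, 0.0)
    return DistanceMatrixResult(
        taxa=list(dm.taxa),
        D=D,
        comparable_counts=dm.comparable_counts.copy(),
        metric=dm.metric,
        mean_dissimilarity=dm.mean_dissimilarity,
        cailliez_constant=float(c),
        status=dict(dm.status),
    )


@dataclass
class OrdinationResult:
    """PCoA coordinates over the retained (positive-eigenvalue) axes."""

    taxa: list[str]
    coordinates: np.ndarray  # (n_taxa, n_axes)
    eigenvalues: np.ndarray  # retained, descending
    cailliez_constant: float | None
    n_positive_axes: int
    status: dict[str, TipStatus]

    def index_of(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise KeyError(f"unknown taxon {label!r}") from None

    def subset(self, labels: list[str]) -> "OrdinationResult":
        """Row subset of the existing ordination (no re-ordination)."""
        idx = [self.index_of(t) for t in labels]
        return OrdinationResult(
            taxa=list(labels),
            coordinates=self.coordinates[idx],
            eigenvalues=self.eigenvalues.copy(),
            cailliez_constant=self.cailliez_constant,
            n_positive_axes=self.n_positive_axes,
            status={t: self.status[t] for t in labels if t in self.status},
        )


def pcoa(dm: DistanceMatrixResult, tol: float = EIGEN_TOL) -> OrdinationResult:
    """Classical multidimensional scaling of a distance matrix.

    Eigendecomposes the double-centred squared-distance matrix; axes with
    eigenvalue above ``tol * max(eigenvalue)`` are retained and scaled by
    the square root of their eigenvalue.  Axis signs are fixed by making
    each axis's largest-magnitude loading positive, so repeated runs give
    identical coordinates.
    """
    D = _check_distance_matrix(dm.D)
    B = _double_centre(D**2)
    eigvals, eigvecs = scipy.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    max_eig = eigvals[0]
    if max_eig <= 0:
        raise ValueError("no positive eigenvalue: degenerate distance matrix")
    keep = eigvals > tol * max_eig
    kept_vals = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(kept_vals)
    for axis in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, axis]))
        if coords[pivot, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    return OrdinationResult(
        taxa=list(dm.taxa),
        coordinates=coords,
        eigenvalues=kept_vals,
        cailliez_constant=dm.cailliez_constant,
        n_positive_axes=int(keep.sum()),
        status=dict(dm.status),
    )
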