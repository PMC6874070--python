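"""Resolution functions for tree shape statistics, with spectral scaling.

Two resolution functions measure how well a statistic separates dissimilar
shapes, given the NNI geometry of tree space:

* geometric resolution  R_D(f) = -1/2 x_f^t D_s x_f   (higher is better),
  with D_s the elementwise-squared NNI distance matrix;
* Laplacian resolution  R_L(f) = x_f^t L x_f          (lower is better),
  with L the Cayley-graph Laplacian, equal to the sum of squared differences
  of x_f across graph edges.

Both are Rayleigh quotients of a symmetric matrix at the centered unit vector
x_f, so by Courant-Fischer they are bracketed by extreme eigenvalues: for R_D
the extreme eigenvalues of X_D = -1/2 H D_s H on the centered subspace, for
R_L the Fiedler value (second-smallest eigenvalue) and the largest eigenvalue
of L.  The scaled resolution maps the raw value onto [0, 1] via
(raw - min) / (max - min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .nni import CayleyGraph, DistanceMatrix, laplacian as graph_laplacian
from .stats import StatVector

__all__ = [
    "SpectralBounds",
    "ResolutionReport",
    "resolution_D",
    "resolution_L",
    "bounds_distance",
    "bounds_laplacian",
    "scaled_resolution",
    "resolution_report",
    "mds_embed",
]

#: eigensolver tolerance; bounds are only needed to table precision
EIG_TOL = 1e-9

#: below this size, dense eigendecompositions are cheaper and exact
_DENSE_LIMIT = 3000


@dataclass(frozen=True)
class SpectralBounds:
    """Extreme Rayleigh-quotient values of the matrix behind a resolution.

    For the Laplacian, ``lower`` is the Fiedler value (smallest eigenvalue on
    the subspace orthogonal to the constant vector) and ``upper`` the largest
    eigenvalue.  For X_D, both extremes are taken on the centered subspace,
    where every x_f lives.
    """

    matrix_role: str  # "X_D" or "L"
    lower: float
    upper: float


@dataclass(frozen=True)
class ResolutionReport:
    """Raw, bounded and scaled resolution of one statistic under one function."""

    statistic: str
    function: str  # "distance" or "laplacian"
    raw: float
    lower: float
    upper: float
    leaf_count: int
    num_shapes: int

    @property
    def scaled(self) -> float:
        return (self.raw - self.lower) / (self.upper - self.lower)


def _check_centered_unit(x: np.ndarray, n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (n,):
        raise ValueError(f"statistic vector has shape {x.shape}, expected ({n},)")
    return x


def resolution_D(x_f: np.ndarray, dist: DistanceMatrix | np.ndarray) -> float:
    """Geometric resolution -1/2 x^t D_s x of a centered unit vector.

    ``dist`` is a DistanceMatrix (squared blockwise, memory-lean) or the
    squared distance matrix D_s itself.
    """
    if isinstance(dist, DistanceMatrix):
        x = _check_centered_unit(x_f, dist.distances.shape[0])
        return float(dist.neg_half_quadform(x))
    D_s = np.asarray(dist, dtype=float)
    x = _check_centered_unit(x_f, D_s.shape[0])
    return float(-0.5 * x @ (D_s @ x))


def resolution_L(x_f: np.ndarray, L: sp.spmatrix) -> float:
    """Laplacian resolution x^t L x of a centered unit vector."""
    x = _check_centered_unit(x_f, L.shape[0])
    return float(x @ (L @ x))


def _xd_operator(dist: DistanceMatrix) -> spla.LinearOperator:
    """X_D = -1/2 H D_s H as a matrix-free operator (centering applied on the fly)."""
    n = dist.distances.shape[0]

    def matvec(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float).ravel()
        v = v - v.mean()
        w = dist.apply_neg_half_squared(v)
        return w - w.mean()

    return spla.LinearOperator((n, n), matvec=matvec, dtype=np.float64)


def bounds_distance(dist: DistanceMatrix | np.ndarray) -> SpectralBounds:
    """Extreme eigenvalues of X_D = -1/2 H D_s H on the centered subspace.

    X_D annihilates the constant vector exactly, so on small spaces the full
    spectrum is computed densely and one zero eigenvalue (the constant
    direction) is removed; on large spaces the two extremes are found by
    Lanczos iteration on a matrix-free centered operator, under which the
    constant direction is an exact zero eigenvector and never extremal once
    the spectrum straddles zero.
    """
    if not isinstance(dist, DistanceMatrix):
        raise TypeError("bounds_distance needs a DistanceMatrix")
    n = dist.distances.shape[0]
    if n < 2:
        raise ValueError("need at least two shapes for spectral bounds")
    if n <= _DENSE_LIMIT:
        D_s = dist.squared
        H = np.eye(n) - 1.0 / n
        X = -0.5 * (H @ D_s @ H)
        X = (X + X.T) / 2.0
        vals, vecs = np.linalg.eigh(X)
        # drop one copy of the constant-direction zero eigenvalue
        const_overlap = np.abs(vecs.sum(axis=0)) / np.sqrt(n)
        drop = int(np.argmax(const_overlap))
        kept = np.delete(vals, drop)
        return SpectralBounds("X_D", float(kept.min()), float(kept.max()))
    op = _xd_operator(dist)
    upper = spla.eigsh(op, k=1, which="LA", tol=EIG_TOL,
                       return_eigenvectors=False)[0]
    lower = spla.eigsh(op, k=1, which="SA", tol=EIG_TOL,
                       return_eigenvectors=False)[0]
    return SpectralBounds("X_D", float(lower), float(upper))


def bounds_laplacian(L: sp.spmatrix) -> SpectralBounds:
    """Fiedler value and largest eigenvalue of a connected graph's Laplacian.

    The zero eigenvalue (constant eigenvector) is excluded by deflation, not
    by magnitude sorting: small spectra are computed densely; on large graphs
    the Fiedler value is the smallest eigenvalue on the subspace orthogonal to
    the constant vector, found by Jacobi-preconditioned LOBPCG constrained
    against that vector.  Raises ValueError when the Fiedler value is
    numerically zero (graph disconnected).
    """
    n = L.shape[0]
    if n < 2:
        raise ValueError("need at least two vertices for Laplacian bounds")
    if n <= _DENSE_LIMIT:
        vals = np.linalg.eigvalsh(L.toarray())
        lam2, lam_max = float(vals[1]), float(vals[-1])
    else:
        lam_max = float(spla.eigsh(L, k=1, which="LA", tol=EIG_TOL,
                                   return_eigenvectors=False)[0])
        rng = np.random.default_rng(0)  # start vector only; result is deterministic
        vals, _ = spla.lobpcg(
            L,
            rng.standard_normal((n, 1)),
            Y=np.ones((n, 1)),
            M=sp.diags(1.0 / L.diagonal()),
            largest=False,
            tol=1e-10,
            maxiter=5000,
        )
        lam2 = float(vals[0])
    if lam2 <= 1e-8:
        raise ValueError(
            f"Fiedler value is numerically zero ({lam2:.3e}); graph disconnected"
        )
    return SpectralBounds("L", lam2, lam_max)


def scaled_resolution(raw: float, bounds: SpectralBounds) -> float:
    """Map a raw resolution onto [0, 1] via (raw - min) / (max - min)."""
    if not bounds.upper > bounds.lower:
        raise ValueError(
            f"degenerate spectrum: upper bound {bounds.upper} <= lower {bounds.lower}"
        )
    return (raw - bounds.lower) / (bounds.upper - bounds.lower)


def resolution_report(
    stat: StatVector,
    operand: DistanceMatrix | CayleyGraph | sp.spmatrix,
    function: str,
    bounds: SpectralBounds | None = None,
) -> ResolutionReport:
    """Compute one statistic's raw and scaled resolution under one function.

    ``function`` is "distance" (operand: DistanceMatrix) or "laplacian"
    (operand: CayleyGraph or a prebuilt Laplacian).  Precomputed spectral
    bounds may be passed to amortize eigenproblems across statistics.
    """
    x = stat.centered_unit
    if function == "distance":
        if not isinstance(operand, DistanceMatrix):
            raise TypeError("distance resolution needs a DistanceMatrix")
        raw = resolution_D(x, operand)
        if bounds is None:
            bounds = bounds_distance(operand)
    elif function == "laplacian":
        L = graph_laplacian(operand) if isinstance(operand, CayleyGraph) else operand
        raw = resolution_L(x, L)
        if bounds is None:
            bounds = bounds_laplacian(L)
    else:
        raise ValueError(f"unknown resolution function {function!r}")
    rep = ResolutionReport(
        statistic=stat.name,
        function=function,
        raw=raw,
        lower=bounds.lower,
        upper=bounds.upper,
        leaf_count=stat.space.leaf_count,
        num_shapes=stat.space.num_shapes,
    )
    return rep


def mds_embed(dist: DistanceMatrix | np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Returns an (n, dims) configuration from the top nonnegative eigenpairs of
    X_D = -1/2 H D_s H.  If fewer than ``dims`` positive eigenvalues exist the
    remaining coordinates are zero.
    """
    D = dist.distances if isinstance(dist, DistanceMatrix) else np.asarray(dist, float)
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    H = np.eye(n) - 1.0 / n
    X = -0.5 * (H @ (D ** 2) @ H)
    X = (X + X.T) / 2.0
    vals, vecs = np.linalg.eigh(X)
    order = np.argsort(vals)[::-1]
    pts = np.zeros((n, dims))
    for k, idx in enumerate(order[:dims]):
        if vals[idx] <= 0:
            break
        pts[:, k] = vecs[:, idx] * np.sqrt(vals[idx])
    return pts
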