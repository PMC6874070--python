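"""Optimal linear combinations of two tree shape statistics.

For statistics f and g with centered value vectors over a shape space, the
combination lambda*f + g has resolution

    R(lambda) = v^t A v / v^t v,   v = lambda * yc_f + yc_g,

with A = X_D (maximize) or A = L (minimize).  Setting the derivative of this
quotient to zero gives a quadratic in lambda,

    (a q - b p) lambda^2 + (a r - c p) lambda + (b r - c q) = 0,

where a = yc_f^t A yc_f, b = yc_f^t A yc_g, c = yc_g^t A yc_g and
p, q, r are the corresponding Gram entries of yc_f, yc_g.  The combination is
formed from CENTERED raw statistic vectors, not individually normalized ones:
the optimal coefficient depends on the statistics' printed normalizations.

The flagship combination is the Saless index, lambda*Sackin + Colless, with
lambda chosen to maximize the geometric resolution R_D.  Published optimal
coefficients correspond to the UNNORMALIZED statistics — total root-leaf path
length for Sackin and total |r - s| for Colless — so those raw forms are the
default here; scaled resolutions are affine-invariant and unaffected by the
choice, but lambda itself is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .nni import DistanceMatrix
from .resolution import SpectralBounds, scaled_resolution
from .shapes import ShapeSpace, TreeShape
from .stats import StatVector, colless_raw, sackin_raw, statistic_vector

__all__ = ["CombinationResult", "optimal_lambda", "saless", "saless_vector",
           "optimal_saless", "combination_table"]


@dataclass(frozen=True)
class CombinationResult:
    """Optimal coefficient for the combination lambda*f + g and its resolution."""

    stat_f: str
    stat_g: str
    lam: float
    objective: str  # "max" (R_D) or "min" (R_L)
    raw: float
    scaled: float
    discriminant: float
    #: combinations with a negative coefficient optimize the resolution but mix
    #: the statistics with opposite signs, which has no natural interpretation
    plausible: bool


def _quadratic_form(A, v: np.ndarray, w: np.ndarray) -> float:
    return float(v @ (A @ w))


def optimal_lambda(
    f: StatVector,
    g: StatVector,
    quadform: np.ndarray | sp.spmatrix,
    sense: str,
    bounds: SpectralBounds | None = None,
) -> CombinationResult:
    """Optimal coefficient of lambda*f + g under a quadratic-form resolution.

    Parameters
    ----------
    f, g : StatVector
        Statistics over the same space; their centered vectors must be
        linearly independent.
    quadform : array or sparse matrix
        The symmetric matrix A of the resolution: X_D (as a dense array, or a
        DistanceMatrix from which X_D's action is derived) or the Laplacian L.
        Because v is centered, v^t X_D v = -1/2 v^t D_s v, so a DistanceMatrix
        may be passed directly.
    sense : "max" or "min"
        Maximize (geometric resolution) or minimize (Laplacian resolution).
    bounds : SpectralBounds, optional
        For the scaled value; if omitted, ``scaled`` is NaN.

    Among the real stationary points the one with the better objective wins;
    ties break toward smaller |lambda|.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    yf = f.centered
    yg = g.centered
    p = float(yf @ yf)
    q = float(yf @ yg)
    r = float(yg @ yg)
    gram_det = p * r - q * q
    if gram_det <= 1e-12 * p * r:
        raise ValueError(
            f"centered vectors of {f.name!r} and {g.name!r} are (nearly) parallel; "
            "the combination is degenerate"
        )
    if isinstance(quadform, DistanceMatrix):
        # on centered vectors H acts as the identity, so v^t X_D v = -1/2 v^t D_s v,
        # evaluated blockwise from the integer distance matrix
        M = quadform.neg_half_quadform(np.column_stack([yf, yg]))
        a, b, c = float(M[0, 0]), float(M[0, 1]), float(M[1, 1])
    else:
        A = quadform
        a = _quadratic_form(A, yf, yf)
        b = _quadratic_form(A, yf, yg)
        c = _quadratic_form(A, yg, yg)

    def rayleigh(lam: float) -> float:
        return ((a * lam + 2.0 * b) * lam + c) / ((p * lam + 2.0 * q) * lam + r)

    c2 = a * q - b * p
    c1 = a * r - c * p
    c0 = b * r - c * q
    if abs(c2) <= 1e-14 * max(abs(c1), abs(c0), 1.0):
        # quotient's stationarity is linear in lambda
        disc = np.inf
        roots = [-c0 / c1] if c1 != 0.0 else []
    else:
        disc = c1 * c1 - 4.0 * c2 * c0
        if disc < 0.0:
            raise ValueError(
                f"complex stationary points (discriminant {disc:.3e} < 0) for "
                f"{f.name!r}, {g.name!r}"
            )
        sq = np.sqrt(disc)
        roots = [(-c1 - sq) / (2.0 * c2), (-c1 + sq) / (2.0 * c2)]
    if not roots:
        raise ValueError("no stationary point found")
    best = None
    for lam in sorted(roots, key=abs):
        val = rayleigh(lam)
        if best is None or (val > best[1] if sense == "max" else val < best[1]):
            best = (lam, val)
    lam, raw = best
    scaled = scaled_resolution(raw, bounds) if bounds is not None else float("nan")
    return CombinationResult(
        stat_f=f.name,
        stat_g=g.name,
        lam=float(lam),
        objective=sense,
        raw=raw,
        scaled=scaled,
        discriminant=float(disc),
        plausible=lam >= 0.0,
    )


def saless(shape: TreeShape, lam: float) -> float:
    """The Saless index lambda*Sackin + Colless of a single shape.

    Sackin and Colless enter in their unnormalized (sum) forms, the
    convention under which the published optimal coefficients are stated.
    """
    if not np.isfinite(lam):
        raise ValueError("lambda must be finite")
    if shape.num_leaves < 3:
        raise ValueError("Saless requires at least 3 leaves")
    return lam * sackin_raw(shape) + colless_raw(shape)


def saless_vector(space: ShapeSpace, lam: float) -> StatVector:
    """Saless values over a whole space, index-aligned."""
    sv = statistic_vector(space, "sackin_raw")
    cv = statistic_vector(space, "colless_raw")
    return StatVector(name="saless", space=space,
                      values=lam * sv.values + cv.values)


def optimal_saless(
    space: ShapeSpace,
    quadform,
    sense: str = "max",
    bounds: SpectralBounds | None = None,
) -> CombinationResult:
    """Optimal Saless coefficient: lambda*Sackin + Colless (raw sums).

    With the geometric resolution (sense="max", quadform a DistanceMatrix or
    X_D) this is the statistic's defining optimization.
    """
    sv = statistic_vector(space, "sackin_raw")
    cv = statistic_vector(space, "colless_raw")
    return optimal_lambda(sv, cv, quadform, sense, bounds=bounds)


def combination_table(
    space: ShapeSpace,
    pairs: list[tuple[str, str]],
    quadform,
    sense: str,
    bounds: SpectralBounds,
) -> list[CombinationResult]:
    """Optimal combinations for several (f, g) statistic pairs on one space.

    Pair (f, g) means the combination lambda*f + g.
    """
    vectors: dict[str, StatVector] = {}

    def vec(name: str) -> StatVector:
        if name not in vectors:
            vectors[name] = statistic_vector(space, name)
        return vectors[name]

    return [
        optimal_lambda(vec(fn), vec(gn), quadform, sense, bounds=bounds)
        for fn, gn in pairs
    ]
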