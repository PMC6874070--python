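"""The classical tree shape statistics and index-aligned statistic vectors.

All statistics are computed from one set of per-node annotations (leaf depths,
subtree heights, left/right leaf counts) obtained in a single traversal.

Inside each statistic formula ``n`` denotes the number of leaves of the tree.
The printed normalizing constants (2/((n-1)(n-2)) for Colless, 1/n for Sackin
and the depth variance, 1/(n-2) for I2) are kept exactly: single-statistic
resolutions are affine-invariant, but the optimal coefficient of a linear
combination of two statistics does depend on them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .shapes import ShapeSpace, TreeShape

__all__ = [
    "NodeAnnotation",
    "annotate",
    "colless",
    "sackin",
    "sigma2",
    "i2",
    "b1",
    "b2",
    "cherries",
    "colless_raw",
    "sackin_raw",
    "STATISTICS",
    "StatVector",
    "statistic_vector",
    "center_unit",
]


@dataclass(frozen=True)
class NodeAnnotation:
    """Per-node quantities of a shape, gathered in one post-order pass.

    leaf_depths: depth (edges from root) of every leaf.
    internal_heights: height (longest downward path) of every internal node,
        in the same order as ``internal_balances``; the root is last.
    internal_balances: |r - s| for every internal node.
    internal_sizes: r + s (leaves below) for every internal node.
    n_cherries: internal nodes whose two children are both leaves.
    """

    leaf_depths: np.ndarray
    internal_heights: np.ndarray
    internal_balances: np.ndarray
    internal_sizes: np.ndarray
    n_cherries: int


def annotate(shape: TreeShape) -> NodeAnnotation:
    depths: list[int] = []
    heights: list[int] = []
    balances: list[int] = []
    sizes: list[int] = []
    n_cherries = 0

    def walk(node: TreeShape, depth: int) -> tuple[int, int]:
        """Return (height, num_leaves) of *node*."""
        nonlocal n_cherries
        if node.is_leaf:
            depths.append(depth)
            return 0, 1
        a, b = node.children
        ha, la = walk(a, depth + 1)
        hb, lb = walk(b, depth + 1)
        heights.append(max(ha, hb) + 1)
        balances.append(abs(la - lb))
        sizes.append(la + lb)
        if a.is_leaf and b.is_leaf:
            n_cherries += 1
        return max(ha, hb) + 1, la + lb

    walk(shape, 0)
    return NodeAnnotation(
        leaf_depths=np.asarray(depths, dtype=np.int64),
        internal_heights=np.asarray(heights, dtype=np.int64),
        internal_balances=np.asarray(balances, dtype=np.int64),
        internal_sizes=np.asarray(sizes, dtype=np.int64),
        n_cherries=n_cherries,
    )


def colless(shape: TreeShape) -> float:
    """Normalized Colless imbalance I_c = 2/((n-1)(n-2)) * sum |r_i - s_i|.

    0 on the maximally balanced shape, 1 on the caterpillar."""
    n = shape.num_leaves
    if n <= 2:
        raise ValueError("Colless index requires at least 3 leaves")
    ann = annotate(shape)
    return 2.0 * int(ann.internal_balances.sum()) / ((n - 1) * (n - 2))


def sackin(shape: TreeShape) -> float:
    """Sackin index: mean root-to-leaf path length."""
    ann = annotate(shape)
    return float(ann.leaf_depths.mean())


def sigma2(shape: TreeShape) -> float:
    """Population variance of the root-to-leaf path lengths."""
    ann = annotate(shape)
    return float(ann.leaf_depths.var())


def i2(shape: TreeShape) -> float:
    """I2 imbalance: mean of |r_j - s_j| / (r_j + s_j - 2) over internal nodes
    with more than two leaves below, normalized by 1/(n-2)."""
    n = shape.num_leaves
    if n <= 2:
        raise ValueError("I2 requires at least 3 leaves")
    ann = annotate(shape)
    mask = ann.internal_sizes > 2
    terms = ann.internal_balances[mask] / (ann.internal_sizes[mask] - 2)
    return float(terms.sum()) / (n - 2)


def b1(shape: TreeShape) -> float:
    """B1 = sum of 1/M_j over internal nodes excluding the root, M_j the
    subtree height (the Shao-Sokal convention)."""
    if shape.num_leaves < 2:
        return 0.0
    heights = annotate(shape).internal_heights[:-1]  # root is appended last
    return float((1.0 / heights).sum())


def b2(shape: TreeShape) -> float:
    """B2 = sum over leaves of N_j / 2^N_j, N_j the leaf depth."""
    d = annotate(shape).leaf_depths
    return float((d / np.exp2(d)).sum())


def cherries(shape: TreeShape) -> int:
    """Number of internal nodes whose two children are both leaves."""
    return annotate(shape).n_cherries


def colless_raw(shape: TreeShape) -> float:
    """Unnormalized Colless imbalance: sum of |r_i - s_i| over internal nodes.

    This is the form most software reports and the one entering published
    optimal linear combinations; ``colless`` divides it by (n-1)(n-2)/2."""
    return float(annotate(shape).internal_balances.sum())


def sackin_raw(shape: TreeShape) -> float:
    """Unnormalized Sackin index: total root-to-leaf path length.

    ``sackin`` divides it by the number of leaves; the raw sum is the form
    entering published optimal linear combinations."""
    return float(annotate(shape).leaf_depths.sum())


#: name -> statistic function, in the conventional reporting order
STATISTICS: dict[str, Callable[[TreeShape], float]] = {
    "colless": colless,
    "sackin": sackin,
    "sigma2": sigma2,
    "i2": i2,
    "b1": b1,
    "b2": b2,
    "cherries": cherries,
    "colless_raw": colless_raw,
    "sackin_raw": sackin_raw,
}


def center_unit(y: np.ndarray) -> np.ndarray:
    """Apply the centering matrix H = I - (1/n) 1 1^t and normalize to unit
    Euclidean norm: x = H y / ||H y||.

    Raises ValueError if y is constant (zero after centering)."""
    y = np.asarray(y, dtype=float)
    centered = y - y.mean()
    norm = np.linalg.norm(centered)
    if norm == 0.0 or not np.isfinite(norm):
        raise ValueError("statistic is constant over the space; cannot center-normalize")
    return centered / norm


@dataclass(frozen=True)
class StatVector:
    """Values of one statistic over a whole shape space.

    values: raw statistic values y_f, index-aligned with the space.
    centered_unit: x_f = H y_f / ||H y_f||, the vector entering both
        resolution functions.
    """

    name: str
    space: ShapeSpace
    values: np.ndarray

    @property
    def centered(self) -> np.ndarray:
        """H y_f — centered but not normalized (used for combinations)."""
        return self.values - self.values.mean()

    @property
    def centered_unit(self) -> np.ndarray:
        return center_unit(self.values)


def statistic_vector(space: ShapeSpace, stat: str | Callable[[TreeShape], float]) -> StatVector:
    """Evaluate a statistic on every shape of the space, index-aligned.

    ``stat`` is a name from :data:`STATISTICS` or any callable on shapes.
    Raises ValueError for an unknown name or a statistic that is constant
    over the space.
    """
    if callable(stat):
        fn, name = stat, getattr(stat, "__name__", "custom")
    else:
        try:
            fn = STATISTICS[stat]
        except KeyError:
            raise ValueError(
                f"unknown statistic {stat!r}; available: {', '.join(STATISTICS)}"
            ) from None
        name = stat
    values = np.array([fn(s) for s in space.shapes], dtype=float)
    vec = StatVector(name=name, space=space, values=values)
    vec.centered_unit  # noqa: B018 - validates non-constancy eagerly
    return vec
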