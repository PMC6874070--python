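"""Unlabeled rooted bifurcating tree shapes: canonical forms, enumeration, newick I/O,
and random generation under the Yule and PDA models.

A *tree shape* is a rooted bifurcating tree considered up to isomorphism — leaf
labels and branch lengths carry no information.  Every shape is held in a
canonical interned form, so two isomorphic trees are literally the same Python
object and equality/hashing are O(1).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterator

import dendropy

__all__ = [
    "TreeShape",
    "ShapeSpace",
    "LEAF",
    "make_shape",
    "enumerate_shapes",
    "count_shapes",
    "canonical_form",
    "parse_newick",
    "write_newick",
    "random_shape",
    "caterpillar",
    "balanced",
]


class TreeShape:
    """A canonical unlabeled rooted bifurcating tree shape.

    Instances are interned: isomorphic shapes are the identical object, so
    ``==`` is identity and the canonical key is stable across runs.

    Attributes
    ----------
    children : tuple
        Empty for a leaf, otherwise exactly two child shapes ordered by
        ``(num_leaves, canonical_key)``, smaller first.
    num_leaves : int
        Number of leaves in the shape.
    canonical_key : str
        Unlabeled newick string without the trailing semicolon; identical for
        isomorphic shapes, distinct otherwise.  A leaf has key ``""``.
    """

    __slots__ = ("children", "num_leaves", "canonical_key")

    _intern: dict[str, "TreeShape"] = {}

    def __new__(cls, children: tuple, num_leaves: int, canonical_key: str):
        obj = cls._intern.get(canonical_key)
        if obj is None:
            obj = object.__new__(cls)
            obj.children = children
            obj.num_leaves = num_leaves
            obj.canonical_key = canonical_key
            cls._intern[canonical_key] = obj
        return obj

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeShape({self.canonical_key + ';'!r}, leaves={self.num_leaves})"

    def __lt__(self, other: "TreeShape") -> bool:
        return (self.num_leaves, self.canonical_key) < (other.num_leaves, other.canonical_key)

    def postorder(self) -> Iterator["TreeShape"]:
        """Yield every subtree (with repetition for repeated nodes) post-order."""
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))


LEAF = TreeShape((), 1, "")


def make_shape(a: TreeShape, b: TreeShape) -> TreeShape:
    """Join two shapes under a new root, in canonical child order."""
    if b < a:
        a, b = b, a
    key = f"({a.canonical_key},{b.canonical_key})"
    return TreeShape((a, b), a.num_leaves + b.num_leaves, key)


def canonical_form(tree) -> TreeShape:
    """Canonicalize an arbitrary rooted strictly-bifurcating tree.

    Accepts a :class:`TreeShape` (idempotent), a nested pair structure
    (any object whose truthiness-of-children mirrors a binary tree: tuples or
    lists of length 2, with any non-sequence treated as a leaf), or a
    :class:`dendropy.Tree`.

    Raises
    ------
    ValueError
        If any internal node does not have exactly two children.
    """
    if isinstance(tree, TreeShape):
        return tree
    if isinstance(tree, dendropy.Tree):
        return _from_dendropy(tree.seed_node)
    return _from_nested(tree)


def _from_nested(obj) -> TreeShape:
    if isinstance(obj, (tuple, list)):
        if len(obj) != 2:
            raise ValueError(
                f"tree is not bifurcating: internal node with {len(obj)} children"
            )
        return make_shape(_from_nested(obj[0]), _from_nested(obj[1]))
    return LEAF


def _from_dendropy(node) -> TreeShape:
    kids = node.child_nodes()
    if not kids:
        return LEAF
    if len(kids) != 2:
        raise ValueError(
            f"tree is not strictly bifurcating: node with {len(kids)} children"
        )
    return make_shape(_from_dendropy(kids[0]), _from_dendropy(kids[1]))


def parse_newick(text: str) -> TreeShape:
    """Parse a newick string into a canonical shape.

    Leaf labels and branch lengths are accepted and discarded; the tree must be
    rooted and strictly bifurcating.
    """
    tree = dendropy.Tree.get(data=text, schema="newick")
    return canonical_form(tree)


def write_newick(shape: TreeShape) -> str:
    """Canonical unlabeled newick serialization, semicolon-terminated."""
    return shape.canonical_key + ";"


# ---------------------------------------------------------------------------
# Enumeration


_enum_cache: dict[int, tuple[TreeShape, ...]] = {1: (LEAF,)}


def _all_shapes(l: int) -> tuple[TreeShape, ...]:
    cached = _enum_cache.get(l)
    if cached is not None:
        return cached
    out: list[TreeShape] = []
    for k in range(1, l // 2 + 1):
        left = _all_shapes(k)
        right = _all_shapes(l - k)
        if k == l - k:
            for i, a in enumerate(left):
                for b in right[i:]:
                    out.append(make_shape(a, b))
        else:
            for a in left:
                for b in right:
                    out.append(make_shape(a, b))
    out.sort(key=lambda s: s.canonical_key)
    result = tuple(out)
    _enum_cache[l] = result
    return result


def count_shapes(l: int) -> int:
    """Number of shapes on ``l`` leaves (the Wedderburn-Etherington numbers),
    by the pairing recurrence — independent of the explicit enumeration."""
    if l < 1 or l != int(l):
        raise ValueError(f"leaf count must be a positive integer, got {l!r}")
    counts = [0, 1]
    for m in range(2, l + 1):
        total = sum(counts[k] * counts[m - k] for k in range(1, m // 2 + 1))
        if m % 2 == 0:
            h = counts[m // 2]
            total += h * (h + 1) // 2 - h * h  # unordered pairs when halves match
        counts.append(total)
    return counts[l]


@dataclass(frozen=True)
class ShapeSpace:
    """The complete, deterministically ordered set of shapes on ``leaf_count`` leaves.

    The ordering (lexicographic in canonical key) fixes the coordinate system
    of every statistic vector and matrix downstream.
    """

    leaf_count: int
    shapes: tuple[TreeShape, ...]
    index: dict[str, int] = field(repr=False)

    @property
    def num_shapes(self) -> int:
        return len(self.shapes)

    def __len__(self) -> int:
        return len(self.shapes)

    def __iter__(self):
        return iter(self.shapes)

    def index_of(self, shape: TreeShape) -> int:
        try:
            return self.index[shape.canonical_key]
        except KeyError:
            raise KeyError(
                f"shape {write_newick(shape)} is not in the space on "
                f"{self.leaf_count} leaves"
            ) from None

    def to_newick_lines(self) -> str:
        """One canonical newick per line, index-ordered."""
        return "\n".join(write_newick(s) for s in self.shapes) + "\n"


def enumerate_shapes(l: int) -> ShapeSpace:
    """Enumerate all isomorphism classes of rooted bifurcating shapes on ``l`` leaves.

    Shapes are generated by the recursive rule: every shape on ``l > 1`` leaves
    is an unordered pair of shapes on ``k`` and ``l - k`` leaves, 1 <= k <= l/2.
    """
    if not isinstance(l, int) or isinstance(l, bool) or l < 1:
        raise ValueError(f"leaf count must be a positive integer, got {l!r}")
    shapes = _all_shapes(l)
    index = {s.canonical_key: i for i, s in enumerate(shapes)}
    return ShapeSpace(leaf_count=l, shapes=shapes, index=index)


# ---------------------------------------------------------------------------
# Deterministic reference shapes


def caterpillar(l: int) -> TreeShape:
    """The completely asymmetric shape: every internal node has a leaf child."""
    if l < 1:
        raise ValueError("leaf count must be >= 1")
    shape = LEAF
    for _ in range(l - 1):
        shape = make_shape(shape, LEAF)
    return shape


def balanced(l: int) -> TreeShape:
    """The unique maximally balanced shape: |r - s| <= 1 at every internal node,
    built by splitting l into ceil(l/2) and floor(l/2) recursively."""
    if l < 1:
        raise ValueError("leaf count must be >= 1")
    if l == 1:
        return LEAF
    return make_shape(balanced(l // 2), balanced(l - l // 2))


# ---------------------------------------------------------------------------
# Random generation (Yule / PDA)


def random_shape(l: int, model: str = "yule", seed=None, rng: random.Random | None = None) -> TreeShape:
    """Draw a random shape on ``l`` leaves.

    model="yule": grow from a single lineage, splitting a uniformly chosen
    extant lineage at each step (equal-rates Markov model).
    model="pda": sample a labeled topology uniformly at random (every labeled
    rooted binary tree equally likely) and drop the labels, so a shape's
    probability is proportional to its number of labeled representatives.
    """
    if l < 2:
        if l == 1:
            return LEAF
        raise ValueError("leaf count must be >= 1")
    if rng is None:
        rng = random.Random(seed)
    if model == "yule":
        return _yule(l, rng)
    if model == "pda":
        return _pda(l, rng)
    raise ValueError(f"unknown model {model!r}; expected 'yule' or 'pda'")


def _yule(l: int, rng: random.Random) -> TreeShape:
    # Lineages are slots in a list; splitting replaces one slot by a cherry of
    # two new slots.  We record the split order and assemble bottom-up.
    children: list[list[int] | None] = [None]  # node id -> [left, right] or None (tip)
    tips = [0]
    while len(tips) < l:
        i = rng.randrange(len(tips))
        node = tips[i]
        a, b = len(children), len(children) + 1
        children.append(None)
        children.append(None)
        children[node] = [a, b]
        tips[i] = a
        tips.append(b)

    def build(node: int) -> TreeShape:
        kids = children[node]
        if kids is None:
            return LEAF
        return make_shape(build(kids[0]), build(kids[1]))

    return build(0)


def _pda(l: int, rng: random.Random) -> TreeShape:
    # Uniform labeled rooted binary topology: attach each new leaf by
    # subdividing a uniformly chosen edge, counting the edge above the root.
    # After k leaves there are 2k - 1 candidate edges, which yields the
    # (2l - 3)!! uniform distribution over labeled topologies.
    parent_of: list[int | None] = [None]
    children: list[list[int]] = [[]]
    root = 0

    def edges() -> list[int]:
        # each non-root node represents the edge above it; root represents the
        # virtual edge above the root
        return list(range(len(children)))

    for _ in range(l - 1):
        cand = edges()
        below = cand[rng.randrange(len(cand))]
        new_internal = len(children)
        children.append([])
        parent_of.append(None)
        new_leaf = len(children)
        children.append([])
        parent_of.append(new_internal)
        p = parent_of[below]
        if p is None:
            # subdividing the edge above the root: new internal node becomes root
            children[new_internal] = [below, new_leaf]
            parent_of[below] = new_internal
            root = new_internal
        else:
            children[p][children[p].index(below)] = new_internal
            parent_of[new_internal] = p
            children[new_internal] = [below, new_leaf]
            parent_of[below] = new_internal

    def build(node: int) -> TreeShape:
        kids = children[node]
        if not kids:
            return LEAF
        return make_shape(build(kids[0]), build(kids[1]))

    return build(root)
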