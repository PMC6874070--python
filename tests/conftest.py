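"""Shared fixtures: session-cached shape spaces, Cayley graphs and matrices.

Everything is generated programmatically; graphs and matrices for a given leaf
count are built once per session because several test modules share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import treeshape as ts


class SpaceCache:
    """Lazily built per-leaf-count artifacts, shared across the session."""

    def __init__(self) -> None:
        self._spaces: dict[int, ts.ShapeSpace] = {}
        self._graphs: dict[int, ts.CayleyGraph] = {}
        self._dists: dict[int, ts.DistanceMatrix] = {}
        self._lapl: dict = {}
        self._bounds_d: dict[int, ts.SpectralBounds] = {}
        self._bounds_l: dict[int, ts.SpectralBounds] = {}
        self._vectors: dict[tuple[int, str], ts.StatVector] = {}

    def space(self, l: int) -> ts.ShapeSpace:
        if l not in self._spaces:
            self._spaces[l] = ts.enumerate_shapes(l)
        return self._spaces[l]

    def graph(self, l: int) -> ts.CayleyGraph:
        if l not in self._graphs:
            self._graphs[l] = ts.build_cayley_graph(self.space(l))
        return self._graphs[l]

    def dist(self, l: int) -> ts.DistanceMatrix:
        if l not in self._dists:
            self._dists[l] = ts.distance_matrix(self.graph(l))
        return self._dists[l]

    def lap(self, l: int):
        if l not in self._lapl:
            self._lapl[l] = ts.laplacian(self.graph(l))
        return self._lapl[l]

    def bounds_d(self, l: int) -> ts.SpectralBounds:
        if l not in self._bounds_d:
            self._bounds_d[l] = ts.bounds_distance(self.dist(l))
        return self._bounds_d[l]

    def bounds_l(self, l: int) -> ts.SpectralBounds:
        if l not in self._bounds_l:
            self._bounds_l[l] = ts.bounds_laplacian(self.lap(l))
        return self._bounds_l[l]

    def vector(self, l: int, name: str) -> ts.StatVector:
        key = (l, name)
        if key not in self._vectors:
            self._vectors[key] = ts.statistic_vector(self.space(l), name)
        return self._vectors[key]

    def drop_dist(self, l: int) -> None:
        """Release a large distance matrix once its tests are done."""
        self._dists.pop(l, None)


@pytest.fixture(scope="session")
def cache() -> SpaceCache:
    return SpaceCache()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20231121)


CLASSICAL = ["colless", "sackin", "sigma2", "i2", "b1", "b2"]


@pytest.fixture(scope="session")
def classical_names() -> list[str]:
    return list(CLASSICAL)
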