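"""Growing self-organizing map (GSOM) engine.

A 2D-lattice SOM that inserts nodes at the map boundary when a node's
accumulated quantization error exceeds a spread-factor threshold
GT = -D * ln(SF), with D the input dimensionality.  Interior nodes over
threshold push their error outward to lattice neighbors instead of growing,
so insertion happens only at the edge of the map and the lattice stays a
connected, hole-free 4-neighborhood grid.

The same engine serves the semantic map (S-MAP, word feature vectors) and
the phonetic map (P-MAP, sensory training vectors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowingMap",
    "ItemAssignment",
    "init_map",
    "find_bmu",
    "adapt",
    "maybe_grow",
    "assign_items",
    "growth_threshold",
]

_NEIGH = ((1, 0), (-1, 0), (0, 1), (0, -1))


def growth_threshold(input_dim: int, spread_factor: float = 0.3) -> float:
    """Spread-factor growth threshold GT = -D * ln(SF)."""
    if not 0.0 < spread_factor < 1.0:
        raise ValueError("spread factor must lie in (0, 1)")
    return -float(input_dim) * float(np.log(spread_factor))


@dataclass
class ItemAssignment:
    """Best-matching node per item, with the inverse node -> items index."""

    bmu_of_item: np.ndarray                 # (n_items,) node ids
    items_of_node: dict[int, list[int]]

    @classmethod
    def from_bmus(cls, bmus: np.ndarray) -> "ItemAssignment":
        inv: dict[int, list[int]] = {}
        for i, b in enumerate(bmus):
            inv.setdefault(int(b), []).append(i)
        return cls(bmu_of_item=np.asarray(bmus), items_of_node=inv)


class GrowingMap:
    """2D-lattice growing SOM with per-node weights and accumulated error.

    Node ids are insertion-ordered and stable; arrays are over-allocated and
    grown in place so training does not reallocate on every insertion.
    """

    def __init__(self, input_dim: int, rng: np.random.Generator | None = None):
        if input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        self.input_dim = int(input_dim)
        self.rng = rng or np.random.default_rng()
        self._cap = 16
        self._w = np.zeros((self._cap, input_dim))
        self._pos = np.zeros((self._cap, 2), dtype=np.int64)
        self._err = np.zeros(self._cap)
        self._sqn = np.zeros(self._cap)
        self.n_nodes = 0
        self._pos_index: dict[tuple[int, int], int] = {}

    # -- views ------------------------------------------------------------

    @property
    def weights(self) -> np.ndarray:
        return self._w[: self.n_nodes]

    @property
    def positions(self) -> np.ndarray:
        return self._pos[: self.n_nodes]

    @property
    def errors(self) -> np.ndarray:
        return self._err[: self.n_nodes]

    # -- construction -----------------------------------------------------

    def _ensure_capacity(self, n: int) -> None:
        if n <= self._cap:
            return
        cap = max(n, 2 * self._cap)
        for name in ("_w", "_pos", "_err", "_sqn"):
            old = getattr(self, name)
            new = np.zeros((cap,) + old.shape[1:], dtype=old.dtype)
            new[: self.n_nodes] = old[: self.n_nodes]
            setattr(self, name, new)
        self._cap = cap

    def add_node(self, position: tuple[int, int], weights: np.ndarray) -> int:
        position = (int(position[0]), int(position[1]))
        if position in self._pos_index:
            raise ValueError(f"position {position} already occupied")
        self._ensure_capacity(self.n_nodes + 1)
        i = self.n_nodes
        self._w[i] = weights
        self._pos[i] = position
        self._err[i] = 0.0
        self._sqn[i] = float(weights @ weights)
        self._pos_index[position] = i
        self.n_nodes += 1
        return i

    def node_at(self, position: tuple[int, int]) -> int | None:
        return self._pos_index.get((int(position[0]), int(position[1])))

    def lattice_neighbors(self, node_id: int) -> list[int]:
        x, y = self._pos[node_id]
        out = []
        for dx, dy in _NEIGH:
            j = self._pos_index.get((int(x) + dx, int(y) + dy))
            if j is not None:
                out.append(j)
        return out

    def free_neighbor_positions(self, node_id: int) -> list[tuple[int, int]]:
        x, y = (int(v) for v in self._pos[node_id])
        return [
            (x + dx, y + dy)
            for dx, dy in _NEIGH
            if (x + dx, y + dy) not in self._pos_index
        ]

    def is_boundary(self, node_id: int) -> bool:
        return len(self.free_neighbor_positions(node_id)) > 0

    # -- core operations ---------------------------------------------------

    def find_bmu(self, x: np.ndarray) -> int:
        """Winner-takes-all node: minimal Euclidean distance, ties to the
        lowest node id."""
        x = np.asarray(x, dtype=np.float64)
        if x.shape != (self.input_dim,):
            raise ValueError(
                f"input has dimension {x.shape}, map expects ({self.input_dim},)"
            )
        d2 = ((self.weights - x) ** 2).sum(axis=1)
        return int(np.argmin(d2))

    def _bmu_fast(self, x: np.ndarray) -> tuple[int, float]:
        """Cached-norm BMU search used by the training loop; returns the
        winner and its squared distance to x."""
        n = self.n_nodes
        d2 = self._sqn[:n] - 2.0 * (self._w[:n] @ x)
        b = int(np.argmin(d2))
        return b, float(d2[b] + x @ x)

    def adapt(
        self,
        x: np.ndarray,
        bmu: int,
        lr: float,
        radius: float,
        sigma: float | None = None,
    ) -> None:
        """Move the BMU and lattice neighbors within `radius` toward x by
        lr * h(lattice distance); accumulate the BMU's quantization error."""
        x = np.asarray(x, dtype=np.float64)
        n = self.n_nodes
        w_b = self._w[bmu]
        diff = x - w_b
        self._err[bmu] += float(diff @ diff)
        if lr <= 0.0:
            return
        sigma = sigma if sigma is not None else max(radius / 2.0, 0.5)
        dpos = np.abs(self._pos[:n] - self._pos[bmu]).sum(axis=1)
        idx = np.nonzero(dpos <= radius)[0]
        h = lr * np.exp(-(dpos[idx] ** 2) / (2.0 * sigma * sigma))
        h[idx == bmu] = lr
        self._w[idx] += h[:, None] * (x - self._w[idx])
        self._sqn[idx] = np.einsum("ij,ij->i", self._w[idx], self._w[idx])

    def maybe_grow(
        self,
        threshold: float,
        node_ids: np.ndarray | list[int] | None = None,
        redistribution: float = 0.125,
        max_new_nodes: int | None = None,
    ) -> list[int]:
        """Grow wherever accumulated error exceeds the threshold.

        Boundary nodes spawn new nodes in their free 4-neighbor positions
        (weights extrapolated from the opposite neighbor, else copy+noise)
        and reset their error.  Interior nodes reset to half the threshold
        and push `redistribution` of their error to each lattice neighbor
        (half the excess in total, so chains dissipate), letting excess error
        migrate to the boundary; the chain is followed within this call.
        `max_new_nodes` caps insertions (per-cycle growth budget).
        """
        if node_ids is None:
            pending = list(np.nonzero(self._err[: self.n_nodes] > threshold)[0])
        else:
            pending = [i for i in node_ids if self._err[i] > threshold]
        new_nodes: list[int] = []
        guard = 0
        while pending:
            if max_new_nodes is not None and len(new_nodes) >= max_new_nodes:
                break
            guard += 1
            if guard > 10000:
                break
            i = int(pending.pop(0))
            if self._err[i] <= threshold:
                continue
            free = self.free_neighbor_positions(i)
            if free:
                x, y = (int(v) for v in self._pos[i])
                for px, py in free:
                    ox, oy = 2 * x - px, 2 * y - py  # opposite neighbor
                    j = self._pos_index.get((ox, oy))
                    if j is not None:
                        w_new = 2.0 * self._w[i] - self._w[j]
                    else:
                        w_new = self._w[i] + 0.01 * self.rng.standard_normal(
                            self.input_dim
                        )
                    new_nodes.append(self.add_node((px, py), w_new))
                self._err[i] = 0.0
            else:
                excess = self._err[i]
                self._err[i] = 0.5 * threshold
                for j in self.lattice_neighbors(i):
                    self._err[j] += redistribution * excess
                    if self._err[j] > threshold:
                        pending.append(j)
        return new_nodes

    def decay_errors(self, factor: float) -> None:
        """Forgetting factor: attenuate accumulated errors (applied once per
        training cycle so only sustained error drives growth)."""
        self._err[: self.n_nodes] *= factor

    def assign(self, vectors: np.ndarray) -> ItemAssignment:
        """BMU of every row of `vectors`, plus the inverse index."""
        vectors = np.asarray(vectors, dtype=np.float64)
        if vectors.ndim != 2 or vectors.shape[0] == 0:
            raise ValueError("vectors must be a nonempty 2D array")
        n = self.n_nodes
        d2 = (
            self._sqn[:n][None, :]
            - 2.0 * vectors @ self._w[:n].T
        )
        return ItemAssignment.from_bmus(np.argmin(d2, axis=1))


# ---------------------------------------------------------------------------
# functional wrappers matching the operation-level interface


def init_map(
    input_dim: int,
    rng: np.random.Generator,
    mean: np.ndarray | None = None,
    noise: float = 0.02,
) -> GrowingMap:
    """Initial 2x2 lattice with weights as small seeded noise around `mean`."""
    m = GrowingMap(input_dim, rng=rng)
    mu = np.zeros(input_dim) if mean is None else np.asarray(mean, dtype=np.float64)
    for pos in [(0, 0), (0, 1), (1, 0), (1, 1)]:
        m.add_node(pos, mu + noise * rng.standard_normal(input_dim))
    return m


def find_bmu(gmap: GrowingMap, x: np.ndarray) -> int:
    return gmap.find_bmu(x)


def adapt(gmap: GrowingMap, x: np.ndarray, bmu: int, lr: float, radius: float) -> None:
    gmap.adapt(x, bmu, lr, radius)


def maybe_grow(gmap: GrowingMap, threshold: float) -> list[int]:
    return gmap.maybe_grow(threshold)


def assign_items(gmap: GrowingMap, vectors: np.ndarray) -> ItemAssignment:
    return gmap.assign(vectors)
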