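"""Growing self-organizing lattice (GSOM).

A growing self-organizing map starts from a 2x2 block of nodes on an open
integer lattice and adds nodes at *boundary* positions (occupied cells with at
least one free von-Neumann neighbour) whenever a best-matching unit's
accumulated quantization error exceeds a growth threshold.  Weight updates are
the usual Kohonen rule with a Gaussian neighbourhood kernel evaluated on the
lattice distance between a node and the BMU.

Coordinates are ``(row, col)`` integer pairs; the initial block occupies
(0,0), (0,1), (1,0), (1,1) and the map may extend to negative coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger("igsom")

GridPosition = tuple[int, int]

#: von-Neumann neighbourhood offsets, in (row, col) lexicographic order.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = ((-1, 0), (0, -1), (0, 1), (1, 0))


def adjacent_positions(pos: GridPosition) -> list[GridPosition]:
    """The four lattice positions directly adjacent to ``pos``, in (row, col) order."""
    r, c = pos
    return [(r + dr, c + dc) for dr, dc in NEIGHBOR_OFFSETS]


@dataclass
class PhaseParams:
    """Learning/growth parameter bundle for one training regime.

    Defaults are the basic-growing (and reviewing) settings; the reinforcing
    regimes raise the initial learning rate to 0.8 and lower the growth
    threshold to 1.

    Parameters
    ----------
    initial_learning_rate : float
        R_learn at the start of each token presentation, in (0, 1].
    initial_neighborhood : float
        Initial Gaussian neighbourhood size sigma, in lattice units.
    growth_threshold : float
        T_grow; a boundary BMU whose accumulated error exceeds it spawns nodes.
    alpha, beta : float
        Per-iteration multiplicative decay factors of the learning rate and of
        sigma respectively, both in (0, 1).
    gamma : float
        Error-distribution factor: a saturated interior BMU pushes
        ``gamma * growth_threshold`` of error onto each direct neighbour.
    learning_constant_q : float
        The constant Q in phi(n) = 1 - Q/n modulating learning-rate decay by
        the current node count; 3.8 because maps start with four nodes.
    """

    initial_learning_rate: float = 0.5
    initial_neighborhood: float = 2.0
    growth_threshold: float = 2.0
    alpha: float = 0.9
    beta: float = 0.9
    gamma: float = 0.5
    learning_constant_q: float = 3.8

    def __post_init__(self) -> None:
        if not 0.0 < self.initial_learning_rate <= 1.0:
            raise ValueError("initial_learning_rate must be in (0, 1]")
        if self.initial_neighborhood <= 0:
            raise ValueError("initial_neighborhood must be positive")
        if self.growth_threshold <= 0:
            raise ValueError("growth_threshold must be positive")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly between 0 and 1")
        if self.learning_constant_q <= 0:
            raise ValueError("learning_constant_q must be positive")


@dataclass
class MapNode:
    """One lattice cell: a weight vector plus its accumulated quantization error."""

    position: GridPosition
    weight: np.ndarray
    accumulated_error: float = 0.0


class GrowingMap:
    """An open-grid collection of :class:`MapNode` that can only grow.

    Nodes are keyed by lattice position.  The occupied region starts as a
    2x2 block and remains 4-connected because new nodes are only ever added
    adjacent to an existing (boundary) node.
    """

    def __init__(self, input_dimension: int) -> None:
        if input_dimension < 1:
            raise ValueError("input_dimension must be a positive integer")
        self.input_dimension = int(input_dimension)
        self.nodes: dict[GridPosition, MapNode] = {}
        # cache: (sorted positions, weight matrix, position -> row index)
        self._cache: tuple[list[GridPosition], np.ndarray, dict[GridPosition, int]] | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def initialize(cls, input_dimension: int, seed: int | np.random.Generator) -> "GrowingMap":
        """Create the initial 2x2 map with uniform-random weights in [0, 1]."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        m = cls(input_dimension)
        for pos in ((0, 0), (0, 1), (1, 0), (1, 1)):
            m._add_node(pos, rng.random(m.input_dimension))
        return m

    def _add_node(self, pos: GridPosition, weight: np.ndarray) -> MapNode:
        if pos in self.nodes:
            raise ValueError(f"position {pos} already occupied")
        node = MapNode(pos, np.asarray(weight, dtype=float), 0.0)
        self.nodes[pos] = node
        self._cache = None
        return node

    # -- bookkeeping -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, pos: GridPosition) -> bool:
        return tuple(pos) in self.nodes

    def __iter__(self) -> Iterator[MapNode]:
        for pos in sorted(self.nodes):
            yield self.nodes[pos]

    def _matrix(self) -> tuple[list[GridPosition], np.ndarray, dict[GridPosition, int]]:
        if self._cache is None:
            positions = sorted(self.nodes)
            weights = np.stack([self.nodes[p].weight for p in positions])
            self._cache = (positions, weights, {p: i for i, p in enumerate(positions)})
        return self._cache

    def weight_matrix(self) -> tuple[list[GridPosition], np.ndarray]:
        """Lexicographically sorted positions and the matching weight matrix."""
        positions, weights, _ = self._matrix()
        return positions, weights

    def _check_vector(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.input_dimension,):
            raise ValueError(
                f"input vector has shape {x.shape}, expected ({self.input_dimension},)"
            )
        return x

    # -- core operations ---------------------------------------------------

    def find_bmu(self, x: np.ndarray) -> tuple[GridPosition, float]:
        """Best-matching unit: the node minimizing Euclidean distance to ``x``.

        Ties are broken by lexicographic (row, col) order.
        """
        x = self._check_vector(x)
        positions, weights, _ = self._matrix()
        dists = cdist(x[None, :], weights)[0]
        i = int(np.argmin(dists))  # argmin returns the first (lexicographic) minimum
        return positions[i], float(dists[i])

    def is_boundary(self, pos: GridPosition) -> bool:
        """True iff at least one of the four adjacent positions is unoccupied."""
        pos = tuple(pos)
        if pos not in self.nodes:
            raise ValueError(f"position {pos} is not occupied")
        return any(p not in self.nodes for p in adjacent_positions(pos))

    def boundary_ratio(self) -> float:
        """Fraction of nodes that are boundary nodes."""
        return sum(self.is_boundary(p) for p in self.nodes) / len(self.nodes)

    def new_node_weight(self, bmu: GridPosition, new_pos: GridPosition) -> np.ndarray:
        """Weight for a node about to grow at ``new_pos`` next to ``bmu``.

        Extrapolates across the BMU from the opposite neighbour when it
        exists (w = 2*w_bmu - w_opp), falls back to extrapolating from the
        first other occupied direct neighbour in (row, col) order, and to a
        plain copy of the BMU weight when the BMU is otherwise isolated.
        Components are clamped to [0, 1].
        """
        bmu = tuple(bmu)
        new_pos = tuple(new_pos)
        if bmu not in self.nodes:
            raise ValueError(f"bmu {bmu} is not occupied")
        if new_pos in self.nodes:
            raise ValueError(f"new position {new_pos} is already occupied")
        if new_pos not in adjacent_positions(bmu):
            raise ValueError(f"{new_pos} is not adjacent to {bmu}")
        w_bmu = self.nodes[bmu].weight
        opposite = (2 * bmu[0] - new_pos[0], 2 * bmu[1] - new_pos[1])
        if opposite in self.nodes:
            w = 2.0 * w_bmu - self.nodes[opposite].weight
        else:
            others = [p for p in adjacent_positions(bmu) if p in self.nodes]
            if others:
                w = 2.0 * w_bmu - self.nodes[others[0]].weight
            else:
                w = w_bmu.copy()
        return np.clip(w, 0.0, 1.0)

    def grow(self, bmu: GridPosition) -> list[GridPosition]:
        """Grow new nodes at every free position adjacent to a boundary BMU.

        New weights are extrapolated from the map state *before* any insertion,
        new nodes start with zero accumulated error, and the BMU's accumulated
        error is reset to zero.  Returns the added positions in (row, col) order.
        """
        bmu = tuple(bmu)
        if not self.is_boundary(bmu):
            raise ValueError(f"grow called on non-boundary node {bmu}")
        free = [p for p in adjacent_positions(bmu) if p not in self.nodes]
        new_weights = [self.new_node_weight(bmu, p) for p in free]
        for pos, w in zip(free, new_weights):
            self._add_node(pos, w)
        self.nodes[bmu].accumulated_error = 0.0
        return free

    def update_weights(
        self, bmu: GridPosition, x: np.ndarray, learning_rate: float, neighborhood_size: float
    ) -> None:
        """Kohonen update of the BMU and its lattice neighbourhood.

        Every occupied node at lattice (Euclidean grid) distance
        d <= ceil(neighborhood_size) from the BMU moves toward ``x`` by
        ``learning_rate * exp(-d^2 / (2 sigma^2))``; the BMU itself has d = 0.
        """
        bmu = tuple(bmu)
        if bmu not in self.nodes:
            raise ValueError(f"bmu {bmu} is not occupied")
        x = self._check_vector(x)
        if neighborhood_size < 1:
            raise ValueError("neighborhood_size must be >= 1")
        if not 0.0 < learning_rate <= 1.0:
            raise ValueError("learning_rate must be in (0, 1]")
        cutoff = math.ceil(neighborhood_size)
        two_sigma_sq = 2.0 * neighborhood_size**2
        cache = self._cache
        for dr in range(-cutoff, cutoff + 1):
            for dc in range(-cutoff, cutoff + 1):
                d_sq = dr * dr + dc * dc
                if d_sq > cutoff * cutoff:
                    continue
                pos = (bmu[0] + dr, bmu[1] + dc)
                node = self.nodes.get(pos)
                if node is None:
                    continue
                h = math.exp(-d_sq / two_sigma_sq)
                node.weight += learning_rate * h * (x - node.weight)
                if cache is not None:
                    cache[1][cache[2][pos]] = node.weight

    def accumulate_error(self, bmu: GridPosition, distance: float) -> None:
        """Add a BMU-to-input quantization distance onto the BMU's error."""
        bmu = tuple(bmu)
        if bmu not in self.nodes:
            raise ValueError(f"bmu {bmu} is not occupied")
        if distance < 0:
            raise ValueError("distance must be non-negative")
        self.nodes[bmu].accumulated_error += float(distance)

    def distribute_error(self, bmu: GridPosition, params: PhaseParams) -> None:
        """Spread a saturated interior BMU's error onto its neighbours.

        The BMU's error drops to T_grow / 2 and every occupied direct
        neighbour gains gamma * T_grow.  Only valid for non-boundary nodes
        (boundary nodes grow instead).
        """
        bmu = tuple(bmu)
        if self.is_boundary(bmu):
            raise ValueError(f"distribute_error called on boundary node {bmu}")
        t = params.growth_threshold
        self.nodes[bmu].accumulated_error = t / 2.0
        for pos in adjacent_positions(bmu):
            node = self.nodes.get(pos)
            if node is not None:
                node.accumulated_error += params.gamma * t


# -- schedule decays -------------------------------------------------------

#: defensive floor for phi(n) = 1 - Q/n when n <= Q (cannot occur after init).
PHI_FLOOR = 0.01


def decay_learning_rate(rate: float, map_: GrowingMap, params: PhaseParams) -> float:
    """R_learn(t+1) = alpha * phi(n) * R_learn(t) with phi(n) = 1 - Q/n(t)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    n = len(map_)
    phi = 1.0 - params.learning_constant_q / n
    if phi <= 0:
        logger.warning("phi(n) non-positive for n=%d, Q=%g; clamping to %g",
                       n, params.learning_constant_q, PHI_FLOOR)
        phi = PHI_FLOOR
    return params.alpha * phi * rate


def decay_neighborhood(sigma: float, params: PhaseParams) -> float:
    """sigma(t) = beta * sigma(t-1)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return params.beta * sigma
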