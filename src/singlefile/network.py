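"""From movement orders to the aggregate social graph.

Each single-file movement yields a binary adjacency matrix marking pairs of
agents that moved consecutively (the adjacency of a Hamiltonian path over
the agents). Summing these over the ``n_exp`` observed movements gives the
weighted association matrix passed to community detection: the weight of
edge {i, j} counts how often i and j were neighbours in file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .serialize import SingleFileMovement


class MalformedMovementError(ValueError):
    """A movement is not a permutation of 1..N."""


class DimensionMismatchError(ValueError):
    """Adjacency matrices of different sizes cannot be aggregated."""


@dataclass
class AggregateGraph:
    """Weighted symmetric adjacency over agents 1..N (integer counts).

    ``M`` is half the total weight; for aggregates of full movements it
    equals ``(N - 1) * n_exp``. ``strengths`` are the weighted degrees k_i.
    """

    weights: np.ndarray  # (N, N) symmetric, zero diagonal, non-negative ints

    @property
    def N(self) -> int:
        return self.weights.shape[0]

    @property
    def total_weight(self) -> int:
        """Sum of all matrix entries, 2M."""
        return int(self.weights.sum())

    @property
    def M(self) -> float:
        return self.total_weight / 2

    @property
    def strengths(self) -> np.ndarray:
        """Weighted degree k_i per agent (row sums), index 0 = agent 1."""
        return self.weights.sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        """Weighted simple graph on nodes 1..N; zero-weight pairs omitted."""
        g = nx.Graph()
        g.add_nodes_from(range(1, self.N + 1))
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        g.add_weighted_edges_from(
            (int(i) + 1, int(j) + 1, int(self.weights[i, j])) for i, j in zip(ii, jj)
        )
        return g

    def edge_list(self) -> list[tuple[int, int, int]]:
        """Sorted (source, target, weight) triples with source < target."""
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        return [
            (int(i) + 1, int(j) + 1, int(self.weights[i, j])) for i, j in zip(ii, jj)
        ]


def movement_to_adjacency(movement: SingleFileMovement) -> np.ndarray:
    """Binary N x N adjacency of one movement: a_ij = 1 iff i, j consecutive."""
    if not movement.is_permutation():
        raise MalformedMovementError(
            "movement order is not a permutation of 1..N: "
            f"{movement.order.tolist()}"
        )
    N = movement.N
    a = np.zeros((N, N), dtype=np.int64)
    idx = movement.order - 1
    a[idx[:-1], idx[1:]] = 1
    a[idx[1:], idx[:-1]] = 1
    return a


def aggregate(adjacencies: Sequence[np.ndarray]) -> AggregateGraph:
    """Entrywise sum of per-movement adjacencies."""
    adjacencies = list(adjacencies)
    if not adjacencies:
        raise DimensionMismatchError("no adjacencies to aggregate")
    N = adjacencies[0].shape[0]
    total = np.zeros((N, N), dtype=np.int64)
    for a in adjacencies:
        if a.shape != (N, N):
            raise DimensionMismatchError(
                f"expected shape {(N, N)}, got {a.shape}"
            )
        total += a
    return AggregateGraph(weights=total)


def aggregate_movements(movements: Iterable[SingleFileMovement]) -> AggregateGraph:
    """Aggregate directly from movement orders (single pass, no N x N temporaries)."""
    total: np.ndarray | None = None
    for mov in movements:
        if not mov.is_permutation():
            raise MalformedMovementError(
                f"movement order is not a permutation of 1..N: {mov.order.tolist()}"
            )
        if total is None:
            total = np.zeros((mov.N, mov.N), dtype=np.int64)
        elif total.shape[0] != mov.N:
            raise DimensionMismatchError(
                f"movement of length {mov.N} in an aggregate of size {total.shape[0]}"
            )
        idx = mov.order - 1
        np.add.at(total, (idx[:-1], idx[1:]), 1)
        np.add.at(total, (idx[1:], idx[:-1]), 1)
    if total is None:
        raise DimensionMismatchError("no movements to aggregate")
    return AggregateGraph(weights=total)
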