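"""Weighted modularity and community detection on the aggregate graph.

Modularity compares the within-community weight against a configuration-model
null that preserves node strengths:

    Q = (1/2M) * sum_ij (a_ij - k_i k_j / 2M) * delta(C(i), C(j))

Communities are found with the Louvain heuristic (greedy single-node moves
followed by community aggregation, iterated to convergence at resolution 1);
for small graphs an exhaustive set-partition oracle gives the exact optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .network import AggregateGraph
from .params import ParameterError

BRUTEFORCE_NODE_LIMIT = 10


class UndefinedModularityError(ValueError):
    """Modularity is undefined on an edgeless graph (2M = 0)."""


@dataclass
class Partition:
    """A hard community assignment over agents 1..N.

    ``labels[k]`` is the community of agent ``k + 1``. Labels are
    canonicalized to ``1..n_eval`` by first appearance in agent-ID order, so
    partitions are comparable across runs regardless of how the detector
    happened to name its communities.
    """

    labels: np.ndarray

    @property
    def N(self) -> int:
        return self.labels.shape[0]

    @property
    def n_eval(self) -> int:
        """Number of distinct communities."""
        return int(np.unique(self.labels).size)

    def community_of(self, agent_id: int) -> int:
        if not 1 <= agent_id <= self.N:
            raise ParameterError(f"agent ID {agent_id} not in 1..{self.N}")
        return int(self.labels[agent_id - 1])

    def members_of(self, label: int) -> np.ndarray:
        """1-based agent IDs carrying a community label."""
        members = np.flatnonzero(self.labels == label) + 1
        if members.size == 0:
            raise ParameterError(f"community label {label} not present")
        return members

    def as_dict(self) -> dict[int, int]:
        return {k + 1: int(self.labels[k]) for k in range(self.N)}

    @staticmethod
    def _canonicalize(raw: np.ndarray) -> np.ndarray:
        mapping: dict[int, int] = {}
        out = np.empty_like(raw)
        for k, lab in enumerate(raw):
            lab = int(lab)
            if lab not in mapping:
                mapping[lab] = len(mapping) + 1
            out[k] = mapping[lab]
        return out

    @classmethod
    def from_labels(cls, raw: Iterable[int]) -> "Partition":
        return cls(labels=cls._canonicalize(np.asarray(list(raw), dtype=np.int64)))

    @classmethod
    def from_mapping(cls, community_of: Mapping[int, int], N: int) -> "Partition":
        raw = np.empty(N, dtype=np.int64)
        for aid in range(1, N + 1):
            if aid not in community_of:
                raise ParameterError(f"agent {aid} missing from partition")
            raw[aid - 1] = community_of[aid]
        return cls(labels=cls._canonicalize(raw))

    @classmethod
    def from_communities(cls, communities: Iterable[Iterable[int]], N: int) -> "Partition":
        mapping: dict[int, int] = {}
        for lab, comm in enumerate(communities):
            for aid in comm:
                mapping[int(aid)] = lab
        return cls.from_mapping(mapping, N)


def modularity(graph: AggregateGraph, partition: Partition) -> float:
    """Newman weighted modularity Q of a partition; Q in [-0.5, 1)."""
    if partition.N != graph.N:
        raise ParameterError(
            f"partition covers {partition.N} nodes, graph has {graph.N}"
        )
    two_m = graph.total_weight
    if two_m == 0:
        raise UndefinedModularityError("graph has no edges; modularity undefined")
    a = graph.weights
    k = graph.strengths
    c = partition.labels
    same = c[:, None] == c[None, :]
    return float(((a - np.outer(k, k) / two_m)[same]).sum() / two_m)


def louvain(graph: AggregateGraph, seed: int) -> Partition:
    """Louvain community detection at resolution 1, deterministic given seed."""
    two_m = graph.total_weight
    if two_m == 0:
        raise UndefinedModularityError("graph has no edges; cannot cluster")
    g = graph.to_networkx()
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=1.0, seed=int(seed)
    )
    return Partition.from_communities(comms, graph.N)


def _set_partitions(items: list[int]):
    # Recursive enumeration of all set partitions (deterministic order).
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def best_partition_bruteforce(graph: AggregateGraph) -> Partition:
    """Exact maximum-modularity partition by exhaustive enumeration.

    Only feasible for graphs of up to ``BRUTEFORCE_NODE_LIMIT`` nodes (the
    number of set partitions grows as the Bell numbers); intended as a test
    oracle, not a production detector. Ties in Q break toward the first
    partition in enumeration order.
    """
    N = graph.N
    if N > BRUTEFORCE_NODE_LIMIT:
        raise ParameterError(
            f"brute-force search limited to {BRUTEFORCE_NODE_LIMIT} nodes, got {N}"
        )
    if graph.total_weight == 0:
        if N == 1:
            return Partition.from_labels([1])
        raise UndefinedModularityError("graph has no edges; modularity undefined")
    best_q = -np.inf
    best: Partition | None = None
    for blocks in _set_partitions(list(range(1, N + 1))):
        part = Partition.from_communities(blocks, N)
        q = modularity(graph, part)
        if q > best_q:
            best_q = q
            best = part
    assert best is not None
    return best
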