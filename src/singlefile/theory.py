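"""Analytic checks on why modularity recovers the latent subgroups.

In the separated regime (sigma_I >> sigma_D) every movement lists each
subgroup as one contiguous block, so the aggregate graph is n_I dense blocks
tied together by a few between-block edges. Merging two true clusters C_p,
C_q changes modularity by

    Q' - Q = m/M - K_p K_q / (2 M^2)

where m is the total weight between the two clusters, K_p and K_q the total
weights incident to each, and M the graph half-weight. Whenever
m < K_p K_q / 2M the true partition beats every single merge, which is the
regime in which greedy modularity optimization is expected to stop at the
true clustering.

The expected between-cluster weight under uniformly random block orderings
is reported in two variants: the "as-printed" value n_exp/n_I (total
between-block weight divided by the number of *ordered* cluster pairs) and
an exhaustive-enumeration value for a specific unordered pair, which is
twice that (for n_I = 2 the unique pair is adjacent in every movement).
Both are surfaced rather than silently reconciled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .communities import Partition, modularity
from .network import AggregateGraph
from .params import ParameterError, SimulationParams
from .population import AgentPopulation

ENUMERATION_LIMIT = 8  # n_I! orderings are enumerated up to here


@dataclass
class MergeDelta:
    """Ingredients and value of the two-cluster merge modularity change."""

    m: float
    K_p: float
    K_q: float
    M: float
    delta: float


@dataclass
class ExpectedBetweenWeight:
    """Expected between-cluster weight for one unordered cluster pair."""

    as_printed: float  # n_exp / n_I (ordered-pair normalization)
    enumeration: float  # brute force over block orderings (unordered pair)


@dataclass
class SufficientConditionReport:
    """The merge-resistance bound and how the expected m compares to it."""

    M: float
    bound: float  # (n_D n_exp)^2 / 2M
    prefactor: float  # (n_D/2) * n_D / ((n_D+1) - 1/n_I)
    expected_m: ExpectedBetweenWeight | None
    holds_as_printed: bool | None
    holds_enumeration: bool | None


def _cluster_weights(
    graph: AggregateGraph, members_p: np.ndarray, members_q: np.ndarray
) -> tuple[float, float, float]:
    w = graph.weights
    ip = members_p - 1
    iq = members_q - 1
    m = float(w[np.ix_(ip, iq)].sum())
    K_p = float(graph.strengths[ip].sum())
    K_q = float(graph.strengths[iq].sum())
    return m, K_p, K_q


def merge_modularity_delta(
    graph: AggregateGraph, partition: Partition, p: int, q: int
) -> MergeDelta:
    """Modularity change Q' - Q from merging communities p and q.

    Equals the direct difference of the modularity of the merged and the
    original partition (to ~1e-15; both routes are exact in real arithmetic).
    """
    if p == q:
        raise ParameterError("cannot merge a community with itself")
    members_p = partition.members_of(p)  # raises on missing label
    members_q = partition.members_of(q)
    m, K_p, K_q = _cluster_weights(graph, members_p, members_q)
    M = graph.M
    if M == 0:
        raise ParameterError("edgeless graph")
    delta = m / M - (K_p * K_q) / (2 * M * M)
    return MergeDelta(m=m, K_p=K_p, K_q=K_q, M=M, delta=delta)


def expected_between_weight(n_I: int, n_exp: int) -> ExpectedBetweenWeight:
    """Expected aggregate weight between one unordered pair of true clusters.

    Assumes fully separated subgroups, so each movement is a uniformly random
    ordering of n_I contiguous blocks contributing n_I - 1 between-block
    adjacencies. The enumeration variant averages, over all n_I! orderings,
    the number of times a fixed pair of blocks is adjacent, times n_exp
    (exhaustive up to n_I = 8; beyond that the symmetry-exact closed form
    2 n_exp / n_I is used, which the enumeration reproduces exactly).
    """
    if n_I < 2:
        raise ParameterError("n_I must be >= 2: no between-subgroup pair exists")
    if n_exp < 1:
        raise ParameterError(f"n_exp must be >= 1, got {n_exp}")
    as_printed = n_exp / n_I
    if n_I <= ENUMERATION_LIMIT:
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n_I)):
            hits += sum(
                1
                for a, b in zip(perm[:-1], perm[1:])
                if {a, b} == {0, 1}  # the fixed pair; any pair is equivalent
            )
            total += 1
        assert total == math.factorial(n_I)
        enumeration = n_exp * hits / total
    else:
        enumeration = 2 * n_exp / n_I
    return ExpectedBetweenWeight(as_printed=as_printed, enumeration=enumeration)


def sufficient_condition_bound(params: SimulationParams) -> SufficientConditionReport:
    """Bound (n_D n_exp)^2 / 2M under which every single merge lowers Q.

    Also reports the bound rewritten as prefactor * (n_exp / n_I), with
    prefactor = (n_D/2) * n_D / ((n_D+1) - 1/n_I) (approximately n_D/2 for
    moderate n_D), and whether each expected-m variant falls below the bound.
    """
    N = params.N
    if N < 2:
        raise ParameterError("N must be >= 2")
    M = (N - 1) * params.n_exp
    n_D = params.n_D
    bound = (n_D * params.n_exp) ** 2 / (2 * M)
    if n_D == 0:
        prefactor = 0.0
    else:
        prefactor = (n_D / 2) * n_D / ((n_D + 1) - 1 / params.n_I)
    expected = None
    holds_printed = None
    holds_enum = None
    if params.n_I >= 2:
        expected = expected_between_weight(params.n_I, params.n_exp)
        holds_printed = expected.as_printed < bound
        holds_enum = expected.enumeration < bound
    return SufficientConditionReport(
        M=float(M),
        bound=float(bound),
        prefactor=float(prefactor),
        expected_m=expected,
        holds_as_printed=holds_printed,
        holds_enumeration=holds_enum,
    )


def empirical_between_weight(
    graph: AggregateGraph, population: AgentPopulation, p: int, q: int
) -> tuple[float, float, float]:
    """Measured (m, K_p, K_q) across the true subgroup boundary p|q."""
    if p == q:
        raise ParameterError("subgroups must differ")
    members_p = population.members_of(p)
    members_q = population.members_of(q)
    if graph.N != population.N:
        raise ParameterError(
            f"graph has {graph.N} nodes but population has {population.N} agents"
        )
    return _cluster_weights(graph, members_p, members_q)
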