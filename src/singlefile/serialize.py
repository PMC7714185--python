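"""Greedy nearest-neighbour serialization into single-file movements.

A single-file movement reduces a collective departure to the order in which
agents move: a uniformly random *initiator* moves first, and thereafter the
next mover is always the not-yet-moved agent nearest (Euclidean) to the
*last* mover. The result is a permutation of all agent IDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterError
from .population import AgentPopulation


@dataclass
class SingleFileMovement:
    """An ordered progression of all agents; ``order[0]`` is the initiator."""

    order: np.ndarray  # 1-based agent IDs, a permutation of 1..N

    @property
    def N(self) -> int:
        return self.order.shape[0]

    @property
    def initiator(self) -> int:
        return int(self.order[0])

    def is_permutation(self) -> bool:
        return np.array_equal(np.sort(self.order), np.arange(1, self.N + 1))

    def __eq__(self, other) -> bool:
        return isinstance(other, SingleFileMovement) and np.array_equal(
            self.order, other.order
        )


def serialize(
    population: AgentPopulation,
    rng: np.random.Generator,
    initiator: int | None = None,
) -> SingleFileMovement:
    """Produce one single-file movement from a population snapshot.

    Parameters
    ----------
    population : AgentPopulation
    rng : numpy Generator
        Used only to draw the initiator when none is forced.
    initiator : int, optional
        1-based agent ID of the first mover; a replay/testing hook. When
        absent the initiator is drawn uniformly over all N agents.

    Notes
    -----
    Distance ties (probability zero under the continuous placement model)
    break toward the lowest agent ID, so replays are deterministic.
    """
    N = population.N
    if N < 1:
        raise ParameterError("population is empty")
    if initiator is None:
        start = int(rng.integers(0, N))
    else:
        if not 1 <= int(initiator) <= N:
            raise ParameterError(f"initiator {initiator} not a valid agent ID (1..{N})")
        start = int(initiator) - 1

    # Squared distances preserve the argmin; argmin's first-occurrence rule
    # implements the lowest-ID tie-break.
    pts = population.locations
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)

    order = np.empty(N, dtype=np.int64)
    moved = np.zeros(N, dtype=bool)
    cur = start
    order[0] = cur + 1
    moved[cur] = True
    for i in range(1, N):
        row = d2[cur].copy()
        row[moved] = np.inf
        cur = int(np.argmin(row))
        order[i] = cur + 1
        moved[cur] = True
    return SingleFileMovement(order=order)
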