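"""Clustered 2-D agent populations.

The latent social structure is a two-level Gaussian hierarchy: independenter
``i`` is drawn from a circular bivariate normal centred at the origin with
per-axis SD ``sigma_I``; each of its ``n_D`` dependers is drawn from a
circular bivariate normal centred at that independenter with per-axis SD
``sigma_D``. Agent IDs are 1-based: independenters occupy IDs ``1..n_I``;
the j-th depender of subgroup i has ID ``n_I + (i-1)*n_D + j``, so dependers
are listed after all independenters, grouped by subgroup.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .params import ParameterError, SimulationParams

ROLE_INDEPENDENTER = "independenter"
ROLE_DEPENDER = "depender"


@dataclass
class AgentPopulation:
    """N agents in the plane with their true (latent) subgroup labels.

    Attributes
    ----------
    n_I, n_D : int
        Subgroup count and dependers per subgroup.
    locations : ndarray, shape (N, 2)
        Coordinates; row ``k`` is agent ID ``k + 1``.
    subgroup : ndarray, shape (N,)
        Subgroup ID in ``1..n_I`` per agent.
    """

    n_I: int
    n_D: int
    locations: np.ndarray
    subgroup: np.ndarray

    @property
    def N(self) -> int:
        return self.locations.shape[0]

    def role_of(self, agent_id: int) -> str:
        self._check_id(agent_id)
        return ROLE_INDEPENDENTER if agent_id <= self.n_I else ROLE_DEPENDER

    def subgroup_of(self, agent_id: int) -> int:
        self._check_id(agent_id)
        return int(self.subgroup[agent_id - 1])

    def members_of(self, subgroup_id: int) -> np.ndarray:
        """1-based agent IDs belonging to a subgroup."""
        if not 1 <= subgroup_id <= self.n_I:
            raise ParameterError(f"subgroup {subgroup_id} not in 1..{self.n_I}")
        return np.flatnonzero(self.subgroup == subgroup_id) + 1

    def _check_id(self, agent_id: int) -> None:
        if not 1 <= agent_id <= self.N:
            raise ParameterError(f"agent ID {agent_id} not in 1..{self.N}")

    def to_csv(self, path: str | Path) -> None:
        """Dump as ``agent_id,subgroup_id,role,x,y`` (1-based IDs, full precision)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["agent_id", "subgroup_id", "role", "x", "y"])
            for k in range(self.N):
                aid = k + 1
                w.writerow(
                    [
                        aid,
                        int(self.subgroup[k]),
                        self.role_of(aid),
                        repr(float(self.locations[k, 0])),
                        repr(float(self.locations[k, 1])),
                    ]
                )


def generate_population(
    params: SimulationParams, rng: np.random.Generator
) -> AgentPopulation:
    """Draw one population realization from the hierarchical Gaussian model.

    Draw order is fixed for reproducibility: all independenter coordinates in
    ID order (one vectorized draw), then all depender offsets in ID order.
    """
    n_I, n_D = params.n_I, params.n_D
    ind = rng.normal(0.0, params.sigma_I, size=(n_I, 2))
    if n_D > 0:
        offsets = rng.normal(0.0, params.sigma_D, size=(n_I * n_D, 2))
        centers = np.repeat(ind, n_D, axis=0)
        dep = centers + offsets
        locations = np.vstack([ind, dep])
    else:
        locations = ind
    subgroup = np.concatenate(
        [np.arange(1, n_I + 1), np.repeat(np.arange(1, n_I + 1), n_D)]
    ).astype(np.int64)
    return AgentPopulation(n_I=n_I, n_D=n_D, locations=locations, subgroup=subgroup)
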