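"""Simulation parameters for the single-file movement model.

A simulated animal group consists of ``n_I`` subgroups. Each subgroup is
anchored by one *independenter* (placed independently of everyone else) and
``n_D`` *dependers* (placed around their independenter). The total group size
is therefore ``N = n_I * (n_D + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


class ParameterError(ValueError):
    """Raised when simulation parameters violate their constraints."""


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the simulation model.

    Parameters
    ----------
    n_I : int
        Number of subgroups (equivalently, of independenters); >= 1.
    n_D : int
        Dependers per subgroup; >= 0.
    sigma_I : float
        Per-axis standard deviation of independenter placement around the
        origin (arbitrary distance units); > 0.
    sigma_D : float
        Per-axis standard deviation of depender placement around its
        subgroup's independenter; > 0. Defaults to 1, the unit in which
        ``sigma_I`` is effectively measured.
    n_exp : int
        Number of single-file movements observed per simulation; >= 1.
    n_reps : int
        Monte-Carlo replicates for averaged scores; >= 1.
    seed : int
        Master RNG seed.
    """

    n_I: int
    n_D: int
    sigma_I: float
    sigma_D: float = 1.0
    n_exp: int = 10
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_I, (int,)) and self.n_I >= 1):
            raise ParameterError(f"n_I must be an integer >= 1, got {self.n_I!r}")
        if not (isinstance(self.n_D, (int,)) and self.n_D >= 0):
            raise ParameterError(f"n_D must be an integer >= 0, got {self.n_D!r}")
        if not self.sigma_I > 0:
            raise ParameterError(f"sigma_I must be > 0, got {self.sigma_I!r}")
        if not self.sigma_D > 0:
            raise ParameterError(f"sigma_D must be > 0, got {self.sigma_D!r}")
        if not (isinstance(self.n_exp, int) and self.n_exp >= 1):
            raise ParameterError(f"n_exp must be an integer >= 1, got {self.n_exp!r}")
        if not (isinstance(self.n_reps, int) and self.n_reps >= 1):
            raise ParameterError(f"n_reps must be an integer >= 1, got {self.n_reps!r}")

    @property
    def N(self) -> int:
        """Total number of agents, ``n_I * (n_D + 1)``."""
        return self.n_I * (self.n_D + 1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        return cls(**d)
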