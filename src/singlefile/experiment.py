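"""End-to-end simulation, replicate averaging and parameter sweeps.

One simulation run observes ``n_exp`` single-file movements — each from a
*fresh* spatial realization of the same latent subgroup structure (same IDs
and memberships, new coordinates), as a field observer would see the group
re-arranged at every departure — aggregates their adjacencies, clusters the
aggregate with Louvain, and scores cluster-count recovery as

    r = n_eval / n_I

(r = 1: the number of latent subgroups is recovered exactly; r > 1 / r < 1:
over-/under-estimation). Monte-Carlo replicates of the whole run are averaged
into the mean score r-bar reported over a parameter grid.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .communities import Partition, louvain
from .network import AggregateGraph, aggregate_movements
from .params import ParameterError, SimulationParams
from .population import AgentPopulation, generate_population
from .serialize import SingleFileMovement, serialize

logger = logging.getLogger(__name__)

SWEEP_COLUMNS = ["n_I", "n_D", "sigma_I", "n_exp", "n_reps", "mean_r", "sd_r"]


class DegenerateRunError(ValueError):
    """The parameter combination cannot yield a scoreable graph (N < 2)."""


def score(n_eval: int, n_I: int) -> float:
    """Cluster-count recovery score r = n_eval / n_I."""
    if not (isinstance(n_eval, (int, np.integer)) and n_eval >= 1):
        raise ParameterError(f"n_eval must be a positive integer, got {n_eval!r}")
    if not (isinstance(n_I, (int, np.integer)) and n_I >= 1):
        raise ParameterError(f"n_I must be a positive integer, got {n_I!r}")
    return float(Fraction(int(n_eval), int(n_I)))


@dataclass
class ScoreRecord:
    """Outcome of one simulation run."""

    params: SimulationParams
    replicate: int
    n_eval: int
    r: float
    populations: list[AgentPopulation] | None = None
    movements: list[SingleFileMovement] | None = None
    graph: AggregateGraph | None = None
    partition: Partition | None = None


@dataclass
class AverageScore:
    """Replicate-averaged score at one parameter combination."""

    params: SimulationParams
    n_reps: int
    mean_r: float
    sd_r: float
    scores: np.ndarray = field(repr=False)


def replicate_seed_sequence(master_seed: int, *spawn_key: int) -> np.random.SeedSequence:
    """Counter-based child stream: SeedSequence(master, spawn_key=(...)).

    Children are statistically independent and depend only on the master seed
    and their key, never on execution order, so sweeps may run replicates in
    any order (or in parallel) without changing results.
    """
    return np.random.SeedSequence(entropy=master_seed, spawn_key=spawn_key)


def run_single_simulation(
    params: SimulationParams,
    rng: np.random.Generator,
    replicate: int = 0,
    keep_artifacts: bool = False,
) -> ScoreRecord:
    """One full simulation: n_exp (population, movement) pairs -> graph -> Louvain -> r.

    Raises
    ------
    DegenerateRunError
        When N < 2: a single agent yields an edgeless graph on which
        modularity is undefined.
    """
    if params.N < 2:
        raise DegenerateRunError(
            f"N = {params.N} < 2 (n_I={params.n_I}, n_D={params.n_D}): "
            "aggregate graph has no edges, score undefined"
        )
    populations: list[AgentPopulation] = []
    movements: list[SingleFileMovement] = []
    for _ in range(params.n_exp):
        pop = generate_population(params, rng)
        mov = serialize(pop, rng)
        movements.append(mov)
        if keep_artifacts:
            populations.append(pop)
    graph = aggregate_movements(movements)
    louvain_seed = int(rng.integers(0, 2**31))
    partition = louvain(graph, seed=louvain_seed)
    n_eval = partition.n_eval
    return ScoreRecord(
        params=params,
        replicate=replicate,
        n_eval=n_eval,
        r=score(n_eval, params.n_I),
        populations=populations if keep_artifacts else None,
        movements=movements if keep_artifacts else None,
        graph=graph if keep_artifacts else None,
        partition=partition if keep_artifacts else None,
    )


def average_score(
    params: SimulationParams,
    n_reps: int | None = None,
    seed: int | None = None,
    spawn_prefix: tuple[int, ...] = (),
    progress: Callable[[int, int], None] | None = None,
) -> AverageScore:
    """Mean and SD of r over independent replicates.

    Each replicate draws from its own child seed stream keyed by
    ``spawn_prefix + (replicate,)`` off the master seed. SD is the population
    standard deviation (ddof=0) of the replicate scores.
    """
    n_reps = params.n_reps if n_reps is None else n_reps
    seed = params.seed if seed is None else seed
    if n_reps < 1:
        raise ParameterError(f"n_reps must be >= 1, got {n_reps}")
    scores = np.empty(n_reps, dtype=float)
    for rep in range(n_reps):
        ss = replicate_seed_sequence(seed, *spawn_prefix, rep)
        rng = np.random.default_rng(ss)
        try:
            rec = run_single_simulation(params, rng, replicate=rep)
        except DegenerateRunError as exc:
            raise DegenerateRunError(f"replicate {rep}: {exc}") from exc
        scores[rep] = rec.r
        if progress is not None:
            progress(rep + 1, n_reps)
    return AverageScore(
        params=params,
        n_reps=n_reps,
        mean_r=float(scores.mean()),
        sd_r=float(scores.std(ddof=0)),
        scores=scores,
    )


def sweep(
    n_I_values: Sequence[int],
    n_D_values: Sequence[int],
    sigma_I_values: Sequence[float],
    n_exp_values: Sequence[int],
    n_reps: int,
    seed: int,
    sigma_D: float = 1.0,
    log_every: int | None = None,
) -> pd.DataFrame:
    """Replicate-averaged scores over the full parameter grid.

    Returns a tidy table with one row per (n_I, n_D, sigma_I, n_exp)
    combination, in row-major grid order, suitable for contour plotting.
    Cell replicate streams are keyed by (cell_index, replicate) so the table
    is bit-reproducible for a given master seed.
    """
    for name, axis in [
        ("n_I", n_I_values),
        ("n_D", n_D_values),
        ("sigma_I", sigma_I_values),
        ("n_exp", n_exp_values),
    ]:
        if len(axis) == 0:
            raise ParameterError(f"empty axis {name}")
    grid = list(itertools.product(n_I_values, n_D_values, sigma_I_values, n_exp_values))
    rows = []
    for cell_idx, (n_I, n_D, sigma_I, n_exp) in enumerate(grid):
        params = SimulationParams(
            n_I=int(n_I),
            n_D=int(n_D),
            sigma_I=float(sigma_I),
            sigma_D=sigma_D,
            n_exp=int(n_exp),
            n_reps=n_reps,
            seed=seed,
        )
        avg = average_score(params, n_reps, seed, spawn_prefix=(cell_idx,))
        rows.append(
            {
                "n_I": int(n_I),
                "n_D": int(n_D),
                "sigma_I": float(sigma_I),
                "n_exp": int(n_exp),
                "n_reps": int(n_reps),
                "mean_r": avg.mean_r,
                "sd_r": avg.sd_r,
            }
        )
        if log_every and (cell_idx + 1) % log_every == 0:
            logger.info("sweep: %d/%d cells done", cell_idx + 1, len(grid))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)
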