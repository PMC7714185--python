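"""File formats and run manifests.

All on-disk agent IDs, positions, replicate and movement indices are
1-based. Outputs are deterministic byte-for-byte for a given input (sorted
edges, canonical community labels), so reruns from a manifest reproduce
every artifact exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import __version__
from .communities import Partition
from .network import AggregateGraph
from .params import SimulationParams
from .serialize import SingleFileMovement

MOVEMENT_HEADER = ["rep", "movement_index", "position", "agent_id"]


class MalformedFileError(ValueError):
    """An on-disk artifact violates its format contract."""


def write_movements(
    movements: list[SingleFileMovement] | dict[int, list[SingleFileMovement]],
    path: str | Path,
) -> None:
    """Write movements as CSV ``rep,movement_index,position,agent_id``.

    A plain list is recorded as replicate 1.
    """
    if isinstance(movements, list):
        movements = {1: movements}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MOVEMENT_HEADER)
        for rep in sorted(movements):
            for mi, mov in enumerate(movements[rep], start=1):
                for pos, aid in enumerate(mov.order, start=1):
                    w.writerow([rep, mi, pos, int(aid)])


def read_movements(path: str | Path) -> dict[int, list[SingleFileMovement]]:
    """Read and validate a movements CSV; inverse of :func:`write_movements`.

    Rows may appear in any order on disk; they are sorted by
    (rep, movement_index, position) before reconstruction. Each movement must
    have contiguous positions 1..N and be a permutation of agent IDs 1..N.
    """
    rows: list[tuple[int, int, int, int, int]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != MOVEMENT_HEADER:
            raise MalformedFileError(
                f"bad header {header!r}, expected {MOVEMENT_HEADER!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                rep, mi, pos, aid = (int(v) for v in row)
            except (TypeError, ValueError) as exc:
                raise MalformedFileError(f"row {lineno}: non-integer field {row!r}") from exc
            rows.append((rep, mi, pos, aid, lineno))
    rows.sort(key=lambda r: r[:3])
    result: dict[int, list[SingleFileMovement]] = {}
    groups: dict[tuple[int, int], list[tuple[int, int, int]]] = {}
    for rep, mi, pos, aid, lineno in rows:
        groups.setdefault((rep, mi), []).append((pos, aid, lineno))
    for (rep, mi), entries in sorted(groups.items()):
        positions = [e[0] for e in entries]
        if positions != list(range(1, len(entries) + 1)):
            raise MalformedFileError(
                f"movement (rep={rep}, movement_index={mi}): positions "
                f"{positions} are not contiguous 1..{len(entries)}"
            )
        agents = [e[1] for e in entries]
        seen: set[int] = set()
        for pos, aid, lineno in entries:
            if aid in seen:
                raise MalformedFileError(
                    f"row {lineno}: agent {aid} appears twice in movement "
                    f"(rep={rep}, movement_index={mi})"
                )
            seen.add(aid)
        mov = SingleFileMovement(order=np.asarray(agents, dtype=np.int64))
        if not mov.is_permutation():
            raise MalformedFileError(
                f"movement (rep={rep}, movement_index={mi}): agent IDs "
                f"{sorted(seen)} are not a permutation of 1..{len(entries)}"
            )
        result.setdefault(rep, []).append(mov)
    return result


def export_graph(
    graph: AggregateGraph, path: str | Path, format: str = "edgelist"
) -> None:
    """Export the aggregate graph, ``edgelist`` (TSV) or ``graphml``.

    The edge list has no header: one ``source<TAB>target<TAB>weight`` row per
    positive-weight pair, source < target, sorted. Zero-weight pairs are
    never materialized.
    """
    if format == "edgelist":
        with open(path, "w", newline="") as fh:
            for s, t, w in graph.edge_list():
                fh.write(f"{s}\t{t}\t{w}\n")
    elif format == "graphml":
        nx.write_graphml(graph.to_networkx(), str(path))
    else:
        raise ValueError(f"unsupported graph format {format!r}")


def read_edge_list(path: str | Path, N: int | None = None) -> AggregateGraph:
    """Rebuild an aggregate graph from a TSV edge list.

    ``N`` defaults to the largest node ID seen (isolated trailing agents
    cannot be inferred from an edge list alone).
    """
    edges: list[tuple[int, int, int]] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MalformedFileError(f"row {lineno}: expected 3 fields, got {parts!r}")
            s, t, w = (int(v) for v in parts)
            edges.append((s, t, w))
    n = N if N is not None else max((max(s, t) for s, t, _ in edges), default=0)
    weights = np.zeros((n, n), dtype=np.int64)
    for s, t, w in edges:
        weights[s - 1, t - 1] += w
        weights[t - 1, s - 1] += w
    return AggregateGraph(weights=weights)


def export_partition(partition: Partition, path: str | Path) -> None:
    """Write CSV ``agent_id,community_id`` with canonical labels."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["agent_id", "community_id"])
        for aid in range(1, partition.N + 1):
            w.writerow([aid, partition.community_of(aid)])


def read_partition(path: str | Path) -> Partition:
    labels: dict[int, int] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["agent_id", "community_id"]:
            raise MalformedFileError(f"bad header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            try:
                aid, cid = int(row[0]), int(row[1])
            except (IndexError, ValueError) as exc:
                raise MalformedFileError(f"row {lineno}: bad row {row!r}") from exc
            labels[aid] = cid
    return Partition.from_mapping(labels, N=len(labels))


@dataclass
class RunManifest:
    """Everything needed to reproduce a run's artifacts bit-for-bit."""

    params: SimulationParams
    seed: int
    artifacts: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def write(self, path: str | Path) -> None:
        payload = {
            "params": self.params.to_dict(),
            "seed": self.seed,
            "artifacts": self.artifacts,
            "version": self.version,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            params=SimulationParams.from_dict(payload["params"]),
            seed=payload["seed"],
            artifacts=payload["artifacts"],
            version=payload["version"],
        )
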