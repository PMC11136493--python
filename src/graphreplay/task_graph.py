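"""Directed task graph: construction, triplet semantics, distractors, behavior.

The task embeds 10 stimulus items in a directed, cyclic graph with 12 edges.
Eight nodes have exactly one direct predecessor and successor; two *hub* nodes
have two of each.  Because a hub's successor is ambiguous from the hub alone,
the task is defined over *triplets* (predecessor, current, successor): each
directed edge (a, b) has exactly one valid successor c, and the two edges
entering a hub map to different successors.  The canonical layout realizes this
as two overlapping directed cycles sharing the two hub nodes; random isomorphs
are obtained by relabelling nodes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "GraphTask",
    "BehavioralRecord",
    "DistractorInfeasibleError",
    "build_task_graph",
    "graph_distance",
    "enumerate_triplets",
    "select_distractors",
    "error_distance_profile",
]

N_NODES = 10
N_EDGES = 12

# Two overlapping directed cycles (length 8 and length 4) sharing the two hub
# nodes 0 and 3, which are adjacent on both cycles (in opposite orientations).
# This is the unique degree-valid topology (up to relabelling and cycle-length
# choice) for which every triplet admits both a close (distance 2-4) and a
# distal (distance 5-8) distractor under the non-adjacency rule.
_CANONICAL_EDGES: tuple[tuple[int, int], ...] = (
    (0, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 8), (8, 9), (9, 0),  # 8-cycle
    (3, 0), (0, 1), (1, 2), (2, 3),                                  # 4-cycle
)
# Context rule at the hubs: stay within the cycle the edge came from.
_CANONICAL_HUB_SUCCESSORS: dict[tuple[int, int], int] = {
    (9, 0): 3, (3, 0): 1, (0, 3): 4, (2, 3): 0,
}


class DistractorInfeasibleError(RuntimeError):
    """No node satisfies the distractor constraints for a given triplet."""


@dataclass(frozen=True)
class GraphTask:
    """The directed 10-node/12-edge task graph.

    Attributes
    ----------
    node_ids : tuple of int
        Stimulus identifiers (always 0..9).
    edges : tuple of (int, int)
        Directed edges (a, b).
    triplet_successor : mapping (a, b) -> c
        The unique valid successor of each edge; (b, c) is itself an edge.
    distance : (10, 10) int array
        Directed shortest-path lengths (number of steps).
    hubs : frozenset of int
        The two nodes with in-degree 2 and out-degree 2.
    """

    node_ids: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    triplet_successor: Mapping[tuple[int, int], int]
    distance: np.ndarray = field(repr=False)
    hubs: frozenset[int]

    def successors(self, node: int) -> list[int]:
        return [b for a, b in self.edges if a == node]

    def predecessors(self, node: int) -> list[int]:
        return [a for a, b in self.edges if b == node]

    def to_networkx(self) -> nx.DiGraph:
        dg = nx.DiGraph()
        dg.add_nodes_from(self.node_ids)
        dg.add_edges_from(self.edges)
        return dg

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": list(self.node_ids),
                "edges": [list(e) for e in self.edges],
                "triplet_successor": {f"{a},{b}": c for (a, b), c in self.triplet_successor.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GraphTask":
        obj = json.loads(text)
        edges = tuple(tuple(e) for e in obj["edges"])
        succ = {tuple(int(x) for x in k.split(",")): v for k, v in obj["triplet_successor"].items()}
        return _assemble(tuple(obj["nodes"]), edges, succ)

    def to_edge_tsv(self) -> str:
        lines = ["from\tto\tsuccessor"]
        for a, b in self.edges:
            lines.append(f"{a}\t{b}\t{self.triplet_successor[(a, b)]}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class BehavioralRecord:
    """One learning/retrieval choice trial."""

    block: int
    cue_edge: tuple[int, int]  # (predecessor, current)
    chosen: int
    correct: bool


def _assemble(nodes: tuple[int, ...], edges: tuple[tuple[int, int], ...],
              succ: dict[tuple[int, int], int]) -> GraphTask:
    dg = nx.DiGraph(list(edges))
    dg.add_nodes_from(nodes)
    dist = np.full((N_NODES, N_NODES), -1, dtype=int)
    for a, lengths in nx.all_pairs_shortest_path_length(dg):
        for b, d in lengths.items():
            dist[a, b] = d
    if (dist < 0).any():
        raise ValueError("graph is not strongly connected")
    hubs = frozenset(n for n in nodes if dg.in_degree(n) == 2 and dg.out_degree(n) == 2)
    g = GraphTask(node_ids=nodes, edges=edges, triplet_successor=succ,
                  distance=dist, hubs=hubs)
    _validate(g, dg)
    return g


def _validate(g: GraphTask, dg: nx.DiGraph) -> None:
    if len(g.node_ids) != N_NODES or len(g.edges) != N_EDGES:
        raise ValueError("expected 10 nodes and 12 edges")
    if len(g.hubs) != 2:
        raise ValueError("expected exactly 2 hub nodes")
    for n in g.node_ids:
        deg = (dg.in_degree(n), dg.out_degree(n))
        if n in g.hubs:
            if deg != (2, 2):
                raise ValueError(f"hub {n} has degree {deg}")
        elif deg != (1, 1):
            raise ValueError(f"node {n} has degree {deg}")
    for (a, b), c in g.triplet_successor.items():
        if (a, b) not in g.edges or (b, c) not in g.edges:
            raise ValueError(f"triplet ({a},{b})->{c} not consistent with edges")
    if set(g.triplet_successor) != set(g.edges):
        raise ValueError("triplet_successor must cover every edge exactly once")
    for h in g.hubs:
        succ_of_in = {g.triplet_successor[(a, h)] for a in g.predecessors(h)}
        if len(succ_of_in) != 2:
            raise ValueError(f"hub {h}: incoming edges must map to distinct successors")


def build_task_graph(seed: int | None = None) -> GraphTask:
    """Build the canonical task graph or a random node-relabelled isomorph.

    The canonical layout is two overlapping directed cycles (lengths 8 and 4)
    sharing the two hub nodes.  With a seed, node labels are permuted
    uniformly at random, preserving all degree/connectivity structure.
    """
    nodes = tuple(range(N_NODES))
    succ = dict(_CANONICAL_HUB_SUCCESSORS)
    # non-hub edges: successor is the unique out-edge of b
    out = {}
    for a, b in _CANONICAL_EDGES:
        out.setdefault(a, []).append(b)
    for a, b in _CANONICAL_EDGES:
        if (a, b) not in succ:
            (c,) = out[b]
            succ[(a, b)] = c
    edges = _CANONICAL_EDGES
    if seed is not None:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(N_NODES)
        relabel = {old: int(perm[old]) for old in range(N_NODES)}
        edges = tuple(sorted((relabel[a], relabel[b]) for a, b in edges))
        succ = {(relabel[a], relabel[b]): relabel[c] for (a, b), c in succ.items()}
    return _assemble(nodes, edges, succ)


def graph_distance(g: GraphTask, a: int, b: int) -> int:
    """Length of the shortest directed path a -> b."""
    for node in (a, b):
        if node not in g.node_ids:
            raise KeyError(f"unknown node identifier: {node!r}")
    return int(g.distance[a, b])


def enumerate_triplets(g: GraphTask) -> list[tuple[int, int, int]]:
    """All 12 (predecessor, current, successor) triplets, one per edge."""
    return [(a, b, g.triplet_successor[(a, b)]) for a, b in g.edges]


def select_distractors(g: GraphTask, triplet: tuple[int, int, int],
                       rng: np.random.Generator) -> tuple[int, int]:
    """Pick a close (distance 2-4) and a distal (distance 5-8) distractor.

    Neither distractor may equal, or be directly connected (distance 1 in
    either direction) to, any on-screen item (predecessor, current, correct
    successor).
    """
    pred, cur, suc = triplet
    onscreen = {pred, cur, suc}

    def admissible(x: int) -> bool:
        if x in onscreen:
            return False
        for o in onscreen:
            if g.distance[o, x] == 1 or g.distance[x, o] == 1:
                return False
        return True

    close_pool = [x for x in g.node_ids if 2 <= g.distance[cur, x] <= 4 and admissible(x)]
    distal_pool = [x for x in g.node_ids if 5 <= g.distance[cur, x] <= 8 and admissible(x)]
    if not close_pool or not distal_pool:
        raise DistractorInfeasibleError(
            f"no admissible {'close' if not close_pool else 'distal'} "
            f"distractor for triplet {triplet}"
        )
    close = int(rng.choice(close_pool))
    pool = [x for x in distal_pool if x != close]
    if not pool:
        raise DistractorInfeasibleError(f"no distinct distal distractor for triplet {triplet}")
    distal = int(rng.choice(pool))
    return close, distal


def error_distance_profile(g: GraphTask, records: Sequence[BehavioralRecord]):
    """Per-block mean graph distance from the correct successor to the chosen item,
    over incorrect trials only.  Blocks without errors yield NaN.

    Returns a pandas Series indexed by block.
    """
    import pandas as pd

    if not records:
        raise ValueError("records must be non-empty")
    rows = []
    for r in records:
        suc = g.triplet_successor[tuple(r.cue_edge)]
        rows.append((r.block, r.correct, g.distance[suc, r.chosen]))
    df = pd.DataFrame(rows, columns=["block", "correct", "dist"])
    blocks = sorted(df["block"].unique())
    out = {}
    for b in blocks:
        errs = df[(df["block"] == b) & (~df["correct"])]
        out[b] = float(errs["dist"].mean()) if len(errs) else float("nan")
    return pd.Series(out, name="mean_error_distance")
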