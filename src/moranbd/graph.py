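"""Directed-graph container and structural predicates.

The spatial population structure of the Moran Birth-death process is a
strongly connected directed graph G = (V, E) on N nodes labelled
0 .. N-1.  A two-way (undirected) connection is represented by the two
opposite one-way edges.  Self-loops and parallel edges are excluded.

Structural predicates implemented here classify graphs into the families
that control fixation-time behaviour:

* ``is_undirected`` / ``is_oriented`` -- every edge reciprocated / none;
* ``is_regular`` / ``is_eulerian`` -- uniform degree / indegree equal to
  outdegree at every node (a circulation);
* ``is_balanced`` -- at every node v the degree-reciprocal sum over
  predecessors' outdegrees, scaled by 1/deg^-(v), equals the analogous
  sum over successors' indegrees scaled by 1/deg^+(v):

      (1/deg^-(v)) * sum_{u->v} 1/deg^+(u)
          == (1/deg^+(v)) * sum_{v->w} 1/deg^-(w).

  Balance is exactly the condition under which the neutral single-mutant
  fixation probability is proportional to 1/deg^-(v); it is evaluated in
  exact rational arithmetic so the predicate has no tolerance knob.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator

log = logging.getLogger(__name__)

__all__ = [
    "DirectedGraph",
    "DegreeProfile",
    "GraphError",
    "read_edge_list",
    "write_edge_list",
]


class GraphError(ValueError):
    """Raised for malformed graph input or violated graph preconditions."""


@dataclass(frozen=True)
class DegreeProfile:
    """In/out degree maps of a graph, plus min/max degree for Eulerian graphs.

    ``min_degree`` (delta) and ``max_degree`` (Delta) refer to the common
    in/out degree and are defined only when the graph is Eulerian; they
    are ``None`` otherwise.
    """

    indegree: tuple[int, ...]
    outdegree: tuple[int, ...]
    min_degree: int | None
    max_degree: int | None


class DirectedGraph:
    """A simple directed graph on nodes ``0 .. n_nodes-1``.

    Parameters
    ----------
    n_nodes:
        Number of nodes N (positive).
    edges:
        Iterable of ordered pairs ``(u, v)`` with ``u != v``.  Duplicates
        collapse silently (logged at debug level).
    """

    __slots__ = ("n_nodes", "edges", "_out", "_in", "_scc", "name")

    def __init__(self, n_nodes: int, edges: Iterable[tuple[int, int]],
                 name: str | None = None):
        if n_nodes < 1:
            raise GraphError(f"n_nodes must be positive, got {n_nodes}")
        edge_set = set()
        for e in edges:
            u, v = int(e[0]), int(e[1])
            if u == v:
                raise GraphError(f"self-loop ({u}, {u}) not allowed")
            if not (0 <= u < n_nodes and 0 <= v < n_nodes):
                raise GraphError(
                    f"edge ({u}, {v}) out of range for {n_nodes} nodes")
            if (u, v) in edge_set:
                log.debug("duplicate edge (%d, %d) collapsed", u, v)
            edge_set.add((u, v))
        self.n_nodes = n_nodes
        self.edges = frozenset(edge_set)
        out: list[list[int]] = [[] for _ in range(n_nodes)]
        inn: list[list[int]] = [[] for _ in range(n_nodes)]
        for u, v in sorted(edge_set):
            out[u].append(v)
            inn[v].append(u)
        self._out = tuple(tuple(x) for x in out)
        self._in = tuple(tuple(x) for x in inn)
        self._scc: bool | None = None
        self.name = name

    # -- basic accessors -------------------------------------------------

    @property
    def out_neighbors(self) -> tuple[tuple[int, ...], ...]:
        return self._out

    @property
    def in_neighbors(self) -> tuple[tuple[int, ...], ...]:
        return self._in

    def outdegree(self, v: int) -> int:
        return len(self._out[v])

    def indegree(self, v: int) -> int:
        return len(self._in[v])

    def degree_profile(self) -> DegreeProfile:
        ind = tuple(len(x) for x in self._in)
        outd = tuple(len(x) for x in self._out)
        if ind == outd:
            return DegreeProfile(ind, outd, min(ind), max(ind))
        return DegreeProfile(ind, outd, None, None)

    def __eq__(self, other) -> bool:
        return (isinstance(other, DirectedGraph)
                and self.n_nodes == other.n_nodes
                and self.edges == other.edges)

    def __hash__(self) -> int:
        return hash((self.n_nodes, self.edges))

    def __repr__(self) -> str:
        tag = f" {self.name!r}" if self.name else ""
        return (f"DirectedGraph(n_nodes={self.n_nodes}, "
                f"n_edges={len(self.edges)}{tag})")

    # -- structural predicates -------------------------------------------

    def is_strongly_connected(self) -> bool:
        """True iff every node reaches every other node along directed edges."""
        if self._scc is None:
            self._scc = (self._reaches_all(self._out)
                         and self._reaches_all(self._in))
        return self._scc

    def _reaches_all(self, adj) -> bool:
        n = self.n_nodes
        seen = [False] * n
        seen[0] = True
        stack = [0]
        count = 1
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    count += 1
                    stack.append(v)
        return count == n

    def require_strongly_connected(self) -> None:
        if not self.is_strongly_connected():
            raise GraphError("graph is not strongly connected")

    def is_undirected(self) -> bool:
        """True iff every edge u->v is reciprocated by v->u."""
        return all((v, u) in self.edges for u, v in self.edges)

    def is_oriented(self) -> bool:
        """True iff no pair of nodes is connected two-way."""
        return not any((v, u) in self.edges for u, v in self.edges)

    def is_eulerian(self) -> bool:
        """True iff indegree equals outdegree at every node (a circulation)."""
        return all(len(self._in[v]) == len(self._out[v])
                   for v in range(self.n_nodes))

    def is_regular(self) -> bool:
        """True iff one d exists with indegree = outdegree = d everywhere."""
        d = len(self._out[0])
        return all(len(self._in[v]) == d and len(self._out[v]) == d
                   for v in range(self.n_nodes))

    def is_balanced(self) -> bool:
        """Exact rational check of the per-node balance equality.

        Requires every node to have indegree >= 1 and outdegree >= 1.
        """
        for v in range(self.n_nodes):
            if not self._in[v] or not self._out[v]:
                raise GraphError(
                    f"node {v} has zero in- or out-degree; balance undefined")
        for v in range(self.n_nodes):
            lhs = Fraction(
                sum(Fraction(1, len(self._out[u])) for u in self._in[v]),
                len(self._in[v]))
            rhs = Fraction(
                sum(Fraction(1, len(self._in[w])) for w in self._out[v]),
                len(self._out[v]))
            if lhs != rhs:
                return False
        return True

    def class_label(self) -> str:
        """Edge-symmetry class: 'undirected', 'oriented' or 'other-directed'."""
        if self.is_undirected():
            return "undirected"
        if self.is_oriented():
            return "oriented"
        return "other-directed"

    # -- interop / serialization -----------------------------------------

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def to_dot(self) -> str:
        lines = ["digraph G {"]
        for v in range(self.n_nodes):
            lines.append(f"  {v};")
        for u, v in sorted(self.edges):
            lines.append(f"  {u} -> {v};")
        lines.append("}")
        return "\n".join(lines)

    def to_descriptor(self) -> dict:
        d = {"n_nodes": self.n_nodes,
             "edges": sorted(list(e) for e in self.edges)}
        if self.name:
            d["family"] = self.name
        return d

    @classmethod
    def from_descriptor(cls, d: dict) -> "DirectedGraph":
        return cls(d["n_nodes"], [tuple(e) for e in d["edges"]],
                   name=d.get("family"))

    def to_json(self) -> str:
        return json.dumps(self.to_descriptor())


# -- edge-list text format ----------------------------------------------


def read_edge_list(path: str | Path) -> DirectedGraph:
    """Read a graph from a plain-text edge list.

    One ``u v`` pair per line, 0-based node ids; ``#`` starts a comment.
    A ``# nodes=N`` header raises the node count above ``1 + max id``.
    Duplicate edge lines collapse to one edge.
    """
    path = Path(path)
    n_declared = None
    edges: list[tuple[int, int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                body = line[1:].strip().replace(" ", "")
                if body.startswith("nodes="):
                    n_declared = int(body[len("nodes="):])
                continue
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GraphError(
                    f"{path}:{lineno}: expected two integers, got {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise GraphError(
                    f"{path}:{lineno}: expected two integers, got {line!r}"
                ) from exc
            if u == v:
                raise GraphError(f"{path}:{lineno}: self-loop ({u}, {u})")
            edges.append((u, v))
    n = 1 + max((max(u, v) for u, v in edges), default=-1)
    if n_declared is not None:
        if n_declared < n:
            raise GraphError(
                f"{path}: header nodes={n_declared} below max node id {n - 1}")
        n = n_declared
    if n < 1:
        raise GraphError(f"{path}: no edges and no node-count header")
    return DirectedGraph(n, edges)


def write_edge_list(g: DirectedGraph, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# nodes={g.n_nodes}\n")
        for u, v in sorted(g.edges):
            fh.write(f"{u} {v}\n")
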