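"""Generators for the named graph families used in the experiments.

All generators return strongly connected :class:`~moranbd.graph.DirectedGraph`
instances with deterministic edge sets for fixed parameters.  Two-way
connections are emitted as both one-way edges.

Wiring notes
------------
``fan(k)`` uses triangle blades: a hub ``h`` and, per blade i, nodes
``a_i`` and ``b_i`` with one-way edges ``h -> a_i -> b_i -> h``.  This
reproduces the stated counts (N = 2k+1 nodes, 3k one-way edges) and is,
by exhaustive landscape scan at N = 5, the slowest oriented 5-node
graph.  Note it satisfies the balance equality only for k = 1.

``vortex(k)`` is a one-way circulation through two relay nodes: relay
``x`` feeds every node of batch A, batch A feeds relay ``y``, ``y``
feeds every node of batch B, and batch B feeds ``x`` (N = 2k+2 nodes,
4k edges).  This wiring is balanced for every k.

``four_column(k)`` realises a two-army tug-of-war on N = 4k nodes:
columns C1..C4 of k nodes each; two-way ladders inside every column;
two-way rungs between the middle columns C2 and C3; one-way pressure
edges from each side-column node onto the middle-column node of the
same row (C1 -> C2 and C4 -> C3); and two-way top-row couplings
C1 <-> C2 and C4 <-> C3 that make the side columns reachable.  With
mutants starting on the left half the middle columns become a contested
front: conversion is slow for small r and fast for large r.
"""

from __future__ import annotations

import numpy as np

from .graph import DirectedGraph, GraphError

__all__ = [
    "complete", "cycle", "star", "lollipop", "four_column", "fan", "vortex",
    "superstar", "metafunnel", "cyclic_complete_multipartite",
    "random_graph_fixture", "make_family", "FAMILIES",
]


def _both(u: int, v: int) -> list[tuple[int, int]]:
    return [(u, v), (v, u)]


def _finish(n: int, edges, name: str) -> DirectedGraph:
    g = DirectedGraph(n, edges, name=name)
    if not g.is_strongly_connected():
        raise GraphError(f"{name}: generated graph is not strongly connected")
    return g


def complete(n: int) -> DirectedGraph:
    """Complete (well-mixed) graph K_n: every ordered pair is an edge."""
    if n < 2:
        raise GraphError("complete: need n >= 2")
    return _finish(n, [(u, v) for u in range(n) for v in range(n) if u != v],
                   f"complete({n})")


def cycle(n: int) -> DirectedGraph:
    """Directed n-cycle 0 -> 1 -> ... -> n-1 -> 0."""
    if n < 2:
        raise GraphError("cycle: need n >= 2")
    return _finish(n, [(i, (i + 1) % n) for i in range(n)], f"cycle({n})")


def star(n: int) -> DirectedGraph:
    """Undirected star S_n: center node 0 two-way to n-1 leaves."""
    if n < 2:
        raise GraphError("star: need n >= 2")
    edges = []
    for leaf in range(1, n):
        edges += _both(0, leaf)
    return _finish(n, edges, f"star({n})")


def lollipop(n: int = 4) -> DirectedGraph:
    """Undirected lollipop L_n: clique on nodes 0..n-2 plus a pendant node.

    For n = 4 this is a triangle {0,1,2} with node 3 attached two-way to
    node 0.  The clique-opposite node (e.g. 1 or 2) and the pendant node 3
    are the two starting nodes with the most extreme fixation-time trends.
    """
    if n < 4:
        raise GraphError("lollipop: need n >= 4")
    edges = []
    for u in range(n - 1):
        for v in range(u + 1, n - 1):
            edges += _both(u, v)
    edges += _both(0, n - 1)
    return _finish(n, edges, f"lollipop({n})")


def four_column(k: int) -> DirectedGraph:
    """Four-column tug-of-war graph on N = 4k nodes (see module docstring).

    Node layout: column c (0..3) and row i (0..k-1) map to node c*k + i.
    """
    if k < 1:
        raise GraphError("four_column: need k >= 1")

    def node(c: int, i: int) -> int:
        return c * k + i

    edges: list[tuple[int, int]] = []
    for c in range(4):          # two-way ladders inside each column
        for i in range(k - 1):
            edges += _both(node(c, i), node(c, i + 1))
    for i in range(k):          # two-way rungs between middle columns
        edges += _both(node(1, i), node(2, i))
    for i in range(k):          # one-way pressure edges from side columns
        edges.append((node(0, i), node(1, i)))
        edges.append((node(3, i), node(2, i)))
    top = k - 1                 # two-way couplings making sides reachable
    edges += _both(node(1, top), node(0, top))
    edges += _both(node(2, top), node(3, top))
    return _finish(4 * k, edges, f"four_column({k})")


def fan(k: int) -> DirectedGraph:
    """Fan F_N with k triangle blades: N = 2k+1 nodes, 3k one-way edges.

    Hub 0; blade i uses nodes a_i = 2i+1 and b_i = 2i+2 with edges
    0 -> a_i -> b_i -> 0.
    """
    if k < 1:
        raise GraphError("fan: need k >= 1")
    edges = []
    for i in range(k):
        a, b = 2 * i + 1, 2 * i + 2
        edges += [(0, a), (a, b), (b, 0)]
    return _finish(2 * k + 1, edges, f"fan({k})")


def vortex(k: int) -> DirectedGraph:
    """Vortex with batch size k: N = 2k+2 nodes, 4k one-way edges.

    Relay x = 0 feeds batch A (nodes 1..k), batch A feeds relay
    y = k+1, y feeds batch B (nodes k+2..2k+1), batch B feeds x.
    """
    if k < 1:
        raise GraphError("vortex: need k >= 1")
    x, y = 0, k + 1
    edges = []
    for i in range(k):
        a = 1 + i
        b = k + 2 + i
        edges += [(x, a), (a, y), (y, b), (b, x)]
    return _finish(2 * k + 2, edges, f"vortex({k})")


def superstar(leaves: int, reservoir: int, path_len: int) -> DirectedGraph:
    """Superstar with ``leaves`` arms, ``reservoir`` nodes per arm and
    total arm path length ``path_len`` (>= 2).

    Center 0 feeds every reservoir node; within an arm the reservoir
    feeds a directed chain of ``path_len - 2`` nodes into the center
    (for ``path_len == 2`` the reservoir feeds the center directly).
    """
    if leaves < 1 or reservoir < 1 or path_len < 2:
        raise GraphError("superstar: need leaves, reservoir >= 1, path_len >= 2")
    edges = []
    nid = 1
    for _ in range(leaves):
        res = list(range(nid, nid + reservoir))
        nid += reservoir
        chain = list(range(nid, nid + path_len - 2))
        nid += path_len - 2
        for v in res:
            edges.append((0, v))
            edges.append((v, chain[0] if chain else 0))
        for a, b in zip(chain, chain[1:]):
            edges.append((a, b))
        if chain:
            edges.append((chain[-1], 0))
    return _finish(nid, edges, f"superstar({leaves},{reservoir},{path_len})")


def metafunnel(arity: int, depth: int) -> DirectedGraph:
    """Metafunnel: a complete ``arity``-ary funnel of the given depth.

    Layer d (the widest, arity**depth nodes) is fed by the root; each
    node of layer i feeds its parent in layer i-1; layer 0 is the root.
    """
    if arity < 1 or depth < 1:
        raise GraphError("metafunnel: need arity >= 1, depth >= 1")
    layers = [[0]]
    nid = 1
    for d in range(1, depth + 1):
        layers.append(list(range(nid, nid + arity ** d)))
        nid += arity ** d
    edges = []
    for d in range(1, depth + 1):
        for j, v in enumerate(layers[d]):
            edges.append((v, layers[d - 1][j // arity]))
    for v in layers[depth]:
        edges.append((0, v))
    return _finish(nid, edges, f"metafunnel({arity},{depth})")


def cyclic_complete_multipartite(part_sizes: list[int]) -> DirectedGraph:
    """Cyclic complete multipartite graph: parts B_1..B_p in a one-way
    cycle, with every node of B_i feeding every node of B_{i+1}.

    Balanced for any part sizes (p >= 2 parts required).
    """
    sizes = list(part_sizes)
    if len(sizes) < 2 or any(s < 1 for s in sizes):
        raise GraphError("cyclic_complete_multipartite: need >= 2 positive parts")
    starts = np.concatenate([[0], np.cumsum(sizes)])
    parts = [list(range(starts[i], starts[i + 1])) for i in range(len(sizes))]
    edges = []
    for i, part in enumerate(parts):
        nxt = parts[(i + 1) % len(parts)]
        for u in part:
            for v in nxt:
                edges.append((u, v))
    return _finish(int(starts[-1]), edges,
                   f"cyclic_complete_multipartite({sizes})")


def random_graph_fixture(kind: str, n: int, density: float,
                         seed: int) -> DirectedGraph:
    """Seeded random graph guaranteed to satisfy the requested predicate.

    kind = 'strongly_connected': a random Hamiltonian cycle superposed on
    a density-``density`` random digraph.
    kind = 'eulerian': a superposition of random directed cycles (each
    conserves in/out degree at every node).
    kind = 'undirected': random symmetric edges on a random spanning tree.
    kind = 'regular': a superposition of d random permutation-derangement
    cycles giving in/out degree d at every node.
    """
    if n < 2:
        raise GraphError("random_graph_fixture: need n >= 2")
    rng = np.random.default_rng(seed)
    edges: set[tuple[int, int]] = set()

    def add_cycle(nodes) -> None:
        for a, b in zip(nodes, list(nodes[1:]) + [nodes[0]]):
            if a != b:
                edges.add((int(a), int(b)))

    if kind == "strongly_connected":
        add_cycle(rng.permutation(n))
        for u in range(n):
            for v in range(n):
                if u != v and rng.random() < density:
                    edges.add((u, v))
    elif kind == "eulerian":
        add_cycle(rng.permutation(n))
        extra = max(1, int(density * n))
        for _ in range(extra):
            size = int(rng.integers(2, n + 1))
            nodes = rng.choice(n, size=size, replace=False)
            cyc = [int(a) for a in nodes]
            if not any((a, b) in edges or a == b
                       for a, b in zip(cyc, cyc[1:] + cyc[:1])):
                add_cycle(cyc)
    elif kind == "undirected":
        order = rng.permutation(n)
        for i in range(1, n):
            u = int(order[i])
            v = int(order[int(rng.integers(0, i))])
            edges.update({(u, v), (v, u)})
        for u in range(n):
            for v in range(u + 1, n):
                if rng.random() < density:
                    edges.update({(u, v), (v, u)})
    elif kind == "regular":
        d = max(1, int(round(density * (n - 1))))
        tries = 0
        while True:
            cand: set[tuple[int, int]] = set()
            ok = True
            add = [rng.permutation(n)]
            for _ in range(d - 1):
                add.append(rng.permutation(n))
            for perm in add:
                cyc_edges = list(zip(perm, list(perm[1:]) + [perm[0]]))
                for a, b in cyc_edges:
                    if a == b or (int(a), int(b)) in cand:
                        ok = False
                cand.update((int(a), int(b)) for a, b in cyc_edges)
            tries += 1
            if ok:
                edges = cand
                break
            if tries > 200:
                edges = {(u, (u + s) % n) for u in range(n)
                         for s in range(1, d + 1)}  # circulant fallback
                break
    else:
        raise GraphError(f"unknown fixture kind {kind!r}")
    g = DirectedGraph(n, edges, name=f"random_{kind}(n={n},seed={seed})")
    g.require_strongly_connected()
    return g


FAMILIES = {
    "complete": complete,
    "cycle": cycle,
    "star": star,
    "lollipop": lollipop,
    "four_column": four_column,
    "fan": fan,
    "vortex": vortex,
    "superstar": superstar,
    "metafunnel": metafunnel,
    "cyclic_complete_multipartite": cyclic_complete_multipartite,
}


def make_family(name: str, *params) -> DirectedGraph:
    """Dispatch to a named family generator, e.g. ``make_family('fan', 5)``."""
    try:
        gen = FAMILIES[name]
    except KeyError:
        raise GraphError(
            f"unknown family {name!r}; known: {sorted(FAMILIES)}") from None
    return gen(*params)
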