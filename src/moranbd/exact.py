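"""Exact absorbing-Markov-chain analysis of the Moran Birth-death process.

The process state is the configuration S of mutant-occupied nodes,
stored as an N-bit mask (bit v set means node v holds a mutant).  In
each step a parent is drawn proportional to fitness (mutants have
relative fitness r, residents 1), a uniform out-neighbour of the parent
dies, and the parent's type is copied there.  The empty and full
configurations are absorbing ("extinction" and "fixation").

For a strongly connected graph on N nodes the full chain has 2^N
states.  :func:`solve_exact` solves, with one LU factorisation shared
across right-hand sides:

* fixation probability     fp(S)  with fp(empty)=0, fp(full)=1;
* absorption time          at(S) = 1 + sum_S' P(S,S') at(S');
* h(S) = fp(S)*ft(S)       h(S) = fp(S) + sum_S' P(S,S') h(S'),
  giving the fixation-conditioned time  ft = h / fp;
* g(S) = (1-fp(S))*ext(S)  symmetrically for the extinction-conditioned
  time ext = g / (1 - fp).

Steps count every Birth-death event, including "lazy" ones where the
offspring replaces an individual of its own type; an active-steps-only
variant is available but never the default.

The neutral (r = 1) single-mutant probabilities additionally satisfy an
N-equation stationarity system (neutral fixation probability is
additive over configurations), solved by :func:`neutral_fp_vector`; on
balanced graphs it has the closed form fp(u) = (1/deg^-(u)) /
sum_v 1/deg^-(v) implemented by :func:`balanced_fp_formula`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .graph import DirectedGraph, GraphError

__all__ = [
    "MoranParams", "ExactSolution", "NeutralFPVector", "CapacityError",
    "step_distribution", "solve_exact", "solve_exact_rational",
    "fixation_time_max", "absorption_time_max",
    "neutral_fp_vector", "balanced_fp_formula", "balanced_fp_vector",
]

#: states beyond this node count are refused by default (2^N scaling)
DEFAULT_MAX_NODES = 14


class CapacityError(RuntimeError):
    """Raised when the 2^N state space exceeds the configured budget."""


@dataclass(frozen=True)
class MoranParams:
    """Process parameters: mutant relative fitness r (> 0, residents at 1).

    Values r < 1 are accepted (disadvantageous mutants); the polynomial
    fixation-time guarantees are only claimed for r >= 1.
    """

    r: float = 1.0

    def __post_init__(self):
        if not self.r > 0:
            raise ValueError(f"fitness r must be positive, got {self.r}")


def _popcounts(n_states: int) -> np.ndarray:
    counts = np.zeros(n_states, dtype=np.int64)
    for s in range(1, n_states):
        counts[s] = counts[s >> 1] + (s & 1)
    return counts


def step_distribution(g: DirectedGraph, params: MoranParams | float,
                      s: int | set[int] | frozenset) -> dict[int, float]:
    """One-step transition distribution from configuration ``s``.

    ``s`` may be an N-bit mask or a set of node ids; keys of the result
    are bit masks.  Probabilities (including the lazy self-transition)
    sum to 1.  Absorbing states map to themselves with probability 1.
    """
    g.require_strongly_connected()
    r = params.r if isinstance(params, MoranParams) else float(params)
    mask = s if isinstance(s, int) else sum(1 << v for v in s)
    n = g.n_nodes
    full = (1 << n) - 1
    if mask == 0 or mask == full:
        return {mask: 1.0}
    m = bin(mask).count("1")
    total = r * m + (n - m)
    dist: dict[int, float] = {}
    for u in range(n):
        w_u = (r if mask >> u & 1 else 1.0) / total
        nbrs = g.out_neighbors[u]
        p_edge = w_u / len(nbrs)
        for v in nbrs:
            t = mask | (1 << v) if mask >> u & 1 else mask & ~(1 << v)
            dist[t] = dist.get(t, 0.0) + p_edge
    return dist


@dataclass
class ExactSolution:
    """Per-configuration solution of the absorbing chain.

    Arrays are indexed by the configuration bit mask.  ``ft`` is NaN at
    the empty configuration (fixation never happens from there) and
    ``ext`` is NaN at the full configuration; these conditional times
    are undefined, not zero or infinite.
    """

    graph: DirectedGraph
    r: float
    fp: np.ndarray
    at: np.ndarray
    ft: np.ndarray
    ext: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.graph.n_nodes

    def _single(self, arr: np.ndarray) -> np.ndarray:
        return np.array([arr[1 << v] for v in range(self.n_nodes)])

    @property
    def fp_single(self) -> np.ndarray:
        """Fixation probability of a single mutant at each node."""
        return self._single(self.fp)

    @property
    def ft_single(self) -> np.ndarray:
        """Conditional fixation time of a single mutant at each node."""
        return self._single(self.ft)

    @property
    def at_single(self) -> np.ndarray:
        return self._single(self.at)

    @property
    def t_max(self) -> float:
        """Largest conditional fixation time over non-empty configurations."""
        return float(np.nanmax(self.ft[1:]))

    @property
    def at_max(self) -> float:
        """Largest absorption time over all configurations."""
        return float(np.max(self.at))

    def uniform_init(self, weighted: bool = True) -> tuple[float, float]:
        """(fp, fixation time) of a single mutant at a uniform random node.

        The fixation probability is the plain average of the N
        single-mutant values.  With ``weighted=True`` (default) the time
        is the fixation-weighted mixture sum_v fp_v ft_v / sum_v fp_v,
        i.e. the expected length of fixating trajectories of the mixture
        process; otherwise the unweighted mean of the N conditional
        times.
        """
        fps = self.fp_single
        fts = self.ft_single
        fp_u = float(np.mean(fps))
        if weighted:
            t_u = float(np.sum(fps * fts) / np.sum(fps))
        else:
            t_u = float(np.mean(fts))
        return fp_u, t_u

    def to_dict(self) -> dict:
        return {
            "graph": self.graph.to_descriptor(),
            "r": self.r,
            "fp_single": self.fp_single.tolist(),
            "at_single": self.at_single.tolist(),
            "ft_single": self.ft_single.tolist(),
            "t_max": self.t_max,
            "at_max": self.at_max,
        }


def _transition_system(g: DirectedGraph, r: float, lazy: bool):
    """Interior transition matrix (I - Q) and fixation-hit vector.

    Returns (A, b_full, interior_index) where A = I - Q over interior
    states (masks 1 .. 2^N - 2), b_full[s] is the one-step probability
    of jumping from interior state s to the full state, and the row/col
    order is by mask value.  With ``lazy=False`` self-transitions are
    removed and rows renormalised (active-steps-only clock).
    """
    n = g.n_nodes
    n_states = 1 << n
    full = n_states - 1
    out = g.out_neighbors
    inv_len = [1.0 / len(x) for x in out]
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    b_full = np.zeros(n_states - 2)
    dense = n <= 11
    if dense:
        A = np.zeros((n_states - 2, n_states - 2))
    for s in range(1, full):
        m = bin(s).count("1")
        total = r * m + (n - m)
        i = s - 1
        self_p = 0.0
        for u in range(n):
            mut = s >> u & 1
            p_u = (r if mut else 1.0) / total * inv_len[u]
            if mut:
                for v in out[u]:
                    t = s | (1 << v)
                    if t == s:
                        self_p += p_u
                    elif t == full:
                        b_full[i] += p_u
                    elif dense:
                        A[i, t - 1] -= p_u
                    else:
                        rows.append(i); cols.append(t - 1); vals.append(-p_u)
            else:
                for v in out[u]:
                    t = s & ~(1 << v)
                    if t == s:
                        self_p += p_u
                    elif t != 0:
                        if dense:
                            A[i, t - 1] -= p_u
                        else:
                            rows.append(i); cols.append(t - 1); vals.append(-p_u)
                    # t == 0 hits the extinction boundary (value 0)
        if lazy:
            if dense:
                A[i, i] += 1.0 - self_p
            else:
                rows.append(i); cols.append(i); vals.append(1.0 - self_p)
        else:
            if not dense:
                raise CapacityError("active-steps mode only for N <= 11")
            scale = 1.0 / (1.0 - self_p)
            b_full[i] *= scale
            A[i, :] *= scale
            A[i, i] += 1.0
    if dense:
        return A, b_full, None
    A = scipy.sparse.csc_matrix(
        (vals, (rows, cols)), shape=(n_states - 2, n_states - 2))
    return A, b_full, None


def solve_exact(g: DirectedGraph, params: MoranParams | float,
                max_nodes: int = DEFAULT_MAX_NODES,
                count_lazy_steps: bool = True) -> ExactSolution:
    """Solve the full 2^N absorbing chain for fp, at, ft and ext.

    Raises :class:`CapacityError` when N exceeds ``max_nodes`` (default
    14); use the Monte Carlo simulator for larger graphs.
    """
    g.require_strongly_connected()
    r = params.r if isinstance(params, MoranParams) else float(params)
    if not r > 0:
        raise ValueError("fitness r must be positive")
    n = g.n_nodes
    if n > max_nodes:
        raise CapacityError(
            f"N={n} means 2^{n} states; beyond max_nodes={max_nodes}. "
            "Use moranbd.simulate for large graphs.")
    n_states = 1 << n
    A, b_full, _ = _transition_system(g, r, lazy=count_lazy_steps)

    ones = np.ones(n_states - 2)
    if isinstance(A, np.ndarray):
        lu = scipy.linalg.lu_factor(A)
        fp_int = scipy.linalg.lu_solve(lu, b_full)
        at_int = scipy.linalg.lu_solve(lu, ones)
        h_int = scipy.linalg.lu_solve(lu, fp_int)
        g_int = scipy.linalg.lu_solve(lu, 1.0 - fp_int)
    else:
        lu = scipy.sparse.linalg.splu(A)
        fp_int = lu.solve(b_full)
        at_int = lu.solve(ones)
        h_int = lu.solve(fp_int)
        g_int = lu.solve(1.0 - fp_int)

    fp = np.empty(n_states)
    fp[0], fp[-1] = 0.0, 1.0
    fp[1:-1] = fp_int
    at = np.zeros(n_states)
    at[1:-1] = at_int
    ft = np.full(n_states, np.nan)
    ft[-1] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ft[1:-1] = h_int / fp_int
    ext = np.full(n_states, np.nan)
    ext[0] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ext[1:-1] = g_int / (1.0 - fp_int)
    return ExactSolution(graph=g, r=r, fp=fp, at=at, ft=ft, ext=ext)


def fixation_time_max(g: DirectedGraph, params: MoranParams | float,
                      **kw) -> float:
    """T_r(G): the largest conditional fixation time over non-empty S."""
    return solve_exact(g, params, **kw).t_max


def absorption_time_max(g: DirectedGraph, params: MoranParams | float,
                        **kw) -> float:
    """AT_r(G): the largest absorption time over all configurations."""
    return solve_exact(g, params, **kw).at_max


# -- exact rational verification path -----------------------------------


def solve_exact_rational(g: DirectedGraph, r: Fraction) -> dict[int, Fraction]:
    """Fixation probabilities as exact rationals (verification mode).

    Solves the same boundary-value system with Fraction arithmetic and
    dense Gaussian elimination; intended for N <= 8.  Independent of the
    floating-point path (no scipy involved).
    """
    g.require_strongly_connected()
    n = g.n_nodes
    if n > 8:
        raise CapacityError("rational mode supports N <= 8")
    r = Fraction(r)
    full = (1 << n) - 1
    interior = list(range(1, full))
    idx = {s: i for i, s in enumerate(interior)}
    dim = len(interior)
    A = [[Fraction(0)] * dim for _ in range(dim)]
    b = [Fraction(0)] * dim
    for s in interior:
        i = idx[s]
        m = bin(s).count("1")
        total = r * m + (n - m)
        A[i][i] += 1
        for u in range(n):
            w = (r if s >> u & 1 else Fraction(1)) / total
            nbrs = g.out_neighbors[u]
            p = w / len(nbrs)
            for v in nbrs:
                t = s | (1 << v) if s >> u & 1 else s & ~(1 << v)
                if t == full:
                    b[i] += p
                elif t != 0:
                    A[i][idx[t]] -= p
    # Gaussian elimination with partial (first-nonzero) pivoting
    for col in range(dim):
        piv = next(row for row in range(col, dim) if A[row][col] != 0)
        A[col], A[piv] = A[piv], A[col]
        b[col], b[piv] = b[piv], b[col]
        inv = 1 / A[col][col]
        A[col] = [a * inv for a in A[col]]
        b[col] *= inv
        for row in range(dim):
            if row != col and A[row][col] != 0:
                f = A[row][col]
                A[row] = [a - f * c for a, c in zip(A[row], A[col])]
                b[row] -= f * b[col]
    out = {0: Fraction(0), full: Fraction(1)}
    for s in interior:
        out[s] = b[idx[s]]
    return out


# -- neutral N-equation system ------------------------------------------


@dataclass
class NeutralFPVector:
    """Neutral (r = 1) single-mutant fixation probabilities fp^(i).

    Entries sum to 1 (neutral fixation probability is additive over
    configurations and the full set fixes surely); the minimum entry
    fp_min is at most 1/N and drives the N^6 / fp_min^4 time bound.
    """

    fp_single: np.ndarray

    @property
    def fp_min(self) -> float:
        return float(np.min(self.fp_single))

    @property
    def n_nodes(self) -> int:
        return len(self.fp_single)

    def to_dict(self) -> dict:
        return {"fp_single": self.fp_single.tolist(), "fp_min": self.fp_min}


def neutral_fp_vector(g: DirectedGraph) -> NeutralFPVector:
    """Solve the N-equation neutral-drift system for fp^(i) and fp_min.

    The vector x with x_v = fp_{r=1}(G, {v}) is the unique solution of

        (1/deg^+(u)) * sum_{u->v} x_v = x_u * sum_{w->u} 1/deg^+(w)

    for every node u, normalised to sum 1.  This reduces the 2^N-state
    neutral chain to N equations via additivity of neutral fixation
    probability.
    """
    g.require_strongly_connected()
    n = g.n_nodes
    M = np.zeros((n, n))
    for u in range(n):
        outdeg = len(g.out_neighbors[u])
        for v in g.out_neighbors[u]:
            M[u, v] += 1.0 / outdeg
        M[u, u] -= sum(1.0 / len(g.out_neighbors[w])
                       for w in g.in_neighbors[u])
    # replace one equation (the system has rank n-1) with normalisation
    A = np.vstack([M[:-1], np.ones(n)])
    b = np.zeros(n)
    b[-1] = 1.0
    x = np.linalg.solve(A, b)
    resid = float(np.max(np.abs(M @ x)))
    if not np.isfinite(x).all() or resid > 1e-9:
        raise GraphError("neutral system is singular; graph not strongly "
                         f"connected? residual={resid:g}")
    return NeutralFPVector(fp_single=x)


def balanced_fp_formula(g: DirectedGraph, u: int) -> float:
    """Closed-form neutral fixation probability on a balanced graph.

    fp_{r=1}(G, {u}) = (1/deg^-(u)) / sum_v 1/deg^-(v), which is always
    at least 1/N^2.  Raises if the graph is not balanced (the formula is
    not asserted for unbalanced graphs).
    """
    if not g.is_balanced():
        raise GraphError("balanced_fp_formula requires a balanced graph")
    denom = sum(Fraction(1, g.indegree(v)) for v in range(g.n_nodes))
    return float(Fraction(1, g.indegree(u)) / denom)


def balanced_fp_vector(g: DirectedGraph) -> np.ndarray:
    """All N closed-form neutral probabilities of a balanced graph."""
    if not g.is_balanced():
        raise GraphError("balanced_fp_vector requires a balanced graph")
    denom = sum(Fraction(1, g.indegree(v)) for v in range(g.n_nodes))
    return np.array([float(Fraction(1, g.indegree(u)) / denom)
                     for u in range(g.n_nodes)])
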