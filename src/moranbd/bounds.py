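"""Efficiently computable upper bounds on absorption and fixation time.

Four regimes, each checked against its preconditions and reported in
steps of the discrete process:

* strong selection (``T1``): if r >= N^2 then AT_r(G) <= 2 N^3 and
  T_r(G) <= 3 N^3, for any strongly connected graph;
* Eulerian graphs (``T2``): if deg^- = deg^+ everywhere, with degrees
  between delta and Delta, and r >= (Delta/delta)(1+eps) for some
  eps > 0, then AT_r(G) <= ((2+eps)/eps) N^3 and
  T_r(G) <= ((1+eps)(2+eps)/eps^2) N^3.  We always use the maximal
  admissible slack eps = r*delta/Delta - 1 (the bound is monotone in
  eps); an override is available for reproducing intermediate values;
* neutral-probability bound (``T3``): for any r >= 1,
  T_r(G) <= N^6 / fp_min(G)^4 where fp_min is the smallest neutral
  single-mutant fixation probability;
* balanced graphs (``T4``): if the graph is balanced and r >= 1 then
  fp_min >= 1/N^2 and hence T_r(G) <= N^14.

:func:`best_bound` evaluates all four and returns the applicable report
with the smallest fixation-time bound, carrying the full audit list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .exact import MoranParams, NeutralFPVector, neutral_fp_vector
from .graph import DirectedGraph

log = logging.getLogger(__name__)

__all__ = [
    "TimeBoundReport", "bound_theorem1", "bound_theorem2",
    "bound_theorem3", "bound_theorem4", "best_bound",
]


@dataclass
class TimeBoundReport:
    """One regime's verdict: preconditions, and AT/T upper bounds in steps."""

    theorem: str
    applicable: bool
    preconditions: list[tuple[str, bool]]
    at_bound: float | None = None
    t_bound: float | None = None
    epsilon: float | None = None
    audit: list["TimeBoundReport"] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "theorem": self.theorem,
            "applicable": self.applicable,
            "preconditions": [list(p) for p in self.preconditions],
            "at_bound": self.at_bound,
            "t_bound": self.t_bound,
        }
        if self.epsilon is not None:
            d["epsilon"] = self.epsilon
        if self.audit:
            d["audit"] = [a.to_dict() for a in self.audit]
        return d


def _r(params: MoranParams | float) -> float:
    return params.r if isinstance(params, MoranParams) else float(params)


def bound_theorem1(g: DirectedGraph, params: MoranParams | float
                   ) -> TimeBoundReport:
    """Strong-selection bound: r >= N^2 gives AT <= 2N^3, T <= 3N^3."""
    g.require_strongly_connected()
    r, n = _r(params), g.n_nodes
    ok = r >= n * n
    pre = [("strongly_connected", True), (f"r >= N^2 = {n * n}", ok)]
    if not ok:
        return TimeBoundReport("T1", False, pre)
    return TimeBoundReport("T1", True, pre,
                           at_bound=2.0 * n ** 3, t_bound=3.0 * n ** 3)


def bound_theorem2(g: DirectedGraph, params: MoranParams | float,
                   epsilon: float | None = None) -> TimeBoundReport:
    """Eulerian bound with slack eps = r*delta/Delta - 1 (maximal by default)."""
    g.require_strongly_connected()
    r, n = _r(params), g.n_nodes
    eul = g.is_eulerian()
    pre = [("strongly_connected", True), ("eulerian", eul)]
    if not eul:
        return TimeBoundReport("T2", False, pre)
    prof = g.degree_profile()
    delta, Delta = prof.min_degree, prof.max_degree
    eps_max = r * delta / Delta - 1.0
    pre.append((f"r > Delta/delta = {Delta}/{delta}", eps_max > 0))
    if eps_max <= 0:
        return TimeBoundReport("T2", False, pre)
    eps = eps_max if epsilon is None else float(epsilon)
    if not 0 < eps <= eps_max + 1e-12:
        raise ValueError(f"epsilon must lie in (0, {eps_max}]")
    at_b = (2 + eps) / eps * n ** 3
    t_b = (1 + eps) * (2 + eps) / eps ** 2 * n ** 3
    return TimeBoundReport("T2", True, pre, at_bound=at_b, t_bound=t_b,
                           epsilon=eps)


def bound_theorem3(g: DirectedGraph, params: MoranParams | float,
                   nfp: NeutralFPVector | None = None) -> TimeBoundReport:
    """Neutral-probability bound T <= N^6 / fp_min^4, any r >= 1."""
    g.require_strongly_connected()
    r, n = _r(params), g.n_nodes
    pre = [("strongly_connected", True), ("r >= 1", r >= 1)]
    if r < 1:
        return TimeBoundReport("T3", False, pre)
    if nfp is None:
        nfp = neutral_fp_vector(g)
    fp_min = nfp.fp_min
    if fp_min <= 0 or fp_min ** 4 == 0.0:
        log.warning("fp_min=%g underflows; reporting infinite bound", fp_min)
        t_b = math.inf
    else:
        t_b = n ** 6 / fp_min ** 4
    return TimeBoundReport("T3", True, pre, t_bound=t_b)


def bound_theorem4(g: DirectedGraph, params: MoranParams | float
                   ) -> TimeBoundReport:
    """Balanced-graph bound T <= N^14, any r >= 1."""
    g.require_strongly_connected()
    r, n = _r(params), g.n_nodes
    bal = g.is_balanced()
    pre = [("strongly_connected", True), ("balanced", bal), ("r >= 1", r >= 1)]
    if not (bal and r >= 1):
        return TimeBoundReport("T4", False, pre)
    return TimeBoundReport("T4", True, pre, t_bound=float(n) ** 14)


def best_bound(g: DirectedGraph, params: MoranParams | float,
               nfp: NeutralFPVector | None = None) -> TimeBoundReport:
    """Smallest applicable fixation-time bound, with all four audited.

    Returns a report whose ``audit`` lists every regime's verdict.  When
    no regime applies (possible only for r < 1 on unbalanced
    non-Eulerian graphs below the strong-selection threshold) the
    returned report has ``applicable=False``.
    """
    reports = [
        bound_theorem1(g, params),
        bound_theorem2(g, params),
        bound_theorem3(g, params, nfp=nfp),
        bound_theorem4(g, params),
    ]
    usable = [rep for rep in reports
              if rep.applicable and rep.t_bound is not None
              and math.isfinite(rep.t_bound)]
    if not usable:
        rep = TimeBoundReport("none", False,
                              [("any regime applicable", False)])
        rep.audit = reports
        return rep
    winner = min(usable, key=lambda rep: rep.t_bound)
    out = TimeBoundReport(winner.theorem, True, winner.preconditions,
                          at_bound=winner.at_bound, t_bound=winner.t_bound,
                          epsilon=winner.epsilon)
    out.audit = reports
    return out
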