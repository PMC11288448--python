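"""Seeded Monte Carlo simulation of the Moran Birth-death process.

A single trajectory (:func:`run_once`) draws, per step, one uniform to
pick the parent (inverse-CDF over the two fitness classes, then a
uniform class member) and one uniform to pick the dying out-neighbour.
Steps count every Birth-death event, including lazy ones.

:func:`estimate` aggregates independent runs.  Each run gets its own
substream spawned from the master ``SeedSequence``, so results are
bit-reproducible and independent of execution order.  Runs hitting the
step cap are reported as censored and excluded from the estimators by
default; stopping mid-way otherwise over-represents trajectories that
die out quickly and biases the averages.  A pessimistic
censored-as-extinct mode is available for lower bounds on fp.

:func:`fpras_sample_plan` turns a proven fixation-time bound B into a
sampling plan with guaranteed additive error: Hoeffding gives the run
count for the target error/confidence, and a Markov-inequality step cap
of B * 2 n_runs / delta makes the total censoring probability at most
delta/2.  On balanced graphs fp >= 1/N^2, so dividing the additive
target by N^2 yields the relative-error (FPRAS) guarantee.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .bounds import TimeBoundReport, best_bound
from .exact import MoranParams
from .graph import DirectedGraph

log = logging.getLogger(__name__)

__all__ = ["RunResult", "SimulationEstimate", "SamplePlan",
           "run_once", "estimate", "fpras_sample_plan", "PlanningError"]

_BLOCK = 4096  # uniforms pre-drawn per batch


class PlanningError(RuntimeError):
    """No finite fixation-time bound available to back a sampling plan."""


@dataclass(frozen=True)
class RunResult:
    outcome: str        # 'fixed' | 'extinct' | 'censored'
    steps: int


@dataclass
class SimulationEstimate:
    """Aggregated Monte Carlo estimates with 95% confidence half-widths."""

    n_runs: int
    n_fixed: int
    n_extinct: int
    n_censored: int
    fp_hat: float
    t_hat: float            # mean steps among fixating runs (NaN if none)
    at_hat: float           # mean steps among all uncensored runs
    ci95_fp: float
    ci95_t: float
    ci95_at: float
    seed: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_runs", "n_fixed", "n_extinct", "n_censored", "fp_hat",
            "t_hat", "at_hat", "ci95_fp", "ci95_t", "ci95_at", "seed")}


@dataclass
class SamplePlan:
    """Run count and step cap guaranteeing |fp_hat - fp| <= additive_error
    with probability >= confidence."""

    n_runs: int
    step_cap: int
    additive_error: float
    confidence: float
    time_bound_used: TimeBoundReport

    def to_dict(self) -> dict:
        return {"n_runs": self.n_runs, "step_cap": self.step_cap,
                "additive_error": self.additive_error,
                "confidence": self.confidence,
                "time_bound_used": self.time_bound_used.to_dict()}


def _mask_to_list(s0, n: int) -> list[int]:
    if isinstance(s0, int):
        return [v for v in range(n) if s0 >> v & 1]
    return sorted(int(v) for v in s0)


def _simulate_one(out, n: int, r: float, mutants0: list[int],
                  rng: np.random.Generator, step_cap: int) -> RunResult:
    is_mut = bytearray(n)
    mut_list: list[int] = []
    pos = [0] * n
    for v in mutants0:
        if not is_mut[v]:
            is_mut[v] = 1
            pos[v] = len(mut_list)
            mut_list.append(v)
    res_list = [v for v in range(n) if not is_mut[v]]
    for i, v in enumerate(res_list):
        pos[v] = i
    m = len(mut_list)
    if m == n:
        return RunResult("fixed", 0)
    if m == 0:
        return RunResult("extinct", 0)
    steps = 0
    buf = rng.random(_BLOCK)
    bi = 0
    while True:
        if bi >= _BLOCK - 2:
            buf = rng.random(_BLOCK)
            bi = 0
        total = r * m + (n - m)
        x = buf[bi] * total
        bi += 1
        if x < r * m:
            u = mut_list[int(x / r)]
            u_mut = 1
        else:
            u = res_list[int(x - r * m)]
            u_mut = 0
        nbrs = out[u]
        v = nbrs[int(buf[bi] * len(nbrs))]
        bi += 1
        steps += 1
        if is_mut[v] != u_mut:
            if u_mut:       # resident v becomes mutant
                i = pos[v]
                last = res_list[-1]
                res_list[i] = last
                pos[last] = i
                res_list.pop()
                pos[v] = len(mut_list)
                mut_list.append(v)
                is_mut[v] = 1
                m += 1
                if m == n:
                    return RunResult("fixed", steps)
            else:           # mutant v becomes resident
                i = pos[v]
                last = mut_list[-1]
                mut_list[i] = last
                pos[last] = i
                mut_list.pop()
                pos[v] = len(res_list)
                res_list.append(v)
                is_mut[v] = 0
                m -= 1
                if m == 0:
                    return RunResult("extinct", steps)
        if steps >= step_cap:
            return RunResult("censored", steps)


def run_once(g: DirectedGraph, params: MoranParams | float, s0,
             seed: int | np.random.Generator,
             step_cap: int = 10 ** 9) -> RunResult:
    """Simulate one trajectory from initial mutant set ``s0``.

    ``s0`` is a bit mask or an iterable of node ids; ``seed`` an integer
    or a Generator.  Identical seed and inputs give an identical
    trajectory.
    """
    g.require_strongly_connected()
    if step_cap < 1:
        raise ValueError("step_cap must be >= 1")
    r = params.r if isinstance(params, MoranParams) else float(params)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return _simulate_one(g.out_neighbors, g.n_nodes, r,
                         _mask_to_list(s0, g.n_nodes), rng, step_cap)


def estimate(g: DirectedGraph, params: MoranParams | float, s0,
             n_runs: int, seed: int, step_cap: int = 10 ** 9,
             censored_as_extinct: bool = False) -> SimulationEstimate:
    """Aggregate ``n_runs`` independent trajectories from ``s0``.

    fp_hat is the fixed fraction among uncensored runs (normal-
    approximation 95% CI); t_hat the mean steps among fixating runs and
    at_hat over all uncensored runs (t-interval CIs).  With a single
    run, or no fixating run, the corresponding CI is NaN.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    g.require_strongly_connected()
    r = params.r if isinstance(params, MoranParams) else float(params)
    out = g.out_neighbors
    n = g.n_nodes
    mut0 = _mask_to_list(s0, n)
    children = np.random.SeedSequence(seed).spawn(n_runs)
    fixed_steps: list[int] = []
    extinct_steps: list[int] = []
    n_censored = 0
    for child in children:
        res = _simulate_one(out, n, r, mut0,
                            np.random.default_rng(child), step_cap)
        if res.outcome == "fixed":
            fixed_steps.append(res.steps)
        elif res.outcome == "extinct":
            extinct_steps.append(res.steps)
        else:
            n_censored += 1
    n_fixed, n_extinct = len(fixed_steps), len(extinct_steps)
    if n_censored and not censored_as_extinct:
        log.warning("%d/%d runs censored at step cap %d; excluded from "
                    "estimators (stopping mid-way biases the averages)",
                    n_censored, n_runs, step_cap)
    if censored_as_extinct:
        n_unc = n_runs
        n_ext_eff = n_extinct + n_censored
    else:
        n_unc = n_fixed + n_extinct
        n_ext_eff = n_extinct
    fp_hat = n_fixed / n_unc if n_unc else math.nan
    ci_fp = (1.96 * math.sqrt(fp_hat * (1 - fp_hat) / n_unc)
             if n_unc > 1 else math.nan)

    def t_interval(xs: list[int]) -> tuple[float, float]:
        if not xs:
            return math.nan, math.nan
        arr = np.asarray(xs, dtype=float)
        mean = float(arr.mean())
        if len(arr) < 2:
            return mean, math.nan
        se = float(arr.std(ddof=1)) / math.sqrt(len(arr))
        return mean, float(scipy.stats.t.ppf(0.975, len(arr) - 1) * se)

    t_hat, ci_t = t_interval(fixed_steps)
    at_hat, ci_at = t_interval(fixed_steps + extinct_steps)
    return SimulationEstimate(
        n_runs=n_runs, n_fixed=n_fixed, n_extinct=n_ext_eff,
        n_censored=0 if censored_as_extinct else n_censored,
        fp_hat=fp_hat, t_hat=t_hat, at_hat=at_hat,
        ci95_fp=ci_fp, ci95_t=ci_t, ci95_at=ci_at, seed=seed)


def fpras_sample_plan(g: DirectedGraph, params: MoranParams | float,
                      additive_error: float, confidence: float,
                      relative: bool = False) -> SamplePlan:
    """Sampling plan with guaranteed error from a proven time bound.

    n_runs = ceil(ln(2/delta) / (2 eps^2)) by Hoeffding (delta = 1 -
    confidence); step_cap = ceil(B * 2 n_runs / delta) by Markov, where
    B is the smallest applicable fixation-time bound.  With
    ``relative=True`` on a balanced graph the additive target is divided
    by N^2, converting the guarantee to relative error via fp >= 1/N^2.
    """
    if not 0 < additive_error < 1 or not 0 < confidence < 1:
        raise ValueError("need 0 < additive_error < 1 and 0 < confidence < 1")
    eps = additive_error
    if relative:
        if not g.is_balanced():
            raise PlanningError("relative-error mode needs a balanced graph "
                                "(uses fp >= 1/N^2)")
        eps = additive_error / g.n_nodes ** 2
    delta = 1.0 - confidence
    bb = best_bound(g, params)
    if not bb.applicable or bb.t_bound is None or not math.isfinite(bb.t_bound):
        raise PlanningError(
            "no finite fixation-time bound applies; use the exact solver "
            "or supply a manual step cap")
    n_runs = math.ceil(math.log(2.0 / delta) / (2.0 * eps * eps))
    step_cap = math.ceil(bb.t_bound * 2.0 * n_runs / delta)
    return SamplePlan(n_runs=n_runs, step_cap=step_cap,
                      additive_error=eps, confidence=confidence,
                      time_bound_used=bb)
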