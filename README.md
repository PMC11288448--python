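# moranbd — Moran Birth-death dynamics on directed graphs

`moranbd` computes how long natural selection takes on a spatially
structured population.  The population is a strongly connected directed
graph *G* = (*V*, *E*) on *N* nodes, each node holding one individual.
A single mutant with relative fitness *r* ≥ 1 invades a resident
population (fitness 1) under the classic Moran Birth-death update: each
step, a parent is drawn with probability proportional to fitness, a
uniform out-neighbour of the parent dies, and the parent's offspring
takes its place.  The mutant lineage eventually either *fixes*
(occupies every node) or goes *extinct*.

The package is for researchers in evolutionary graph theory and
population dynamics who need, beyond the classical fixation probability
fp<sub>r</sub>(G, S), the *timescale* of fixation on graphs with one-way
connections — where it can be exponentially long — and tools to decide
in advance whether simulation is feasible.  It provides:

* **Exact solvers** (`moranbd.exact`) — fixation probability, absorption
  time AT, conditional fixation time T and extinction time ExtT for all
  2^N configurations, related by
  AT = fp·T + (1 − fp)·ExtT, plus the neutral *N*-equation system whose
  solution fp<sup>(i)</sup> gives fp_min(G) = min_i fp_{r=1}(G, {v_i}).
* **Polynomial fixation-time bounds** (`moranbd.bounds`) — four regimes:
  r ≥ N² gives AT ≤ 2N³ and T ≤ 3N³ on any graph; Eulerian graphs with
  degrees in [δ, Δ] and r ≥ (Δ/δ)(1+ε) give T ≤ ((1+ε)(2+ε)/ε²)·N³;
  any graph with r ≥ 1 has T ≤ N⁶ / fp_min⁴; and *balanced* graphs
  (where each node's degree-reciprocal balance equality holds, which
  forces fp_{r=1}(G, {u}) = (1/deg⁻(u)) / Σ_v 1/deg⁻(v) ≥ 1/N²) have
  T ≤ N¹⁴ for every r ≥ 1.
* **A seeded simulator** (`moranbd.simulate`) with censoring-aware
  estimators and a sampling plan that turns a proven time bound into a
  run count (Hoeffding) and step cap (Markov) guaranteeing
  |fp̂ − fp| ≤ ε with chosen confidence — a randomized approximation
  scheme for fixation probability wherever a polynomial bound applies.
* **Isomorphism-free enumeration** (`moranbd.enumeration`,
  `moranbd.scans`) of all strongly connected digraphs on up to 5 nodes
  (1, 5, 83, 5048 classes for N = 2..5, re-derived from scratch) and
  exhaustive experiments over them: the stochastic-slowdown census, the
  fixation-time landscape under uniform initialization, and family
  scaling sweeps.

## Worked example

Generate the undirected star S₅ (one centre, four leaves, all
connections two-way), solve it exactly at r = 1.1, and bound its
fixation time:

```bash
$ moranbd generate --family star -p 5 -o s5.edges
wrote s5.edges: N=5, 8 edges

$ moranbd exact --graph s5.edges -r 1.1
```

yields (abridged) per-start-node values

```
fp_single: [0.0785, 0.2965, 0.2965, 0.2965, 0.2965]
ft_single: [53.48, 56.26, 56.26, 56.26, 56.26]
t_max:  56.26        fp_min: 0.058824
```

A leaf mutant fixes with probability 0.297 — the star amplifies
selection relative to the well-mixed value — and fixating invasions
last 56.3 Birth-death steps on average.  The smallest neutral
single-mutant fixation probability is 1/17 (the centre), matching the
balanced-graph closed form with indegrees {4, 1, 1, 1}.

```bash
$ moranbd bound --graph s5.edges -r 1.0
regime applicable       AT bound        T bound
    T1      False              -              -
    T2      False              -              -
    T3       True              -   1305015625.0
    T4       True              -   6103515625.0
best: T3 (T <= 1305015625.0)
```

At r = 1 only the fp_min-based and balanced-graph regimes apply;
N⁶/fp_min⁴ = 5⁶·17⁴ ≈ 1.3·10⁹ steps beats N¹⁴ ≈ 6.1·10⁹.  Either
certifies *before any simulation* that runs terminate on a polynomial
timescale.  A seeded simulation agrees with the exact solution:

```bash
$ moranbd simulate --graph s5.edges -r 1.1 --start 1 --runs 5000 --seed 1 --max-steps 100000
{'n_runs': 5000, 'n_fixed': 1505, 'fp_hat': 0.301, 't_hat': 57.26,
 'ci95_fp': 0.0127, 'ci95_t': 1.94, ...}
```

(exact leaf values: fp = 0.2965, T = 56.26 — inside both intervals).
Enumeration-scale experiments run the same way:
`moranbd enumerate -n 4 --count` prints `83`, `moranbd sweep -n 4`
runs the slowdown census, and `moranbd scan -n 5 -r 1.1` computes the
5048-graph landscape.

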