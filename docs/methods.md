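# Methods

## Model

The population structure is a strongly connected simple digraph
*G* = (*V*, *E*) on *N* nodes, one individual per node; two-way links
are pairs of opposite one-way edges, self-loops and parallel edges are
excluded.  Mutants carry relative fitness *r* > 0 (residents 1); all
guarantees implemented here concern *r* ≥ 1, but the solvers and the
simulator accept *r* < 1 (a disadvantageous invader) unchanged.

One step of the Moran Birth-death (Bd) process: draw a parent *u* with
probability proportional to fitness over the whole population, draw the
dying node *v* uniformly among *u*'s out-neighbours, copy *u*'s type
onto *v*.  The state is the mutant-occupied set *S* (an *N*-bit mask);
∅ and *V* are absorbing.  **Clock convention:** a "step" is every
Birth-death event, including lazy ones in which offspring replaces an
individual of the same type.  An active-steps-only clock
(`count_lazy_steps=False`) is provided for comparison but is never the
default, and none of the reported numbers use it.

## Exact solver

For *N* ≤ 14 (default guard; 2^N states) the absorbing chain is solved
directly.  With Q the transient-to-transient block and b the one-step
fixation-hit vector, one LU factorisation of (I − Q) is reused for four
right-hand sides: fp = (I−Q)⁻¹b; at = (I−Q)⁻¹1;
h = (I−Q)⁻¹fp with T = h/fp; g = (I−Q)⁻¹(1−fp) with ExtT = g/(1−fp).
The matrix is dense for *N* ≤ 11 and sparse (SuperLU) above.
Conditional times are undefined — reported as NaN, never 0 or ∞ — only
where conditioning has probability zero (T at ∅, ExtT at *V*; on a
strongly connected graph every transient state has 0 < fp < 1).
Identity and cross-checks (decomposition at = fp·T + (1−fp)·ExtT,
agreement with 1-D birth-death closed forms on complete and regular
graphs, agreement with an independent exact-rational Gaussian
elimination path, and with seeded simulation) are asserted at 1e−10
relative tolerance in the test suite.

The neutral (*r* = 1) single-mutant probabilities are obtained from the
*N*-equation stationarity system
(1/deg⁺(u))·Σ_{u→v} x_v = x_u·Σ_{w→u} 1/deg⁺(w), normalised to
Σ x = 1 (neutral fixation probability is additive over configurations,
which is also a property test).  Its minimum entry fp_min ≤ 1/N drives
the time bounds.

## Balance and its consequences

A graph is *balanced* when, at every node *v*,
(1/deg⁻(v))·Σ_{u→v} 1/deg⁺(u) = (1/deg⁺(v))·Σ_{v→w} 1/deg⁻(w).  The
check is done in exact rational arithmetic (`fractions.Fraction`), so
the predicate has no tolerance knob.  Balance is precisely the
condition under which the neutral law is the reciprocal-indegree law
x_u ∝ 1/deg⁻(u) — the closed form
fp_{r=1}(G, {u}) = (1/deg⁻(u)) / Σ_v 1/deg⁻(v) ≥ 1/N² — and the test
suite asserts this characterization in both directions.  Undirected
graphs, regular digraphs, directed cycles, cyclic complete multipartite
graphs (any part sizes) and the vortex family are balanced.

**Caveat on superstars and metafunnels.**  Under the standard wiring
implemented here (superstar: centre → all reservoirs, reservoir →
funnel chain → centre; metafunnel: root → widest layer, layers funnel
back to the root), instances with ℓ ≥ 2 arms (depth ≥ 2) are *not*
balanced: at a reservoir node the predecessor side is 1/(ℓm) while the
successor side is 1/m, and numerically their neutral law indeed
deviates from 1/deg⁻.  Only the degenerate instances (single arm,
depth 1) pass.  Claims that these amplifier families fall in the
balanced class must therefore refer to a different wiring or a
different balance notion; with the printed equality and the standard
construction they do not, and the tests assert the characterization
rather than family membership.

## Fixation-time bounds

All bounds are in steps of the discrete process.

* **T1** (strong selection): applicable iff r ≥ N²; AT ≤ 2N³, T ≤ 3N³.
* **T2** (Eulerian): applicable iff deg⁻ = deg⁺ everywhere and
  r > Δ/δ strictly; with slack ε, AT ≤ ((2+ε)/ε)N³ and
  T ≤ ((1+ε)(2+ε)/ε²)N³.  ε is always set to the maximal admissible
  slack rδ/Δ − 1, since both bounds are decreasing in ε; an override
  exists for reproducing intermediate values.
* **T3** (neutral-probability): applicable for any r ≥ 1;
  T ≤ N⁶/fp_min⁴.  If fp_min⁴ underflows double precision the bound is
  reported as +∞ with a warning, never as a garbage float.
* **T4** (balanced): applicable iff balanced and r ≥ 1; T ≤ N¹⁴,
  a function of N only.

`best_bound` returns the applicable regime with the smallest T bound
and attaches all four verdicts.  Note the winner is not always the
"obvious" one: on the star S₄, N⁶/fp_min⁴ = 4⁶·10⁴ ≈ 4.1·10⁷ beats
N¹⁴ ≈ 2.7·10⁸, and on Eulerian graphs with large degree slack the T2
bound can undercut 3N³ even when r ≥ N².  Soundness — no applicable
bound ever exceeded by the exact maximal fixation/absorption time — is
verified exhaustively over every strongly connected graph on 2–5 nodes
at r ∈ {1, 1.1, 2, 25}.

## Simulator and sampling plan

Trajectories use one uniform draw for the parent (inverse CDF over the
two fitness classes, then a uniform class member via swap-remove lists,
O(1) per step) and one for the victim.  Each run receives its own
`SeedSequence`-spawned substream from the master seed, so estimates are
bit-reproducible and order-independent.  Runs hitting the step cap are
*censored* and excluded from the estimators (with a logged warning):
treating capped runs as extinctions over-represents fast-dying
trajectories and biases both fp̂ and the time averages downward.  The
pessimistic censored-as-extinct mode is available explicitly as a lower
bound on fp.  Intervals: normal approximation for fp̂, t-intervals for
the time means, both at 95%.

The guaranteed-error plan uses Hoeffding for the run count,
n = ⌈ln(2/δ)/(2ε²)⌉, and Markov for the cap: with B the best proven
fixation-time bound, capping every run at ⌈B·2n/δ⌉ steps keeps the
total censoring probability below δ/2, giving |fp̂ − fp| ≤ ε with
probability ≥ 1 − δ.  These are standard constants chosen for
transparency, not the sharpest possible.  On balanced graphs dividing ε
by N² (via fp ≥ 1/N²) converts the guarantee to relative error.

## Enumeration

Labelled digraphs on n nodes are n(n−1)-bit masks.  Strong connectivity
is decided for all masks at once by boolean closure (batched uint8
matrix squaring of A ∨ I); survivors are canonicalised by taking the
minimum, over all n! relabellings, of the relabelled bit mask — one
integer matvec per permutation over the whole batch.  Distinct keys are
the isomorphism classes; decoding a key yields the canonical
representative, and idempotence (key(representative) = key) is a test
invariant.  The counts 1, 5, 83, 5048 for n = 2..5 are re-derived
independently (no nauty); n = 2, 3 are additionally cross-checked
against a pairwise networkx-isomorphism oracle.  n = 5 takes a few
seconds; n = 6 (2^30 masks, chunked) is gated behind `expensive=True`.

## Experiment conventions and discrepancies

**Slowdown census** (all 83 four-node graphs × 4 start nodes): the
fitness grid is r = 1.000, 1.005, …, 1.300 (61 points, resolving the
≈1.023 star peak); a pair counts as "fixation time goes up" when some
grid value of the exact conditional fixation time exceeds its r = 1
value by relative tolerance 1e−9.  The criterion string is embedded in
the output metadata.  Our count is **167 of 332** and is fully robust:
unchanged under grid halving and quartering, tolerance loosening to
1e−6 or tightening to strict inequality, a derivative-at-1 criterion, a
running-minimum (any local rise) criterion, and range extension beyond
1.3; the 165 non-increasing pairs are strictly decreasing in exact
rational arithmetic.  The published value of this census, 182, is
therefore not reproducible from the printed definitions (for reference:
an active-steps clock gives 96, absorption time 297, conditional
extinction time 93, death-Birth updating 180 — none yields 182).  The
corresponding reference-value test is expected to fail and documents
this.

**Star peak:** the leaf-mutant conditional fixation time on S₄ is
maximised at r = 1.023 (coarse grid plus bounded golden-section
refinement to 1e−5, reported to 3 decimals).  The increase is small
(≈0.02% above the neutral value); the *centre* start shows a larger
relative slowdown peaking near r ≈ 1.115.

**Landscape** (all 5048 five-node graphs, single mutant at a uniformly
random node): fp_uniform is the plain mean of single-mutant fixation
probabilities; t_uniform is fixation-weighted,
Σ_v fp_v·T_v / Σ_v fp_v — the expected length of fixating trajectories
of the mixture process — with the unweighted mean available behind a
flag (both conventions give identical extreme graphs here).  The
slowest graph at r = 1.1 and r = 2 is the undirected star S₅ under
both conventions.  The slowest *oriented* graph is the balanced 7-edge
hub/collector graph (0→1, 1→{2,3,4}, {2,3,4}→0), not the 6-edge
triangle-blade fan; the reference-value test asserting the fan is
expected to fail.  No 5-node oriented graph with the fan family's
stated counts (2k+1 nodes, 3k edges) is among the top seven slowest.

**Family wirings** (design choices, frozen):

* fan(k): hub plus k triangle blades h→a_i→b_i→h — the unique strongly
  connected uniform wiring with 2k+1 nodes and 3k one-way edges.  Not
  balanced for k ≥ 2.
* vortex(k): relay → batch A (k nodes) → relay' → batch B (k nodes) →
  relay; 2k+2 nodes, 4k edges, balanced for every k.
* four_column(k): four k-node columns with two-way vertical ladders,
  two-way rungs between the middle columns, one-way row-wise pressure
  edges from each side column onto its middle column, and two-way
  top-row couplings that make the side columns reachable (N = 4k).
  With mutants starting on the left half, fixation is several-fold
  slower at r = 1.1 than at r = 100 (where it is within a few N²
  steps); the separation grows with k but is modest at the sizes tested
  (k ≤ 3 exactly, simulation beyond).

**Scaling sweeps** (fan/vortex, seeded simulation, single uniform
mutant, conditional fixation time): at r = 100 the log-log slope of
time against N over k ∈ {4, …, 32} is ≈2.45, inside the quadratic band
[1.5, 2.5]; at r = 1.1 it is ≈2.9–3.0 (local slopes decline slowly,
from ≈3.1 near N = 10 to ≈2.75 near N = 65), outside the band at these
sizes — the weak-selection band test is expected to fail and records
this measurement.  The same ≈N³ weak-selection scaling holds for the
hub/collector family, so it is not an artefact of the blade wiring.

## Problem sizes and tolerances

Exhaustive experiments run at N ≤ 5 (5137 graphs, four fitness values;
about a minute of solves), the census at 61 grid points × 83 graphs,
CI-calibration at 100 replications × 400 runs, and scaling sweeps at
1200 runs per (family, k, r) — sizes chosen so the full suite solves
every claim exactly where exactness is feasible and keeps simulation
noise well below the asserted margins.  Cross-check tolerance is 1e−10
relative throughout; the balance predicate and the rational
verification solver are exact.

## Limitations

Death-Birth updating, weighted or multigraph structures, the megastar
family and the strong-selection limit T_∞ as a standalone quantity are
out of scope.  The exact solver is limited by the 2^N state space
(N ≤ 14); beyond that the bounds plus the planned simulator are the
intended tool.  Bound constants are as printed, not sharpened; lower
bounds on fixation time are not provided.
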