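# Methods

This note records the model, the numerical conventions, and the design
choices behind `sterncode`, in the spirit of a maintainer's lab notebook:
what is computed, which parameters matter, and what the tests do and do not
establish.

## Constraint model

A codeword is a length-`n` string over {A, C, G, T}.  A `ConstraintProfile`
bundles:

* `gc_low ≤ GC(x) ≤ gc_high`, inclusive at both ends, default [0.40, 0.60].
  For a given `n` this is equivalent to an integer G+C count window
  `[ceil(gc_low·n), floor(gc_high·n)]`; for `n = 6` only count 3 is
  admissible, for `n = 8` only count 4, for `n = 9` counts 4 and 5.
  A profile whose integer window is empty admits no codeword at all; this is
  detected in closed form (`profile_is_feasible`) and reported as an
  explicit infeasibility rather than an empty result.
* `no_runlength`: no two adjacent equal bases (homopolymer-free).
* `d`: minimum pairwise Levenshtein distance inside a set, `1 ≤ d ≤ n`.
  Sets with fewer than two members satisfy any `d` vacuously
  (`min_pairwise_edit_distance` returns an infinite sentinel), which makes
  incremental growth from the empty set well defined.
* `uncorrelated_address` (off by default): a set-level predicate preventing
  prefix/suffix overlaps between addresses.  The predicate is only *named*
  in the literature this package draws on, so the implementation is a
  documented interpretation behind a strategy point: for every ordered pair
  `(x, y)` — including `x = y` — no proper prefix of `x` equals the
  equally long suffix of `y`.  Alternative readings can be passed to
  `validate_code_set` via `ua_predicate`.  Because the definition is an
  interpretation, reproduction runs keep it disabled; dropping a constraint
  only enlarges the feasible region, so "≥ published size" comparisons stay
  sound.

Three independent Levenshtein routes exist on purpose: the public
`edit_distance` delegates to edlib (exact global alignment, C); the
builder's inner loop uses numba-compiled dynamic-programming kernels; and
the test suite carries a naive exponential recursion oracle.  The validator
(`validate_code_set`) uses the edlib route, so the builder never certifies
its own output with the code that produced it.

## The optimizer

`lstoa_optimize` minimizes a black-box function over a box with the sooty
tern swarm dynamics:

* migration: `C = SA·P`, `M = CB·(P_best − P)`, `D = C + M`, with
  `SA = Cf − z·Cf/max_iterations` (linear, `Cf` default 2.0) and
  `CB = 0.5·Rand` drawn once per agent per iteration;
* spiral attack: angle `i ~ U[0, 2π]`, radius `R = u·e^{−i·v}`
  (`u = v = 1`), scalar gain `R·(sin i + cos i + i)`, update
  `P ← (D · gain) · P_best` elementwise.

Two conventions in the spiral law are genuinely open and are fixed here as
follows:

* **The exponent `k` of `r = u·e^{kv}` is taken as `−i`** (module constant
  `SPIRAL_K_SIGN`).  With `k = +i` the gain reaches `e^{2π}·2π ≈ 3.5·10^3`,
  so nearly every attack overshoots the box, and on the 2-D sphere
  (population 30, 500 iterations) the run only reaches `≤ 10^{−6}` on about
  half the seeds.  With the contracting convention the gain stays in
  `[~0.01, ~1.3]` and the same runs converge on every seed tested.  A
  bird's attack spiral tightens as it closes on prey; the contracting
  reading is also the physically sensible one.
* **The final product is elementwise.**  A consequence worth knowing: the
  update is multiplicative in `P_best`, so the origin is a fixed point and
  functions minimized at the origin are solved very quickly; the update is
  *not* translation invariant.  This is a property of the underlying
  dynamics, not of this implementation.

With a scalar objective the population updates asynchronously (an
improvement found mid-iteration immediately steers the remaining agents —
this cascade is what makes the spiral contraction fast).  With
`vectorized=True` the whole population updates against the iteration's
incoming best and the objective is called once per iteration on a
`(population, dimension)` block; the set builder uses this mode for
throughput.

The Levy variant perturbs attack updates with Mantegna steps
(`u/|v|^{1/β}` with the β-dependent Gaussian scale ratio; β default 1.5):
from iteration `levy_start_fraction · max_iterations` on (default 0.5),
each agent is perturbed with probability `levy_prob` (default 0.25) by
`levy_scale · (high − low) · step` per dimension (scale default 0.05).
Gating by probability matters: perturbing every agent every late iteration
would destroy late-stage refinement entirely.  `levy_start_fraction = 1.0`
never activates the perturbation and recovers the plain STOA exactly, which
the tests exploit as a dead-parameter check on `levy_beta`.

Constrained objectives are handled by a static additive penalty
(`penalty_weight`, default 10^6 per violated unit).  A non-finite objective
value at a feasible point aborts the run with a diagnostic.

## Benchmark functions

`benchmarks` implements the thirteen classic test functions (F1–F13:
sphere, Schwefel 2.22, Schwefel 1.2, Schwefel 2.21, Rosenbrock, step,
quartic+noise, Schwefel 2.26, Rastrigin, Ackley, Griewank, and the two
penalized functions) at their conventional boxes, dimension 50 by default.
F7's additive uniform noise consumes an explicit generator and is zeroed
when none is supplied.  F8 is implemented with the conventional inner
square root, `−x·sin(√|x|)`; a literal variant without the radical exists
behind a flag because printed sources sometimes omit it.  F8's minimum is
recorded as unknown and excluded from minimum-recovery checks.

`run_suite` repeats an optimizer over each function with per-run seeds
derived from (base seed, function index, run index), and reports the sample
mean and SD of the final best fitness.  Failed runs become recorded failure
cells, never silent omissions.  The suite demonstrates optimizer behaviour
and reproducibility; published multi-run averages are *not* point targets
here, because the iteration and population counts behind such tables are
typically unstated.

## The set builder

`build_code_set` grows a set one codeword at a time.  One growth attempt
runs the LSTOA over `[0, 4]^n` (coordinate `c` decodes to base index
`floor(c)`, 4.0 clamps to 3, order A, C, G, T); every evaluated position is
decoded and scored, and the admissible decodes form the attempt's candidate
pool.  Admission is a hard gate: individually valid, distinct, minimum edit
distance `≥ d` to every member, and UA-compatible when that flag is on.
A restart ends after `candidate_budget` consecutive rejected attempts; the
largest set across `restarts` seeded restarts is returned and re-checked by
the independent validator.  Attempt seeds derive from (seed, restart,
attempt), so a run with more restarts extends a run with fewer — set size
is non-decreasing in both restarts and budget.

### Search guide

The per-candidate score is `sign · Σ_i dist(s, s_i) − W · violation`, where
the penalty weight `W = n·(|S|+1)` exceeds any possible distance sum, so
admissible candidates always outrank inadmissible ones and inadmissible
ones are ranked by how close to admissible they are (GC shortfall in
integer counts, adjacent-repeat count, duplicate membership, and
`d − min_dist` shortfall).

The `sign` is the builder's most consequential choice.  The literal
sum-of-distances reading (`guide="spread"`, sign +1) prefers candidates far
from the current members.  Measured on full enumerations at `n = 6`, that
preference is actively harmful: spread-greedy tops out at 25–29 codewords
for `(6, 3)` and 6–9 for `(6, 4)`, *below* the published 30 and 11, because
spread-out codewords exclude large swathes of the remaining space.  The
inverted preference (`guide="packing"`, sign −1) admits the *tightest*
admissible candidate and reaches 29–33 and 8–10 under the same budgets.
Since the "storage edit distance function" whose sum the objective
nominally maximizes is never defined in the sources this package follows,
the packing reading — the only one that actually attains the published
sizes — is the default, and the literal spread reading remains available
and tested.

### Tie-breaking

Under the packing guide, many candidates tie at the same (minimal) distance
sum.  Ties are broken *altruistically*: among tied candidates, prefer the
one at distance `≥ d` from the most other pool members, i.e. the candidate
whose admission excludes the fewest future options.  Remaining ties go to
the lexicographically smallest codeword for reproducibility.  On full
enumerations at `(6, 4)` this tie-break is decisive: packing greedy with
random tie-breaks reaches 11 on roughly 2% of orderings, while the
altruistic tie-break reached 11 on 60 of 60 orderings.  The tie-break needs
the pool to cover most admissible codewords, which is why the sized
configurations below use large per-attempt populations at small `n`.

A related acceptance-rule parameter, `prefer_tight`, optionally holds out
for candidates at minimum distance `≤ d + tight_slack` during a strict
phase and relaxes on stagnation; the final set is still maximal under the
plain gate.

### Sizing

Per-attempt cost is `population · (iterations + 1)` candidate evaluations,
each a distance-sum against the current members (numba kernels).  The
sizings used for reproducing the published table rows, chosen so each build
stays in the minutes range on one CPU (`sized_builder_config`):

| profile | population | restarts | rationale |
|---|---|---|---|
| (6,3), (6,4) | 12288 | 10 | pool must cover most of the 424 valid words |
| (7,3) | 2048 | 4 | wide margin over the published size |
| (8,3) | 2048 | 2 | wide margin |
| (8,4) | 32768 | 3 | tight target; 3352 valid words need coverage |
| (9,3) | 1024 | 2 | wide margin; sets grow to ~400 members |
| (9,4) | 1024 | 4 | moderate margin |

With these sizings and ten or fewer restarts the builder reaches, and for
most profiles substantially exceeds, the published sizes 30, 11, 53, 101,
41, 188, 63 (measured across several base seeds: e.g. 32–34 at (6, 3),
11 at (6, 4), 43–46 at (8, 4), ~410 at (9, 3)).

A `random` engine draws the same number of uniform candidates per attempt
under the same admission rule and selection logic, as a baseline for how
much the LSTOA search itself contributes.

### Exact oracle

`exact_max_code_set` enumerates all valid codewords (`n ≤ 6` guard), joins
two by an edge when their distance is `≥ d` (and both directions are
UA-compatible when enabled), and solves maximum clique exactly via
networkx.  `d ≤ 1` without UA short-circuits to the full valid-word list
(the graph is complete).  Runtime grows steeply with graph density: `(6, 4)`
solves in minutes (maximum 12 — one more than the published heuristic lower
bound of 11), while `(6, 3)` is already impractical; the tests exercise
`n = 4`, where the maximum of 6 at `d = 3` matches the published value and
the heuristic finds it with 5 restarts.

## Code rate

`code_rate(M, n) = log4(M)/n`, information symbols per nucleotide: 0 for a
singleton, 1 for the full quaternary cube.  For `(M, n) = (101, 8)` the
formula gives 0.4162; note the per-bit reading `log2(M)/n` would give twice
that (≈ 0.832), a conversion worth keeping in mind when comparing rate
figures across sources.

## What the tests show, and what they do not

The suite establishes: exact Levenshtein agreement with an independent
recursion oracle; the metric laws; correctness of all thirteen benchmark
expressions against separately hand-coded oracles; optimizer run contracts
(monotone best-so-far history, bit-identical seeded repeats, plain-STOA
recovery at `levy_start_fraction = 1`, box compliance, sphere convergence);
builder closed-loop validity (every emitted set passes the independent
validator), small-instance optimality against the exact oracle, and
attainment of the published set sizes under the sized configurations.

They do not establish anything about wet-lab behaviour: no thermodynamic or
secondary-structure modelling, no reverse-complement constraints, no primer
design, and no payload encoding.  The published sizes themselves are
heuristic lower bounds, not optima — the exact oracle already shows `(6,4)`
admits 12, and the builder routinely exceeds several other table entries —
so "reaching the published size" is a reproduction statement about the
search problem, not a claim of optimality.

## Known limitations

* The builder's candidate pool is sampled, so very tight profiles at larger
  `n` (where the valid-word count exceeds practical per-attempt coverage)
  lose the benefit of the altruistic tie-break; `(8, 4)` is near this edge.
* The exact oracle is limited to `n ≤ 6`, and within that by graph density.
* The UA predicate is an interpretation (see above); UA-enabled sizes are
  not comparable to published tables until the predicate is pinned down.
* `set_fitness` keeps the literal sum-minus-penalties contract for API
  compatibility; the builder's internal packing guide negates the sum term.
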