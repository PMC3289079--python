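# Methods

## Model

A protein is an HP string `s = s_1…s_n`. A conformation is a
self-avoiding walk of the chain on the 2D triangular lattice, encoded
as a fold string of length n−1 over the six absolute step directions.
The lattice is held in integer axial coordinates with unit steps
R = (1,0), RU = (0,1), LU = (−1,1), L = (−1,0), LD = (0,−1),
RD = (1,−1); the directions are numbered 0..5 counter-clockwise so a
60°·k rotation is addition of k mod 6, and two sites are neighbors iff
their difference d satisfies |d_x| ≤ 1, |d_y| ≤ 1, |d_x + d_y| ≤ 1 with
d ≠ 0 (hex distance 1). Integer coordinates make self-avoidance and
contact tests exact; the Euclidean embedding (x + y/2, y·√3/2) is used
only for geometry checks and plots.

The free energy is −1 per topological H–H contact: a pair (i, j),
j > i+1, with both residues H and their sites at unit distance. Since
each residue has at most six neighbors and two are covalently bonded
(one at the ends), a residue takes part in at most four contacts and
0 ≥ E ≥ −2·#H always.

## Penalized fitness

The search operates on unrestricted fold strings, so chromosomes may
self-collide. Rather than repairing or rejecting them, fitness adds a
penalty of 4n per colliding residue pair (counting pairs, not sites) on
top of the raw contact score, computed on the coordinates as laid out.
4n strictly exceeds any attainable contact count, so every infeasible
chromosome ranks below every feasible one, while the raw contact term
and the pair count give the landscape a gradient toward feasibility.
Counting contacts on colliding layouts is a modeling convenience; it
cannot affect reported results because the returned best is always
feasible (asserted in code and tests).

## ERS-GA

Population 200 (fold strings drawn uniformly), fitness-sorted; each of
200 generations keeps the top half unchanged and replaces the bottom
half with offspring: parents are paired by a random shuffle, each pair
undergoes two-point crossover with probability 0.8 (cut points p ≤ q
uniform on 0..n−1; p = q clones), and each offspring undergoes uniform
mutation at rate 0.4. Sorting is stable, so equal-fitness ties keep
insertion order and runs are bit-reproducible from one seeded NumPy
generator whose draw order is fixed (init → pairing → crossover →
mutation → local search).

Two points in the reproduction scheme are genuinely ambiguous, and the
package resolves both empirically; the alternatives remain available as
`GAConfig` switches:

* **Mutation semantics** (`mutation_scope`). Read per-gene, rate 0.4
  re-draws ~40% of all loci and nearly randomizes each offspring; the
  GA then behaves like random search (on the 20-residue benchmark, 10
  seeds: HHGA mean −11.4, ERS-GA mean −6.0, far from the published
  −14.73 / −12.5). Read per-chromosome — with probability 0.4 one
  random gene is re-drawn — the published means are reproduced closely
  (HHGA −15.0, ERS-GA −12.4). The default is `"chromosome"`.
* **Parent pool** (`parent_pool`). Breeding exclusively from the
  bottom half (the literal reading of "crossover and mutation on the
  second half") removes selection pressure from the breeding lineage;
  pairing across the whole population performs markedly better and
  matches the published numbers. The default is `"whole"`.

The best feasible individual ever seen is tracked across generations;
with pure elitism it coincides with the final best, but tracking is
kept for robustness. If no feasible chromosome ever appears (possible
only in pathological configurations — a straight chain is always
feasible and mutation reaches it), the run reports an explicit
no-solution status instead of an infeasible fold.

## Hill climbing and the HHGA

* **Local search I** — one pass visits every gene in a random order,
  proposes a uniformly random different direction, and accepts iff
  fitness strictly improves (first-improvement).
* **Local search II** — one pivot uniform among the interior gene
  positions 1..n−2; the five rotations of all genes from the pivot
  onward by 60°k rigidly rotate the decoded tail about the pivot
  residue; the best of the five replaces the input iff it strictly
  improves, ties favoring the smallest angle.

Strict improvement (no plateau moves) guarantees termination and
monotone traces. The HHGA applies LS-I (one pass) then LS-II (one
pivot) to every newly bred offspring before insertion; elite members
are not re-searched. This costs about (n+5)× the fitness evaluations of
the plain ERS-GA per generation — the same order as the published ~5×
runtime ratio. Per-offspring budgets (`ls1_passes`,
`ls2_trials_per_offspring`, `ls2_scan_all`) are configurable; with a
zero budget the HHGA reduces exactly to the ERS-GA under the same seed.

## Oracle

Exact minima for short chains come from depth-first enumeration of all
self-avoiding fold strings with prefix pruning and incremental contact
counting over a site dictionary — an implementation deliberately
independent of the search path's grid kernel. Lattice symmetries are
quotiented: the first step is fixed to R (kills the 6 rotations) and
the first step off the R/L axis is restricted to the upper half-plane
(kills the reflection), a ~12× reduction that leaves the minimum
unchanged; the optimum count is then per symmetry class. The unpruned
enumeration remains available and the two are cross-checked over all
sequences up to length 6 (plus sampled length 7) in the tests. The
default size guard refuses n > 12 (the space grows like ~4.15^n).

## Numerical and engineering choices

* Inner loops (decode, contact/collision counting, both local
  searches) are numba-compiled; collision pairs are counted exactly via
  per-site index chains, so multiply-occupied sites contribute C(k,2).
  The kernel is verified against an independent vectorized all-pairs
  counter and against the oracle in the test suite.
* All integers; no floating-point enters the fitness, so results are
  machine-independent given the seed.
* Repeated runs use consecutive seeds base, base+1, …; published-table
  protocols use 30 runs. The acceptance script runs the full 30-run
  protocol for benchmarks 2–6; the test suite uses 30 runs for the
  short benchmarks (lengths 20–36) and 10 runs for lengths 48–50, the
  package's choice of a desk-scale protocol for its own regression
  checks.

## What the tests do and do not show

Benchmarks are the eight published HP chains (lengths 20–64); there is
no synthetic biology here — the HP model itself is the abstraction, and
its known limitations apply: two-letter alphabet, 2D lattice backbone
geometry, no side chains, contact-only energetics. Matching the
published best energies shows the search reproduces the reference
optimization results, not that the folds resemble real tertiary
structures. Lengths 60–64 are reported by the tooling but not gated in
tests: at this budget the search lands a few contacts above the
published bests, consistent with the stochastic spread reported there.
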