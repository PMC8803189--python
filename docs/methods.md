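# Methods

## Model

A synchronous Boolean network over nodes x_1 … x_n assigns each node an
update function f_i over its input set IN(x_i); the global state
**x**(t+1) = **f**(**x**(t)) updates all nodes simultaneously. Determinism
plus a finite state space make every trajectory eventually periodic; the
cycle it enters is an attractor with period t_p ≥ 1. Only synchronous
semantics are supported: in bipartite reaction/state models a consumption
update unmatched by its production update would silently delete a component,
so those models are only meaningful under synchronous updates, and the
trajectory-based search relies on deterministic successors.

States are bit tuples in node order; the integer view places x_n in the
least significant bit. This convention fixes the within-weight tie order of
the search (below) and makes canonical attractor phases well defined
(rotation to the numerically smallest cycle state).

The `targets, factors` text dialect is a compatible subset of the BoolNet
format (operators `&`, `|`, `!`, parentheses, constants 0/1, `#` comments).
Probabilistic rules and `all()` are rejected explicitly rather than
misparsed. Constant rules (`name, 0`) express clamped inputs. Per-step cost
is O(total expression size): each rule is compiled once to Python bytecode
over the state tuple, so networks in the thousands of nodes step at
microsecond-per-node rates and never materialize 2^k truth tables.

A note on the bundled 3-node example: its second and third rules are read as
x1 ∧ ¬x3 and x1 ∧ ¬x2 (negation binding the single variable). This reading
is the one consistent with the example's published attractor census (two
fixed points and one period-2 cycle); the alternative scope ¬(x1 ∧ x3) is
not used.

## Prior-guided search

A prior assigns each node a guess bit and a confidence in (0, 1].
Canonicalization flips any guess with confidence below 0.5 (guessing 1 with
probability 0.3 *is* guessing 0 with probability 0.7), after which
confidences lie in [0.5, 1]. Nodes partition into classes by confidence:

* **fixed** (p = 1): never flipped; start vectors always carry the guess;
* **informed** (0.5 < p < 1): flips are rationed by likelihood;
* **uninformed** (p = 0.5): no information; enumerated exhaustively.

**Single-class order.** Start vectors are ordered by Hamming distance k from
the guess, and within a distance class by increasing numeric value of the
flip pattern (x_n least significant): 000, 001, 010, 100, 011, 101, 110,
111 for n = 3. The theory is insensitive to the within-class tie-break; this
one is fixed so that ranks are computable. The trial index of any vector is
S(m, k) + colex(flips) + 1 over the m flippable bits, where colex is the
combinatorial-number-system rank Σ C(c_i, i) of the flipped significance
positions — O(n) big-integer arithmetic. This is what lets the benchmark
count trials with means of order 10^10 without enumerating anything, and it
is mathematically identical to running the search with the success test
"start vector equals target" and counting trials.

**Multiple classes.** The published description fixes only "higher
probabilities before lower ones" with per-class flip thresholds; the exact
interleaving is a design choice here. Flip-count tuples (k_1 … k_h) over the
informed classes are enumerated in nondecreasing total log-odds cost
Σ k_c ln(p_c/(1−p_c)) — the most probable flip patterns first, which reduces
to the single-class order when h = 1 — with ties broken by fewer total flips
then lexicographic tuple. Within a tuple, the Cartesian product of per-class
constant-weight patterns runs with higher-confidence classes varying slower.
Theory-level tests avoid depending on tie order.

**Uninformed bits.** For each informed pattern, all 2^n2 assignments to the
p = 0.5 bits are enumerated innermost in a pseudo-random order, seeded
deterministically from (stream seed, informed-pattern index): blocks up to
2^16 use a Fisher–Yates permutation; larger blocks use a lazy affine
bijection j ↦ (a·j + b) mod 2^n2 with odd a, so the stream needs no stored
permutations. Randomness here only serves to avoid systematic bias in which
uninformed corner is explored first; determinism makes runs reproducible.

**Trials.** Each trial simulates from the next start vector, keeping a
visited map from state integer to time index, so the first repeated state
and its earlier position t′ are found in one pass and the attractor is
⟨x(t′) … x(T)⟩. The default step cap is 100·n (transients of practically
occurring networks are far shorter — see the trajectory benchmark); capped
trajectories count as failed trials. Transient length excludes the cycle.
First-hit mode stops at the first attractor matching the criteria (period
range and/or node values required stable in every cycle state; an
"in some state" variant exists behind a flag). Collect-all mode runs to
exhaustion or limits, deduplicating canonical attractors in discovery order.
The time limit is checked between trials, the trial limit exactly. There is
no cross-trial memoization of visited states: the expected-trials analysis
treats trials independently, and memoization would trade O(trajectory)
memory for O(2^n).

## Closed-form expectations

E(n, p) uses the collapsed inner sum C(n,k)·S(n,k) + C(n,k)(C(n,k)+1)/2 and
exact `fractions.Fraction` arithmetic for n ≤ 64 (the benchmark sizes are
exact); beyond that, log-sum-exp in double precision. p = 0.5 and p = 1 are
admitted as the uninformed and certain limits (E = (2^n+1)/2 and 1). The
envelope f(α*)^n · n² fixes the unspecified asymptotic constant at 1 and is
documented as an envelope, not a tight bound; comparison tests assert only
the inequality direction against E. Reporting rounds bases to 3 decimals;
the naive-ratio comparison uses the literal 3-decimal base 1.917 by default,
since that is how the headline ratios are defined. `log_naive_ratio` is
exposed because the ratio itself overflows doubles near n ≈ 25 000.

## Synthetic benchmarks

The N-K generator draws, per node, K distinct inputs uniformly (self-inputs
allowed by default, a flag disallows them) and an independent uniform random
truth table, realized as a minterm expression — exact semantics, bounded
size at the K = 2 used throughout. All generators derive their RNG streams
from a master seed via labeled CRC-derived offsets, so every experiment is
reproducible bit-for-bit.

* **Trial counts** (sizes up to 40, confidences 0.7–0.9, 1000 replicates):
  a target attractor state is obtained by simulating a seeded network from a
  random state; each replicate perturbs it bitwise (keep probability p) into
  a guess and computes the closed-form trial index. The analytic E(n, p) is
  the exact expectation of this statistic, and the suite checks agreement
  within 3 standard errors. Caveat: the trial-index distribution is heavily
  right-tailed at N = 40 (rare many-flip perturbations dominate the mean),
  so 1000-replicate means scatter widely around E — comparisons at that size
  are order-of-magnitude by nature.
* **Trajectory lengths** (N up to 100, 100 replicates): mean transient from
  uniform random starts, cycle excluded, truncations reported and excluded.
  Means stay well under 300 at N = 100, K = 2, which also justifies the
  default step cap.
* **Guided vs random restarts** (N ∈ {10..40}, p = 0.9): total transient
  steps until the target attractor is reached, restarting from prior-ordered
  vs uniform random states. Both methods identify the target by canonical
  attractor identity. The guided totals are asserted no worse than the
  random ones within a 3-SE margin; individual small-N cells are noisy
  because basin structure varies strongly across random networks.
* **Scenario sweeps**: fixed nodes at confidence 1 (e.g. a microenvironment
  configuration and constitutively active inputs), remaining nodes guessed
  all-ON or all-OFF at a swept confidence, collect-all under limits. This is
  the protocol used for real models; the suite exercises it on toy networks.

What the synthetic generators do *not* emulate: realistic topology
(scale-free in-degree, canalyzing functions), correlated priors, and the
bipartite reaction/state structure of large mechanistic models. Passing
benchmarks therefore validate the algorithm and its counting — not any
biological claim about a particular network.

## Annotation rules

Behavior classification requires a marker signature to hold in every cycle
state (a stable signature); an oscillating marker or a non-matching stable
pattern yields "atypical". Signatures may be partial — unnamed markers are
unconstrained — and the bundled endothelial-cell scheme (phalanx: AKT=1,
JAGa=0, NRP1=0; stalk: JAGa=1, NRP1=0; tip: NRP1=1, DLL4a=1, AKT=0) is
mutually inconsistent by construction; user schemes that let two behaviors
match the same attractor raise a configuration error rather than picking one.

For bipartite models, an attractor is *valid* iff every mutually exclusive
stage group has exactly one true member in every cycle state (and every
required component, when given, is represented in every state); otherwise
the attractor is a technical artifact. A valid attractor is *viable* iff it
is periodic and traverses every stage of every group; point attractors are
always lethal. A component is called *absent* (an in-silico deletion mutant)
when all its state nodes are constitutively 0 while the reference attractor
activates at least one of them; constitutively-zero nodes outside any
component are listed as residue for manual review. Group, marker and
component tables are user-supplied TSV configs — the model-specific tables
of large published networks ship with those models, not with this package.

## Problem sizes and determinism

The test suite and the acceptance script run in seconds: enumeration oracles
use n ≤ 10 (the exhaustive check is over 2^n states), rank/unrank is checked
exhaustively at n = 12, the trial-count benchmark uses the closed-form rank
(no simulation), and the trajectory benchmark simulates 100 networks of 100
nodes. Every stochastic quantity is seeded; hypothesis profiles are
derandomized. Statistical assertions use 3-standard-error margins.

## Known limitations

* No guarantee of finding attractors whose every state is far from the
  guess within the configured limits; the method is a guided heuristic with
  an expected-case guarantee, not a complete enumerator (full enumeration
  via collect-all exists but costs ≥ 2^n trials).
* Asynchronous update schemes are out of scope (trajectories are not unique
  there, so the trial construction does not transfer).
* The multi-class interleaving and uninformed-block orders are fixed
  conventions; other implementations may order ties differently while
  matching the same theory.
* Exact E(n, p) beyond n = 64 falls back to double precision; relative error
  is negligible for plotting but not exact.
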