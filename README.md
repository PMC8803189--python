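# attapriori

Prior-guided attractor detection in synchronous Boolean networks.

Boolean networks (BNs) model gene regulation and signaling qualitatively:
each node carries 0/1 and updates synchronously through a Boolean function of
its inputs. The long-term behavior of a BN is its *attractors* — fixed points
(period 1) or cycles of period t_p > 1 — which are read as the stable cellular
states or programs of the modeled system. Finding attractors is hard: there
are 2^n global states, the problem is NP-hard in general, and no exact method
beats the naive O(2^n) sweep for long periodic attractors.

This package implements a search that breaks that barrier *in expectation*
when per-node a priori information is available. Suppose for each node you
can guess its value b_i in one state of the attractor you are after, and the
guess is right with probability p_i ≥ p > 0.5 (from binarized expression
data, a known related attractor, or an assumed scenario). The search tries
start vectors in order of plausibility — the guess itself, then all vectors
one flip away, then two, and so on — simulating each trajectory to its first
repeated state. The expected number of trials until the target state itself
is examined is exactly

    E(n, p) = Σ_k p^(n−k) (1−p)^k Σ_{j=1..C(n,k)} (S(n,k) + j),
    S(n, k) = Σ_{i<k} C(n, i),

which grows like f(α*)^n · n² with α* = 1/(1 + √(p/(1−p))),
β = (1/α)^α (1/(1−α))^(1−α) and f(α) = p^(1−α)(1−p)^α β². The base f(α*) is
strictly below 2 for any p > 0.5 — e.g. **1.917** at p = 0.7 and **1.600** at
p = 0.9 — so informative priors buy an exponential speedup over the naive
sweep while the algorithm stays exact about what it reports: every returned
attractor is a genuine cycle of the dynamics.

The toolkit is aimed at systems biologists analyzing mid-to-large logical
models (it handles networks with thousands of nodes, e.g. bipartite
reaction/state models of the cell cycle) and comprises:

* `network` — BoolNet-compatible `targets, factors` dialect, expression
  trees, synchronous stepping;
* `dynamics` — trajectory simulation with cycle detection, canonical
  attractors, exhaustive enumeration for small n;
* `search` — prior canonicalization, closed-form rank/unrank of start
  vectors, the prior-ordered stream (multi-class confidences, thresholds,
  uninformed bits), first-hit and collect-all search;
* `theory` — exact E(n, p) (rational arithmetic), complexity constants,
  log-domain envelopes;
* `synthetic` — seeded random N-K networks, guess perturbation, AND↔OR
  functional mutants;
* `experiments` — the trial-count, trajectory-length, guided-vs-random and
  scenario-sweep benchmark protocols;
* `annotation` — attractor interpretation: behavior marker signatures,
  validity/viability of bipartite-model attractors, in-silico deletion-mutant
  calls.

## Worked example

The bundled 3-node network (`x1 ← x3`, `x2 ← x1 ∧ ¬x3`, `x3 ← x1 ∧ ¬x2`) has
two fixed points and one period-2 cycle:

```sh
$ attapriori enumerate-all --network example.txt
period=1 basin=3 cycle=000
period=1 basin=1 cycle=101
period=2 basin=4 cycle=011 -> 100
total attractors: 3
```

States are printed as bit strings in node order (`011` means x1=0, x2=1,
x3=1); `basin` counts the start states leading to each attractor (3+1+4 = 2³).

Searching with a prior guess of (1,1,0) at confidence 0.9 per node, asking
for a periodic attractor:

```sh
$ attapriori detect --network example.txt --prior prior.tsv --period-min 2 --out hit.jsonl
seed=0 mode=first_hit
trials=2 termination=criteria_met attractors=1
$ cat hit.jsonl
{"period": 2, "kind": "periodic", "cycle": ["011", "100"], "canonical": true, "nodes": ["x1", "x2", "x3"]}
```

Trial 1 starts at the guess (1,1,0) and falls into the fixed point 000, which
the period criterion rejects; trial 2 flips the least-significant admissible
bit (start 111… i.e. pattern 001 applied to the guess) and lands in the
period-2 cycle {011, 100}, which is returned.

The closed-form theory for the same quantities:

```sh
$ attapriori theory base --p 0.7
p=0.7 alpha*=0.395644 beta=1.956595 base=1.917
$ attapriori theory expected-trials --n 2 --p 0.75 --exact
E(2, 0.75) = 7/4 = 1.75
$ attapriori theory ratio --n 1000
2^1000/(1.917^1000*1000^2) = 2.558e+12
```

With two bits guessed at confidence 3/4 the expected number of trials is
7/4 — versus 5/2 for an uninformed sweep — and at n = 1000 the guided
envelope is twelve orders of magnitude below the naive one.

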