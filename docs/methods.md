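# Methods

## Overview

`causalmi` learns a partially oriented mixed graph from an observational
sample-by-variable table in four stages:

1. **Skeleton.** Starting from the complete graph, every pair whose
   regularized mutual information I′(X;Y) rectifies to zero is removed with
   an empty separating set.  For the surviving edges the algorithm
   iteratively collects *information contributors*: at each step it picks
   the edge whose residual I′(X;Y|{Ai}) minus its best next contribution is
   smallest (the most confidently reducible edge), adds the contributor
   with the largest strictly positive contribution
   I′(X;Y;Ak|{Ai}k−1) = I′(X;Y|{Ai}k−1) − I′(X;Y|{Ai}k), and deletes the
   edge as soon as its rectified residual reaches exactly zero, recording
   the ordered contributor list as the separating set.
2. **Orientation.** Unshielded triples X−Z−Y are scored by the conditional
   3-point information I′(X;Y;Z|{Ai}), computed as the difference of two
   *rectified* conditional terms on a shared complete-case sample.
   Negative N·I′3 signals a v-structure, with head probability
   P = (1+e^{N·I′3})/(1+3e^{N·I′3}) carried as the numerically stable score
   score_v = −N·I′3 + log1p(e^{N·I′3}) − ln 2, P = σ(score_v).  An existing
   arrowhead into Z induces a mark (head for negative, tail for positive
   3-point terms) on the opposite edge at Z with the rectified induced
   score score_i = max(0, m − log1p(e^{m−M} + e^{−M})),
   m = min(N·|I′3|, score_src), M = max(...), which can never exceed the
   confidence of its source.  Marks are applied strictly in decreasing
   score order and are never overwritten by lower-scoring events; equal
   scores resolve by lexicographic triple order.  With propagation enabled
   an induced tail at Z on X−Z is propagated as a head at the X end when
   that end is still undefined.
3. **Classification.** Each endpoint carries separate head and tail
   probabilities.  Against a confidence threshold β ∈ [0.5, 1): a head on
   one side with p_head>β and a tail on the other with p_tail>β is a
   *genuine* cause; a single significant head is *putative*; two
   significant heads are a *bidirected* edge (unobserved common cause);
   anything else stays undirected.  Tails come only from induced-tail
   scores and from contextual priors: a variable declared contextual
   (e.g. sex, year of birth) has p_tail = 1 at all of its endpoints and
   never receives an arrowhead.
4. **Consistency (optional).** Learning is repeated with contributor
   candidates filtered against the previous graph — skeleton level: the
   candidate lies on a simple path between the pair's extremities (checked
   through the block-cut tree); orientation level: additionally a
   non-descendant neighbor of an extremity, where descent follows
   head-marked directed edges only — until the graph sequence enters a
   limit cycle.  The edge-union of the cycle is returned, merging endpoint
   marks by the higher probability (equal-confidence conflicts become
   undefined).  A fixed point is a cycle of length 1 and is reached on the
   second iteration when the first-pass graph is already consistent.

Indirect contributions are reported for every pair with I′(X;Y) > 0 as
IndC(Ak) = I′(X;Y;Ak|{Ai}k−1) / I′(X;Y).  Because contributions are
recorded as successive drops of the rectified residual, the identity
Σk IndC + residual/I′(X;Y) = 1 holds exactly (to float addition), and the
residual fraction is zero for removed pairs.

## Information estimation

All estimates are complete-case over exactly the variables involved
(tuple-wise deletion); the two terms of a 3-point difference share one
complete-case sample so the difference is coherent under missingness.

**Units.** `raw_info` is per-sample nats; the penalty k(N) is total nats;
`reg_info = raw_info − k(N)/N`, so N·reg_info = N·I − k(N) is the quantity
entering the orientation scores.  Negative regularized values indicate
(conditional) independence and are rectified to exactly zero; downstream
code tests `== 0`, never an epsilon.  At the estimator level, values below
1e−8 per-sample nats are snapped to zero — such values are within the
floating-point residue of the plug-in sums and would otherwise leak
meaningless "edges" with vanishing information.

**Categorical data.** Plug-in (conditional) MI from the stratified
contingency cube.  The default penalty is the NML (normalized maximum
likelihood) codelength difference, per conditioning stratum and on the
stratum's *observed support*:

    k(N) = Σ_u [ log C_{r_xu · r_yu}(n_u) − log C_{r_xu}(n_u) − log C_{r_yu}(n_u) ]

with C_r(n) the multinomial parametric complexity, computed exactly via
the standard linear recurrence (C_r = C_{r−1} + n/(r−2)·C_{r−2}); C_2 is
summed exactly up to n = 4096 and by its √(πn/2) asymptotic beyond, and
supports above r = 64 use the Rissanen asymptotic
((r−1)/2)·log(n/2) + log(√π/Γ(r/2)).  Charging only observed support is
the fNML convention: a stratum cannot pay for levels that never occur in
it; with full-support penalties the conditional tests were so conservative
on mixed tables that most detectable edges were explained away, while the
observed-support version still shows a 0/40 false-positive rate under
simulated conditional independence at n = 500–1000.  A BIC penalty
(½(r_x−1)(r_y−1)·r_u·ln N) is available via `complexity="bic"`.

**Continuous and mixed data.** Continuous variables are partitioned by a
dynamic program over equal-frequency candidate cutpoints (quantiles over
the sample, ties toward the lower value; up to 100 candidates for
marginal estimates, 16 for conditional ones).  The DP maximizes the
(conditional) regularized MI against the partner's current partition; two
continuous variables alternate DPs (partner initialized at ~n^{1/3}
equal-frequency bins, with a 2-bin restart when the first pass collapses),
evaluating the objective after *every* half-step so that a good partition
is never lost when the partner side subsequently collapses.  Chosen
partitions are evaluated with the same per-stratum NML penalty as
categorical data — continuous and categorical variables are treated alike —
plus a cutpoint coding cost of ln(C) per cutpoint; the DP's per-bin search
penalty is the exact NML one-to-two-bin increment.  Independence is exact:
if no partition achieves a positive regularized value, the estimator
returns zero with single-bin partitions.  Bins are capped at 50
(`max_bins`), which keeps the optimization near-linear in N; for y = x
exactly the unconstrained optimum stays below the cap until roughly
n ≈ 1.5·10^5 under this penalty, and the cap binds beyond that.
Continuous *conditioning* variables enter as an equal-frequency-binned
joint factor (5 bins by default, fewer for small samples).

Conditional MI is computed directly in this stratified form rather than as
the difference of two joint-variable optimizations: one DP instead of two,
exactly zero under conditional independence, and symmetric in X↔Y by
construction.  Rectification applies identically.

The penalized statistic is deliberately smaller than any consistent MI
estimate (it subtracts k(N)/N); the MI *estimate* associated with the
optimum is the plug-in value at the chosen partition (`raw_info`), which
tracks a k-nearest-neighbor estimator within ~0.04 nats at moderate
dependence and n = 500.

## Synthetic benchmark generator

The generator emulates registry-style health data at the scale of the
motivating application: 51 variables with a right-skewed (lognormal,
σ = 0.5) degree distribution of mean ≈ 11 (≈ 280 edges), ±2 per-node
jitter, realized by Havel–Hakimi construction plus seeded edge-swap
randomization, and oriented into a DAG by a uniform random node ordering.
A configurable fraction of nodes is categorical with 2–6 levels.  Root
categorical variables draw skewed multinomials (dominant level 40–70%
mass); root continuous variables draw a two-component location mixture
(separation 1–3 SD).  Each parent contributes a z-scored effect scaled to
a standardized magnitude uniform in [0.3, 1.0] (random sign toward
continuous children); continuous children add unit Gaussian noise and
categorical children sample a multinomial logit over the summed parent
effects.  Everything derives from a single root seed.

What the generator does *not* emulate: real registry marginals and
near-deterministic clinical couplings (care-pathway variables), missing
data, selection bias, and the empirical degree structure of networks
inferred from large patient subsets.  Benchmarks on this generator
therefore probe the method's calibration and ranking behavior under dense
graphs with weak-to-moderate effects — a deliberately hard regime — and
their absolute precision/recall levels are not comparable to runs on
sparser or stronger-signal generators; both `mean_degree` and
`effect_range` are exposed so such regimes can be explored directly.

## Scoring

Three levels against the true CPDAG (compelled edges via v-structures plus
the standard orientation-closure rules, verified against exhaustive
enumeration on all DAGs of ≤ 5 nodes): skeleton scores ignore marks; CPDAG
scores count a present-but-mark-mismatched edge as a false positive; the
oriented-edge subgraph restricts to edges oriented in the truth versus
edges oriented in the inference (genuine and putative alike; an inferred
bidirected edge matches a truth arrowhead into either of its heads).
Precision is defined as 0 when nothing is predicted, F as 0 when both
precision and recall vanish.

## Problem sizes and defaults

Defaults: `max_bins=50`, `complexity="nml"`, β = 0.5, propagation off for
observational analysis and on in benchmark runs, consistency off unless
requested, `max_cond=20`.  The acceptance script averages 10 networks per
setting at N ∈ {500, 1000}; the test suite uses 8 networks and the same
sample sizes, 100 seeds for the 3-node structure-recovery oracles
(n = 2000) and the hidden-confounder construction (n = 5000).

## Known limitations

* Level merging for many-level categorical variables is limited to the
  single-bin comparison implicit in rectification; full combinatorial
  merging is out of scope.
* The union graph of a limit cycle longer than 1 re-checks separating-set
  consistency but cannot always restore it; such records are surfaced in
  `ConsistentResult.inconsistent_records` rather than silently dropped.
* Orientation probabilities for cascaded inductions can rectify to zero
  (P = 1/2); such marks are drawn but never classified as causal.
* The Rissanen large-support asymptotic underestimates log C_r(n) by a few
  nats near the r = 64 crossover; this only affects tables with more than
  64 cells per stratum.
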