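# Methods

## Model

A two-layer tree-structured network maps an N-dimensional binary feature
vector to a binary outcome and a risk probability.  The first layer holds M
independent Boolean modules; module *m* reads a fixed block of n_m features
(Σ n_m = N) and emits one bit.  The output module maps the M-bit vector —
encoded as a 1-based decimal index in {1…2^M} — to a label and a risk.
Feature-to-module assignment is part of the model specification (clinical
knowledge), not learned; it is supplied as a named topology config so that
file column order can never re-wire the network.

All configuration indexing uses the 1-based encoding
`Decimal(x₁…x_n) = 1 + Σ 2^(n−i) x_i`.  Interfaces report 1-based vertex
and configuration indices throughout; arrays are 0-based internally.

## Identification of module functions

For each module a conflict graph is built over its 2^{n_m} input
configurations.  Two samples whose decimal profiles agree everywhere except
in exactly module *m* and whose labels differ witness that the module's
outputs at the two configurations differ; each such pair adds one unit of
weight to the corresponding edge.  The production implementation aggregates
these counts from the sparse label tensors (for each context profile of the
other modules, `T0[a,c]·T1[b,c] + T0[b,c]·T1[a,c]`), iterating a plain loop
over modules; the circular-permutation presentation of the same computation
selects which module varies while the rest are held fixed and yields an
identical matrix, so the plain loop is used for clarity and arbitrary M.
An O(S²) pairwise enumeration of the defining condition is kept in the
package as an independent oracle and the equivalence of the two routes is
property-tested.

The module function is read off the max-cut of the conflict graph.  Because
the cut is complement-invariant, the learned lookup is canonicalised
(vertex 1 → 0); the output module is learned afterwards and absorbs any
per-module complementation, so predictions are unaffected.  Conflict-graph
vertices with no incident weight are unconstrained by the data; they land on
side 0 by canonicalisation and are listed in the model metadata.

## Max-cut solvers

*Exact*: vectorised enumeration of all 2^(n−1) partitions with vertex 1
pinned to side 0; ties broken toward the lexicographically smallest
assignment so fitted models are bit-reproducible.  The exact/SDP dispatch
cap is 20 vertices (≈5×10⁵ partitions, well under a second), which covers
modules of up to 5 inputs exactly; practical module sizes are 6–8 inputs at
most, beyond which the 2^{n_m} structures dominate cost anyway (a size
warning is emitted above 8).

*Relaxation*: the semidefinite relaxation assigns each vertex a unit vector
and maximises Σ w_uv (1 − v_u·v_v)/2.  It is solved by low-rank
Burer–Monteiro factorisation: rank k = ⌈√(2n)⌉+1 unit rows optimised by
L-BFGS with an analytic projected gradient and two random restarts — at this
rank the factorised landscape generically has no spurious local optima, and
on graphs small enough to verify by enumeration the solver attains the
relaxation optimum.  Rounding draws `n_roundings` (default 1000) random
hyperplanes; each distinct rounded partition is refined by greedy
single-vertex swaps (strictly non-decreasing in cut value) unless the
pure-rounding mode is selected, and the best cut is returned.  All
randomness flows from one explicit seed.  The classical expected guarantee
for randomized rounding is quoted at 0.87 of the optimum (the literature
constant is ≈0.878); the test suite asserts the 0.87 bound per graph, which
best-of-R rounding plus local search clears comfortably.

## Output module, risk, and degenerate cases

Each of the 2^M output configurations reached in training receives
`Risk[i] = counter1[i] / (counter0[i] + counter1[i])` and the majority-vote
label.  Decisions for the cases the ratio leaves open:

* **Unseen configuration** (counter0 + counter1 = 0): the ratio is
  undefined; the model returns the training prevalence of the positive
  class as risk, the overall training majority class as label, and flags
  the prediction out-of-support.  With binary features such predictions are
  extrapolations; the prevalence is the honest prior.
* **Tie** (counter0 = counter1 > 0): risk is exactly 0.5 by the ratio; the
  label resolves to 1, conservative toward flagging risk.
* **Single-class training data**: the model fits (all conflict graphs are
  empty, all modules constant) but a warning is attached; ROC AUC on a
  single-class evaluation set is reported as missing.

Labels are consistent with risks: label 1 ⇔ risk > 0.5, except exactly at
ties (label 1 at risk 0.5) and out-of-support defaults.

Evaluation reports accuracy, recall, precision, F1 and ROC AUC; the AUC
ranks the risk scores with midrank tie handling (the standard estimator;
no alternative is asserted).

## Synthetic data: what it emulates, what it does not

The planted-model generator produces ground truths shaped like fitted
models: a topology, random module lookups, a random output lookup, and
per-feature Bernoulli prevalences.  Planted functions are rejection-sampled
until every module is *relevant* — some context exists in which flipping the
module's output flips the network output.  Without relevance a module's
conflict graph is empty and its function unidentifiable, so recovery tests
would be vacuous; irrelevant-module behaviour is covered by a dedicated
degenerate test instead.  Labels may be flipped independently with rate
ε ∈ [0, 0.5) to emulate outcome noise; multi-cohort generation shifts the
feature prevalences additively per cohort to emulate hospital case-mix
differences, with cross-cohort Jaccard similarity quantifying relatedness.

Defaults: prevalence 0.5 per feature (maximally informative for recovery
studies; configurable to Table-1-style case mixes), noise 0, iid features.
Real ICD indicators are correlated within organ systems and have prevalences
far from 0.5; the generator's independent-Bernoulli default does not emulate
ICD-code co-occurrence or coding practice variation, so passing recovery
tests demonstrates correctness of the learning machinery, not clinical
performance.  The reference "simple case" is the 7-feature, 3-module
topology with sizes [3, 2, 2].

## Attribution and consistency

Shapley players are the M module outputs.  A coalition's value is the
model's risk with in-coalition module outputs fixed to the explained
sample's and out-of-coalition outputs averaged (interventionally) over a
background distribution of module-output profiles; the default background is
the training distribution, recovered exactly from the fitted output-module
counters, and any sample matrix may be supplied instead.  All 2^M coalitions
are enumerated with the standard weights |C|!(M−1−|C|)!/M!, capped at
M ≤ 15.  Exactness gives the efficiency identity (base value + attributions
= prediction) to machine precision and removes kernel-sampling variance —
with M = 5 the coalition space is 2⁵ versus 2¹² for raw features.  No
sampling mode is provided.

The consistency analysis takes per-subset, per-module mean absolute
attributions (k subsets × M modules), ranks modules within each subset
(rank 1 = largest), and tests distribution differences with the Friedman
omnibus statistic plus pairwise comparisons
`z = |R̄_i − R̄_j| / √(M(M+1)/6k)` under Holm step-down adjustment at a
default α = 0.1.  The classical Friedman χ² form is used without the
Iman–Davenport correction, and two-sided normal p-values feed the step-down;
these defaults are documented choices, not assertions about any particular
published variant.  Cohort relatedness is the mean pairwise Jaccard
similarity over all cross-cohort sample pairs with a normal-approximation
95% CI; two all-zero vectors are defined to have similarity 1.0 (identical
samples) with a warning.

## Problem sizes in the shipped tests

The suite exercises topologies up to [2, 4, 1, 2, 3] (N = 12, exhaustive
4096-row datasets), oracle-equivalence datasets up to S = 500, a 50-graph
max-cut bound suite at 6–14 vertices × 1000 roundings, 20 planted-recovery
truths plus a 6400-row noisy recovery (ε = 0.05, 50× replication of the
128-row input space, accuracy ≥ 0.95 against planted labels), and a
300-replicate null calibration of the consistency test at 80 subsets × 5
modules — sizes at which every check is exact or has comfortable
sampling-error margins while the whole suite runs in well under a minute.

## Known limitations

Binary inputs only; continuous features require an upstream discretisation
step the package does not provide.  Module identification cost grows as
2^{n_m}, so modules beyond ~8 inputs are impractical.  The learner has no
regularisation: with few samples per output configuration the risk ratios
are high-variance, and out-of-support defaults dominate when the training
case mix is narrow.  Conflict-graph weights assume label noise is
symmetric; strongly asymmetric noise biases the cut evidence.
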