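# treestrat

Tree-structured hybrid classifiers on binary clinical features, learned by
solving max-cut problems on conflict graphs.

## The problem

ICU mortality-risk models built on binary diagnosis indicators (ICD-code
presence/absence) face two linked difficulties: with purely binary inputs
every prediction on an unseen configuration is an extrapolation, and flat
black-box learners interpret their features inconsistently across hospitals
with different case mixes.  `treestrat` implements a structured alternative:
``N`` binary features are assigned — by clinical knowledge — to ``M``
independent first-layer Boolean modules (e.g. *kidney failure*, *lung
failure*), each emitting one bit, and a small output module aggregates the
``M`` bits into a mortality-risk probability by majority voting over the
training data.  The structure confines the learning problem to blocks of
6–8 features and makes the attribution space ``2^M`` instead of ``2^N``.

## The learning algorithm

Write the network as **F** : {0,1}^N → {0,1} with module input blocks of
sizes n₁…n_M.  A block's configuration is encoded by the 1-based decimal
index ``Decimal(x₁…x_n) = 1 + Σᵢ 2^(n−i)·xᵢ``, so a sample becomes the
decimal profile **X** ∈ ∏ {1…2^{n_m}}.  For each module *m* a **conflict
graph** G_m is built on the 2^{n_m} configurations: the weight w_m^{kl}
counts training pairs that agree on every other module's inputs but differ
in label while reaching configurations *k* and *l* on module *m* — such a
pair forces F_m(k) ≠ F_m(l).  Equivalently, with label-count tensors
T0/T1 indexed by decimal profile,

    w_m^{kl} = Σ_contexts T0[k,c]·T1[l,c] + T0[l,c]·T1[k,c].

The module's Boolean function is the bipartition of G_m that honours the
most conflict evidence: the **max-cut**

    max Σ_{u<v} w_uv (x_u + x_v − 2 x_u x_v),  x_u ∈ {0,1},

solved exactly by enumeration up to 20 vertices and otherwise by the
Goemans–Williamson semidefinite relaxation with randomized hyperplane
rounding (expected guarantee 0.87 × optimum; this package adds best-of-R
rounding and single-swap local refinement).  The output module assigns each
of the 2^M reached configurations the empirical risk
``Risk[i] = counter1[i] / (counter0[i] + counter1[i])`` and the
majority-vote label.  Interpretation uses **exact Shapley values** over the
M module outputs (all 2^M coalitions enumerated — no sampling noise), a
rank-based consistency test across validation subsets (Friedman omnibus,
pairwise z with Holm step-down), and Jaccard case-mix relatedness between
cohorts.

## Worked example

```python
from treestrat import FitConfig, evaluate, fit, make_simple_case, sample_dataset

truth = make_simple_case(seed=3)            # planted [3,2,2] network, N=7
dataset = sample_dataset(truth, mode="exhaustive")   # all 128 inputs, noiseless
model = fit(dataset, truth.topology, FitConfig(seed=11))
print(evaluate(model, dataset))
```

prints

```
metrics: {'accuracy': 1.0, 'recall': 1.0, 'precision': 1.0, 'f1': 1.0, 'roc_auc': 1.0}
```

— on exhaustive noiseless data from a planted truth whose modules are all
relevant, the max-cut learner recovers every module function (up to a
complementation absorbed by the output module) and therefore reproduces
every planted label.  The `examples/` directory holds narrative scripts for
each capability: fitting and evaluation, conflict-graph anatomy, exact
Shapley attribution with the consistency test, and a multi-cohort
external-validation design with shifted case mixes.

## Command line

```bash
treestrat simulate --sizes 3,2,2 --n-cohorts 3 --shift 0.1 --seed 7 --outdir cohorts/
treestrat fit cohorts/cohort_1.csv cohorts/topology.json -o model.json --seed 7
treestrat predict model.json cohorts/cohort_2.csv -o preds.csv
treestrat evaluate model.json cohorts/cohort_2.csv
treestrat explain model.json cohorts/cohort_2.csv -o shap.csv --summary summary.json
treestrat relatedness cohorts/cohort_1.csv cohorts/cohort_2.csv
```

Data CSVs must contain literal 0/1 cells plus a label column; topologies are
JSON/YAML maps of module name → ordered feature list, and columns are
matched by name, never by position.

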