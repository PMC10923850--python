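"""External-validation design on shifted synthetic cohorts.

Generates several cohorts from one planted truth with shifted per-feature
prevalences (different case mixes, as across hospitals), trains on the first
(derivation) cohort, evaluates on the rest, and reports each cohort's Jaccard
relatedness to the derivation cohort.  Lower relatedness means the validation
cohort probes the model further from its training distribution.
"""

from treestrat import FitConfig, evaluate, fit, make_shifted_cohorts, random_planted_truth

truth = random_planted_truth([3, 2, 2], seed=29, prevalences=0.45, noise_rate=0.05)
cohorts = make_shifted_cohorts(
    truth, n_cohorts=4, prevalence_shifts=[0.0, 0.0, 0.15, -0.25],
    sizes=1200, seed=8,
)

model = fit(cohorts.datasets[0], truth.topology, FitConfig(seed=0))
print("trained on cohort 1 (derivation); validating on cohorts 2-4\n")
for i, (dataset, (mean_j, ci)) in enumerate(
    zip(cohorts.datasets, cohorts.relatedness_to_base), start=1
):
    metrics = evaluate(model, dataset)
    role = "derivation" if i == 1 else "validation"
    print(f"cohort {i} ({role}): jaccard-to-derivation "
          f"{mean_j:.3f} [{ci[0]:.3f}, {ci[1]:.3f}]")
    print("   " + ", ".join(f"{k}={v:.3f}" for k, v in metrics.items()))
print("\nWith a shared planted truth, accuracy stays high even where the "
      "case mix (and hence Jaccard relatedness) shifts — the behaviour the "
      "tree-structured model is designed for.")
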