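"""Full cohort battery on a simulated 34-subject cohort.

Simulates the two-group design (enlarged CSF spaces with a wider, longer,
straighter optic nerve, and elevated complication risk), then runs
normative Z-scoring, abnormality scoring, group comparisons, diagnostic
ROC models, the enlargement odds ratio, and two-step clustering with
risk stratification.
"""

from hydromorph import cohort, pipeline, stats

spec = cohort.CohortSpec(n_subjects=34, rng_seed=7)
subjects, _ = cohort.simulate_cohort(spec)
normative = stats.NormativeTable(cohort.default_normative_table())

results, augmented = pipeline.run_cohort(subjects, normative)

sizes = results["group_sizes"]
print(f"quantified groups: {sizes['enlarged']} enlarged, {sizes['normal']} normal "
      "(abnormality score >= 1 from Z > 1.96 on either CSF space)")
for var, row in results["group_comparisons"].items():
    print(f"  {var:>22}: {row['enlarged_mean']:.2f} vs {row['normal_mean']:.2f} "
          f"(Mann-Whitney p = {row['pvalue']:.4f})")
for target, row in results["roc"].items():
    print(f"ROC {target}: AUC = {row['auc']:.3f} (features: {', '.join(row['features'])})")
strat = results["risk_stratification"]
rr = strat["risk_ratio"]
print(f"clusters: {results['cluster']['sizes']} -> high-risk cluster "
      f"{strat['high_risk_cluster']}, complication RR = {rr['risk_ratio']:.2f} "
      f"(95% CI {rr['ci_low']:.2f}-{rr['ci_high']:.2f})")
print("The enlarged group shows the planted pattern: wider and longer but "
      "less tortuous nerves, and the high-risk cluster carries the excess "
      "complication risk.")
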