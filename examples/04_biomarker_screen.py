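"""Full biomarker screen: perturbation contributions and the RC filter.

Trains the sequence model on the planted-effect study conditions (reduced
size), computes removal-perturbation feature contributions for every
patient, and prints the features passing the significance filter
(Bonferroni-adjusted p < 0.05 and 95% CI excluding 1), flagging each as
risk (RC > 1) or protective (RC < 1).
"""

from visitrisk import (
    CohortConfig,
    ContributionConfig,
    EncodingConfig,
    FeatureEncoder,
    analyze_contributions,
    build_cohort,
    build_fc_table,
    generate_population,
    significance_filter,
    train_model,
)
from visitrisk.presets import STUDY_EFFECTS, study_model_config, study_sim_config

sim = study_sim_config(n_patients=2500, seed=2)
cohort = build_cohort(generate_population(sim), CohortConfig(seed=2))
encoder = FeatureEncoder(EncodingConfig()).fit(cohort["train"])
parts = {p: encoder.encode(cohort[p]) for p in ("train", "valid", "test")}
model, _ = train_model(study_model_config(len(encoder.vocab), seed=0),
                       parts["train"], parts["valid"])

samples = parts["train"] + parts["valid"] + parts["test"]
config = ContributionConfig()
fc = build_fc_table(model, samples, set(encoder.vocab.index.values()), config)
names = {i: t for t, i in encoder.vocab.index.items()}
results, exclusions = analyze_contributions(fc, config, names)
significant = significance_filter(results)

planted = {f"{e.domain}:{e.code}" for e in STUDY_EFFECTS}
print(f"features tested: {len(results)}, excluded: {len(exclusions)}, "
      f"significant: {len(significant)}")
print()
print(f"{'feature':<14} {'RC':>6} {'CI95':>15} {'p(Bonf)':>10}  direction  planted?")
for _, row in significant.sort_values("p_bonferroni").head(15).iterrows():
    ci = f"({row.ci95_low:.2f},{row.ci95_high:.2f})"
    mark = "yes" if row.feature_name in planted else ""
    print(f"{row.feature_name:<14} {row.rc:>6.2f} {ci:>15} {row.p_bonferroni:>10.2e}"
          f"  {row.direction:<10} {mark}")
print()
print("RC is the ratio of mean perturbation contribution among event patients")
print("to that among event-free patients; planted risk codes should surface")
print("with RC > 1 and planted protective codes with RC < 1. At this reduced")
print("cohort size expect a few unplanted features among the significant set;")
print("the false-positive rate drops with the full study size (see tests).")
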