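"""Construct an event-anchored case/control cohort from simulated timelines.

Each SRE anchors case samples at the encounters of the preceding 90 days
(augmentation); controls contribute their latest eligible encounter only and
are undersampled to balance; the split is 8:1:1 by patient.
"""

from visitrisk import CohortConfig, PlantedEffect, SimConfig, build_cohort, generate_population

sim = SimConfig(
    n_patients=1000,
    study_span_days=1825,
    encounter_rate=8.0,
    base_hazard=0.008,
    planted_effects=[PlantedEffect("A05", "DX", 2.0)],
    seed=7,
)
cohort = build_cohort(generate_population(sim), CohortConfig(seed=7))

c = cohort["counts"]
print(f"patients:                 {c['patients']}")
print(f"case samples:             {c['cases']}  (from {c['case_patients']} patients)")
print(f"control-eligible:         {c['controls_eligible']}")
print(f"controls kept (balanced): {c['controls_kept']}")
print(f"train / valid / test:     {c['train']} / {c['valid']} / {c['test']}")
print()
print("Case samples may outnumber case patients: every encounter in the 90")
print("days before an SRE that passes the one-year SRE-free washout becomes")
print("its own training sample, anchored at its own index date.")
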