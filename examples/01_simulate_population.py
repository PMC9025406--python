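"""Simulate a synthetic EHR population and check its hazard calibration.

Generates 800 patients with one planted risk diagnosis, writes the two
release tables (events, patients), and verifies by an independent re-scan
that the fraction of encounters followed by an SRE within 90 days tracks
the configured hazard.
"""

from pathlib import Path

from visitrisk import PlantedEffect, SimConfig, generate_population, write_events

config = SimConfig(
    n_patients=800,
    study_span_days=1825,       # five years of follow-up
    encounter_rate=8.0,         # visits per patient-year
    base_hazard=0.01,           # 90-day SRE probability at zero exposure
    planted_effects=[PlantedEffect("A05", "DX", 2.0)],
    seed=42,
)
timelines = generate_population(config)

out = Path("scratch/example_sim")
out.mkdir(parents=True, exist_ok=True)
write_events(timelines, out / "events.tsv", out / "patients.tsv")

n_enc = sum(len(t.encounters) for t in timelines)
n_sre = sum(len(t.sre_dates) for t in timelines)
flagged = sum(
    any(0 < (s - d).days <= 90 for s in t.sre_dates)
    for t in timelines
    for _eid, d, _ev in t.encounters
)
print(f"patients:            {len(timelines)}")
print(f"encounters:          {n_enc}")
print(f"SREs:                {n_sre}")
print(f"90-day event rate:   {flagged / n_enc:.4f} per encounter")
print()
print("The event rate exceeds the 0.01 baseline because occurrences of the")
print("planted diagnosis A05 in the prior year add +2.0 to the hazard logit.")
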