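"""Canonical study conditions for the planted-effect evaluation.

These fix the synthetic population used throughout the examples,
property tests and the recovery analysis: a multi-year PTSD-like cohort
with ten planted effects of magnitude +-2 log-odds spread over the three
domains (risk and protective diagnoses, medications and lab tests), a low
baseline hazard, and code frequencies skewed so planted codes sit in the
mid-frequency range — common enough for statistical support, rare enough
that most patient-years carry no exposure.
"""

from __future__ import annotations

import dataclasses

from .cohort import CohortConfig
from .models import ModelConfig
from .synthetic import PlantedEffect, SimConfig


def _dx(rank: int) -> str:
    return f"{chr(ord('A') + rank // 100)}{rank % 100:02d}"


#: planted ground truth: +2 log-odds risk codes and -2 protective codes
STUDY_EFFECTS: tuple[PlantedEffect, ...] = (
    PlantedEffect(_dx(12), "DX", 2.0),
    PlantedEffect(_dx(18), "DX", 2.0),
    PlantedEffect(_dx(28), "DX", 2.0),
    PlantedEffect("med0008", "MED", 2.0),
    PlantedEffect("med0014", "MED", 2.0),
    PlantedEffect("lab0007", "LAB", 2.0),
    PlantedEffect("lab0012", "LAB", 2.0),
    PlantedEffect(_dx(6), "DX", -2.0),
    PlantedEffect("med0005", "MED", -2.0),
    PlantedEffect("lab0004", "LAB", -2.0),
)


def study_sim_config(n_patients: int = 6000, seed: int = 11) -> SimConfig:
    """The planted-effect population: 5-year span, 8 encounters/year,
    baseline 90-day SRE hazard 0.0015 per encounter."""
    return SimConfig(
        n_patients=n_patients,
        study_span_days=1825,
        encounter_rate=8.0,
        base_hazard=0.0015,
        planted_effects=list(STUDY_EFFECTS),
        seed=seed,
    )


def study_cohort_config(seed: int = 11) -> CohortConfig:
    return CohortConfig(seed=seed)


def study_model_config(vocab_size: int, seed: int = 0) -> ModelConfig:
    """Model sized for the synthetic vocabulary (a few hundred codes).

    The full-width reference configuration (embedding 128, hidden 128, two
    layers, input 30,000) is the package default in :class:`ModelConfig`;
    this preset narrows it to the synthetic problem so a training run takes
    seconds, without changing the architecture family.
    """
    return ModelConfig(
        embed_dim=48,
        hidden_size=48,
        num_layers=1,
        input_size=vocab_size + 1,
        max_epochs=40,
        batch_size=32,
        learning_rate=1e-3,
        linear_bypass=True,
        weight_decay=1e-3,
        seed=seed,
    )


def with_domains(sim: SimConfig, domains: tuple[str, ...]) -> SimConfig:
    """Restrict planted effects to the given domains (ablation studies
    re-encode instead; this is for generator-level experiments)."""
    return dataclasses.replace(
        sim, planted_effects=[e for e in sim.planted_effects if e.domain in domains]
    )
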