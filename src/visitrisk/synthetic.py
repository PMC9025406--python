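"""Synthetic longitudinal EHR populations with planted risk/protective effects.

The generator emulates the data shape of a hospital-system EMR extract for a
PTSD cohort: irregular encounter timing over a multi-year span, three event
domains (diagnoses, medications, lab tests) with a power-law code-frequency
skew, lab results carrying a RESULT_FLAG, and sparse suicide-related events
(SREs) whose discrete-time hazard is shifted on the logit scale by planted
codes. Because the ground truth (which codes raise or lower the hazard, and
by how much) is known, every downstream stage — cohort construction, sequence
modelling, contribution analysis — can be tested for recovery without any
external data.

Event mechanics
---------------
At each encounter the probability that the patient experiences an SRE within
the following ``horizon_days`` is

    logit(h) = logit(base_hazard) + sum_e  log_odds_e * n_e

where ``n_e`` counts occurrences of planted code *e* in the 365 days up to
and including the encounter (for planted lab codes, only abnormal-flagged
results count — an in-range result carries no risk information, mirroring
the abnormal-lab filter applied at modelling time).  When the draw succeeds, the SRE is recorded
exactly ``horizon_days`` after the triggering encounter and no encounters are
generated strictly between trigger and SRE (an acute episode interrupting
routine care).  This convention makes the per-encounter hazard *identifiable*
from the released data alone: the fraction of encounters followed by an SRE
within ``horizon_days``, measured by an independent re-scan of the event
table, is an unbiased binomial estimate of ``h`` — overlapping risk windows
of neighbouring encounters never double-count a single SRE.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np

DOMAINS = ("DX", "MED", "LAB")
LAB_FLAGS = ("NORMAL", "ABNORMAL", "HIGH", "LOW")

#: calendar date of simulation day 0
EPOCH = datetime.date(2010, 1, 1)


def day_to_date(day: int) -> datetime.date:
    return EPOCH + datetime.timedelta(days=int(day))


def date_to_day(d: datetime.date) -> int:
    return (d - EPOCH).days


class ConfigurationError(ValueError):
    """Raised when a simulation config fails validation; names the field."""


@dataclass(frozen=True)
class PlantedEffect:
    """A code whose recent occurrences shift the SRE hazard.

    ``log_odds`` is added to the hazard's logit once per occurrence of
    ``code`` in the 365 days before (and including) an encounter. Positive
    values plant a risk factor, negative values a protective one.
    """

    code: str
    domain: str  # DX | MED | LAB
    log_odds: float


@dataclass(frozen=True)
class EventRecord:
    """One clinical event. ``result_flag`` is set iff ``domain == "LAB"``."""

    patient_id: str
    encounter_id: str
    date: datetime.date
    domain: str
    code: str
    result_flag: str | None = None


@dataclass
class PatientTimeline:
    """Date-ordered encounters for one patient plus anchor dates.

    ``encounters`` is a list of ``(encounter_id, date, events)`` with strictly
    increasing dates (same-date records are merged into one encounter).
    """

    patient_id: str
    encounters: list[tuple[str, datetime.date, list[EventRecord]]]
    ptsd_date: datetime.date
    sre_dates: list[datetime.date]


@dataclass
class SimConfig:
    """Study conditions for one synthetic population.

    Parameters
    ----------
    n_patients:
        Number of patients to simulate.
    study_span_days:
        Length of the observation window per patient, in days.
    encounter_rate:
        Mean encounters per patient-year (homogeneous Poisson process).
    vocab_sizes:
        Number of distinct codes per domain.
    code_frequency_skew:
        Zipf exponent of the code-frequency distribution within each domain
        (0 = uniform; 1–1.5 is typical of clinical coding).
    events_per_encounter:
        Poisson mean of the number of events per domain at each encounter.
    planted_effects:
        Codes with a known log-odds effect on the SRE hazard.
    base_hazard:
        Per-encounter probability of an SRE within ``horizon_days`` at zero
        exposure.
    horizon_days:
        Outcome horizon (90 days = the "3 months" convention).
    lab_flag_probs:
        Probabilities over RESULT_FLAG values NORMAL/ABNORMAL/HIGH/LOW.
    seed:
        RNG seed; a fixed seed makes the output bit-identical.
    """

    n_patients: int = 1000
    study_span_days: int = 2920  # 8 years
    encounter_rate: float = 8.0
    vocab_sizes: dict[str, int] = field(
        default_factory=lambda: {"DX": 300, "MED": 200, "LAB": 150}
    )
    code_frequency_skew: float = 1.1
    events_per_encounter: dict[str, float] = field(
        default_factory=lambda: {"DX": 1.6, "MED": 1.2, "LAB": 1.4}
    )
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    base_hazard: float = 0.03
    horizon_days: int = 90
    exposure_window_days: int = 365
    lab_flag_probs: dict[str, float] = field(
        default_factory=lambda: {"NORMAL": 0.55, "ABNORMAL": 0.15, "HIGH": 0.17, "LOW": 0.13}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        for name in ("study_span_days", "horizon_days", "exposure_window_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.encounter_rate <= 0:
            raise ConfigurationError("encounter_rate must be > 0")
        if not (0.0 < self.base_hazard < 1.0):
            raise ConfigurationError("base_hazard must be in (0, 1)")
        for d in DOMAINS:
            if self.vocab_sizes.get(d, 0) <= 0:
                raise ConfigurationError(f"vocab_sizes[{d}] must be > 0")
            if self.events_per_encounter.get(d, 0.0) < 0:
                raise ConfigurationError(f"events_per_encounter[{d}] must be >= 0")
        total = sum(self.lab_flag_probs.get(f, 0.0) for f in LAB_FLAGS)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("lab_flag_probs must sum to 1")
        vocab = {d: set(domain_codes(d, self.vocab_sizes[d])) for d in DOMAINS}
        for eff in self.planted_effects:
            if eff.domain not in DOMAINS:
                raise ConfigurationError(f"planted_effects: unknown domain {eff.domain!r}")
            if eff.code not in vocab[eff.domain]:
                raise ConfigurationError(
                    f"planted_effects: code {eff.code!r} not in the {eff.domain} vocabulary"
                )
            if not np.isfinite(eff.log_odds):
                raise ConfigurationError("planted_effects: log_odds must be finite")


def domain_codes(domain: str, size: int) -> list[str]:
    """The configured code vocabulary for one domain, in frequency-rank order.

    Diagnosis codes are emitted directly in a 3-character ICD-10-like
    category space (A00, A01, ... Z99) so that category truncation downstream
    is the identity; medication and lab codes are opaque tokens.
    """
    if domain == "DX":
        if size > 2600:
            raise ConfigurationError("vocab_sizes[DX] must be <= 2600")
        return [f"{chr(ord('A') + i // 100)}{i % 100:02d}" for i in range(size)]
    prefix = {"MED": "med", "LAB": "lab"}[domain]
    return [f"{prefix}{i:04d}" for i in range(size)]


def _zipf_probs(size: int, skew: float) -> np.ndarray:
    w = (np.arange(1, size + 1, dtype=float)) ** (-skew)
    return w / w.sum()


def generate_population(config: SimConfig) -> list[PatientTimeline]:
    """Simulate ``config.n_patients`` timelines under the configured hazard.

    Deterministic under a fixed ``config.seed`` (per-patient independent
    substreams, so the output for patient *i* does not depend on how many
    patients precede it).
    """
    config.validate()
    if config.n_patients == 0:
        return []

    codes = {d: np.array(domain_codes(d, config.vocab_sizes[d])) for d in DOMAINS}
    probs = {d: _zipf_probs(config.vocab_sizes[d], config.code_frequency_skew) for d in DOMAINS}
    flag_p = np.array([config.lab_flag_probs[f] for f in LAB_FLAGS])
    effects = {(e.domain, e.code): e.log_odds for e in config.planted_effects}
    base_logit = float(np.log(config.base_hazard / (1.0 - config.base_hazard)))

    streams = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    timelines = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"P{i:06d}"
        timelines.append(_simulate_patient(pid, rng, config, codes, probs, flag_p, effects, base_logit))
    return timelines


def _simulate_patient(pid, rng, config, codes, probs, flag_p, effects, base_logit) -> PatientTimeline:
    span = config.study_span_days
    mean_gap = 365.0 / config.encounter_rate
    # homogeneous point process, integer days, same-day arrivals merged
    n_draw = max(8, int(2.5 * span / mean_gap) + 8)
    gaps = rng.exponential(mean_gap, size=n_draw)
    arrivals = np.cumsum(gaps)
    while arrivals[-1] < span:  # rarely needed top-up
        gaps = rng.exponential(mean_gap, size=n_draw)
        arrivals = np.concatenate([arrivals, arrivals[-1] + np.cumsum(gaps)])
    days = np.unique(arrivals[arrivals < span].astype(int))

    ptsd_day = int(rng.integers(0, max(1, span // 3)))

    # bulk event draws per domain for every candidate encounter
    n_days = len(days)
    per_enc_codes: list[list[tuple[str, str, str | None]]] = [[] for _ in range(n_days)]
    for d in DOMAINS:
        counts = rng.poisson(config.events_per_encounter[d], size=n_days)
        total = int(counts.sum())
        if total == 0:
            continue
        draws = rng.choice(config.vocab_sizes[d], size=total, p=probs[d])
        flags = rng.choice(len(LAB_FLAGS), size=total, p=flag_p) if d == "LAB" else None
        pos = 0
        for e in range(n_days):
            n = counts[e]
            if n == 0:
                continue
            idx = np.unique(draws[pos:pos + n])
            for j, ci in enumerate(idx):
                flag = LAB_FLAGS[flags[pos + j]] if d == "LAB" else None
                per_enc_codes[e].append((d, str(codes[d][ci]), flag))
            pos += n
    # every visit records at least the encounter diagnosis
    empty = [e for e in range(n_days) if not per_enc_codes[e]]
    if empty:
        fill = rng.choice(config.vocab_sizes["DX"], size=len(empty), p=probs["DX"])
        for e, ci in zip(empty, fill):
            per_enc_codes[e].append(("DX", str(codes["DX"][ci]), None))

    encounters: list[tuple[str, datetime.date, list[EventRecord]]] = []
    sre_days: list[int] = []
    # (day, log_odds) occurrences of planted codes, for exposure counting
    recent: list[tuple[int, float]] = []
    blocked_until = -1  # no encounters strictly between a trigger and its SRE
    k = 0
    unext = rng.random(size=n_days)  # one hazard draw reserved per encounter
    for e in range(n_days):
        day = int(days[e])
        if day <= blocked_until:
            continue
        eid = f"{pid}-e{k:04d}"
        date = day_to_date(day)
        events = [EventRecord(pid, eid, date, d, code, flag)
                  for (d, code, flag) in per_enc_codes[e]]
        if effects:
            for d, code, flag in per_enc_codes[e]:
                # a planted lab code contributes only through abnormal
                # results; a NORMAL-flagged occurrence carries no risk
                if d == "LAB" and flag == "NORMAL":
                    continue
                lo = effects.get((d, code))
                if lo is not None:
                    recent.append((day, lo))
            # exposure = planted occurrences within the trailing window, incl. today
            lo_sum = sum(lo for (dy, lo) in recent if day - dy < config.exposure_window_days)
        else:
            lo_sum = 0.0
        encounters.append((eid, date, events))
        k += 1
        h = 1.0 / (1.0 + np.exp(-(base_logit + lo_sum)))
        if unext[e] < h:
            sre_day = day + config.horizon_days
            sre_days.append(sre_day)
            blocked_until = sre_day - 1

    return PatientTimeline(
        patient_id=pid,
        encounters=encounters,
        ptsd_date=day_to_date(ptsd_day),
        sre_dates=[day_to_date(d) for d in sre_days],
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """A copy of ``config`` with a different RNG seed."""
    return replace(config, seed=seed)
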