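"""Event-anchored case/control construction from patient timelines.

Every encounter on or after the PTSD diagnosis date is a candidate index
date. An encounter is

* **excluded** when any SRE falls in the washout ``[index - 365 d, index]``
  (history of recent SREs would leak the outcome into the features);
* **case-eligible** when an SRE falls in the outcome window
  ``(index, index + 90 d]``;
* **control-eligible** otherwise.

Cases are *augmented*: every case-eligible encounter in the 90 days before
an SRE yields one sample, so one patient can contribute several case samples
anchored at different encounters. Controls are collapsed to the single
latest control-eligible encounter per patient (the latest health status),
and a patient contributing case samples contributes no control. Controls are
then undersampled without replacement to the number of cases, and the cohort
is split 8:1:1 into train/validation/test — by patient by default, so that
near-duplicate augmented samples of one patient never straddle partitions.

Interval conventions: outcome window half-open ``(index, index+90]``,
lookback half-open ``(index-365, index]`` (the index encounter's own events
belong to the history), washout closed ``[index-365, index]``.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic import PatientTimeline

logger = logging.getLogger(__name__)

CASE, CONTROL, EXCLUDED = "case", "control", "excluded"


@dataclass
class CohortConfig:
    horizon_days: int = 90
    lookback_days: int = 365
    sre_washout_days: int = 365
    balance: bool = True
    split_ratio: tuple[int, int, int] = (8, 1, 1)
    split_unit: str = "patient"  # or "sample"
    seed: int = 0

    def validate(self) -> None:
        for name in ("horizon_days", "lookback_days", "sre_washout_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if sum(self.split_ratio) != 10 or len(self.split_ratio) != 3:
            raise ValueError("split_ratio must be three parts summing to 10")
        if self.split_unit not in ("patient", "sample"):
            raise ValueError("split_unit must be 'patient' or 'sample'")


@dataclass(frozen=True)
class Visit:
    """One encounter in a sample's history, ``days_before_index`` >= 0.

    ``events`` holds raw ``(domain, code, result_flag)`` triples; integer
    encoding happens later, once a vocabulary is fitted on the training
    partition.
    """

    days_before_index: int
    events: tuple[tuple[str, str, str | None], ...]


@dataclass
class CohortSample:
    patient_id: str
    index_date: datetime.date
    label: int  # 1 = case (SRE within the horizon), 0 = control
    history: list[Visit] = field(default_factory=list)


def classify_encounter(
    index_date: datetime.date, sre_dates: list[datetime.date], config: CohortConfig
) -> str:
    """Eligibility of one candidate index date against the patient's SREs."""
    for s in sre_dates:
        delta = (s - index_date).days
        if -config.sre_washout_days <= delta <= 0:
            return EXCLUDED
    for s in sre_dates:
        delta = (s - index_date).days
        if 0 < delta <= config.horizon_days:
            return CASE
    return CONTROL


def enumerate_candidates(
    timeline: PatientTimeline, config: CohortConfig
) -> list[tuple[tuple, str]]:
    """Label every encounter on/after the PTSD date as case/control/excluded."""
    out = []
    for enc in timeline.encounters:
        _eid, date, _events = enc
        if date < timeline.ptsd_date:
            continue
        out.append((enc, classify_encounter(date, timeline.sre_dates, config)))
    return out


def _history(timeline: PatientTimeline, index_date: datetime.date, config: CohortConfig) -> list[Visit]:
    visits = []
    for _eid, date, events in timeline.encounters:
        back = (index_date - date).days
        if 0 <= back < config.lookback_days:
            visits.append(
                Visit(back, tuple((ev.domain, ev.code, ev.result_flag) for ev in events))
            )
    return visits  # encounters are date-ordered, so oldest -> newest


def sample_cases(timeline: PatientTimeline, config: CohortConfig) -> list[CohortSample]:
    """One sample per case-eligible encounter (event-anchored oversampling)."""
    seen: set[datetime.date] = set()
    samples = []
    for (_, date, _), status in enumerate_candidates(timeline, config):
        if status == CASE and date not in seen:
            seen.add(date)
            samples.append(
                CohortSample(timeline.patient_id, date, 1, _history(timeline, date, config))
            )
    return samples


def sample_controls(timeline: PatientTimeline, config: CohortConfig) -> CohortSample | None:
    """The latest control-eligible encounter, or None."""
    last = None
    for (_, date, _), status in enumerate_candidates(timeline, config):
        if status == CONTROL and (last is None or date > last):
            last = date
    if last is None:
        return None
    return CohortSample(timeline.patient_id, last, 0, _history(timeline, last, config))


def balance_cohort(
    cases: list[CohortSample], controls: list[CohortSample], config: CohortConfig
) -> tuple[list[CohortSample], list[CohortSample]]:
    """Undersample controls (uniform, without replacement) to the case count."""
    if not config.balance or len(controls) <= len(cases):
        if len(controls) < len(cases):
            logger.warning(
                "fewer controls (%d) than cases (%d); keeping all controls",
                len(controls), len(cases),
            )
        return cases, list(controls)
    rng = np.random.default_rng(config.seed)
    keep = rng.choice(len(controls), size=len(cases), replace=False)
    return cases, [controls[i] for i in sorted(keep)]


def split_cohort(
    samples: list[CohortSample], config: CohortConfig
) -> tuple[list[CohortSample], list[CohortSample], list[CohortSample]]:
    """Seeded, disjoint 8:1:1 partition by patient (default) or by sample."""
    rng = np.random.default_rng(config.seed + 1)
    a, b, c = config.split_ratio
    if config.split_unit == "patient":
        units = sorted({s.patient_id for s in samples})
    else:
        units = list(range(len(samples)))
    if len(units) < 10:
        raise ValueError(f"need at least 10 {config.split_unit}s to split, got {len(units)}")
    order = rng.permutation(len(units))
    n = len(units)
    cut1 = round(n * a / 10)
    cut2 = round(n * (a + b) / 10)
    groups = (
        {units[i] for i in order[:cut1]},
        {units[i] for i in order[cut1:cut2]},
        {units[i] for i in order[cut2:]},
    )
    if config.split_unit == "patient":
        parts = tuple(
            [s for s in samples if s.patient_id in g] for g in groups
        )
    else:
        parts = tuple([samples[i] for i in sorted(g)] for g in groups)
    return parts  # type: ignore[return-value]


def build_cohort(
    timelines: list[PatientTimeline], config: CohortConfig
) -> dict:
    """Full cohort construction: sampling, balancing, splitting.

    Returns a dict with keys ``train``, ``valid``, ``test`` (lists of
    :class:`CohortSample`) and ``counts`` (summary of sample counts at each
    stage).
    """
    config.validate()
    cases: list[CohortSample] = []
    controls: list[CohortSample] = []
    for tl in timelines:
        cs = sample_cases(tl, config)
        if cs:
            # a patient contributing case samples contributes no control
            cases.extend(cs)
        else:
            ctrl = sample_controls(tl, config)
            if ctrl is not None:
                controls.append(ctrl)
    n_controls_raw = len(controls)
    cases, controls = balance_cohort(cases, controls, config)
    samples = cases + controls
    train, valid, test = split_cohort(samples, config)
    counts = {
        "patients": len(timelines),
        "cases": len(cases),
        "case_patients": len({s.patient_id for s in cases}),
        "controls_eligible": n_controls_raw,
        "controls_kept": len(controls),
        "train": len(train),
        "valid": len(valid),
        "test": len(test),
    }
    logger.info("cohort: %s", counts)
    return {"train": train, "valid": valid, "test": test, "counts": counts}
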