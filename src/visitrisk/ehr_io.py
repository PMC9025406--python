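"""Read/write long-format clinical event tables.

Two UTF-8 delimited text files (tab by default) describe a population:

* ``events``: one row per clinical event with columns
  ``patient_id, encounter_id, date, domain, code, result_flag``
  (ISO-8601 dates; ``result_flag`` empty for non-lab events);
* ``patients``: one row per patient with columns
  ``patient_id, ptsd_date, sre_dates`` where ``sre_dates`` is a
  semicolon-joined list of ISO dates (empty when the patient had none).

``read_events(write_events(timelines))`` is the identity; same-date
encounter records are merged into a single encounter on read.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import pandas as pd

from .synthetic import EventRecord, PatientTimeline

EVENT_COLUMNS = ["patient_id", "encounter_id", "date", "domain", "code", "result_flag"]
PATIENT_COLUMNS = ["patient_id", "ptsd_date", "sre_dates"]


def events_frame(timelines: list[PatientTimeline]) -> pd.DataFrame:
    rows = [
        (ev.patient_id, ev.encounter_id, ev.date.isoformat(), ev.domain, ev.code,
         ev.result_flag or "")
        for tl in timelines
        for (_eid, _date, events) in tl.encounters
        for ev in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def patients_frame(timelines: list[PatientTimeline]) -> pd.DataFrame:
    rows = [
        (tl.patient_id, tl.ptsd_date.isoformat(),
         ";".join(d.isoformat() for d in tl.sre_dates))
        for tl in timelines
    ]
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS)


def write_events(timelines: list[PatientTimeline], events_path, patients_path, sep: str = "\t") -> None:
    """Serialize timelines to an event table and a patient table."""
    events_frame(timelines).to_csv(events_path, sep=sep, index=False, lineterminator="\n")
    patients_frame(timelines).to_csv(patients_path, sep=sep, index=False, lineterminator="\n")


def _parse_date(s: str) -> datetime.date:
    return datetime.date.fromisoformat(s)


def read_events(events_path, patients_path, sep: str = "\t") -> list[PatientTimeline]:
    """Load timelines back from the two tables written by :func:`write_events`.

    Events of one patient on the same calendar date are merged into one
    encounter (keeping the first encounter_id seen); encounters are returned
    in strict date order. Patients present in the patient table but without
    events yield timelines with empty encounter lists.
    """
    events = pd.read_csv(events_path, sep=sep, dtype=str, keep_default_na=False)
    patients = pd.read_csv(patients_path, sep=sep, dtype=str, keep_default_na=False)
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    missing = set(PATIENT_COLUMNS) - set(patients.columns)
    if missing:
        raise ValueError(f"patient table missing columns: {sorted(missing)}")

    by_patient: dict[str, dict[datetime.date, tuple[str, list[EventRecord]]]] = {}
    for row in events.itertuples(index=False):
        date = _parse_date(row.date)
        flag = row.result_flag or None
        enc_map = by_patient.setdefault(row.patient_id, {})
        if date not in enc_map:
            enc_map[date] = (row.encounter_id, [])
        eid = enc_map[date][0]
        enc_map[date][1].append(
            EventRecord(row.patient_id, eid, date, row.domain, row.code, flag)
        )

    timelines = []
    for row in patients.itertuples(index=False):
        enc_map = by_patient.get(row.patient_id, {})
        encounters = [
            (enc_map[d][0], d, enc_map[d][1]) for d in sorted(enc_map)
        ]
        sre_dates = [
            _parse_date(s) for s in str(row.sre_dates).split(";") if s
        ]
        timelines.append(
            PatientTimeline(
                patient_id=row.patient_id,
                encounters=encounters,
                ptsd_date=_parse_date(row.ptsd_date),
                sre_dates=sorted(sre_dates),
            )
        )
    return timelines


def file_digest(path) -> str:
    """SHA-256 hex digest of a file (for run manifests and determinism checks)."""
    import hashlib

    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
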