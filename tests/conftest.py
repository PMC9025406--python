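import datetime

import pytest

from visitrisk.synthetic import EventRecord, PatientTimeline, day_to_date


def make_timeline(pid="P0", encounter_events=None, sre_days=(), ptsd_day=0):
    """Hand-built timeline from {day: [(domain, code, flag), ...]}.

    Encounter days are taken from the dict keys (sorted); an empty event
    list still creates the encounter.
    """
    encounter_events = encounter_events or {}
    encounters = []
    for k, day in enumerate(sorted(encounter_events)):
        eid = f"{pid}-e{k:04d}"
        date = day_to_date(day)
        events = [
            EventRecord(pid, eid, date, dom, code, flag)
            for dom, code, flag in encounter_events[day]
        ]
        encounters.append((eid, date, events))
    return PatientTimeline(
        patient_id=pid,
        encounters=encounters,
        ptsd_date=day_to_date(ptsd_day),
        sre_dates=[day_to_date(d) for d in sorted(sre_days)],
    )


@pytest.fixture
def timeline_factory():
    return make_timeline
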