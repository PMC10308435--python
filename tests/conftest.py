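import datetime

import pytest

from otmetrics import CaseRecord, Cohort, Interval, TheatreList


def make_list(
    cases,
    sched=(540, 1020),
    list_id="L0001",
    unit="TrustA",
    specialty="General Surgery",
    date=datetime.date(2023, 1, 2),
):
    """Build a TheatreList from [(start, end), ...] or [[(s, e), ...], ...].

    Each element is one case: a single (start, end) tuple for a
    one-segment case, or a list of segment tuples for a multi-segment one.
    """
    records = []
    for i, case in enumerate(cases):
        segs = [case] if isinstance(case, tuple) else list(case)
        records.append(
            CaseRecord(f"c{i + 1:02d}", [Interval(s, e) for s, e in segs])
        )
    return TheatreList(
        list_id=list_id,
        unit=unit,
        specialty=specialty,
        date=date,
        scheduled=Interval(*sched),
        cases=records,
    )


def make_cohort(*lists):
    return Cohort(lists)


def list_with_deltas(start_delta, finish_delta, sched=(540, 1020), **kw):
    """A single-case list whose timing deltas are exactly the given values."""
    return make_list(
        [(sched[0] + start_delta, sched[1] + finish_delta)], sched=sched, **kw
    )


@pytest.fixture
def worked_example():
    from otmetrics import make_worked_example

    return make_worked_example()
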