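"""Core data model for theatre sessions, cases, and time intervals.

All clock times are integer minutes since midnight of the session day.
Values at or above 1440 denote spill past midnight, so a session and its
overrun stay on a single number line. Intervals are half-open in
arithmetic (``[start, end)``, duration ``end - start``): two abutting
touch segments create a zero-length gap, never a negative one.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

#: Upper bound for clock values: minute 1919 is 7:59 a.m. the next day,
#: comfortably past any overnight overrun of an elective list.
MAX_MINUTE = 1919


class CancelledListError(ValueError):
    """Raised when a timing statistic is requested for a zero-case list."""


class InvalidSessionError(ValueError):
    """Raised when a list's allocated (scheduled) duration is not positive."""


class EmptyCohortError(ValueError):
    """Raised when an aggregate is requested over a cohort with no usable lists."""


@dataclass(frozen=True, order=True)
class Interval:
    """A half-open time interval ``[start, end)`` in minutes since midnight.

    The constructor is deliberately permissive (``end < start`` is
    representable) so that :func:`validate_list` can *report* a reversed
    segment instead of the reader crashing mid-file. Every operation in
    this package assumes intervals that have passed validation.
    """

    start: int
    end: int

    @property
    def duration(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        """Half-open overlap test: abutting intervals do not overlap."""
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


def clip_to_window(iv: Interval, window: Interval) -> Optional[Interval]:
    """Intersect ``iv`` with ``window``; ``None`` when they are disjoint.

    This is the capping primitive: touch time falling outside the
    scheduled window (overruns, or early starts when capping both sides)
    is discarded by clipping each segment before summing durations.
    Idempotent, and never increases duration.
    """
    start = max(iv.start, window.start)
    end = min(iv.end, window.end)
    if end <= start:
        return None
    return Interval(start, end)


@dataclass(frozen=True)
class CaseRecord:
    """One operation on one list: an ordered set of touch segments.

    A touch segment is an interval of direct patient contact (delivering
    anaesthesia or surgery). Most cases have a single segment; multiple
    segments model within-case pauses, which is what makes the two
    intercase-downtime definitions genuinely differ.
    """

    case_id: str
    segments: tuple[Interval, ...]

    def __init__(self, case_id: str, segments: Iterable[Interval]):
        object.__setattr__(self, "case_id", case_id)
        object.__setattr__(self, "segments", tuple(segments))

    @property
    def touch_time(self) -> int:
        """Total minutes of patient contact across all segments."""
        return sum(seg.duration for seg in self.segments)

    @property
    def span(self) -> Interval:
        """First segment start to last segment end (includes any pauses)."""
        return Interval(self.segments[0].start, self.segments[-1].end)


@dataclass(frozen=True)
class TheatreList:
    """One scheduled theatre session: the allocated window and its cases.

    ``scheduled.duration`` is the allocated time in minutes — the
    denominator of every utilisation fraction. Zero cases is valid data
    (a cancelled list): it counts as utilisation 0 but has no defined
    start or finish time.
    """

    list_id: str
    unit: str
    specialty: str
    date: datetime.date
    scheduled: Interval
    cases: tuple[CaseRecord, ...]

    def __init__(
        self,
        list_id: str,
        unit: str,
        specialty: str,
        date: datetime.date,
        scheduled: Interval,
        cases: Iterable[CaseRecord] = (),
    ):
        object.__setattr__(self, "list_id", list_id)
        object.__setattr__(self, "unit", unit)
        object.__setattr__(self, "specialty", specialty)
        object.__setattr__(self, "date", date)
        object.__setattr__(self, "scheduled", scheduled)
        object.__setattr__(self, "cases", tuple(cases))

    @property
    def allocated(self) -> int:
        """Allocated session duration in minutes (utilisation denominator)."""
        return self.scheduled.duration

    @property
    def is_cancelled(self) -> bool:
        return len(self.cases) == 0


@dataclass(frozen=True)
class Cohort:
    """A collection of theatre lists — the 'team or hospital' aggregation unit."""

    lists: tuple[TheatreList, ...]

    def __init__(self, lists: Iterable[TheatreList]):
        object.__setattr__(self, "lists", tuple(lists))

    def __len__(self) -> int:
        return len(self.lists)

    def __iter__(self) -> Iterator[TheatreList]:
        return iter(self.lists)

    def non_cancelled(self) -> tuple[TheatreList, ...]:
        return tuple(lst for lst in self.lists if not lst.is_cancelled)

    def by_unit(self) -> dict[str, "Cohort"]:
        groups: dict[str, list[TheatreList]] = {}
        for lst in self.lists:
            groups.setdefault(lst.unit, []).append(lst)
        return {unit: Cohort(ls) for unit, ls in sorted(groups.items())}

    def by_specialty(self) -> dict[str, "Cohort"]:
        groups: dict[str, list[TheatreList]] = {}
        for lst in self.lists:
            groups.setdefault(lst.specialty, []).append(lst)
        return {sp: Cohort(ls) for sp, ls in sorted(groups.items())}

    def by_week(self) -> dict[str, "Cohort"]:
        """Group by ISO year-week, keyed ``YYYY-Www``."""
        groups: dict[str, list[TheatreList]] = {}
        for lst in self.lists:
            iso = lst.date.isocalendar()
            key = f"{iso[0]}-W{iso[1]:02d}"
            groups.setdefault(key, []).append(lst)
        return {wk: Cohort(ls) for wk, ls in sorted(groups.items())}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def validate_list(lst: TheatreList) -> list[str]:
    """Check every structural invariant of a list; return violation messages.

    Validation never raises — it reports. An empty result means the list
    is well-formed. Each message names the offending field or case and
    the rule it breaks.
    """
    violations: list[str] = []

    if lst.scheduled.duration <= 0:
        violations.append(
            f"scheduled: allocated duration must be positive, got "
            f"{lst.scheduled.duration} min ([{lst.scheduled.start}, {lst.scheduled.end}))"
        )
    if lst.scheduled.start < 0 or lst.scheduled.end > MAX_MINUTE + 1:
        violations.append(
            f"scheduled: window [{lst.scheduled.start}, {lst.scheduled.end}) "
            f"outside the representable day (0..{MAX_MINUTE})"
        )

    for case in lst.cases:
        if len(case.segments) == 0:
            violations.append(f"case {case.case_id!r}: must have at least one touch segment")
            continue
        for i, seg in enumerate(case.segments):
            if seg.end < seg.start:
                violations.append(
                    f"case {case.case_id!r} segment {i}: end < start "
                    f"([{seg.start}, {seg.end}))"
                )
            if seg.start < 0:
                violations.append(
                    f"case {case.case_id!r} segment {i}: negative start ({seg.start})"
                )
        for i in range(len(case.segments) - 1):
            a, b = case.segments[i], case.segments[i + 1]
            if b.start < a.end:
                violations.append(
                    f"case {case.case_id!r}: segments {i} and {i + 1} overlap "
                    f"or are unsorted ([{a.start},{a.end}) then [{b.start},{b.end}))"
                )
        if all(seg.end >= seg.start for seg in case.segments) and case.touch_time <= 0:
            violations.append(
                f"case {case.case_id!r}: total touch time must be positive"
            )

    # cross-case checks only make sense for structurally sound cases
    sound = [
        c for c in lst.cases if c.segments and all(s.end >= s.start for s in c.segments)
    ]
    for i in range(len(sound) - 1):
        a, b = sound[i], sound[i + 1]
        if b.segments[0].start < a.segments[0].start:
            violations.append(
                f"cases: {a.case_id!r} and {b.case_id!r} are not sorted by first segment start"
            )
        if a.span.overlaps(b.span):
            violations.append(
                f"cases: spans of {a.case_id!r} and {b.case_id!r} overlap "
                f"([{a.span.start},{a.span.end}) and [{b.span.start},{b.span.end}))"
            )

    return violations


def validate_cohort(cohort: Cohort) -> list[str]:
    """Validate every list plus cohort-level uniqueness of list_ids."""
    violations: list[str] = []
    seen: set[str] = set()
    for lst in cohort:
        if lst.list_id in seen:
            violations.append(f"cohort: duplicate list_id {lst.list_id!r}")
        seen.add(lst.list_id)
        violations.extend(f"list {lst.list_id!r}: {v}" for v in validate_list(lst))
    return violations


def session_span(lst: TheatreList) -> Optional[Interval]:
    """Worked interval of the list: first touch start to last touch end.

    ``None`` for a cancelled (zero-case) list, for which 'when they
    started' is undefined.
    """
    if lst.is_cancelled:
        return None
    return Interval(lst.cases[0].segments[0].start, lst.cases[-1].segments[-1].end)


def total_touch_time(lst: TheatreList) -> int:
    """Sum of touch-segment durations across all cases; 0 when cancelled."""
    return sum(case.touch_time for case in lst.cases)
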