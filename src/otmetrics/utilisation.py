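"""The utilisation family, downtime, aggregation regimes, and potential gains.

Per-list measures
    *raw* — session span (first start to last finish) over allocated time;
    can exceed 1 when a list overruns.
    *touch* — total patient-contact minutes over allocated time.
    *capped touch* — touch minutes after clipping every segment to the
    scheduled window, so it can never exceed 1. The capping window is the
    full scheduled interval by default (``cap_side="both"``); pass
    ``cap_side="end"`` to discard only overruns past the scheduled end.

Aggregation regimes
    *pooled* — sum all used minutes, divide by summed allocated minutes:
    one scalar, deliberately with no variance fields, because that is the
    point of the critique.
    *distribution* — convert each list's fraction to a decimal and report
    median (inter-quartile range; range).

*Potential gains* divides pooled unused minutes by a mean case duration
to claim extra-case capacity; its *feasible* counterpart applies the same
division list by list, which is what scattered spare minutes actually
permit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .schedule import (
    Cohort,
    EmptyCohortError,
    Interval,
    InvalidSessionError,
    TheatreList,
    clip_to_window,
    session_span,
    total_touch_time,
)
from .timing import SummaryDistribution

UtilisationMode = Literal["raw", "touch", "capped"]
DowntimeMethod = Literal["gap_sum", "span_minus_touch"]
CapSide = Literal["end", "both"]


@dataclass(frozen=True)
class UtilisationBundle:
    """All per-list utilisation variants and downtimes, with their minutes."""

    raw: float
    touch: float
    capped_touch: float
    downtime_gap_sum: int
    downtime_span_minus_touch: int
    allocated: int
    used_span: int
    used_touch: int
    used_touch_capped: int

    def to_dict(self) -> dict:
        return {
            "raw": self.raw,
            "touch": self.touch,
            "capped_touch": self.capped_touch,
            "downtime_gap_sum_min": self.downtime_gap_sum,
            "downtime_span_minus_touch_min": self.downtime_span_minus_touch,
            "allocated_min": self.allocated,
            "used_span_min": self.used_span,
            "used_touch_min": self.used_touch,
            "used_touch_capped_min": self.used_touch_capped,
        }


@dataclass(frozen=True)
class PooledUtilisation:
    """Pooled-ratio aggregate: Σ used / Σ allocated across lists.

    Carries its numerator and denominator so the fraction is auditable.
    Deliberately has *no* variance fields: pooling all minutes into one
    ratio destroys the between-list information a variance would need.
    """

    value: float
    numerator_minutes: int
    denominator_minutes: int
    n_lists: int

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "numerator_minutes": self.numerator_minutes,
            "denominator_minutes": self.denominator_minutes,
            "n_lists": self.n_lists,
        }


@dataclass(frozen=True)
class PotentialGains:
    """Extra-case capacity claims: the pooled figure and its feasible check.

    ``pooled_extra_cases`` divides the *summed* unused minutes by the
    mean case duration — the calculation under critique, which treats
    spare minutes on disparate lists as poolable. ``feasible_extra_cases``
    applies the same division within each list before summing: a case
    fits only where a whole case-duration of contiguous-list slack
    exists. Pooled ≥ feasible always.
    """

    unused_minutes: int
    mean_case_duration_minutes: float
    pooled_extra_cases: int
    feasible_extra_cases: int
    mode: str
    rounding: str = "floor"

    def to_dict(self) -> dict:
        return {
            "unused_minutes": self.unused_minutes,
            "mean_case_duration_minutes": self.mean_case_duration_minutes,
            "pooled_extra_cases": self.pooled_extra_cases,
            "feasible_extra_cases": self.feasible_extra_cases,
            "mode": self.mode,
            "rounding": self.rounding,
        }


def _check_allocated(lst: TheatreList) -> None:
    if lst.allocated <= 0:
        raise InvalidSessionError(
            f"list {lst.list_id!r}: allocated duration must be positive, "
            f"got {lst.allocated}"
        )


def raw_utilisation(lst: TheatreList) -> float:
    """Session-span minutes over allocated minutes; 0 for a cancelled list.

    May exceed 1: a list that overruns has used more wall-clock span
    than it was allocated.
    """
    _check_allocated(lst)
    span = session_span(lst)
    if span is None:
        return 0.0
    return span.duration / lst.allocated


def touch_time_utilisation(lst: TheatreList) -> float:
    """Total patient-contact minutes over allocated minutes."""
    _check_allocated(lst)
    return total_touch_time(lst) / lst.allocated


def _cap_window(lst: TheatreList, cap_side: CapSide) -> Interval:
    if cap_side == "end":
        return Interval(0, lst.scheduled.end)
    return lst.scheduled


def capped_touch_minutes(lst: TheatreList, cap_side: CapSide = "both") -> int:
    """Touch minutes surviving the clip of every segment to the scheduled window."""
    window = _cap_window(lst, cap_side)
    total = 0
    for case in lst.cases:
        for seg in case.segments:
            clipped = clip_to_window(seg, window)
            if clipped is not None:
                total += clipped.duration
    return total


def capped_touch_time_utilisation(lst: TheatreList, cap_side: CapSide = "both") -> float:
    """Touch-time utilisation after discarding out-of-window touch; always ≤ 1."""
    _check_allocated(lst)
    return capped_touch_minutes(lst, cap_side) / lst.allocated


def intercase_downtime(lst: TheatreList, method: DowntimeMethod = "gap_sum") -> int:
    """Non-touch minutes within the worked session, by one of two definitions.

    ``gap_sum`` sums the positive gaps between consecutive cases' spans —
    time between patient-out and next patient-in. ``span_minus_touch``
    subtracts total touch time from the session-span duration, which
    additionally counts pauses *within* cases. The two coincide when
    every case is a single contiguous segment; otherwise
    ``gap_sum <= span_minus_touch``. Both definitions are in-house
    reconstructions: the choice affects the numerical value of touch-time
    utilisation but not its structure.
    """
    if lst.is_cancelled:
        return 0
    if method == "gap_sum":
        total = 0
        for prev, nxt in zip(lst.cases, lst.cases[1:]):
            gap = nxt.span.start - prev.span.end
            if gap > 0:
                total += gap
        return total
    if method == "span_minus_touch":
        span = session_span(lst)
        assert span is not None
        return span.duration - total_touch_time(lst)
    raise ValueError(f"unknown downtime method {method!r}")


def utilisation_bundle(lst: TheatreList, cap_side: CapSide = "both") -> UtilisationBundle:
    """All per-list utilisation variants in one pass."""
    _check_allocated(lst)
    span = session_span(lst)
    used_span = span.duration if span is not None else 0
    used_touch = total_touch_time(lst)
    used_capped = capped_touch_minutes(lst, cap_side)
    alloc = lst.allocated
    return UtilisationBundle(
        raw=used_span / alloc,
        touch=used_touch / alloc,
        capped_touch=used_capped / alloc,
        downtime_gap_sum=intercase_downtime(lst, "gap_sum"),
        downtime_span_minus_touch=intercase_downtime(lst, "span_minus_touch"),
        allocated=alloc,
        used_span=used_span,
        used_touch=used_touch,
        used_touch_capped=used_capped,
    )


def used_minutes(lst: TheatreList, mode: UtilisationMode, cap_side: CapSide = "both") -> int:
    """Per-list 'used' minutes under the chosen utilisation definition."""
    if mode == "raw":
        span = session_span(lst)
        return span.duration if span is not None else 0
    if mode == "touch":
        return total_touch_time(lst)
    if mode == "capped":
        return capped_touch_minutes(lst, cap_side)
    raise ValueError(f"unknown utilisation mode {mode!r}")


def per_list_utilisation(
    lst: TheatreList, mode: UtilisationMode, cap_side: CapSide = "both"
) -> float:
    _check_allocated(lst)
    return used_minutes(lst, mode, cap_side) / lst.allocated


def pooled_utilisation(
    cohort: Cohort, mode: UtilisationMode = "capped", cap_side: CapSide = "both"
) -> PooledUtilisation:
    """Pooled-ratio aggregate: Σ used minutes / Σ allocated minutes.

    Algebraically this is the allocated-minutes-weighted mean of the
    per-list utilisations — every minute of allocated time votes once,
    so long or heavily used lists dominate and no variance survives.
    """
    if len(cohort) == 0:
        raise EmptyCohortError("pooled utilisation undefined for an empty cohort")
    for lst in cohort:
        _check_allocated(lst)
    num = sum(used_minutes(lst, mode, cap_side) for lst in cohort)
    den = sum(lst.allocated for lst in cohort)
    return PooledUtilisation(
        value=num / den,
        numerator_minutes=num,
        denominator_minutes=den,
        n_lists=len(cohort),
    )


def distribution_utilisation(
    cohort: Cohort, mode: UtilisationMode = "touch", cap_side: CapSide = "both"
) -> SummaryDistribution:
    """Distributional aggregate: per-list decimals, then median/IQR/range."""
    if len(cohort) == 0:
        raise EmptyCohortError("distribution utilisation undefined for an empty cohort")
    values = [per_list_utilisation(lst, mode, cap_side) for lst in cohort]
    return SummaryDistribution.from_values(values)


def pooled_relative_reduction(total_pre: float, total_post: float) -> float:
    """Percent reduction of a pooled total: 100 × (pre − post) / pre.

    Exposes the pooled-aggregation analogy as an executable calculation:
    summing raw measurements across subjects and comparing totals yields
    a single percentage with no measure of variance, which is exactly
    why no trial is analysed this way.
    """
    if total_pre <= 0:
        raise ValueError(f"total_pre must be positive, got {total_pre}")
    return 100.0 * (total_pre - total_post) / total_pre


def potential_gains(
    cohort: Cohort,
    mean_case_duration: float,
    mode: UtilisationMode = "capped",
    cap_side: CapSide = "both",
    strict_box1: bool = False,
) -> PotentialGains:
    """Extra-case capacity: the pooled claim and the per-list feasible count.

    Per-list unused minutes are ``allocated − used``. In ``capped`` mode
    used minutes never exceed allocated, so unused is naturally
    non-negative. In the uncapped modes a per-list over-use (overrun)
    contributes zero unused rather than negative — potential gain is a
    capacity concept, and letting overruns cancel other lists' idle time
    would net away exactly the fallacy under test. ``strict_box1=True``
    restores signed netting of the pooled total for fidelity studies.

    Counts use floor division: a partial case cannot be done.
    """
    if mean_case_duration <= 0:
        raise ValueError(
            f"mean_case_duration must be positive, got {mean_case_duration}"
        )
    if len(cohort) == 0:
        raise EmptyCohortError("potential gains undefined for an empty cohort")
    per_list_unused = []
    signed_total = 0
    for lst in cohort:
        _check_allocated(lst)
        unused = lst.allocated - used_minutes(lst, mode, cap_side)
        signed_total += unused
        per_list_unused.append(max(0, unused))
    total_unused = signed_total if strict_box1 else sum(per_list_unused)
    pooled = max(0, math.floor(total_unused / mean_case_duration))
    feasible = sum(math.floor(u / mean_case_duration) for u in per_list_unused)
    return PotentialGains(
        unused_minutes=total_unused,
        mean_case_duration_minutes=mean_case_duration,
        pooled_extra_cases=pooled,
        feasible_extra_cases=feasible,
        mode=f"{mode}{'+strict_box1' if strict_box1 else ''}",
    )
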