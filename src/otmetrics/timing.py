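"""Start- and finish-time statistics in both reporting regimes.

The Model Hospital (MH) regime reports a conditional mean for each
category — the average late start computed *only over lists that started
late*, and likewise for early and late finishes — without the category
counts. The conventional regime summarises the signed deltas of *all*
lists as median (inter-quartile range; range), which is free of the
selection bias: improving punctuality can only improve it, whereas the
MH statistic can stay flat or worsen as late starts are eliminated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .schedule import (
    CancelledListError,
    Cohort,
    EmptyCohortError,
    TheatreList,
    session_span,
)

#: Quartile convention used throughout: linear interpolation between the
#: closest order statistics (numpy's ``method="linear"``). Recorded in
#: report metadata so another implementation can match bit-exact.
QUARTILE_METHOD = "linear"


@dataclass(frozen=True)
class TimingDeltas:
    """Signed start/finish deviations for one list, in minutes.

    ``start_delta`` = actual first-touch start − scheduled start
    (positive = late start). ``finish_delta`` = actual last-touch end −
    scheduled end (positive = late finish). Only defined for lists with
    at least one case.
    """

    start_delta: int
    finish_delta: int


@dataclass(frozen=True)
class MHTimingPanel:
    """The Model Hospital timing panel, plus the n's it leaves unreported.

    Each average is a mean over its category only and is reported as a
    non-negative magnitude; it is ``None`` exactly when its category is
    empty. ``n_early_finish + n_late_finish + n_on_time_finish == n_lists``.
    """

    avg_late_start: Optional[float]
    n_late_start: int
    avg_early_finish: Optional[float]
    n_early_finish: int
    avg_late_finish: Optional[float]
    n_late_finish: int
    n_on_time_finish: int
    n_lists: int
    grace: int = 0

    def to_dict(self) -> dict:
        return {
            "avg_late_start": self.avg_late_start,
            "n_late_start": self.n_late_start,
            "avg_early_finish": self.avg_early_finish,
            "n_early_finish": self.n_early_finish,
            "avg_late_finish": self.avg_late_finish,
            "n_late_finish": self.n_late_finish,
            "n_on_time_finish": self.n_on_time_finish,
            "n_lists": self.n_lists,
            "grace_min": self.grace,
        }


@dataclass(frozen=True)
class SummaryDistribution:
    """Median (inter-quartile range; range) with n — the conventional shape."""

    median: float
    q25: float
    q75: float
    min: float
    max: float
    n: int

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SummaryDistribution":
        if len(values) == 0:
            raise EmptyCohortError("summary distribution needs at least one value")
        arr = np.asarray(values, dtype=float)
        return cls(
            median=float(np.median(arr)),
            q25=float(np.percentile(arr, 25, method=QUARTILE_METHOD)),
            q75=float(np.percentile(arr, 75, method=QUARTILE_METHOD)),
            min=float(arr.min()),
            max=float(arr.max()),
            n=int(arr.size),
        )

    def to_dict(self) -> dict:
        return {
            "median": self.median,
            "q25": self.q25,
            "q75": self.q75,
            "min": self.min,
            "max": self.max,
            "n": self.n,
            "quartile_method": QUARTILE_METHOD,
        }


def timing_deltas(lst: TheatreList) -> TimingDeltas:
    """Signed start/finish deltas for one list; exact integer minutes.

    Raises :class:`CancelledListError` for a zero-case list — a cancelled
    session has no start time, so timing is undefined (unlike
    utilisation, which is simply zero).
    """
    span = session_span(lst)
    if span is None:
        raise CancelledListError(
            f"timing undefined for cancelled list {lst.list_id!r}"
        )
    return TimingDeltas(
        start_delta=span.start - lst.scheduled.start,
        finish_delta=span.end - lst.scheduled.end,
    )


def _deltas(cohort: Cohort) -> list[TimingDeltas]:
    lists = cohort.non_cancelled()
    if not lists:
        raise EmptyCohortError("cohort has no lists with cases; timing undefined")
    return [timing_deltas(lst) for lst in lists]


def mh_timing_panel(cohort: Cohort, grace: int = 0) -> MHTimingPanel:
    """Timing panel the Model Hospital way: conditional means per category.

    A list is 'late' only when its delta exceeds ``grace`` (strictly);
    with the default grace of 0 a list starting exactly on time falls in
    no category. Early-finish magnitudes are reported positive.
    """
    deltas = _deltas(cohort)
    late_starts = [d.start_delta for d in deltas if d.start_delta > grace]
    early_fin = [-d.finish_delta for d in deltas if d.finish_delta < -grace]
    late_fin = [d.finish_delta for d in deltas if d.finish_delta > grace]
    n = len(deltas)
    return MHTimingPanel(
        avg_late_start=float(np.mean(late_starts)) if late_starts else None,
        n_late_start=len(late_starts),
        avg_early_finish=float(np.mean(early_fin)) if early_fin else None,
        n_early_finish=len(early_fin),
        avg_late_finish=float(np.mean(late_fin)) if late_fin else None,
        n_late_finish=len(late_fin),
        n_on_time_finish=n - len(early_fin) - len(late_fin),
        n_lists=n,
        grace=grace,
    )


def conventional_timing_summary(
    cohort: Cohort,
) -> tuple[SummaryDistribution, SummaryDistribution]:
    """All-list distributional summaries of (start_delta, finish_delta).

    No subsetting by sign: every non-cancelled list contributes its
    signed delta, and the median/IQR/range describe the whole
    distribution.
    """
    deltas = _deltas(cohort)
    starts = [d.start_delta for d in deltas]
    finishes = [d.finish_delta for d in deltas]
    return (
        SummaryDistribution.from_values(starts),
        SummaryDistribution.from_values(finishes),
    )
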