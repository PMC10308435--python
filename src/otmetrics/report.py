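"""Dual-dashboard assembly, caterpillar ordering, and divergence reports.

A :class:`CohortReport` computes, from one identical cohort, both the
Model Hospital (MH) panel — conditional-mean timing statistics, pooled
capped utilisation, pooled potential gains — and the conventional panel —
all-list distributional timing summaries, median utilisation, and the
per-list feasible extra-case count. Its metadata records every regime
decision (grace, cap side, quartile convention, rounding) so that two
runs are comparable and every number is reproducible: undisclosed
calculation choices are precisely the failure mode this tool exists to
surface.

Reports are pure functions of (cohort, options): repeated invocation is
bit-identical, and the canonical JSON serialisation is key-sorted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional

from .schedule import Cohort, EmptyCohortError
from .timing import (
    QUARTILE_METHOD,
    MHTimingPanel,
    SummaryDistribution,
    conventional_timing_summary,
    mh_timing_panel,
)
from .utilisation import (
    CapSide,
    PooledUtilisation,
    PotentialGains,
    distribution_utilisation,
    pooled_utilisation,
    potential_gains,
)

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class ReportOptions:
    """Every tunable regime decision, recorded verbatim in report metadata."""

    grace: int = 0
    cap_side: CapSide = "both"
    mean_case_duration: float = 60.0
    strict_box1: bool = False

    def to_dict(self) -> dict:
        return {
            "grace_min": self.grace,
            "cap_side": self.cap_side,
            "mean_case_duration_min": self.mean_case_duration,
            "strict_box1": self.strict_box1,
            "quartile_method": QUARTILE_METHOD,
            "gains_rounding": "floor",
            "lateness_rule": "strictly greater than grace",
        }


@dataclass(frozen=True)
class CohortReport:
    """Both regimes' panels computed from one identical cohort."""

    mh_timing: MHTimingPanel
    mh_pooled_capped: PooledUtilisation
    mh_pooled_touch: PooledUtilisation
    mh_gains: PotentialGains
    conv_start: SummaryDistribution
    conv_finish: SummaryDistribution
    conv_util_touch: SummaryDistribution
    conv_util_raw: SummaryDistribution
    conv_gains: PotentialGains
    options: ReportOptions
    n_lists: int
    n_cancelled: int

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "metadata": {
                **self.options.to_dict(),
                "n_lists": self.n_lists,
                "n_cancelled": self.n_cancelled,
            },
            "mh_panel": {
                "timing": self.mh_timing.to_dict(),
                "pooled_utilisation_capped": self.mh_pooled_capped.to_dict(),
                "pooled_utilisation_touch": self.mh_pooled_touch.to_dict(),
                "potential_gains": self.mh_gains.to_dict(),
            },
            "conventional_panel": {
                "start_delta": self.conv_start.to_dict(),
                "finish_delta": self.conv_finish.to_dict(),
                "utilisation_touch": self.conv_util_touch.to_dict(),
                "utilisation_raw": self.conv_util_raw.to_dict(),
                "feasible_extra_cases": self.conv_gains.feasible_extra_cases,
                "potential_gains": self.conv_gains.to_dict(),
            },
        }

    def to_json(self) -> str:
        """Canonical key-sorted JSON; bit-identical across invocations."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def build_report(cohort: Cohort, options: Optional[ReportOptions] = None) -> CohortReport:
    """Compute the dual dashboard for one cohort.

    Mirrors the four-way utilisation comparison — pooled capped and
    pooled uncapped touch (the MH pair, means of pooled minutes) against
    median touch and median raw (the conventional pair) — plus both
    timing regimes and both potential-gains figures.
    """
    if len(cohort) == 0:
        raise EmptyCohortError("cannot report on an empty cohort")
    opts = options or ReportOptions()
    mh_gains = potential_gains(
        cohort,
        opts.mean_case_duration,
        mode="capped",
        cap_side=opts.cap_side,
        strict_box1=opts.strict_box1,
    )
    conv_gains = potential_gains(
        cohort, opts.mean_case_duration, mode="touch", cap_side=opts.cap_side
    )
    conv_start, conv_finish = conventional_timing_summary(cohort)
    return CohortReport(
        mh_timing=mh_timing_panel(cohort, grace=opts.grace),
        mh_pooled_capped=pooled_utilisation(cohort, "capped", opts.cap_side),
        mh_pooled_touch=pooled_utilisation(cohort, "touch", opts.cap_side),
        mh_gains=mh_gains,
        conv_start=conv_start,
        conv_finish=conv_finish,
        conv_util_touch=distribution_utilisation(cohort, "touch", opts.cap_side),
        conv_util_raw=distribution_utilisation(cohort, "raw", opts.cap_side),
        conv_gains=conv_gains,
        options=opts,
        n_lists=len(cohort),
        n_cancelled=len(cohort) - len(cohort.non_cancelled()),
    )


@dataclass(frozen=True)
class CaterpillarOrdering:
    """Units ordered best-to-worst on one metric, with deterministic ties."""

    entries: tuple[tuple[str, float, int], ...]  # (unit, value, rank)
    direction: str

    def units(self) -> tuple[str, ...]:
        return tuple(u for u, _, _ in self.entries)

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "entries": [
                {"unit": u, "value": v, "rank": r} for u, v, r in self.entries
            ],
        }


def caterpillar_order(
    unit_metrics: dict[str, float],
    direction: Literal["higher_better", "lower_better"] = "higher_better",
) -> CaterpillarOrdering:
    """Order units best-to-worst on one metric value.

    Stable sort; ties are broken alphabetically by unit name so the
    ordering is deterministic. Equal values share their metric but not
    their rank (ranks are 1..n positional, as on a bar chart).
    """
    if not unit_metrics:
        raise EmptyCohortError("caterpillar ordering needs at least one unit")
    if direction not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown direction {direction!r}")
    reverse = direction == "higher_better"
    ordered = sorted(
        unit_metrics.items(), key=lambda kv: ((-kv[1] if reverse else kv[1]), kv[0])
    )
    entries = tuple((unit, value, rank + 1) for rank, (unit, value) in enumerate(ordered))
    return CaterpillarOrdering(entries=entries, direction=direction)


def _unit_metric_pairs(cohort: Cohort, options: ReportOptions):
    """Per-unit (MH metric, conventional metric) values for ranking checks."""
    per_unit = cohort.by_unit()
    mh_util = {}
    conv_util = {}
    mh_start = {}
    conv_start = {}
    for unit, sub in per_unit.items():
        mh_util[unit] = pooled_utilisation(sub, "capped", options.cap_side).value
        conv_util[unit] = distribution_utilisation(sub, "touch", options.cap_side).median
        if sub.non_cancelled():
            panel = mh_timing_panel(sub, grace=options.grace)
            mh_start[unit] = (
                panel.avg_late_start if panel.avg_late_start is not None else 0.0
            )
            conv_start[unit] = conventional_timing_summary(sub)[0].median
    return mh_util, conv_util, mh_start, conv_start


def divergence_report(
    cohort: Cohort, options: Optional[ReportOptions] = None
) -> dict:
    """Structured MH-vs-conventional comparison on one cohort.

    For each headline metric: the MH value, the conventional value
    computed from the same data, their difference, and — when the cohort
    spans two or more units — a flag marking metrics on which the two
    regimes would order the units differently (a ranking reversal).
    """
    if len(cohort) == 0:
        raise EmptyCohortError("cannot compare regimes on an empty cohort")
    opts = options or ReportOptions()
    rep = build_report(cohort, opts)

    def entry(metric: str, mh, conv, reversal: Optional[bool]) -> dict:
        diff = None
        if mh is not None and conv is not None:
            diff = mh - conv
        return {
            "metric": metric,
            "mh_value": mh,
            "conventional_value": conv,
            "difference": diff,
            "ranking_reversal": reversal,
        }

    reversals: dict[str, Optional[bool]] = {
        "start_time": None,
        "utilisation": None,
    }
    if len(cohort.by_unit()) >= 2:
        mh_util, conv_util, mh_start, conv_start = _unit_metric_pairs(cohort, opts)
        reversals["utilisation"] = (
            caterpillar_order(mh_util, "higher_better").units()
            != caterpillar_order(conv_util, "higher_better").units()
        )
        if len(mh_start) >= 2:
            reversals["start_time"] = (
                caterpillar_order(mh_start, "lower_better").units()
                != caterpillar_order(conv_start, "lower_better").units()
            )

    entries = [
        entry(
            "avg_late_start_vs_median_start_delta",
            rep.mh_timing.avg_late_start,
            rep.conv_start.median,
            reversals["start_time"],
        ),
        entry(
            "avg_late_finish_vs_median_finish_delta",
            rep.mh_timing.avg_late_finish,
            rep.conv_finish.median,
            None,
        ),
        entry(
            "pooled_capped_vs_median_touch_utilisation",
            rep.mh_pooled_capped.value,
            rep.conv_util_touch.median,
            reversals["utilisation"],
        ),
        entry(
            "pooled_vs_feasible_extra_cases",
            rep.mh_gains.pooled_extra_cases,
            rep.conv_gains.feasible_extra_cases,
            None,
        ),
    ]
    flagged = [
        e["metric"]
        for e in entries
        if e["difference"] not in (None, 0, 0.0) or e["ranking_reversal"]
    ]
    return {
        "schema_version": SCHEMA_VERSION,
        "metadata": rep.to_dict()["metadata"],
        "comparisons": entries,
        "divergent_metrics": flagged,
        "gains_overstated_by": rep.mh_gains.pooled_extra_cases
        - rep.conv_gains.feasible_extra_cases,
    }
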