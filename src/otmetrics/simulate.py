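"""Seeded synthetic theatre-cohort generator.

Emulates cohorts of elective operating lists — of the kind a single
specialty in one Trust accrues over some weeks — with configurable
start-delay, case-duration (normal / log-normal / Weibull), turnover-gap
and overrun behaviour, so that every metric and every aggregation
paradox in this package is testable without any real Trust data.

Reproducibility contract: one pseudo-random stream per list, derived
from ``(seed, list index)`` via :class:`numpy.random.SeedSequence`, so a
cohort is deterministic for a fixed config and byte-identical when
written to CSV, even under parallel generation.

All preset parameter values are editorial choices of this package,
documented in the methods note; no published numeric parameters exist
for the scenarios they operationalise.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .schedule import CaseRecord, Cohort, Interval, TheatreList

PRESET_NAMES = ("punctual", "chronic_late_start", "overrun", "fragmented_gaps")

_MAX_CASES_PER_LIST = 100


class ConfigError(ValueError):
    """Raised for invalid scenario/distribution parameters."""


@dataclass(frozen=True)
class DistSpec:
    """One sampling distribution for a duration or delay, in minutes.

    kinds and params:
        ``normal``     — mean, sd (sd ≥ 0; sd 0 is a degenerate constant)
        ``lognormal``  — mu, sigma of the underlying normal, plus an
                         additive ``shift`` (earliest value; may be
                         negative to permit early starts)
        ``weibull``    — shape k > 0, scale λ > 0, plus ``shift``
        ``constant``   — value
    Samples are rounded to whole minutes (the data model is integer
    minutes).
    """

    kind: str
    params: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        p = self.params
        if self.kind == "normal":
            if p.get("sd", 0.0) < 0:
                raise ConfigError(f"normal sd must be >= 0, got {p.get('sd')}")
        elif self.kind == "lognormal":
            if p.get("sigma", 1.0) <= 0:
                raise ConfigError(f"lognormal sigma must be > 0, got {p.get('sigma')}")
        elif self.kind == "weibull":
            if p.get("shape", 1.0) <= 0 or p.get("scale", 1.0) <= 0:
                raise ConfigError("weibull shape and scale must be > 0")
        elif self.kind == "constant":
            if "value" not in p:
                raise ConfigError("constant distribution needs a 'value' param")
        else:
            raise ConfigError(f"unknown distribution kind {self.kind!r}")

    def sample(self, rng: np.random.Generator) -> int:
        p = self.params
        if self.kind == "normal":
            x = rng.normal(p.get("mean", 0.0), p.get("sd", 0.0))
        elif self.kind == "lognormal":
            x = p.get("shift", 0.0) + rng.lognormal(p.get("mu", 0.0), p.get("sigma", 1.0))
        elif self.kind == "weibull":
            x = p.get("shift", 0.0) + p.get("scale", 1.0) * rng.weibull(p.get("shape", 1.0))
        elif self.kind == "constant":
            x = p["value"]
        else:  # pragma: no cover - validate() rejects earlier
            raise ConfigError(f"unknown distribution kind {self.kind!r}")
        return int(round(float(x)))

    @property
    def mean(self) -> float:
        """Theoretical mean of the continuous distribution (pre-rounding)."""
        import math

        p = self.params
        if self.kind == "normal":
            return p.get("mean", 0.0)
        if self.kind == "lognormal":
            return p.get("shift", 0.0) + math.exp(
                p.get("mu", 0.0) + p.get("sigma", 1.0) ** 2 / 2
            )
        if self.kind == "weibull":
            return p.get("shift", 0.0) + p.get("scale", 1.0) * math.gamma(
                1 + 1 / p.get("shape", 1.0)
            )
        if self.kind == "constant":
            return p["value"]
        raise ConfigError(f"unknown distribution kind {self.kind!r}")

    @property
    def sd(self) -> float:
        """Theoretical standard deviation of the continuous distribution."""
        import math

        p = self.params
        if self.kind == "normal":
            return p.get("sd", 0.0)
        if self.kind == "lognormal":
            s2 = p.get("sigma", 1.0) ** 2
            return math.sqrt((math.exp(s2) - 1)) * math.exp(p.get("mu", 0.0) + s2 / 2)
        if self.kind == "weibull":
            k, lam = p.get("shape", 1.0), p.get("scale", 1.0)
            return lam * math.sqrt(
                math.gamma(1 + 2 / k) - math.gamma(1 + 1 / k) ** 2
            )
        if self.kind == "constant":
            return 0.0
        raise ConfigError(f"unknown distribution kind {self.kind!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one synthetic cohort.

    The default scheduled window is 540–1020 minutes (9 a.m.–5 p.m., an
    all-day 480-minute session). ``fill_target`` is the fraction of the
    allocated window the scheduler aims to fill with touch time;
    ``overrun_policy`` decides what happens at the scheduled end:
    ``stop_at_end`` abandons cases that would not finish in time, while
    ``complete_all`` keeps operating past the end until the booked work
    is done. ``fixed_unused_minutes``, when set, overrides stochastic
    filling: cases are laid end to end from the scheduled start so that
    exactly that many allocated minutes remain unused — the construction
    behind the scattered-spare-minutes scenario.
    """

    n_lists: int = 15
    sched_start: int = 540
    sched_end: int = 1020
    start_delay_dist: DistSpec = field(
        default_factory=lambda: DistSpec("normal", {"mean": 0.0, "sd": 0.0})
    )
    case_duration_dist: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal", {"mu": 4.2, "sigma": 0.45})
    )
    turnover_gap_dist: DistSpec = field(
        default_factory=lambda: DistSpec("normal", {"mean": 15.0, "sd": 5.0})
    )
    fill_target: float = 0.85
    overrun_policy: str = "stop_at_end"
    segment_split_prob: float = 0.0
    intra_case_pause_dist: DistSpec = field(
        default_factory=lambda: DistSpec("constant", {"value": 10.0})
    )
    fixed_unused_minutes: Optional[int] = None
    unit: str = "TrustA"
    specialty: str = "General Surgery"
    start_date: datetime.date = datetime.date(2023, 1, 2)
    seed: int = 0

    def validate(self) -> None:
        if self.n_lists < 1:
            raise ConfigError(f"n_lists must be >= 1, got {self.n_lists}")
        if self.sched_end <= self.sched_start:
            raise ConfigError("scheduled window must have positive duration")
        if not (0.0 < self.fill_target <= 1.5):
            raise ConfigError(f"fill_target must be in (0, 1.5], got {self.fill_target}")
        if self.overrun_policy not in ("stop_at_end", "complete_all"):
            raise ConfigError(f"unknown overrun_policy {self.overrun_policy!r}")
        if not (0.0 <= self.segment_split_prob <= 1.0):
            raise ConfigError("segment_split_prob must be in [0, 1]")
        if self.fixed_unused_minutes is not None:
            alloc = self.sched_end - self.sched_start
            if not (0 <= self.fixed_unused_minutes < alloc):
                raise ConfigError(
                    "fixed_unused_minutes must be in [0, allocated duration)"
                )
        for dist in (
            self.start_delay_dist,
            self.case_duration_dist,
            self.turnover_gap_dist,
            self.intra_case_pause_dist,
        ):
            dist.validate()

    @property
    def allocated(self) -> int:
        return self.sched_end - self.sched_start


def preset(name: str, n_lists: Optional[int] = None, seed: int = 0) -> ScenarioConfig:
    """A fully specified named scenario; deterministic given the seed.

    ``punctual``          every list starts exactly on time and stops at
                          the scheduled end: zero start deltas, finish
                          deltas ≤ 0.
    ``chronic_late_start`` lists start late by 30 ± 10 min (normal).
    ``overrun``           heavy booking with complete-all behaviour:
                          lists routinely finish past the scheduled end.
    ``fragmented_gaps``   every list leaves exactly 5 unused allocated
                          minutes — the scattered-spare-minutes scenario.
    """
    if name == "punctual":
        cfg = ScenarioConfig(
            start_delay_dist=DistSpec("normal", {"mean": 0.0, "sd": 0.0}),
            case_duration_dist=DistSpec("lognormal", {"mu": 4.2, "sigma": 0.45}),
            turnover_gap_dist=DistSpec("normal", {"mean": 12.0, "sd": 4.0}),
            fill_target=0.85,
            overrun_policy="stop_at_end",
            seed=seed,
        )
    elif name == "chronic_late_start":
        cfg = ScenarioConfig(
            start_delay_dist=DistSpec("normal", {"mean": 30.0, "sd": 10.0}),
            case_duration_dist=DistSpec("lognormal", {"mu": 4.2, "sigma": 0.45}),
            turnover_gap_dist=DistSpec("normal", {"mean": 15.0, "sd": 5.0}),
            fill_target=0.85,
            overrun_policy="stop_at_end",
            segment_split_prob=0.15,
            seed=seed,
        )
    elif name == "overrun":
        cfg = ScenarioConfig(
            start_delay_dist=DistSpec("normal", {"mean": 10.0, "sd": 15.0}),
            case_duration_dist=DistSpec("weibull", {"shape": 1.6, "scale": 90.0, "shift": 15.0}),
            turnover_gap_dist=DistSpec("normal", {"mean": 15.0, "sd": 5.0}),
            fill_target=1.0,
            overrun_policy="complete_all",
            seed=seed,
        )
    elif name == "fragmented_gaps":
        cfg = ScenarioConfig(
            fixed_unused_minutes=5,
            case_duration_dist=DistSpec("normal", {"mean": 95.0, "sd": 20.0}),
            seed=seed,
        )
    else:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if n_lists is not None:
        cfg = replace(cfg, n_lists=n_lists)
    return cfg


def _list_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _sample_positive(dist: DistSpec, rng: np.random.Generator, minimum: int = 1) -> int:
    return max(minimum, dist.sample(rng))


def _generate_fixed_unused(config: ScenarioConfig, rng: np.random.Generator) -> list[CaseRecord]:
    # Cases laid end to end from the scheduled start; last case truncated
    # so the worked span ends exactly fixed_unused_minutes before the
    # scheduled end. Touch equals span, so unused minutes are the same
    # under raw, touch, and capped accounting.
    assert config.fixed_unused_minutes is not None
    span_end = config.sched_end - config.fixed_unused_minutes
    cases: list[CaseRecord] = []
    cursor = config.sched_start
    k = 0
    while cursor < span_end and k < _MAX_CASES_PER_LIST:
        duration = _sample_positive(config.case_duration_dist, rng)
        end = min(cursor + duration, span_end)
        cases.append(CaseRecord(f"c{k + 1:02d}", [Interval(cursor, end)]))
        cursor = end
        k += 1
    return cases


def _make_case(
    config: ScenarioConfig, rng: np.random.Generator, case_no: int, start: int
) -> CaseRecord:
    duration = _sample_positive(config.case_duration_dist, rng)
    split = (
        config.segment_split_prob > 0
        and duration >= 20
        and rng.random() < config.segment_split_prob
    )
    if split:
        # Within-case pause: two touch segments separated by a non-touch
        # interval, e.g. anaesthesia contact, wait, then surgical contact.
        pause = _sample_positive(config.intra_case_pause_dist, rng)
        first = int(rng.integers(10, duration - 9))
        segments = [
            Interval(start, start + first),
            Interval(start + first + pause, start + duration + pause),
        ]
    else:
        segments = [Interval(start, start + duration)]
    return CaseRecord(f"c{case_no:02d}", segments)


def _generate_cases(config: ScenarioConfig, rng: np.random.Generator) -> list[CaseRecord]:
    if config.fixed_unused_minutes is not None:
        return _generate_fixed_unused(config, rng)

    delay = config.start_delay_dist.sample(rng)
    start = max(0, config.sched_start + delay)
    target_touch = config.fill_target * config.allocated
    cases: list[CaseRecord] = []
    touch_booked = 0
    cursor = start
    while touch_booked < target_touch and len(cases) < _MAX_CASES_PER_LIST:
        if cases:
            cursor += max(0, config.turnover_gap_dist.sample(rng))
        case = _make_case(config, rng, len(cases) + 1, cursor)
        if config.overrun_policy == "stop_at_end" and case.span.end > config.sched_end:
            if not cases:
                # The session must do some work: truncate the first case
                # to the scheduled end rather than emit a cancelled list.
                end = config.sched_end
                if end > cursor:
                    cases.append(CaseRecord("c01", [Interval(cursor, end)]))
            break
        cases.append(case)
        touch_booked += case.touch_time
        cursor = case.span.end
    return cases


def generate_cohort(config: ScenarioConfig) -> Cohort:
    """Generate a valid, reproducible cohort from a scenario config.

    Every produced list passes :func:`otmetrics.schedule.validate_list`;
    the same (config, seed) always yields the same cohort. Lists are
    dated on consecutive weekdays starting from ``config.start_date``.
    """
    config.validate()
    lists = []
    date = config.start_date
    for i in range(config.n_lists):
        while date.weekday() >= 5:
            date += datetime.timedelta(days=1)
        rng = _list_rng(config.seed, i)
        cases = _generate_cases(config, rng)
        lists.append(
            TheatreList(
                list_id=f"L{i + 1:04d}",
                unit=config.unit,
                specialty=config.specialty,
                date=date,
                scheduled=Interval(config.sched_start, config.sched_end),
                cases=cases,
            )
        )
        date += datetime.timedelta(days=1)
    return Cohort(lists)


def make_worked_example() -> Cohort:
    """The single-list illustrative cohort: 10 h allocated, 8 h worked.

    One session allocated 600 minutes (8 a.m.–6 p.m.) whose team worked
    a 480-minute span containing 360 touch minutes and 120 minutes of
    intercase downtime (two 60-minute gaps). Raw utilisation is 80 %,
    touch-time utilisation 60 %.
    """
    scheduled = Interval(480, 1080)
    cases = [
        CaseRecord("c01", [Interval(480, 600)]),
        CaseRecord("c02", [Interval(660, 780)]),
        CaseRecord("c03", [Interval(840, 960)]),
    ]
    lst = TheatreList(
        list_id="WE0001",
        unit="TrustA",
        specialty="General Surgery",
        date=datetime.date(2023, 1, 2),
        scheduled=scheduled,
        cases=cases,
    )
    return Cohort([lst])
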