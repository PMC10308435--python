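"""CSV reader/writer for theatre cohorts.

Two files describe a cohort:

``lists.csv``
    ``list_id, unit, specialty, date, sched_start, sched_end``

``cases.csv``
    ``list_id, case_id, segment_index, touch_start, touch_end``

Dates are ISO-8601. Time columns accept either integer minutes since
midnight or ``HH:MM`` clock strings; the dialect is auto-detected per
column. The writer always emits the minutes dialect, so a read/write
round trip on minutes-dialect files is byte-identical.
"""

from __future__ import annotations

import datetime
import re
from os import PathLike
from typing import Union

import pandas as pd

from .schedule import CaseRecord, Cohort, Interval, TheatreList

PathArg = Union[str, PathLike]

_HHMM = re.compile(r"^(\d{1,2}):([0-5]\d)$")

LISTS_COLUMNS = ["list_id", "unit", "specialty", "date", "sched_start", "sched_end"]
CASES_COLUMNS = ["list_id", "case_id", "segment_index", "touch_start", "touch_end"]


def parse_time_column(values: pd.Series) -> pd.Series:
    """Convert one time column to integer minutes, auto-detecting the dialect.

    If every non-null entry matches ``HH:MM`` the column is read as clock
    time; otherwise it must be integer minutes. Mixing dialects within a
    column is rejected to avoid silent misreads.
    """
    as_str = values.astype(str).str.strip()
    hhmm = as_str.map(lambda v: bool(_HHMM.match(v)))
    if hhmm.all():
        def conv(v: str) -> int:
            m = _HHMM.match(v)
            assert m is not None
            return int(m.group(1)) * 60 + int(m.group(2))

        return as_str.map(conv).astype(int)
    if hhmm.any():
        bad = as_str[hhmm].iloc[0]
        raise ValueError(
            f"time column {values.name!r} mixes HH:MM (e.g. {bad!r}) with minute values"
        )
    try:
        return as_str.astype(int)
    except ValueError as exc:
        raise ValueError(
            f"time column {values.name!r} is neither all HH:MM nor all integer minutes"
        ) from exc


def read_cohort(lists_path: PathArg, cases_path: PathArg) -> Cohort:
    """Join ``lists.csv`` and ``cases.csv`` into a :class:`Cohort`.

    Lists keep file order; within a list, cases keep first-appearance
    order and segments are sorted by ``segment_index``. A list with no
    rows in ``cases.csv`` becomes a cancelled list.
    """
    lists_df = pd.read_csv(lists_path, dtype=str)
    missing = [c for c in LISTS_COLUMNS if c not in lists_df.columns]
    if missing:
        raise ValueError(f"lists.csv missing columns: {missing}")
    cases_df = pd.read_csv(cases_path, dtype=str)
    missing = [c for c in CASES_COLUMNS if c not in cases_df.columns]
    if missing:
        raise ValueError(f"cases.csv missing columns: {missing}")

    lists_df = lists_df.copy()
    lists_df["sched_start"] = parse_time_column(lists_df["sched_start"])
    lists_df["sched_end"] = parse_time_column(lists_df["sched_end"])

    if len(cases_df):
        cases_df = cases_df.copy()
        cases_df["touch_start"] = parse_time_column(cases_df["touch_start"])
        cases_df["touch_end"] = parse_time_column(cases_df["touch_end"])
        cases_df["segment_index"] = cases_df["segment_index"].astype(int)

    cases_by_list: dict[str, dict[str, list[tuple[int, Interval]]]] = {}
    for row in cases_df.itertuples(index=False):
        per_list = cases_by_list.setdefault(row.list_id, {})
        per_list.setdefault(row.case_id, []).append(
            (row.segment_index, Interval(int(row.touch_start), int(row.touch_end)))
        )

    lists = []
    for row in lists_df.itertuples(index=False):
        case_map = cases_by_list.get(row.list_id, {})
        cases = [
            CaseRecord(case_id, [iv for _, iv in sorted(segs, key=lambda t: t[0])])
            for case_id, segs in case_map.items()
        ]
        cases.sort(key=lambda c: c.segments[0].start if c.segments else 0)
        lists.append(
            TheatreList(
                list_id=row.list_id,
                unit=row.unit,
                specialty=row.specialty,
                date=datetime.date.fromisoformat(row.date),
                scheduled=Interval(int(row.sched_start), int(row.sched_end)),
                cases=cases,
            )
        )
    return Cohort(lists)


def write_cohort(cohort: Cohort, lists_path: PathArg, cases_path: PathArg) -> None:
    """Write a cohort to the two-file schema in the minutes dialect.

    Output is deterministic for a given cohort: fixed column order,
    ``\\n`` line endings, no index — which is what makes simulated
    cohorts byte-reproducible from a seed.
    """
    list_rows = [
        {
            "list_id": lst.list_id,
            "unit": lst.unit,
            "specialty": lst.specialty,
            "date": lst.date.isoformat(),
            "sched_start": lst.scheduled.start,
            "sched_end": lst.scheduled.end,
        }
        for lst in cohort
    ]
    case_rows = [
        {
            "list_id": lst.list_id,
            "case_id": case.case_id,
            "segment_index": i,
            "touch_start": seg.start,
            "touch_end": seg.end,
        }
        for lst in cohort
        for case in lst.cases
        for i, seg in enumerate(case.segments)
    ]
    pd.DataFrame(list_rows, columns=LISTS_COLUMNS).to_csv(
        lists_path, index=False, lineterminator="\n"
    )
    pd.DataFrame(case_rows, columns=CASES_COLUMNS).to_csv(
        cases_path, index=False, lineterminator="\n"
    )
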