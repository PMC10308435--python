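# otmetrics

Operating-theatre performance metrics, computed **both ways** from one
dataset: the way the NHS Model Hospital dashboard computes them, and the
mathematically conventional alternatives — so that anyone building,
auditing, or consuming a theatre dashboard can see exactly where and by
how much the two regimes diverge.

Who it is for: health-services researchers, theatre managers, and
anaesthetic departments developing local "fine-filter" dashboards who
need to reconcile their numbers with national "coarse-filter"
benchmarks.

## The metrics

For a theatre list with scheduled window `[S, F)` (allocated minutes
`A = F − S`), worked span `[s, f)` (first patient contact to last), and
total *touch time* `T` (minutes delivering anaesthesia and surgery):

| metric | definition |
|---|---|
| start / finish delta | `s − S`, `f − F` (signed; positive = late) |
| raw utilisation | `(f − s) / A` — may exceed 1 on overruns |
| touch-time utilisation | `T / A` |
| capped touch utilisation | `T′ / A`, touch clipped to the scheduled window; ≤ 1 |
| intercase downtime | gaps between cases (`gap_sum`) or span − touch (`span_minus_touch`) |

Two aggregation regimes across a cohort of lists:

- **pooled (dashboard style)** — `Σ usedᵢ / Σ allocatedᵢ`: one scalar, no
  variance; equivalently the allocation-weighted mean of per-list values;
- **distributional (conventional)** — per-list decimals summarised as
  median (inter-quartile range; range).

Timing is reported the dashboard way as *conditional means* — the
"average late start" is averaged only over lists that started late,
category sizes unreported — and conventionally as all-list medians with
IQR and range. **Potential gains** divides pooled unused minutes by a
mean case duration; its *feasible* counterpart applies the division
per list, which is what scattered spare minutes actually permit:

```
pooled_extra_cases   = ⌊Σᵢ max(0, Aᵢ − usedᵢ) / d⌋
feasible_extra_cases = Σᵢ ⌊max(0, Aᵢ − usedᵢ) / d⌋
```

A seeded synthetic generator produces cohorts with configurable start
delays, case durations (normal / log-normal / Weibull), turnover gaps,
and overrun behaviour, so every divergence is reproducible without any
real Trust data. See `docs/methods.md` for the full model and the design
decisions.

## Worked example

```python
from otmetrics import (make_worked_example, raw_utilisation,
                       touch_time_utilisation, intercase_downtime,
                       generate_cohort, preset, potential_gains)

we = make_worked_example().lists[0]   # 10 h allocated, 8 h worked, 2 h downtime
print(f"raw utilisation:        {raw_utilisation(we):.2f}")
print(f"touch-time utilisation: {touch_time_utilisation(we):.2f}")
print(f"intercase downtime:     {intercase_downtime(we, 'gap_sum')} min")

frag = generate_cohort(preset("fragmented_gaps", n_lists=100, seed=1))
g = potential_gains(frag, mean_case_duration=60, mode="touch")
print(f"pooled unused minutes:  {g.unused_minutes}")
print(f"pooled extra cases:     {g.pooled_extra_cases}")
print(f"feasible extra cases:   {g.feasible_extra_cases}")
```

prints

```
raw utilisation:        0.80
touch-time utilisation: 0.60
intercase downtime:     120 min
pooled unused minutes:  500
pooled extra cases:     8
feasible extra cases:   0
```

The first block is the classic textbook session: a team allocated 600
minutes works a 480-minute span (80 % raw), of which 120 minutes are
intercase gaps, leaving 360 minutes of patient contact (60 %
touch-time). The second block is the fragmentation fallacy made
concrete: 100 lists each leaving exactly 5 unused minutes "pool" to 500
minutes and a claimed 8 extra 60-minute cases — yet no list can host
even one, so the feasible count is 0.

## Command line

```bash
otmetrics simulate --preset overrun --n-lists 100 --seed 42 --out-prefix cohort
otmetrics timing      cohort_lists.csv cohort_cases.csv --regime both
otmetrics utilisation cohort_lists.csv cohort_cases.csv --mode capped --aggregate both
otmetrics gains       cohort_lists.csv cohort_cases.csv --case-duration 60 --mode capped
otmetrics report      cohort_lists.csv cohort_cases.csv            # dual dashboard JSON
otmetrics report      cohort_lists.csv cohort_cases.csv --divergence
otmetrics caterpillar cohort_lists.csv cohort_cases.csv --metric pooled_capped
```

Input CSVs follow a two-file schema (`lists.csv`:
`list_id,unit,specialty,date,sched_start,sched_end`; `cases.csv`:
`list_id,case_id,segment_index,touch_start,touch_end`), with times as
integer minutes or `HH:MM`, auto-detected per column. All output JSON
carries the numerator/denominator minutes and every regime decision
(grace, cap side, quartile convention), so each number is auditable.

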