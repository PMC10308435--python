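# Methods

## The problem

NHS operating-theatre performance is benchmarked nationally through a
dashboard whose headline KPIs — average late start, average early
finish, average late finish, capped touch-time utilisation, pooled
utilisation, and "potential gains" in extra cases — are computed in ways
that diverge from conventional statistical practice. `otmetrics`
implements both regimes over one common theatre-list data model so the
divergences can be measured, not just argued about. It is a tool for
health-services researchers and theatre managers building or auditing
local dashboards.

## Data model

A **theatre list** is one scheduled session: an allocated window
`[sched_start, sched_end)` plus an ordered set of cases. A **case** is
an ordered set of **touch segments** — intervals of direct patient
contact (anaesthesia and surgery). All times are integer minutes since
midnight of the session day; values ≥ 1440 represent spill past
midnight, which keeps overrun arithmetic on one number line. Intervals
are half-open, so abutting segments create a zero-length gap, never a
negative one.

Zero-case (cancelled) lists are valid data. They are excluded from
timing statistics (a list that never started has no start delta — the
operations raise `CancelledListError`) but included in utilisation with
value 0 (an empty allocated session is used capacity of zero).

"Start time" is taken as the first touch-segment start — effectively
anaesthesia start. No national standard pins down whether start means
anaesthesia start, patient-in-theatre, or knife-to-skin; the choice is
recorded here and a `grace` parameter (below) absorbs small definitional
offsets.

Validation (`validate_list`) reports violations rather than raising, so
malformed CSV input can be diagnosed in full rather than failing on the
first bad row.

## Timing metrics

For a non-cancelled list with worked span `[s, f)` and scheduled window
`[S, F)`:

    start_delta  = s − S   (positive ⇒ late start)
    finish_delta = f − F   (positive ⇒ late finish)

**Dashboard regime** (`mh_timing_panel`): arithmetic means computed
*within category only* — mean of `start_delta` over lists with
`start_delta > grace`, mean of `|finish_delta|` over lists with
`finish_delta < −grace`, mean of `finish_delta` over lists with
`finish_delta > grace`. The panel also reports each category's `n`,
which the dashboard it models leaves unreported. Because the average
conditions on being in the category, it is structurally a conditional
mean: it always dominates the unconditional truncated mean, is invariant
to anything the punctual lists do, and can *rise* when punctuality
improves (remove a +10 from {+10, +50} and the "average late start"
climbs from 30 to 50). Both an average early finish and an average late
finish are reported simultaneously whenever both categories are
non-empty; that is a structural feature of conditioning, not a
contradiction.

**Conventional regime** (`conventional_timing_summary`): the signed
deltas of *all* non-cancelled lists summarised as median
(inter-quartile range; range) with `n`. Quartiles use linear
interpolation between closest order statistics (numpy `method="linear"`);
the convention is echoed in output metadata so another implementation
can match bit-exact.

`grace` (default 0 min) sets how much slack a start or finish gets
before it counts as late/early; lateness is strict (`delta > grace`), so
an exactly-on-time list falls in no category.

## Utilisation metrics

Per list with allocated minutes `A`:

- **raw** = span duration / `A`. Can exceed 1 when the list overruns.
- **touch** = Σ touch-segment minutes / `A`. Always ≤ raw when the list
  has cases, since segments lie within the span.
- **capped touch** = Σ clipped touch-segment minutes / `A`, where each
  segment is intersected with the capping window first. Never exceeds 1.

The capping window defaults to the full scheduled interval
(`cap_side="both"`): touch before the scheduled start and after the
scheduled end are both discarded. `cap_side="end"` discards only
overruns past the scheduled end, for dashboards that penalise late
finishes but not early starts. Which side the modelled dashboard
actually caps is not public; exposing both makes the choice auditable.

**Intercase downtime** comes in two reconstructions (the emulated
dashboard's exact pair of definitions is not published):

- `gap_sum` — Σ positive gaps between consecutive cases' spans.
- `span_minus_touch` — span duration − total touch, which additionally
  counts pauses *within* cases.

They coincide when every case is one contiguous segment; otherwise
`gap_sum ≤ span_minus_touch`. Multi-segment cases exist in the data
model precisely so this difference is testable.

## Aggregation regimes

**Pooled** (`pooled_utilisation`): Σ used minutes / Σ allocated minutes
across the cohort. Algebraically the allocation-weighted mean of
per-list utilisations. The result type carries its numerator and
denominator for audit but — deliberately — no variance fields: pooling
minutes into one ratio destroys the between-list variation a variance
would describe. `pooled_relative_reduction` exposes the same arithmetic
for any pair of pooled totals (e.g. summed pre- vs post-treatment
measurements), making the "25 % efficacy with no standard deviation"
analogy executable.

**Distributional** (`distribution_utilisation`): per-list fractions as
decimals, summarised as median (IQR; range). The two regimes agree
exactly only when every list shares one utilisation value; generically
they differ, and on cohorts mixing long and short lists they can order
two units oppositely (`divergence_report` flags such ranking reversals).

## Potential gains

Given a mean case duration `d` (minutes):

    per-list unused u_i = max(0, A_i − used_i)      (uncapped modes)
                    u_i = A_i − capped_used_i       (capped mode; ≥ 0 already)
    pooled_extra_cases   = ⌊(Σ u_i) / d⌋
    feasible_extra_cases = Σ ⌊u_i / d⌋

Floor division because a partial case cannot be done. The pooled figure
treats minutes scattered across disparate lists as if they were one
contiguous block — 5 spare minutes on each of 100 lists "pools" to 500
minutes and 8 claimed cases, while the feasible count is 0 because no
single list can host a 60-minute case. `pooled ≥ feasible` always, and
capped-mode gains always dominate touch-mode gains (capping can only
shrink used minutes). In uncapped modes an overrunning list contributes
zero unused rather than negative: potential gain is a capacity concept,
and letting overruns net off other lists' idle time would hide exactly
the fallacy being measured. `strict_box1=True` restores signed netting
for fidelity studies; the `pooled ≥ feasible` guarantee is stated only
for the default.

## Synthetic cohorts

`generate_cohort(ScenarioConfig)` emulates elective cohorts: per list it
samples a start delay, then schedules cases — durations from a normal,
log-normal, or Weibull distribution; turnover gaps between cases;
optional within-case pauses (probability `segment_split_prob`) — until
the booked touch time reaches `fill_target × allocated`, stopping early
(`stop_at_end`) or running past the scheduled end (`complete_all`).
Samples are rounded to whole minutes to match the data model; negative
normal delays give early starts, and the log-normal option takes an
additive shift for a configurable earliest start. Each list gets its own
random stream derived from `(seed, list index)` via
`numpy.random.SeedSequence`, so cohorts are byte-reproducible even under
parallel generation.

Preset parameters are editorial choices of this package (no published
parameters exist for the narrative scenarios they operationalise):

- `punctual` — zero start delay, `stop_at_end`, 85 % fill: every list
  starts on time and never overruns.
- `chronic_late_start` — normal delay 30 ± 10 min; 15 % of cases split
  into two segments so the downtime methods differ.
- `overrun` — Weibull(k = 1.6, λ = 90, +15) case durations, booking to
  100 % of the allocation with `complete_all`: turnover on top of a full
  book makes late finishes routine and pushes touch utilisation past
  100 % on many lists.
- `fragmented_gaps` — deterministic construction: cases laid end to end
  from the scheduled start, the last truncated so exactly 5 allocated
  minutes remain unused on every list; touch equals span, so the unused
  figure is identical under raw, touch, and capped accounting.

Case-duration defaults (log-normal μ = 4.2, σ = 0.45, i.e. mean ≈ 74 min)
sit in the range typical of general-surgical elective lists; turnover
gaps of 15 ± 5 min reflect routine cleaning/send-for times.

What the generator does *not* emulate: case-mix correlation between
duration and order, cancellations mid-list, multi-theatre parallel
(high-intensity) lists, staffing effects, or day-of-week structure.
Passing tests therefore demonstrate the *arithmetic* properties of the
metrics on structurally realistic schedules, not calibration to any real
Trust's data — the one real-data comparison in the source material is
unpublished, so it is reproduced qualitatively (orderings and
divergences), never numerically.

## Reporting

`build_report` computes both panels from one identical cohort: the
dashboard panel (conditional-mean timing, pooled capped and pooled touch
utilisation, pooled potential gains at the configured mean case
duration) and the conventional panel (all-list timing summaries, median
touch and median raw utilisation, feasible extra cases). Metadata
records every regime decision — grace, cap side, quartile convention,
rounding rule — because undisclosed calculation choices are the failure
mode this tool exists to surface. Reports are pure functions of
(cohort, options); the canonical JSON is key-sorted and bit-identical
across runs. `caterpillar_order` ranks units best-to-worst with
deterministic alphabetical tie-breaks. Plots are optional artifacts
behind a CLI flag; all numbers live in the JSON/CSV output.

## Numerical choices and edge cases

- All primitive quantities are integer minutes; fractions are formed
  only at reporting, so worked examples are exact.
- Quartiles: linear interpolation (see above). Medians of integer data
  can therefore be half-integers.
- Ties: a list exactly on time is in no late/early category; caterpillar
  ties break by unit name.
- Degenerate inputs: zero allocated duration raises
  `InvalidSessionError`; empty cohorts raise `EmptyCohortError`
  (CLI exit code 3); structural violations are reported by
  `validate_list` (CLI exit code 2).
- Problem sizes used in the shipped checks: cohorts of tens to a few
  hundred lists, and a sweep of 1 000 three-list cohorts with varied
  distributions and overrun policies for the invariant suite — ample to
  exercise every code path while keeping the whole suite near-instant.

## Known limitations

- The two downtime definitions and the capping side are reconstructions
  of an unpublished specification; both options are exposed rather than
  one guessed.
- Whether the emulated dashboard computes potential gains from capped or
  uncapped unused time is implied but unstated; both modes are exposed
  and the capped-dominates-uncapped ordering is verified instead.
- No modelling of parallel-theatre lists, staggered starts, or
  case-level covariates; scheduled windows must be supplied, never
  inferred.
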