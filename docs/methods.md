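# Methods

## Scope and model

`burnoutkit` implements the scoring core of a burnout self-screening
workflow: two fixed-form instruments, a deterministic combination rule,
longitudinal bookkeeping, and a usability-survey scorer. Everything is
rule-based — there is no fitted model — so correctness means faithfully
reproducing the printed coding tables, cut-offs and decision tables, and
the engineering questions are about boundary conventions, degenerate
inputs and reproducibility.

### GHQ-12

Each of the 12 items has four ordered options, most positive first; the
exact option wording varies per question (six distinct label sets,
grouped into four variant families in the item bank). Bimodal scoring
codes the first two options 0 and the last two 1 — this 0/0/1/1 pattern
holds uniformly across all items, and the test suite asserts it cell by
cell. The Likert 0-1-2-3 scoring used elsewhere in the GHQ literature is
deliberately not implemented.

Parameters: `threshold` (points, default 3) controls the `distress`
flag. Three is a sensitive screening choice — one point below the
conventional "possible distress" cut-off — so the result object always
carries `standard_band` (none / possible_distress at ≥4 /
stress_disorders at ≥8) and the conventional reading is never lost.

### CBI

Nineteen items in three subscales (personal 6, work 7, client 6), five
options each, points 100/75/50/25/0 from most to least intense. Two
printed label packs ("Always…", "To a very high degree…") are treated as
synonymous label sets for the same five ordinal codes; records may use
either. The single positively worded item (work, "enough energy for
family and friends") is reverse-scored: its points are 100 − the forward
value, an identity the tests check for all five codes.

A subscale score is the plain item mean; no prorating of incomplete
responses is done — validation rejects them, because neither instrument
defines a missing-data rule and both are short. Levels use
`[0,50) / [50,75) / [75,100]`. The printed moderate band ends at "74",
but for 6-item subscales no attainable mean lies strictly between 74 and
75 (means are multiples of 25/6; the suite verifies this exhaustively),
and for 7-item subscales the convention `[50,75)` treats the label as
inclusive shorthand; 75 itself is high, matching the printed "75-100"
high band.

Overall risk is a total, monotone function of the three levels:
high ⇔ ≥2 high; else moderate ⇔ exactly 1 high or ≥2 moderate; else
low. The printed case list has a garbled row (it names four dimensions);
it is read as the two three-dimension cases MML and MMH, both moderate —
the minimal consistent reading. The two combinations the source never
enumerates (LLH, LMH) resolve to moderate under the same rule:
conservatively, one high subscale never yields an all-clear. The suite
checks all 27 combinations and all single-level upgrades.

### Diagnosis

The category is a total function of `(distress, overall_risk)`:
moderate risk dominates (category *moderate* regardless of the GHQ),
then *critical* (distress + high), *great* (no distress + low), and the
remaining two cells — distress+low and no-distress+high — are
*contradictory*, which is defined as the complement of the three
positive rules and prompts a retest. Whether "distress" here should mean
the sensitive threshold-3 flag or the conventional ≥4 band is an open
interpretive point; the engine uses the result's `distress` flag, so the
choice follows whatever threshold scored the GHQ (default 3).

### Monitoring

Histories are immutable, timestamp-sorted sequences of test records;
duplicate timestamps are rejected (UTC ISO-8601 timestamps make ordering
unambiguous). The chart series reports the last *n* (default 4)
sittings' overall risk *and* category, so either can be plotted. Deltas
compare the last two sittings per dimension; "improved" means a lower
score, since all subscales are symptom-positive. The status message
gives *alert* on distress, *congratulations* on an all-zero CBI without
distress; alert strictly dominates when both conditions hold, because
distress marks a critical state. Retest dates use calendar-month
addition with end-of-month clamping (Nov 30 + 3 months → Feb 28/29):
"every 3 months" is a calendar statement, not 90 days.

### SUS

Per-respondent score: `2.5·[Σ_odd(xᵢ−1) + Σ_even(5−xᵢ)]` on 1–5 answers,
range 0–100. Cohorts reported only as per-item answer counts are scored
exactly through linearity of the mean rather than by reconstructing
individuals — the counts determine the mean score even though they do
not determine the cohort. The bundled 40-user field survey scores
exactly 95.625; the survey's original report rounds/states 95.8, a
0.175-point gap the package documents rather than reproduces (the test
accepts the reported figure within 0.5% relative). Interpretation bands
overlap as printed at 68 and 80.3; they are disambiguated as
(80.3, 100] excellent, (68, 80.3] good, exactly 68 okay, [51, 68) poor,
[0, 51) awful — the minimal-change reading that keeps the printed
singleton "68 = okay".

## Simulator

The generator emulates questionnaire sittings, not epidemiology: it
draws plausible answer patterns at controllable severity and makes no
attempt to match real burnout prevalence, item correlations, or
response styles (acquiescence, straight-lining). Passing tests therefore
demonstrate that the scoring rules behave correctly across the response
space, not that the instruments are valid on real populations.

* **GHQ**: each item independently falls in the 1-coded option pair with
  probability `ghq_negativity` (uniform within the pair), so the total
  is Binomial(12, negativity) — mean 6.0 at 0.5, which the acceptance
  suite verifies over 2,000 seeded draws.
* **CBI**: at `cbi_noise=0` the generator realizes, per dimension, the
  attainable mean (a multiple of 25/n) closest to `cbi_target`, nudged
  one 25-point option step if plain rounding would cross a level
  boundary. Rounding every item to the single nearest option would
  break level recovery for targets such as 70 (nearest option 75 flips
  moderate to high); realizing the nearest attainable *mean* keeps the
  classified level equal to `classify_level(target)` for every target
  off the 50/75 boundaries, which is the property the tests pin down.
  The reverse item is handled in coded space. Noise displaces each
  item's option one step up or down with probability `cbi_noise/2`
  each, clamped at the scale ends.
* **SUS**: optimal answer with probability `sus_positivity`, else
  uniform over 1–5.

All draws derive from one integer seed (numpy `default_rng`; history
generation spawns per-record seeds below 2³¹), so fixtures are
bit-reproducible, and every emitted record passes response validation.

## Numerical and design choices

* Option codes, not labels, are the scoring currency; label→code
  resolution accepts both CBI packs and is the only string-sensitive
  step.
* Dimension means are exact small rationals in floating point
  (multiples of 25/6, 25/7); comparisons against cut-offs are exact, no
  tolerance is needed.
* Validation collects all violations in one pass and distinguishes
  *incomplete* from *malformed*, so batch ingestion surfaces every
  problem at once.
* Presentation order is a seeded shuffle; for the CBI it rejects orders
  with runs of more than three same-dimension items (always feasible at
  6/7/6) to discourage stereotypical answering.
* Problem sizes in the statistical tests — 1,000-response recounts,
  2,000 GHQ draws, 500 aggregation cohorts, exhaustive 27-combination
  and 5⁶ enumerations — were chosen as comfortable desk-scale checks
  that keep the whole suite in a few seconds.

## Limitations

* English item wording only; the item ids (`ghq.q01`, `cbi.wrk.q7`, …)
  are the stable keys, so translations are a front-end concern.
* No population norms, reliability statistics, percentile scales, or
  alternative instrument versions (GHQ-28/30/60, MBI, OBI).
* The lifestyle sign-up questionnaire is a stored data type only; no
  scoring rules exist for it.
* The screening categories are decision-table outputs, not calibrated
  risk probabilities.
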