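# burnoutkit

A screening engine for occupational burnout and psychological distress,
built for researchers and app developers who need reproducible,
rule-based scoring of two free, widely used self-report instruments:

- **GHQ-12** (General Health Questionnaire, 12 items) — screens for
  psychological distress. Each item offers four ordered options; under
  **bimodal scoring** the first two options code 0 and the last two code
  1, so the total `G = Σ gᵢ ∈ [0, 12]`. A configurable threshold flags
  distress (default `G ≥ 3`, a deliberately sensitive cut-off); the
  conventional bands (`G ≥ 4` possible distress, `G ≥ 8` stress-related
  disorders) are always reported alongside.
- **CBI** (Copenhagen Burnout Inventory, 19 items) — three subscales:
  personal (6 items), work-related (7), client-related (6). Answers map
  to points `{100, 75, 50, 25, 0}` (one positively worded work item is
  reverse-scored), each subscale score is the item mean on 0–100, and is
  levelled **low** (<50), **moderate** (50–<75) or **high** (≥75). The
  three levels combine into an overall risk: *high* with ≥2 high
  subscales; *moderate* with exactly 1 high or ≥2 moderate; *low*
  otherwise.

The two results combine into a four-outcome screening category —
**critical** (distress + high risk), **moderate** (moderate risk,
regardless of the GHQ), **great** (no distress + low risk) or
**contradictory** (the instruments disagree; retest recommended). None
of this is a medical diagnosis; it is a self-screening aid.

The package also provides longitudinal monitoring (recent-diagnosis
chart series, per-dimension deltas, alert/congratulations messaging,
3-month retest scheduling), **System Usability Scale** scoring
(per-respondent and exactly from aggregated count tables via linearity
of the mean), and a seeded synthetic-respondent simulator so every
pipeline stage is testable without collecting data.

## Worked example

`examples/score_one_respondent.py` scores a single sitting built from
answer labels:

```text
GHQ-12 bimodal total : 3/12 (distress at threshold 3: True; conventional band: none)
CBI personal :  50.00/100 -> moderate
CBI work     :  75.00/100 -> high
CBI client   :  25.00/100 -> low
CBI overall risk     : moderate
Screening category   : moderate (moderate burnout risk on the CBI, independently of the GHQ result)
```

Three symptomatic GHQ answers trip the sensitive distress threshold;
the CBI subscale means 50/75/25 level moderate/high/low, which combine
to moderate overall risk, and a moderate CBI risk fixes the category
regardless of the GHQ flag. The other example scripts cover monitoring
(`track_progress.py`), usability surveys (`usability_survey.py`, which
prints the bundled 40-user survey's exact mean of **95.625**,
"excellent") and cohort simulation (`simulate_cohort.py`).

A thin CLI mirrors the library:

```bash
burnoutkit simulate --out sim --n 10 --seed 7
burnoutkit score-ghq --in sim/ghq_responses.json
burnoutkit diagnose --ghq sim/ghq_responses.json --cbi sim/cbi_responses.json --out record.json
burnoutkit history add --history hist.json --record record.json
burnoutkit sus aggregate
```

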