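"""Score a System Usability Scale survey, per respondent and from counts.

Shows the two scoring routes: individual 10-answer responses, and the
exact cohort mean computed directly from an aggregated per-item count
table (here the bundled 40-user field survey of the screening app).
"""

from burnoutkit import (
    SusResponse,
    interpret_sus,
    load_builtin_survey_counts,
    mean_sus_from_counts,
    score_sus,
)

# Route 1: one respondent's raw answers (items alternate positive/negative).
response = SusResponse((5, 1, 4, 2, 5, 1, 5, 1, 4, 1))
score = score_sus(response)
print(f"single respondent : {score:.1f}/100 -> {interpret_sus(score).value}")

# Route 2: the bundled field survey, aggregated as per-item answer counts.
table = load_builtin_survey_counts()
mean = mean_sus_from_counts(table)
print(f"cohort of n={table.n}   : {mean:.3f}/100 -> {interpret_sus(mean).value}")
# The count-table mean is exact by linearity: it equals the average of the
# per-respondent scores for any cohort consistent with the counts.  Scores
# above 80.3 rate "excellent" on the conventional interpretation bands.
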