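"""Score one respondent's GHQ-12 and CBI sitting and diagnose it.

Builds the two questionnaire responses by answer label (exactly what a
form front-end would collect), scores both instruments, and combines
them into the four-outcome screening category.
"""

from datetime import datetime, timezone

from burnoutkit import ResponseRecord, load_builtin_instruments, make_record

banks = load_builtin_instruments()
now = datetime(2022, 9, 6, 10, 30, tzinfo=timezone.utc)

# A respondent with frequent sleep loss and strain on the GHQ...
ghq_labels = {
    "ghq.q01": "As usual",
    "ghq.q02": "Much more than usual",   # lost sleep
    "ghq.q03": "As usual",
    "ghq.q04": "As usual",
    "ghq.q05": "A little more than usual",  # under strain
    "ghq.q06": "A little more than usual",
    "ghq.q07": "As usual",
    "ghq.q08": "As usual",
    "ghq.q09": "No more than usual",
    "ghq.q10": "Not at all",
    "ghq.q11": "Not at all",
    "ghq.q12": "Approximately the same as usual",
}
# ...and heavy work-related burnout on the CBI, but little client strain.
cbi_labels = {}
for item in banks["CBI"].items:
    if item.id.startswith("cbi.wrk"):
        cbi_labels[item.id] = "Seldom" if item.reverse else "Often"
    elif item.id.startswith("cbi.per"):
        cbi_labels[item.id] = "Sometimes"
    else:
        cbi_labels[item.id] = "Seldom"

to_codes = lambda inst, labels: {
    item_id: banks[inst].item(item_id).code_for_label(lab) for item_id, lab in labels.items()
}
ghq_response = ResponseRecord("GHQ12", "maria", now, to_codes("GHQ12", ghq_labels))
cbi_response = ResponseRecord("CBI", "maria", now, to_codes("CBI", cbi_labels))

record = make_record(ghq_response, cbi_response, now=now)

print(f"GHQ-12 bimodal total : {record.ghq.score}/12 "
      f"(distress at threshold {record.ghq.threshold}: {record.ghq.distress}; "
      f"conventional band: {record.ghq.standard_band.value})")
for ds in record.cbi.dimension_scores:
    print(f"CBI {ds.dimension.value:<8} : {ds.score:6.2f}/100 -> {ds.level.value}")
print(f"CBI overall risk     : {record.cbi.overall_risk.value}")
print(f"Screening category   : {record.diagnosis.category.value} "
      f"({record.diagnosis.rationale})")
# The GHQ total counts symptomatic answers (3 here trips the sensitive
# threshold); CBI subscale means of 75/50/25 give one high, one moderate
# and one low level, which combine to moderate overall risk, so the
# category is "moderate" regardless of the GHQ flag.
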