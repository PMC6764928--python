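"""Summarize the packaged 25-patient study table.

Loads the transcription of the published per-patient table (diagnosis, tumor
location, the three personally selected tests, pre-surgical impairment on them,
and progression status) and prints counts with percentages.  The totals — 25
patients, 15 with progressive disease, 21 glioblastoma, 10 left-hemisphere
tumors, 6 occipital tumors — are the cohort margins the analysis operates on.
"""

from cogsurv import load_study_fixture, summarize_cohort

fixture = load_study_fixture()
summary = summarize_cohort(fixture)
print(summary.to_string(index=False, formatters={"percent": "{:.0f}%".format}))
print(f"\n{len(fixture)} patients; "
      f"{fixture['pd_during_followup'].sum()} progressed during follow-up.")
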