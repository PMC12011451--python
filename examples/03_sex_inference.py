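"""Infer sex from Y-marker read ratios and score against field records.

A male devotes ~0.5% / 0.3% of on-target reads to the ddx3Y / usp9Y
amplicons; a female, only contamination-level counts.  The observed vs
expected ratio per marker gives M (> 0.2), F (< 0.1) or unassigned, and
both markers must agree for a consensus.
"""

from gtpanel import sexing, synth

tallies, field_sex = synth.make_paper_fixtures()["sexing"]
calls = sexing.call_from_tallies(tallies)
conc = sexing.evaluate_concordance(calls, field_sex)

print(f"samples evaluated: {conc['n_total']}")
print(f"unassigned: {conc['n_unassigned']} "
      f"({conc['n_conflict']} marker conflicts, {conc['n_not_genotyped']} not genotyped)")
print(f"accuracy among assigned: {conc['n_match']}/{conc['n_assigned']} "
      f"= {100 * conc['accuracy_assigned']:.1f}%")
print(f"accuracy overall: {100 * conc['accuracy_overall']:.0f}%")
# Unassigned samples abstain rather than err: accuracy among assigned is the
# headline number, overall accuracy charges abstentions as misses.
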