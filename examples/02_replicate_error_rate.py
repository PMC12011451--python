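"""Estimate the genotyping error rate from replicate samples.

Uses the canned replicate fixture whose comparison counts match the
published panel validation: 69 mismatches across 17,578 pairwise genotype
comparisons (0.39%), broken down by sample type.
"""

from gtpanel import genotyper, synth

calls, groups = synth.make_paper_fixtures()["replicates"]
res = genotyper.estimate_error_rate(calls, groups)

print(f"overall: {res.mismatches}/{res.comparisons} = {100 * res.rate:.2f}%")
for stype, (rate, m, c) in res.per_type.items():
    print(f"  {stype:7s}: {m}/{c} = {100 * rate:.2f}%")
# The error rate is mismatching genotypes over genotypes compared between
# replicates; scat (noninvasive) runs ~7x the blood/tissue rate.
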