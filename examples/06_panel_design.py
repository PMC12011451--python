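"""Select panel candidates from a dense SNP catalog.

Simulates a three-population SNP catalog, applies the quality-filter
cascade (MAF, missingness, Hardy-Weinberg, LD pruning), ranks loci by Nei
FST per population comparison, and finds microhaplotype windows and
spaced diversity markers.
"""

import numpy as np

from gtpanel import panel_design

rng = np.random.default_rng(5)
n_loci, n_per_pop = 300, 60

snps, rows = [], []
pos = 0
for i in range(n_loci):
    # every third SNP sits 30-80 bp after the previous one, forming the
    # tight clusters that can be phased into microhaplotypes
    if i % 3 == 2:
        pos += int(rng.integers(30, 80))
    else:
        pos += int(rng.integers(2000, 120_000))
    p = {f"pop{k}": float(np.clip(rng.beta(2, 2), 0.02, 0.98)) for k in range(3)}
    geno = np.concatenate(
        [rng.binomial(2, p[f"pop{k}"], size=n_per_pop) for k in range(3)]
    )
    alt = geno.mean() / 2
    snps.append(panel_design.CandidateSnp(
        "chr1", pos, "A", "G", min(alt, 1 - alt), 0.0, per_pop_freq=p
    ))
    rows.append(geno)
geno = np.vstack(rows)

kept = panel_design.filter_candidates(snps, geno)
print(f"{len(kept)}/{n_loci} SNPs pass MAF/missingness/HWE/LD filters")

records = [
    panel_design.FstRecord(s.locus_id, "all_pops", panel_design.per_locus_fst(s.per_pop_freq))
    for s in kept
]
top, _ = panel_design.rank_and_select_fst(records, top_n=10)
print(f"top 10 FST-ranked loci: {top[:3]} ...")

windows = panel_design.discover_microhap_windows(sorted(kept, key=lambda s: (s.chrom, s.pos)))
spaced = panel_design.select_diversity_markers(kept)
print(f"microhaplotype windows: {len(windows)}; spaced diversity markers: {len(spaced)}")
# FST-ranked loci separate populations; microhap windows pack several SNPs
# into one amplicon; diversity markers cover the genome at >=250 kb spacing.
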