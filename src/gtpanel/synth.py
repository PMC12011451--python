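"""Synthetic data with known ground truth for the whole pipeline.

Everything the other modules consume can be generated here: population
allele frequencies at a target F\\ :sub:`ST` (Balding-Nichols), cohorts
with parent-offspring and full-sibling pairs, amplicon reads with
sequencing error and negative-binomial depth dispersion, contaminated
negative PCR controls, replicate samples with a configurable genotype
discordance rate, Y-marker read tallies for both sexes, and
concentration -> genotyping-success screening data.  All randomness flows
from a single seed, so two runs with the same config are identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotyper import GenotypeCall, PanelDefinition, PanelLocus, ReplicateGroup, PASS, MISSING, LOW_DEPTH
from .power import LocusFrequencies

BASES = "ACGT"


@dataclass
class SimConfig:
    """Knobs for the generator; defaults mirror the study conditions."""

    seed: int
    n_loci: int = 50
    n_snps_per_locus: int = 2
    alleles_per_locus: int = 3
    n_populations: int = 3
    theta: float = 0.1               # target FST under Balding-Nichols
    amplicon_length: int = 120
    probe_length: int = 20
    depth_mean: float = 100.0
    depth_dispersion: float = 5.0    # NB shape; larger = closer to Poisson
    per_base_error: float = 0.005
    on_target_fraction: float = 0.85
    contamination_rate: float = 0.001  # fraction of expected depth leaking into negatives
    replicate_discordance: float = 0.0039
    sex_fractions: dict = field(default_factory=lambda: {"ddx3Y": 0.005, "usp9Y": 0.003})
    female_sex_fraction: float = 0.0002  # stray Y reads in females
    logistic_params: tuple[float, float] = (-2.0, 6.0)  # success ~ concentration
    base_quality: int = 37

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 1.0):
            raise ValueError("theta must be in (0, 1)")
        for name in ("per_base_error", "contamination_rate", "replicate_discordance",
                     "on_target_fraction", "female_sex_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic data."""

    genotypes: dict[str, dict[str, tuple[str, str]]]  # sample -> locus -> allele pair
    sex: dict[str, str]                               # sample -> M|F
    relationships: list[tuple[str, str, str]]         # (a, b, PO|FS)
    replicate_groups: list[ReplicateGroup]
    allele_freqs: dict[str, list[LocusFrequencies]]   # population -> loci
    population_of: dict[str, str]


def _random_alleles(rng: np.random.Generator, n_snps: int, k: int) -> list[str]:
    """k distinct haplotype strings of length n_snps."""
    all_haps = ["".join(t) for t in itertools.product(BASES, repeat=n_snps)]
    idx = rng.choice(len(all_haps), size=k, replace=False)
    return sorted(all_haps[i] for i in idx)


def simulate_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, list[LocusFrequencies]], list[LocusFrequencies]]:
    """Balding-Nichols allele frequencies for each population.

    Ancestral frequencies are symmetric-Dirichlet; each population draws
    Dirichlet(ancestral * (1 - theta')/theta').  theta' is the target
    theta corrected for the finite number of populations r: Nei's GST
    computed from r sampled populations has expectation
    theta'(1 - 1/r)/(1 - theta'/r), so theta' = theta*r/(r - 1 + theta)
    makes the *measured* mean per-locus FST land on theta.  Returns
    (population -> per-locus frequencies, ancestral frequencies).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pops = [f"pop{i + 1}" for i in range(config.n_populations)]
    r = config.n_populations
    theta_eff = config.theta * r / (r - 1 + config.theta)
    conc = (1.0 - theta_eff) / theta_eff
    out: dict[str, list[LocusFrequencies]] = {p: [] for p in pops}
    ancestral: list[LocusFrequencies] = []
    floor = 1e-6
    for li in range(config.n_loci):
        locus_id = f"L{li + 1:04d}"
        alleles = _random_alleles(rng, config.n_snps_per_locus, config.alleles_per_locus)
        anc = rng.dirichlet(np.ones(len(alleles)))
        anc = np.clip(anc, floor, None)
        anc /= anc.sum()
        ancestral.append(LocusFrequencies(locus_id, alleles, anc))
        for p in pops:
            f = rng.dirichlet(anc * conc)
            f = np.clip(f, floor, None)
            f /= f.sum()
            out[p].append(LocusFrequencies(locus_id, alleles, f))
    return out, ancestral


def _draw_genotype(rng: np.random.Generator, lf: LocusFrequencies) -> tuple[str, str]:
    a = rng.choice(lf.alleles, size=2, p=lf.freqs)
    return tuple(sorted(a))


def _mendelian_child(
    rng: np.random.Generator, g1: tuple[str, str], g2: tuple[str, str]
) -> tuple[str, str]:
    return tuple(sorted((g1[rng.integers(2)], g2[rng.integers(2)])))


def simulate_cohort(
    config: SimConfig,
    freqs: list[LocusFrequencies],
    n_founders: int = 20,
    n_po_pairs: int = 0,
    n_fs_pairs: int = 0,
    replicates: dict[str, int] | None = None,
    replicate_types: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
    population: str = "pop1",
) -> TruthSet:
    """Simulate a cohort: HWE founders, families, replicates, sexes.

    Parent-offspring pairs add one child of a founder and a fresh mate;
    full-sibling pairs add two children of two fresh founders.  Replicate
    entries duplicate a sample's truth genotypes, then flip each genotype
    with probability ``replicate_discordance`` to a *different* HWE draw,
    so the realized pairwise mismatch rate equals the configured rate.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    genotypes: dict[str, dict[str, tuple[str, str]]] = {}
    sex: dict[str, str] = {}
    relationships: list[tuple[str, str, str]] = []
    pop_of: dict[str, str] = {}

    def new_sample(name: str, geno: dict[str, tuple[str, str]]) -> None:
        genotypes[name] = geno
        sex[name] = "M" if rng.random() < 0.5 else "F"
        pop_of[name] = population

    def hwe_individual() -> dict[str, tuple[str, str]]:
        return {lf.locus_id: _draw_genotype(rng, lf) for lf in freqs}

    for i in range(n_founders):
        new_sample(f"F{i + 1:03d}", hwe_individual())
    founder_ids = list(genotypes)

    for i in range(n_po_pairs):
        parent = founder_ids[i % len(founder_ids)]
        mate = hwe_individual()
        child = {
            lf.locus_id: _mendelian_child(rng, genotypes[parent][lf.locus_id], mate[lf.locus_id])
            for lf in freqs
        }
        cid = f"PO{i + 1:03d}"
        new_sample(cid, child)
        relationships.append((parent, cid, "PO"))

    for i in range(n_fs_pairs):
        pa, pb = hwe_individual(), hwe_individual()
        sibs = []
        for k in range(2):
            sid = f"FS{i + 1:03d}{'ab'[k]}"
            geno = {
                lf.locus_id: _mendelian_child(rng, pa[lf.locus_id], pb[lf.locus_id])
                for lf in freqs
            }
            new_sample(sid, geno)
            sibs.append(sid)
        relationships.append((sibs[0], sibs[1], "FS"))

    groups: list[ReplicateGroup] = []
    lf_by_id = {lf.locus_id: lf for lf in freqs}
    for src, k in sorted((replicates or {}).items()):
        members = [src]
        for r in range(k - 1):
            rid = f"{src}_rep{r + 1}"
            geno = dict(genotypes[src])
            for locus_id, g in geno.items():
                if rng.random() < config.replicate_discordance:
                    lf = lf_by_id[locus_id]
                    for _ in range(1000):
                        alt = _draw_genotype(rng, lf)
                        if alt != g:
                            geno[locus_id] = alt
                            break
            genotypes[rid] = geno
            sex[rid] = sex[src]
            pop_of[rid] = population
            members.append(rid)
        stype = (replicate_types or {}).get(src, "tissue")
        groups.append(
            ReplicateGroup(
                group_id=f"grp_{src}",
                sample_ids=members,
                sample_types={m: stype for m in members},
            )
        )

    return TruthSet(
        genotypes=genotypes,
        sex=sex,
        relationships=relationships,
        replicate_groups=groups,
        allele_freqs={population: freqs},
        population_of=pop_of,
    )


def make_panel(
    config: SimConfig,
    freqs: list[LocusFrequencies],
    rng: np.random.Generator | None = None,
    include_sex_markers: bool = True,
) -> PanelDefinition:
    """Random amplicon references + probes consistent with the frequencies.

    Every locus gets a unique probe (first ``probe_length`` bases) and SNP
    offsets placed downstream of the probe; the haplotype alleles in
    ``freqs`` index those offsets.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    loci: list[PanelLocus] = []
    seen_probes: set[str] = set()

    def random_seq(n: int) -> str:
        return "".join(BASES[i] for i in rng.integers(0, 4, size=n))

    def unique_probe(seq: str) -> str:
        # regenerate until the probe is far from all existing ones
        probe = seq[: config.probe_length]
        while any(
            sum(a != b for a, b in zip(probe, p)) <= 4 for p in seen_probes
        ):
            seq = random_seq(config.amplicon_length)
            probe = seq[: config.probe_length]
        seen_probes.add(probe)
        return seq

    for lf in freqs:
        n_snps = len(lf.alleles[0])
        seq = unique_probe(random_seq(config.amplicon_length))
        lo = config.probe_length + 5
        hi = config.amplicon_length - 5
        offsets = sorted(rng.choice(np.arange(lo, hi), size=n_snps, replace=False).tolist())
        ref = list(seq)
        for k, off in enumerate(offsets):
            ref[off] = lf.alleles[0][k]  # reference carries the first allele
        ref = "".join(ref)
        loci.append(
            PanelLocus(
                locus_id=lf.locus_id,
                reference=ref,
                probe=ref[: config.probe_length],
                snp_offsets=offsets,
                marker_class="diversity",
            )
        )
    if include_sex_markers:
        for mid in sorted(config.sex_fractions):
            seq = unique_probe(random_seq(config.amplicon_length))
            loci.append(
                PanelLocus(
                    locus_id=mid,
                    reference=seq,
                    probe=seq[: config.probe_length],
                    snp_offsets=[],
                    marker_class="sex",
                )
            )
    return PanelDefinition(loci=loci)


@dataclass
class ReadSim:
    """In-memory read sets plus the plate layout used to generate them."""

    reads: dict[str, list[tuple[str, list[int]]]]  # sample -> [(seq, quals)]
    plate_map: pd.DataFrame  # sample_id, plate, role
    panel: PanelDefinition
    truth: TruthSet
    true_on_target: dict[str, float]


def _mutate(seq: str, rng: np.random.Generator, error: float) -> str:
    if error <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < error)
    for i in hits:
        choices = [b for b in BASES if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # gamma-poisson mixture; dispersion -> inf recovers Poisson
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return int(rng.poisson(lam))


def simulate_reads(
    truth: TruthSet,
    panel: PanelDefinition,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    samples: list[str] | None = None,
    plate_size: int = 95,
) -> ReadSim:
    """Amplicon reads per sample, plus one negative PCR control per plate.

    Per sample x autosomal locus, depth is negative-binomial; each read is
    the reference amplicon carrying one of the sample's two haplotypes at
    the SNP offsets, with per-base substitution error.  Off-target junk
    reads pad each sample to the configured on-target fraction.  Males get
    Binomial(on-target total, marker fraction) reads of each sex-marker
    amplicon, females Binomial(total, female_sex_fraction).  Each plate's
    negative control receives Binomial(depth, contamination_rate) stray
    reads per locus, copied from random samples' alleles.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    sample_ids = samples if samples is not None else sorted(truth.genotypes)
    autosomal = panel.autosomal()
    sex_loci = [l for l in panel if l.marker_class == "sex"]
    q = config.base_quality
    reads: dict[str, list[tuple[str, list[int]]]] = {}
    plate_rows = []
    true_on_target: dict[str, float] = {}
    # contamination donors: pool of (locus, haplotype) choices
    donor_samples = sample_ids

    plates = [sample_ids[i : i + plate_size] for i in range(0, len(sample_ids), plate_size)]
    for pi, plate_samples in enumerate(plates):
        plate = f"plate{pi + 1}"
        for s in plate_samples:
            plate_rows.append({"sample_id": s, "plate": plate, "role": "SAMPLE"})
            sample_reads: list[tuple[str, list[int]]] = []
            n_on = 0
            for locus in autosomal:
                g = truth.genotypes[s].get(locus.locus_id)
                if g is None:
                    continue
                depth = _nb_depth(rng, config.depth_mean, config.depth_dispersion)
                for _ in range(depth):
                    hap = g[rng.integers(2)]
                    seq = list(locus.reference)
                    for k, off in enumerate(locus.snp_offsets):
                        seq[off] = hap[k]
                    read = _mutate("".join(seq), rng, config.per_base_error)
                    sample_reads.append((read, [q] * len(read)))
                n_on += depth
            for locus in sex_loci:
                frac = (
                    config.sex_fractions[locus.locus_id]
                    if truth.sex.get(s) == "M"
                    else config.female_sex_fraction
                )
                n_sex = int(rng.binomial(max(n_on, 1), frac))
                for _ in range(n_sex):
                    read = _mutate(locus.reference, rng, config.per_base_error)
                    sample_reads.append((read, [q] * len(read)))
                n_on += n_sex
            f = config.on_target_fraction
            n_off = int(round(n_on * (1.0 - f) / f)) if f < 1.0 else 0
            for _ in range(n_off):
                junk = "".join(BASES[i] for i in rng.integers(0, 4, size=config.amplicon_length))
                sample_reads.append((junk, [q] * len(junk)))
            order = rng.permutation(len(sample_reads))
            reads[s] = [sample_reads[i] for i in order]
            total = n_on + n_off
            true_on_target[s] = n_on / total if total else 0.0
        neg_id = f"NEG_{plate}"
        plate_rows.append({"sample_id": neg_id, "plate": plate, "role": "NEGATIVE"})
        neg_reads: list[tuple[str, list[int]]] = []
        for locus in autosomal:
            depth = _nb_depth(rng, config.depth_mean, config.depth_dispersion)
            n_stray = int(rng.binomial(depth, config.contamination_rate))
            for _ in range(n_stray):
                donor = donor_samples[rng.integers(len(donor_samples))]
                g = truth.genotypes[donor].get(locus.locus_id)
                if g is None:
                    continue
                hap = g[rng.integers(2)]
                seq = list(locus.reference)
                for k, off in enumerate(locus.snp_offsets):
                    seq[off] = hap[k]
                read = _mutate("".join(seq), rng, config.per_base_error)
                neg_reads.append((read, [q] * len(read)))
        reads[neg_id] = neg_reads
    return ReadSim(
        reads=reads,
        plate_map=pd.DataFrame(plate_rows),
        panel=panel,
        truth=truth,
        true_on_target=true_on_target,
    )


def simulate_sex_tallies(
    config: SimConfig,
    n_samples: int,
    total_reads: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-sample sex-marker read tallies with known true sex.

    Males draw Binomial(total, expected fraction) reads per marker,
    females Binomial(total, female contamination fraction).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    rows = []
    truth: dict[str, str] = {}
    markers = sorted(config.sex_fractions)
    for i in range(n_samples):
        sid = f"S{i + 1:04d}"
        sex = "M" if rng.random() < 0.5 else "F"
        truth[sid] = sex
        row = {"sample_id": sid, "total_on_target": total_reads}
        for m in markers:
            p = config.sex_fractions[m] if sex == "M" else config.female_sex_fraction
            row[f"{m}_reads"] = int(rng.binomial(total_reads, p))
        rows.append(row)
    return pd.DataFrame(rows), truth


def simulate_screen_data(
    config: SimConfig,
    n_samples: int = 300,
    success_threshold: float = 0.5,
    conc_range: tuple[float, float] = (0.001, 2.0),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Concentration -> genotyping-success data following a known logistic.

    P(fraction genotyped >= threshold) = expit(b0 + b1 * concentration)
    with (b0, b1) from ``config.logistic_params``.
    """
    from scipy.special import expit

    rng = rng if rng is not None else np.random.default_rng(config.seed + 5)
    b0, b1 = config.logistic_params
    conc = rng.uniform(*conc_range, size=n_samples)
    p = expit(b0 + b1 * conc)
    success = rng.random(n_samples) < p
    pct = np.where(
        success,
        rng.uniform(success_threshold, 1.0, size=n_samples),
        rng.uniform(0.0, success_threshold, size=n_samples),
    )
    return pd.DataFrame(
        {"sample_id": [f"Q{i + 1:04d}" for i in range(n_samples)],
         "concentration": conc,
         "pct_loci_genotyped": pct}
    )


def simulate_standard_curve_points(
    intercept: float = 22.0,
    slope: float = -3.32,
    concentrations: tuple[float, ...] = (20.0, 2.0, 0.2, 0.02, 0.002),
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """Five ten-fold standards from 20 to 0.002 ng/uL with optional Cq noise."""
    rng = rng if rng is not None else np.random.default_rng(0)
    pts = []
    for c in concentrations:
        cq = intercept + slope * np.log10(c)
        if noise_sd > 0:
            cq += rng.normal(0.0, noise_sd)
        pts.append((c, float(cq)))
    return pts


# ------------------------------------------------------------ fixed fixtures


PANEL_SIZE = 194
_REPLICATE_PLAN = {
    # sample type -> (total comparisons, total mismatches)
    "blood": (10_268, 20),
    "tissue": (4_125, 3),
    "scat": (3_185, 46),
}
_SEXING_PLAN = {
    "n_total": 205,
    "n_correct_male": 88,
    "n_correct_female": 87,
    "n_wrong": 5,
    "n_conflict": 5,
    "n_not_genotyped": 20,
}


def make_paper_fixtures() -> dict[str, object]:
    """Deterministic fixtures reproducing the study's printed tallies.

    ``replicates``: (calls, groups) built as two-member replicate pairs —
    full pairs compare all 194 panel loci, one partial pair per sample
    type makes the comparison totals land exactly on 10,268 / 4,125 /
    3,185 with 20 / 3 / 46 planted mismatches (0.39% overall).

    ``sexing``: read-tally table and field-sex map for 205 samples — 175
    correct, 5 assigned-but-wrong, 5 marker conflicts, 20 with a marker in
    the unassignable ratio band.
    """
    loci = [f"L{i + 1:03d}" for i in range(PANEL_SIZE)]
    calls: list[GenotypeCall] = []
    groups: list[ReplicateGroup] = []

    def passing(sample: str, locus: str, a1: str = "AC", a2: str = "AC") -> GenotypeCall:
        return GenotypeCall(sample, locus, a1, a2, depth=50, allelic_ratio=None
                            if a1 == a2 else 0.5, filter_status=PASS)

    for stype, (n_comp, n_mism) in _REPLICATE_PLAN.items():
        n_full, rem = divmod(n_comp, PANEL_SIZE)
        n_pairs = n_full + (1 if rem else 0)
        for p in range(n_pairs):
            a = f"{stype}_{p + 1:03d}_a"
            b = f"{stype}_{p + 1:03d}_b"
            n_loci_here = PANEL_SIZE if p < n_full else rem
            for li in range(PANEL_SIZE):
                locus = loci[li]
                if li < n_loci_here:
                    mismatch_here = p == 0 and li < n_mism
                    calls.append(passing(a, locus))
                    calls.append(
                        passing(b, locus, "GT", "GT") if mismatch_here else passing(b, locus)
                    )
                else:
                    calls.append(passing(a, locus))
                    calls.append(
                        GenotypeCall(b, locus, MISSING, MISSING, 0, None, LOW_DEPTH)
                    )
            groups.append(
                ReplicateGroup(
                    group_id=f"{stype}_{p + 1:03d}",
                    sample_ids=[a, b],
                    sample_types={a: stype, b: stype},
                )
            )

    total = 100_000  # expected ddx3Y 500, usp9Y 300 at the shipped fractions
    rows = []
    field_sex: dict[str, str] = {}
    plan = _SEXING_PLAN

    def add(sid: str, ddx: int, usp: int, truth: str) -> None:
        rows.append({"sample_id": sid, "total_on_target": total,
                     "ddx3Y_reads": ddx, "usp9Y_reads": usp})
        field_sex[sid] = truth

    i = 0
    for _ in range(plan["n_correct_male"]):
        i += 1
        add(f"sex{i:03d}", 450, 270, "M")  # ratios 0.9 -> M, M
    for _ in range(plan["n_correct_female"]):
        i += 1
        add(f"sex{i:03d}", 5, 3, "F")  # ratios 0.01 -> F, F
    for _ in range(plan["n_wrong"]):
        i += 1
        add(f"sex{i:03d}", 450, 270, "F")  # called M, field says F
    for _ in range(plan["n_conflict"]):
        i += 1
        add(f"sex{i:03d}", 450, 3, "M")  # ddx3Y male, usp9Y female
    for _ in range(plan["n_not_genotyped"]):
        i += 1
        add(f"sex{i:03d}", 75, 270, "M")  # ddx3Y ratio 0.15: dead zone
    assert i == plan["n_total"]

    return {
        "replicates": (calls, groups),
        "sexing": (pd.DataFrame(rows), field_sex),
    }
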