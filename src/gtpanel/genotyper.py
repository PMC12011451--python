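"""Microhaplotype genotype calling from amplicon reads.

The caller tallies, for every sample x locus, the phased base combination
observed at the locus's SNP offsets on each read ("microhaplotypes"), then
applies three filters before emitting a genotype:

* minimum read depth (default 20x),
* minimum allelic ratio for heterozygote calls (default 0.1, measured as
  second-most-frequent haplotype count over callable depth),
* a dynamic contamination filter — depth must exceed twice the read depth
  of the same locus in the plate's negative PCR control.

Reads reach the caller either from FASTQ via probe matching
(:func:`assign_reads`) or pre-aligned from SAM (:func:`reads_from_sam`).
Replicate-based error-rate estimation and locus-level QC live here too.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MISSING = "MISSING"
PASS = "PASS"
LOW_DEPTH = "LOW_DEPTH"
NEG_CONTROL = "NEG_CONTROL"
AMBIGUOUS = "AMBIGUOUS"


@dataclass
class PanelLocus:
    """One amplicon marker: reference sequence, probe, SNP offsets (0-based)."""

    locus_id: str
    reference: str
    probe: str
    snp_offsets: list[int]
    marker_class: str = "diversity"  # fst | diversity | sex

    def __post_init__(self) -> None:
        if self.probe not in self.reference:
            raise ValueError(f"{self.locus_id}: probe not found in reference sequence")
        offs = list(self.snp_offsets)
        if offs != sorted(set(offs)):
            raise ValueError(f"{self.locus_id}: snp_offsets must be strictly increasing")
        if offs and (offs[0] < 0 or offs[-1] >= len(self.reference)):
            raise ValueError(f"{self.locus_id}: snp_offsets outside reference")
        if self.marker_class not in ("fst", "diversity", "sex"):
            raise ValueError(f"{self.locus_id}: bad marker_class {self.marker_class!r}")

    @property
    def probe_offset(self) -> int:
        return self.reference.index(self.probe)


@dataclass
class PanelDefinition:
    loci: list[PanelLocus]

    def __post_init__(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus_ids in panel")

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def get(self, locus_id: str) -> PanelLocus:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)

    def autosomal(self) -> list[PanelLocus]:
        return [l for l in self.loci if l.marker_class != "sex"]

    def validate_probes(self, max_mismatches: int = 1) -> None:
        """Probes must be mutually distinguishable at the match tolerance."""
        for a, b in itertools.combinations(self.loci, 2):
            if len(a.probe) == len(b.probe):
                mism = sum(x != y for x, y in zip(a.probe, b.probe))
                if mism <= 2 * max_mismatches:
                    raise ValueError(
                        f"probes for {a.locus_id} and {b.locus_id} collide at "
                        f"{max_mismatches} mismatches"
                    )


@dataclass
class HaplotypeCounts:
    """Tally of observed microhaplotype strings for one sample x locus."""

    sample_id: str
    locus_id: str
    counts: dict[str, int] = field(default_factory=dict)
    total_on_target: int = 0
    total_reads: int = 0


@dataclass
class GenotypeCall:
    sample_id: str
    locus_id: str
    allele1: str
    allele2: str
    depth: int
    allelic_ratio: float | None
    filter_status: str

    @property
    def is_missing(self) -> bool:
        return self.filter_status != PASS

    def genotype(self) -> frozenset[tuple[str, int]] | None:
        """Unordered allele pair as a multiset, or None when missing."""
        if self.is_missing:
            return None
        return frozenset(Counter([self.allele1, self.allele2]).items())


@dataclass
class ReplicateGroup:
    group_id: str
    sample_ids: list[str]
    sample_types: dict[str, str] = field(default_factory=dict)  # blood|tissue|scat

    def __post_init__(self) -> None:
        if len(self.sample_ids) < 2:
            raise ValueError(f"group {self.group_id}: needs >=2 members")


def _mismatch_positions(seq: str, probe: str, start: int) -> int:
    m = 0
    for k in range(len(probe)):
        if seq[start + k] != probe[k]:
            m += 1
    return m


def _find_probe(seq: str, probe: str, max_mismatches: int) -> int | None:
    """Leftmost offset where probe matches seq within the mismatch budget."""
    if max_mismatches == 0:
        i = seq.find(probe)
        return i if i >= 0 else None
    best: int | None = None
    for i in range(len(seq) - len(probe) + 1):
        m = 0
        for k in range(len(probe)):
            if seq[i + k] != probe[k]:
                m += 1
                if m > max_mismatches:
                    break
        if m <= max_mismatches:
            best = i
            break
    return best


@dataclass
class ReadAssignment:
    """Per-sample result of probe-based read binning."""

    sample_id: str
    bins: dict[str, list[tuple[str, list[int], int]]]  # locus -> [(seq, quals, aln_start)]
    n_total: int
    n_assigned: int
    n_ambiguous: int

    @property
    def on_target_fraction(self) -> float:
        return self.n_assigned / self.n_total if self.n_total else 0.0


def assign_reads(
    reads: list[tuple[str, list[int]]],
    panel: PanelDefinition,
    sample_id: str = "",
    max_probe_mismatches: int = 1,
) -> ReadAssignment:
    """Bin reads to panel loci by probe-sequence matching.

    Each read is scanned for every locus probe (allowing up to
    ``max_probe_mismatches`` mismatches at the best offset); a read hitting
    exactly one probe is assigned, a read hitting two or more is counted as
    ambiguous and left unassigned.  The alignment start recorded per read
    places the read on the amplicon via the probe's known reference offset.

    Exact probe hits are found with C-level substring search; only reads
    with no exact hit fall back to the vectorized mismatch scan.
    """
    panel.validate_probes(max_probe_mismatches)
    bins: dict[str, list[tuple[str, list[int], int]]] = {l.locus_id: [] for l in panel}
    n_assigned = 0
    n_ambiguous = 0
    loci = list(panel)
    probe_lens = {len(l.probe) for l in loci}
    probe_mats: dict[int, tuple[list[PanelLocus], np.ndarray]] = {}
    for plen in probe_lens:
        group = [l for l in loci if len(l.probe) == plen]
        mat = np.array([np.frombuffer(l.probe.encode(), dtype=np.uint8) for l in group])
        probe_mats[plen] = (group, mat)
    for seq, quals in reads:
        hits: list[tuple[str, int]] = []
        for locus in loci:
            off = seq.find(locus.probe)
            if off >= 0:
                hits.append((locus.locus_id, off))
        if not hits and max_probe_mismatches > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            for plen, (group, mat) in probe_mats.items():
                if len(arr) < plen:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(arr, plen)
                # (n_probes, n_offsets) mismatch counts
                mism = (windows[None, :, :] != mat[:, None, :]).sum(axis=2)
                best = mism.min(axis=1)
                for gi in np.flatnonzero(best <= max_probe_mismatches):
                    off = int(np.argmax(mism[gi] <= max_probe_mismatches))
                    hits.append((group[gi].locus_id, off))
        if len(hits) == 1:
            locus_id, read_off = hits[0]
            locus = panel.get(locus_id)
            aln_start = locus.probe_offset - read_off  # ref coord of read's first base
            bins[locus_id].append((seq, quals, aln_start))
            n_assigned += 1
        elif len(hits) > 1:
            n_ambiguous += 1
    return ReadAssignment(
        sample_id=sample_id,
        bins=bins,
        n_total=len(reads),
        n_assigned=n_assigned,
        n_ambiguous=n_ambiguous,
    )


def extract_haplotypes(
    bin_reads: list[tuple[str, list[int], int]],
    locus: PanelLocus,
    sample_id: str = "",
    qmin: int = 20,
    total_reads: int | None = None,
) -> HaplotypeCounts:
    """Tally microhaplotypes from one locus's read bin.

    A read contributes one haplotype observation only if it covers every
    SNP offset with base quality >= ``qmin`` at each; reads failing that
    stay in ``total_on_target`` but not in ``counts``.
    """
    counts: Counter[str] = Counter()
    for seq, quals, aln_start in bin_reads:
        bases = []
        for off in locus.snp_offsets:
            ridx = off - aln_start
            if ridx < 0 or ridx >= len(seq) or quals[ridx] < qmin:
                bases = []
                break
            bases.append(seq[ridx])
        if bases:
            counts["".join(bases)] += 1
    return HaplotypeCounts(
        sample_id=sample_id,
        locus_id=locus.locus_id,
        counts=dict(counts),
        total_on_target=len(bin_reads),
        total_reads=total_reads if total_reads is not None else len(bin_reads),
    )


def reads_from_sam(path: str, panel: PanelDefinition) -> dict[str, dict[str, list[tuple[str, list[int], int]]]]:
    """Load pre-aligned reads, binned per read group (sample) and locus.

    Reference names in the SAM must be panel locus ids; the sample is taken
    from the read group ``SM`` tag, falling back to the query-name prefix
    before the first ``/``.
    """
    import pysam

    out: dict[str, dict[str, list[tuple[str, list[int], int]]]] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        rg_sample = {
            rg.get("ID"): rg.get("SM", rg.get("ID"))
            for rg in (sam.header.to_dict().get("RG") or [])
        }
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            locus_id = rec.reference_name
            try:
                rg = rec.get_tag("RG")
                sample = rg_sample.get(rg, rg)
            except KeyError:
                sample = rec.query_name.split("/")[0]
            quals = list(rec.query_qualities) if rec.query_qualities is not None else [40] * len(rec.query_sequence)
            out.setdefault(sample, {}).setdefault(locus_id, []).append(
                (rec.query_sequence, quals, rec.reference_start)
            )
    return out


def call_genotype(
    hc: HaplotypeCounts,
    min_depth: int = 20,
    min_allelic_ratio: float = 0.1,
    neg_control_depth: int = 0,
    ratio_basis: str = "second_over_total",
) -> GenotypeCall:
    """Call one genotype from a haplotype tally.

    Filter order: callable depth < ``min_depth`` -> LOW_DEPTH; depth not
    exceeding twice the plate negative's depth -> NEG_CONTROL; then the two
    most frequent haplotypes define the call — a heterozygote when the
    second's ratio clears ``min_allelic_ratio``, a homozygote otherwise.
    A third haplotype also clearing the ratio makes the call AMBIGUOUS
    (possible contamination or paralog).

    ``ratio_basis`` selects the denominator: ``second_over_total``
    (microhaplot convention, default) or ``minor_over_major``.
    """
    callable_counts = {h: c for h, c in hc.counts.items() if "N" not in h}
    depth = sum(callable_counts.values())

    def missing(status: str) -> GenotypeCall:
        return GenotypeCall(hc.sample_id, hc.locus_id, MISSING, MISSING, depth, None, status)

    if depth < min_depth:
        return missing(LOW_DEPTH)
    if depth <= 2 * neg_control_depth:
        return missing(NEG_CONTROL)
    ranked = sorted(callable_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    h1, c1 = ranked[0]
    if len(ranked) == 1:
        return GenotypeCall(hc.sample_id, hc.locus_id, h1, h1, depth, None, PASS)
    h2, c2 = ranked[1]
    if ratio_basis == "minor_over_major":
        ratio2 = c2 / c1
    else:
        ratio2 = c2 / depth
    if ratio2 >= min_allelic_ratio:
        if len(ranked) > 2:
            c3 = ranked[2][1]
            ratio3 = c3 / c1 if ratio_basis == "minor_over_major" else c3 / depth
            if ratio3 >= min_allelic_ratio:
                return missing(AMBIGUOUS)
        a1, a2 = sorted((h1, h2))
        return GenotypeCall(hc.sample_id, hc.locus_id, a1, a2, depth, c2 / depth, PASS)
    return GenotypeCall(hc.sample_id, hc.locus_id, h1, h1, depth, c2 / depth, PASS)


def negative_control_depths(
    tallies: list[HaplotypeCounts],
    plate_of: dict[str, str],
    negatives: dict[str, list[str]],
) -> dict[tuple[str, str], int]:
    """Per (plate, locus) negative-control read depth.

    With several negatives on a plate the maximum per-locus depth is used
    (conservative).  Plates with no negative contribute depth 0.
    """
    neg_samples = {s for members in negatives.values() for s in members}
    out: dict[tuple[str, str], int] = {}
    for hc in tallies:
        if hc.sample_id in neg_samples:
            plate = plate_of[hc.sample_id]
            depth = sum(c for h, c in hc.counts.items() if "N" not in h)
            key = (plate, hc.locus_id)
            out[key] = max(out.get(key, 0), depth)
    return out


def discover_panel_variants(
    pileups: dict[int, Counter],
    reference: str,
    min_qual: float = 30.0,
    min_maf: float = 0.006,
    primer_mask: list[tuple[int, int]] | None = None,
    error_rate: float = 0.001,
) -> list[int]:
    """Find callable SNP offsets on one amplicon from cross-sample pileups.

    ``pileups`` maps 0-based offset -> Counter of base -> read count pooled
    across samples.  A site qualifies when (a) its minor allele frequency is
    >= ``min_maf``, (b) its phred-scaled variant quality — the binomial
    surprise of the minor-allele count under the per-base ``error_rate``
    null — reaches ``min_qual``, and (c) the offset lies outside every
    primer-masked range (0-based inclusive).  Only biallelic sites are
    emitted.
    """
    from scipy import stats as _stats

    mask = primer_mask or []
    offsets: list[int] = []
    for off in sorted(pileups):
        if any(lo <= off <= hi for lo, hi in mask):
            continue
        counts = {b: c for b, c in pileups[off].items() if b in "ACGT"}
        if len(counts) != 2:
            continue
        total = sum(counts.values())
        minor = min(counts.values())
        if total == 0 or minor / total < min_maf:
            continue
        p_null = float(_stats.binom.sf(minor - 1, total, error_rate))
        qual = 10_000.0 if p_null <= 0 else -10.0 * np.log10(p_null)
        if qual < min_qual:
            continue
        offsets.append(off)
    return offsets


@dataclass
class ErrorRateResult:
    rate: float
    mismatches: int
    comparisons: int
    per_type: dict[str, tuple[float, int, int]]  # type -> (rate, mism, comps)
    per_locus: dict[str, tuple[int, int]]  # locus -> (mism, comps)


def estimate_error_rate(
    calls: list[GenotypeCall], groups: list[ReplicateGroup]
) -> ErrorRateResult:
    """Replicate-concordance genotyping error rate.

    Every pair of group members with PASS calls at a locus contributes one
    comparison; a comparison mismatches when the unordered allele pairs
    differ.  The rate is total mismatches over total comparisons.  Per-type
    rates use only comparisons whose two members share the sample type.
    """
    table: dict[tuple[str, str], GenotypeCall] = {
        (c.sample_id, c.locus_id): c for c in calls
    }
    loci = sorted({c.locus_id for c in calls})
    mismatches = 0
    comparisons = 0
    per_type: dict[str, list[int]] = {}
    per_locus: dict[str, list[int]] = {}
    for group in groups:
        for locus_id in loci:
            present = [
                (s, table[(s, locus_id)])
                for s in group.sample_ids
                if (s, locus_id) in table and not table[(s, locus_id)].is_missing
            ]
            for (sa, ca), (sb, cb) in itertools.combinations(present, 2):
                mism = int(ca.genotype() != cb.genotype())
                comparisons += 1
                mismatches += mism
                pl = per_locus.setdefault(locus_id, [0, 0])
                pl[0] += mism
                pl[1] += 1
                ta = group.sample_types.get(sa)
                tb = group.sample_types.get(sb)
                if ta is not None and ta == tb:
                    pt = per_type.setdefault(ta, [0, 0])
                    pt[0] += mism
                    pt[1] += 1
    if comparisons == 0:
        raise ValueError("no comparable genotypes between replicates")
    return ErrorRateResult(
        rate=mismatches / comparisons,
        mismatches=mismatches,
        comparisons=comparisons,
        per_type={
            t: (m / c if c else float("nan"), m, c) for t, (m, c) in sorted(per_type.items())
        },
        per_locus={l: (m, c) for l, (m, c) in sorted(per_locus.items())},
    )


def locus_qc(
    per_locus_error: dict[str, float],
    per_locus_on_target: dict[str, float],
    max_error: float = 0.05,
    min_on_target: float = 0.10,
) -> tuple[list[str], dict[str, str]]:
    """Drop loci failing the error-rate or on-target amplification rules.

    A locus is removed when its replicate error rate is strictly greater
    than ``max_error`` (5%), or when under 10% of its assigned reads match
    the expected amplicon structure.  Returns (retained ids, dropped id ->
    reason code ERROR_RATE|OFF_TARGET).
    """
    dropped: dict[str, str] = {}
    all_ids = sorted(set(per_locus_error) | set(per_locus_on_target))
    for lid in all_ids:
        err = per_locus_error.get(lid)
        if err is not None and err > max_error:
            dropped[lid] = "ERROR_RATE"
            continue
        ot = per_locus_on_target.get(lid)
        if ot is not None and ot < min_on_target:
            dropped[lid] = "OFF_TARGET"
    retained = [lid for lid in all_ids if lid not in dropped]
    return retained, dropped


def sample_summary(
    calls: list[GenotypeCall],
    assignments: dict[str, ReadAssignment],
    panel_size: int,
) -> "pd.DataFrame":
    """Per-sample genotyping summary table.

    Columns: pct_loci_genotyped (PASS autosomal calls / panel size),
    on_target_fraction, total_reads, plus a flag for zero-read samples.
    """
    import pandas as pd

    by_sample: dict[str, int] = {}
    for c in calls:
        if not c.is_missing:
            by_sample[c.sample_id] = by_sample.get(c.sample_id, 0) + 1
    rows = []
    samples = sorted(set(by_sample) | set(assignments))
    for s in samples:
        asn = assignments.get(s)
        n_pass = by_sample.get(s, 0)
        rows.append(
            {
                "sample_id": s,
                "pct_loci_genotyped": 100.0 * n_pass / panel_size if panel_size else 0.0,
                "on_target_fraction": asn.on_target_fraction if asn else float("nan"),
                "total_reads": asn.n_total if asn else 0,
                "zero_reads": bool(asn and asn.n_total == 0),
            }
        )
    return pd.DataFrame(rows)
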