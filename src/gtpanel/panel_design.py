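"""Marker selection from population genotype data.

Implements the filtering and ranking steps used to build an amplicon panel
from a dense SNP catalog: quality filters (MAF, missingness, Hardy-Weinberg,
window-based LD pruning), a read-depth filter against multi-copy loci,
per-locus Nei F\\ :sub:`ST` ranking for diagnostic markers, microhaplotype
window discovery, and genome-spaced high-MAF "diversity" markers.

Genotypes are coded as alt-allele dosages 0/1/2 with ``-1`` (or NaN) for
missing, one row per locus, one column per sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class CandidateSnp:
    """A single biallelic SNP candidate.

    Positions are 1-based (VCF convention).  ``per_pop_freq`` maps a
    population label to the alt-allele frequency in that population.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float
    missingness: float
    per_pop_freq: dict[str, float] = field(default_factory=dict)
    mean_depth: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"maf must be in [0, 0.5], got {self.maf}")
        if not (0.0 <= self.missingness <= 1.0):
            raise ValueError(f"missingness must be in [0, 1], got {self.missingness}")
        for pop, f in self.per_pop_freq.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"per_pop_freq[{pop}]={f} outside [0, 1]")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class MicrohapCandidate:
    """A cluster of nearby SNPs treated as one multiallelic marker."""

    chrom: str
    window_start: int
    window_end: int
    snps: list[CandidateSnp]
    anchor_maf: float
    freq_sd: float

    @property
    def span(self) -> int:
        return self.window_end - self.window_start + 1

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.window_start}-{self.window_end}"


@dataclass
class FstRecord:
    locus_id: str
    grouping: str
    fst: float


def snp_stats_from_matrix(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele frequency and missingness per locus from a dosage matrix."""
    g = np.asarray(geno, dtype=float)
    miss = np.isnan(g) | (g == MISSING)
    n_called = (~miss).sum(axis=1)
    with np.errstate(invalid="ignore"):
        alt = np.where(miss, 0.0, g).sum(axis=1) / np.maximum(2 * n_called, 1)
    missingness = miss.sum(axis=1) / g.shape[1]
    return alt, missingness


def hwe_pvalue(genotypes: np.ndarray) -> float:
    """Chi-square (1 df) Hardy-Weinberg test on one locus's dosage vector.

    Yates continuity correction is applied for n < 100 called genotypes.
    Monomorphic loci return p = 1 (nothing to test).
    """
    g = np.asarray(genotypes, dtype=float)
    g = g[~(np.isnan(g) | (g == MISSING))]
    n = g.size
    if n == 0:
        return 1.0
    n_hom_ref = float(np.sum(g == 0))
    n_het = float(np.sum(g == 1))
    n_hom_alt = float(np.sum(g == 2))
    p = (2 * n_hom_alt + n_het) / (2 * n)
    q = 1.0 - p
    if p <= 0.0 or p >= 1.0:
        return 1.0
    expected = np.array([q * q * n, 2 * p * q * n, p * p * n])
    observed = np.array([n_hom_ref, n_het, n_hom_alt])
    correction = 0.5 if n < 100 else 0.0
    dev = np.maximum(np.abs(observed - expected) - correction, 0.0)
    chi2 = float(np.sum(dev**2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def _pairwise_r2(gi: np.ndarray, gj: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over shared calls."""
    mask = ~(np.isnan(gi) | (gi == MISSING) | np.isnan(gj) | (gj == MISSING))
    if mask.sum() < 2:
        return 0.0
    a, b = gi[mask], gj[mask]
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    geno: np.ndarray,
    order: np.ndarray | None = None,
    r2_max: float = 0.5,
    window: int = 50,
    step: int = 5,
) -> np.ndarray:
    """Window-based LD pruning over loci (rows of ``geno``).

    Within each sliding window of ``window`` loci (advanced by ``step``),
    any pair with r^2 > ``r2_max`` loses one member: the locus later in the
    supplied order is dropped.  Returns indices of retained loci in the
    original order.
    """
    n_loci = geno.shape[0]
    idx = np.arange(n_loci) if order is None else np.asarray(order)
    keep = np.ones(n_loci, dtype=bool)
    start = 0
    while start < n_loci:
        win = idx[start : start + window]
        for ii in range(len(win)):
            i = win[ii]
            if not keep[i]:
                continue
            for jj in range(ii + 1, len(win)):
                j = win[jj]
                if not keep[j]:
                    continue
                if _pairwise_r2(geno[i].astype(float), geno[j].astype(float)) > r2_max:
                    keep[j] = False
        if start + window >= n_loci:
            break
        start += step
    return np.flatnonzero(keep)


def filter_candidates(
    snps: list[CandidateSnp],
    geno: np.ndarray,
    maf_min: float = 0.01,
    max_missing: float = 0.10,
    hwe_alpha: float = 0.05,
    ld_r2_max: float = 0.5,
    ld_window: int = 50,
    ld_step: int = 5,
) -> list[CandidateSnp]:
    """Apply the MAF -> missingness -> HWE -> LD filter cascade.

    ``geno`` is the loci x samples dosage matrix aligned with ``snps``.
    The cascade is idempotent: re-running it on its own output is a no-op.
    """
    if len(snps) == 0:
        warnings.warn("filter_candidates: empty input", stacklevel=2)
        return []
    if geno.shape[0] != len(snps):
        raise ValueError("genotype matrix rows must match number of SNPs")
    g = np.asarray(geno, dtype=float)

    alt_freq, missingness = snp_stats_from_matrix(g)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep = maf >= maf_min
    keep &= missingness <= max_missing
    hwe_p = np.array([hwe_pvalue(g[i]) if keep[i] else 1.0 for i in range(len(snps))])
    keep &= hwe_p >= hwe_alpha

    surviving = np.flatnonzero(keep)
    if surviving.size:
        retained_local = ld_prune(
            g[surviving], r2_max=ld_r2_max, window=ld_window, step=ld_step
        )
        surviving = surviving[retained_local]
    logger.info(
        "filter_candidates: %d/%d retained (maf>=%g, miss<=%g, hwe>=%g, r2<=%g)",
        surviving.size, len(snps), maf_min, max_missing, hwe_alpha, ld_r2_max,
    )
    return [snps[i] for i in surviving]


def per_locus_fst(
    per_pop_freq: dict[str, float | np.ndarray],
    pop_sizes: dict[str, int] | None = None,
) -> float:
    """Nei's per-locus F_ST, (HT - HS)/HT.

    HS is the unweighted mean within-population expected heterozygosity and
    HT the expected heterozygosity at the mean (pooled) allele frequencies.
    A population's value may be a single alt-allele frequency (biallelic)
    or a full allele-frequency vector (microhaplotypes).  Returns 0 where
    HT = 0 (fixed in all populations); ``pop_sizes`` is accepted for
    interface symmetry but the estimator is unweighted.
    """
    if len(per_pop_freq) < 2:
        raise ValueError("need >=2 populations")
    vecs = []
    for pop, f in per_pop_freq.items():
        v = np.atleast_1d(np.asarray(f, dtype=float))
        if v.size == 1:
            v = np.array([v[0], 1.0 - v[0]])
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"allele frequencies for {pop} outside [0, 1]")
        vecs.append(v)
    freqs = np.vstack(vecs)
    hs = float(np.mean(1.0 - np.sum(freqs**2, axis=1)))
    p_bar = freqs.mean(axis=0)
    ht = float(1.0 - np.sum(p_bar**2))
    if ht == 0.0:
        return 0.0
    return (ht - hs) / ht


def rank_and_select_fst(
    records: list[FstRecord], top_n: int = 30
) -> tuple[list[str], dict[str, list[str]]]:
    """Select the top-``top_n`` loci by F_ST within each grouping.

    Ties at the cutoff break by locus id (lexicographic, ascending) so the
    selection is deterministic.  Returns the deduplicated union plus the
    per-grouping selections; overlap across groupings is logged.
    """
    by_group: dict[str, list[FstRecord]] = {}
    for rec in records:
        by_group.setdefault(rec.grouping, []).append(rec)
    per_group: dict[str, list[str]] = {}
    for grouping, recs in sorted(by_group.items()):
        if len(recs) < top_n:
            warnings.warn(
                f"grouping {grouping!r}: only {len(recs)} loci (< top_n={top_n}); keeping all",
                stacklevel=2,
            )
        ranked = sorted(recs, key=lambda r: (-r.fst, r.locus_id))
        per_group[grouping] = [r.locus_id for r in ranked[:top_n]]
    union: list[str] = []
    seen: set[str] = set()
    for grouping in sorted(per_group):
        for lid in per_group[grouping]:
            if lid not in seen:
                seen.add(lid)
                union.append(lid)
    n_overlap = sum(len(v) for v in per_group.values()) - len(union)
    if n_overlap:
        logger.info("rank_and_select_fst: %d loci shared between groupings", n_overlap)
    return union, per_group


def discover_microhap_windows(
    snps: list[CandidateSnp],
    window_bp: int = 100,
    anchor_maf_range: tuple[float, float] = (0.2, 0.45),
    min_freq_sd: float = 0.01,
) -> list[MicrohapCandidate]:
    """Find SNP clusters that can be phased into microhaplotype markers.

    A qualifying cluster spans at most ``window_bp`` (inclusive of both end
    positions), holds >= 2 SNPs, contains at least one anchor SNP with MAF
    inside ``anchor_maf_range``, and the sample (n-1) standard deviation of
    the member MAFs exceeds ``min_freq_sd`` — the last rule rejects SNPs in
    perfect phase, whose frequencies are identical.

    Clusters are grown maximally from the leftmost unused SNP on each
    chromosome; each SNP belongs to at most one emitted candidate.
    """
    lo, hi = anchor_maf_range
    for a, b in zip(snps, snps[1:]):
        if (a.chrom, a.pos) > (b.chrom, b.pos):
            raise ValueError("snps must be sorted by (chrom, pos)")
    out: list[MicrohapCandidate] = []
    by_chrom: dict[str, list[CandidateSnp]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom):
        arr = by_chrom[chrom]
        pos = np.array([s.pos for s in arr])
        i = 0
        while i < len(arr):
            j = i
            while j + 1 < len(arr) and pos[j + 1] - pos[i] + 1 <= window_bp:
                j += 1
            cluster = arr[i : j + 1]
            if len(cluster) >= 2:
                mafs = np.array([s.maf for s in cluster])
                anchors = mafs[(mafs >= lo) & (mafs <= hi)]
                sd = float(np.std(mafs, ddof=1))
                if anchors.size and sd > min_freq_sd:
                    out.append(
                        MicrohapCandidate(
                            chrom=chrom,
                            window_start=int(pos[i]),
                            window_end=int(pos[j]),
                            snps=list(cluster),
                            anchor_maf=float(anchors[0]),
                            freq_sd=sd,
                        )
                    )
                    i = j + 1
                    continue
            i += 1
    return out


def select_diversity_markers(
    snps: list[CandidateSnp],
    maf_range: tuple[float, float] = (0.30, 0.45),
    min_spacing_bp: int = 250_000,
) -> list[str]:
    """Greedy left-to-right pick of high-MAF SNPs spaced along the genome."""
    lo, hi = maf_range
    selected: list[str] = []
    by_chrom: dict[str, list[CandidateSnp]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom):
        last_pos: int | None = None
        for s in sorted(by_chrom[chrom], key=lambda s: s.pos):
            if not (lo <= s.maf <= hi):
                continue
            if last_pos is None or s.pos - last_pos >= min_spacing_bp:
                selected.append(s.locus_id)
                last_pos = s.pos
    return selected


def depth_peak_filter(
    mean_depths: dict[str, float], grid_size: int = 512
) -> tuple[list[str], float | None]:
    """Drop loci in the doubled-coverage depth peak (multi-copy mapping).

    Loci that map to two genomic copies collect roughly twice the read
    depth of single-copy loci, producing a second mode in the depth
    distribution.  A Gaussian KDE (Silverman bandwidth) is fitted; the
    valley between the first mode m1 and 2*m1 becomes the retention
    cutoff.  Unimodal distributions retain everything with a warning.

    Returns (retained locus ids, cutoff or None).
    """
    ids = list(mean_depths)
    depths = np.array([mean_depths[i] for i in ids], dtype=float)
    if depths.size == 0:
        return [], None
    if np.allclose(depths, depths[0]):
        warnings.warn("depth_peak_filter: all depths equal; retaining all", stacklevel=2)
        return ids, None
    kde = stats.gaussian_kde(depths)  # Silverman via scott-like default is fine at this scale
    kde.set_bandwidth("silverman")
    grid = np.linspace(depths.min(), depths.max(), grid_size)
    dens = kde(grid)
    d = np.diff(dens)
    maxima = np.flatnonzero((np.hstack([d, -1]) < 0) & (np.hstack([1, d]) > 0))
    if maxima.size < 2:
        warnings.warn("depth_peak_filter: unimodal depth distribution; retaining all", stacklevel=2)
        return ids, None
    m1 = grid[maxima[0]]
    upper = min(2.0 * m1, grid[-1])
    region = (grid > m1) & (grid < upper)
    if not region.any():
        warnings.warn("depth_peak_filter: no valley region; retaining all", stacklevel=2)
        return ids, None
    valley = float(grid[region][np.argmin(dens[region])])
    # a valley at the region edge means density is still falling: no second peak
    if np.isclose(valley, grid[region][-1]):
        second = [m for m in maxima if grid[m] > valley]
        if not second:
            warnings.warn("depth_peak_filter: no second peak; retaining all", stacklevel=2)
            return ids, None
    retained = [lid for lid, dep in zip(ids, depths) if dep < valley]
    return retained, valley
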