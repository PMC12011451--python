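"""Identity and kinship power analysis for a multilocus panel.

Two questions are answered from population allele frequencies alone:

* **Identity** — the probability that two distinct individuals share an
  identical multilocus genotype.  The conservative variant assumes the
  pair are full siblings (PID\\ :sub:`sibs`); per locus

  .. math::

     \\mathrm{PID}_{sib} = 0.25 + 0.5\\sum p_i^2
        + 0.5\\left(\\sum p_i^2\\right)^2 - 0.25\\sum p_i^4

  multiplied across loci (in log space).

* **Kinship** — power of the log-likelihood-ratio test for
  parent-offspring (PO) or full-sibling (FS) versus unrelated pairs.
  Genotype-pair probabilities condition on the number of alleles shared
  identical by descent via the kappa coefficients (1,0,0) / (0,1,0) /
  (0.25,0.5,0.25); genotyping error replaces an observed genotype with a
  fresh Hardy-Weinberg draw with probability epsilon.  False positive
  rates far below 1/n_sims are reached by importance sampling: pairs are
  simulated under the *related* hypothesis and re-weighted by
  P(pair|U)/P(pair|related) = exp(-Lambda).

Microhaplotypes enter simply as multiallelic loci; loci are assumed
unlinked and in Hardy-Weinberg proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

KAPPAS = {
    "UNRELATED": (1.0, 0.0, 0.0),
    "PO": (0.0, 1.0, 0.0),
    "FS": (0.25, 0.5, 0.25),
}


@dataclass
class LocusFrequencies:
    locus_id: str
    alleles: list[str]
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.alleles) != len(self.freqs) or len(self.alleles) < 1:
            raise ValueError(f"{self.locus_id}: alleles/freqs length mismatch or empty")
        if np.any(self.freqs <= 0):
            raise ValueError(f"{self.locus_id}: frequencies must be > 0")
        if abs(float(self.freqs.sum()) - 1.0) > 1e-9:
            raise ValueError(f"{self.locus_id}: frequencies must sum to 1")


@dataclass
class RelationshipModel:
    name: str
    kappas: tuple[float, float, float]

    @classmethod
    def from_name(cls, name: str) -> "RelationshipModel":
        return cls(name, KAPPAS[name])


@dataclass
class PowerCurve:
    relationship: str
    n_loci: int
    error_rate: float
    points: list[tuple[float, float]]  # (FNR, FPR)
    mc_se: list[float] = field(default_factory=list)


# ---------------------------------------------------------------- identity


def _pid_sibs_locus(freqs: np.ndarray) -> float:
    s2 = float(np.sum(freqs**2))
    s4 = float(np.sum(freqs**4))
    return 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4


def _pid_unrelated_locus(freqs: np.ndarray) -> float:
    hom = float(np.sum(freqs**4))
    het = 0.0
    for i in range(len(freqs)):
        for j in range(i + 1, len(freqs)):
            het += (2.0 * freqs[i] * freqs[j]) ** 2
    return hom + het


def pid_sibs(loci: list[LocusFrequencies]) -> float:
    """Multilocus probability of identity between full siblings."""
    if not loci:
        raise ValueError("need >= 1 locus")
    return math.exp(sum(math.log(_pid_sibs_locus(l.freqs)) for l in loci))


def pid_unrelated(loci: list[LocusFrequencies]) -> float:
    """Multilocus probability of identity between unrelated individuals."""
    if not loci:
        raise ValueError("need >= 1 locus")
    return math.exp(sum(math.log(_pid_unrelated_locus(l.freqs)) for l in loci))


def pid_subsample_curve(
    loci: list[LocusFrequencies],
    n_range: list[int] | None = None,
    iterations: int = 1000,
    seed: int = 0,
) -> dict[int, float]:
    """Mean PID_sibs over random locus subsets of each size.

    Subsets are drawn without replacement within each iteration; the mean
    over ``iterations`` draws is returned per subset size.  Emulates panel
    degradation from missing data.
    """
    L = len(loci)
    if n_range is None:
        n_range = list(range(1, L + 1))
    if max(n_range) > L:
        raise ValueError(f"subset size {max(n_range)} exceeds panel size {L}")
    log_pid = np.array([math.log(_pid_sibs_locus(l.freqs)) for l in loci])
    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    for n in n_range:
        if n == L:
            out[n] = float(np.exp(log_pid.sum()))
            continue
        vals = np.empty(iterations)
        for it in range(iterations):
            idx = rng.choice(L, size=n, replace=False)
            vals[it] = np.exp(log_pid[idx].sum())
        out[n] = float(vals.mean())
    return out


# ----------------------------------------------------------------- kinship


def _genotype_index(n_alleles: int) -> list[tuple[int, int]]:
    """Unordered genotypes (i <= j) over allele indices."""
    return [(i, j) for i in range(n_alleles) for j in range(i, n_alleles)]


def _genotype_probs(freqs: np.ndarray, genos: list[tuple[int, int]]) -> np.ndarray:
    return np.array(
        [freqs[i] ** 2 if i == j else 2.0 * freqs[i] * freqs[j] for i, j in genos]
    )


def _transmit_prob(shared: int, g2: tuple[int, int], freqs: np.ndarray) -> float:
    """P(g2 | one allele of g2 is IBD-copied allele `shared`)."""
    i, j = g2
    if i == j:
        return freqs[i] if i == shared else 0.0
    if shared == i:
        return freqs[j]
    if shared == j:
        return freqs[i]
    return 0.0


def pair_probability_tables(
    locus: LocusFrequencies, model: RelationshipModel, error_rate: float = 0.0
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Joint probability matrix over unordered genotype pairs.

    Returns (genotype index list, matrix P with P[g1, g2] =
    P(observe g1, g2 | model, error)).  The error model mixes the true
    pair distribution with independent Hardy-Weinberg draws: with
    probability (1 - eps) an individual's genotype is observed intact,
    with probability eps it is replaced by a random HWE genotype.  Because
    each individual's marginal is HWE under every kappa model, the mixture
    collapses to

        P_obs = (1-eps)^2 * P_model + (1 - (1-eps)^2) * P_HWE (x) P_HWE.
    """
    freqs = locus.freqs
    genos = _genotype_index(len(freqs))
    gp = _genotype_probs(freqs, genos)
    n = len(genos)
    k0, k1, k2 = model.kappas

    p0 = np.outer(gp, gp)
    p2 = np.diag(gp)
    p1 = np.zeros((n, n))
    if k1 > 0:
        for a, g1 in enumerate(genos):
            i, j = g1
            for b, g2 in enumerate(genos):
                if i == j:
                    t = _transmit_prob(i, g2, freqs)
                else:
                    t = 0.5 * _transmit_prob(i, g2, freqs) + 0.5 * _transmit_prob(j, g2, freqs)
                p1[a, b] = gp[a] * t
    p_model = k0 * p0 + k1 * p1 + k2 * p2
    if error_rate > 0.0:
        keep2 = (1.0 - error_rate) ** 2
        p_model = keep2 * p_model + (1.0 - keep2) * p0
    return genos, p_model


def genotype_pair_probability(
    g1: tuple[str, str],
    g2: tuple[str, str],
    locus: LocusFrequencies,
    model: RelationshipModel,
    error_rate: float = 0.0,
) -> float:
    """P(observed unordered genotype pair | relationship model, error)."""
    lookup = {a: k for k, a in enumerate(locus.alleles)}
    try:
        i1 = tuple(sorted(lookup[a] for a in g1))
        i2 = tuple(sorted(lookup[a] for a in g2))
    except KeyError as exc:
        raise ValueError(f"allele {exc} not found at locus {locus.locus_id}") from exc
    genos, table = pair_probability_tables(locus, model, error_rate)
    idx = {g: k for k, g in enumerate(genos)}
    return float(table[idx[i1], idx[i2]])


def _locus_llr_tables(
    loci: list[LocusFrequencies], model: RelationshipModel, error_rate: float
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-locus flattened (related pair probs, log-likelihood ratios)."""
    unrelated = RelationshipModel.from_name("UNRELATED")
    p_rel_flat: list[np.ndarray] = []
    llr_flat: list[np.ndarray] = []
    for locus in loci:
        _, p_rel = pair_probability_tables(locus, model, error_rate)
        _, p_un = pair_probability_tables(locus, unrelated, error_rate)
        pr = p_rel.ravel()
        pu = p_un.ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            llr = np.where(pr > 0, np.log(pr) - np.log(pu), -np.inf)
        p_rel_flat.append(pr)
        llr_flat.append(llr)
    return p_rel_flat, llr_flat


def _simulate_lambda(
    p_rel_flat: list[np.ndarray],
    llr_flat: list[np.ndarray],
    n_sims: int,
    rng: np.random.Generator,
) -> np.ndarray:
    lam = np.zeros(n_sims)
    for pr, llr in zip(p_rel_flat, llr_flat):
        idx = rng.choice(len(pr), size=n_sims, p=pr / pr.sum())
        lam += llr[idx]
    return lam


def fpr_at_fnr(
    loci: list[LocusFrequencies],
    model: RelationshipModel | str,
    error_rate: float = 0.0039,
    fnr_grid: list[float] | None = None,
    n_sims: int = 100_000,
    seed: int = 0,
) -> PowerCurve:
    """Monte-Carlo FPR of the kinship likelihood-ratio test at given FNRs.

    Lambda = sum over loci of log[P(pair|related)/P(pair|unrelated)].  The
    FNR-quantile of Lambda under the related hypothesis sets the decision
    threshold (related pairs below it are the false negatives); the FPR is
    the probability an unrelated pair reaches the threshold, estimated by
    importance sampling from the related distribution with weights
    exp(-Lambda), so FPRs many orders below 1/n_sims remain estimable.
    """
    if isinstance(model, str):
        model = RelationshipModel.from_name(model)
    if not loci:
        raise ValueError("need >= 1 locus")
    if fnr_grid is None:
        fnr_grid = [0.3, 0.2, 0.1, 0.05, 0.01]
    p_rel_flat, llr_flat = _locus_llr_tables(loci, model, error_rate)
    if all(len(pr) == 1 for pr in p_rel_flat):
        raise ValueError("all loci monomorphic; likelihood ratio is degenerate")
    rng = np.random.default_rng(seed)
    lam_thr = _simulate_lambda(p_rel_flat, llr_flat, n_sims, rng)  # threshold batch
    lam_is = _simulate_lambda(p_rel_flat, llr_flat, n_sims, rng)  # estimation batch
    log_w = -lam_is  # P_U / P_rel per simulated pair
    points: list[tuple[float, float]] = []
    ses: list[float] = []
    for fnr in fnr_grid:
        thr = float(np.quantile(lam_thr, fnr))
        contrib = np.where(lam_is >= thr, np.exp(log_w), 0.0)
        fpr = float(contrib.mean())
        se = float(contrib.std(ddof=1) / math.sqrt(n_sims))
        points.append((fnr, fpr))
        ses.append(se)
    return PowerCurve(
        relationship=model.name,
        n_loci=len(loci),
        error_rate=error_rate,
        points=points,
        mc_se=ses,
    )


def fpr_direct(
    loci: list[LocusFrequencies],
    model: RelationshipModel | str,
    error_rate: float,
    threshold: float,
    n_sims: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Plain Monte-Carlo FPR: simulate unrelated pairs, count Lambda >= thr.

    Cross-check for the importance-sampling estimator; only useful when
    the FPR is within reach of n_sims.
    """
    if isinstance(model, str):
        model = RelationshipModel.from_name(model)
    unrelated = RelationshipModel.from_name("UNRELATED")
    p_un_flat, llr_flat = [], []
    for locus in loci:
        _, p_rel = pair_probability_tables(locus, model, error_rate)
        _, p_un = pair_probability_tables(locus, unrelated, error_rate)
        pr, pu = p_rel.ravel(), p_un.ravel()
        with np.errstate(divide="ignore"):
            llr = np.where(pu > 0, np.log(np.maximum(pr, 1e-300)) - np.log(pu), 0.0)
        p_un_flat.append(pu)
        llr_flat.append(llr)
    rng = np.random.default_rng(seed)
    lam = np.zeros(n_sims)
    for pu, llr in zip(p_un_flat, llr_flat):
        idx = rng.choice(len(pu), size=n_sims, p=pu / pu.sum())
        lam += llr[idx]
    hits = lam >= threshold
    fpr = float(hits.mean())
    se = float(hits.std(ddof=1) / math.sqrt(n_sims))
    return fpr, se


def related_lambda_threshold(
    loci: list[LocusFrequencies],
    model: RelationshipModel | str,
    error_rate: float,
    fnr: float,
    n_sims: int = 100_000,
    seed: int = 0,
) -> float:
    """FNR-quantile of Lambda under the related hypothesis (the threshold)."""
    if isinstance(model, str):
        model = RelationshipModel.from_name(model)
    p_rel_flat, llr_flat = _locus_llr_tables(loci, model, error_rate)
    rng = np.random.default_rng(seed)
    lam = _simulate_lambda(p_rel_flat, llr_flat, n_sims, rng)
    return float(np.quantile(lam, fnr))


def subsample_fpr(
    loci: list[LocusFrequencies],
    fractions: list[float],
    model: RelationshipModel | str = "PO",
    error_rate: float = 0.0039,
    fnr: float = 0.01,
    n_sims: int = 100_000,
    seed: int = 0,
) -> dict[float, tuple[int, float, float]]:
    """FPR at one FNR when randomly retaining a fraction of the panel.

    Returns fraction -> (subset size, FPR, mc_se).  Subset size is
    fraction * L rounded half-up (so 25% of 194 is 49); a fraction
    yielding zero loci is an error.
    """
    L = len(loci)
    rng = np.random.default_rng(seed)
    out: dict[float, tuple[int, float, float]] = {}
    for frac in fractions:
        n = int(math.floor(frac * L + 0.5))
        if n < 1:
            raise ValueError(f"fraction {frac} leaves no loci from panel of {L}")
        idx = sorted(rng.choice(L, size=n, replace=False)) if n < L else list(range(L))
        subset = [loci[i] for i in idx]
        curve = fpr_at_fnr(
            subset, model, error_rate, fnr_grid=[fnr], n_sims=n_sims,
            seed=int(rng.integers(2**31 - 1)),
        )
        out[frac] = (n, curve.points[0][1], curve.mc_se[0])
    return out


def frequencies_from_genotypes(
    genotypes: dict[str, dict[str, tuple[str, str]]],
) -> list[LocusFrequencies]:
    """Empirical allele frequencies from a sample -> locus -> allele-pair map."""
    from collections import Counter

    per_locus: dict[str, Counter] = {}
    for _, loci in genotypes.items():
        for locus_id, pair in loci.items():
            if pair is None:
                continue
            per_locus.setdefault(locus_id, Counter()).update(pair)
    out = []
    for locus_id in sorted(per_locus):
        counts = per_locus[locus_id]
        total = sum(counts.values())
        alleles = sorted(counts)
        freqs = np.array([counts[a] / total for a in alleles])
        out.append(LocusFrequencies(locus_id, alleles, freqs))
    return out
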