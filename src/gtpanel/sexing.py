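"""Genetic sex inference from Y-chromosome marker read counts.

Males carry the Y-linked amplicons, so a male sample should devote a small,
roughly constant fraction of its on-target reads to each sex marker (0.005
for ddx3Y, 0.003 for usp9Y in the shipped panel).  The observed/expected
read ratio therefore sits near 1 for males and near 0 for females; ratios
in the dead zone between 0.1 and 0.2, or markers with too little depth to
judge, are left unassigned.  A sample's sex is reported only when both
markers are called and agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

MALE = "M"
FEMALE = "F"
UNASSIGNED = "UNASSIGNED"
CONFLICT = "CONFLICT"
NOT_GENOTYPED = "NOT_GENOTYPED"

DEFAULT_MARKERS = {"ddx3Y": 0.005, "usp9Y": 0.003}


@dataclass
class SexMarkerSpec:
    marker_id: str
    expected_male_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 < self.expected_male_fraction < 1.0):
            raise ValueError("expected_male_fraction must be in (0, 1)")


@dataclass
class MarkerCall:
    marker_id: str
    observed_reads: int
    expected_reads: float
    ratio: float | None
    call: str


@dataclass
class SexCall:
    sample_id: str
    markers: dict[str, MarkerCall] = field(default_factory=dict)
    consensus: str = UNASSIGNED
    reason: str | None = None  # CONFLICT | NOT_GENOTYPED when unassigned


def call_marker(
    total_on_target: int,
    marker_reads: int,
    spec: SexMarkerSpec,
    min_depth: int = 10,
    low_thr: float = 0.1,
    high_thr: float = 0.2,
) -> MarkerCall:
    """Call one sex marker from its read tally.

    expected = total_on_target x expected_male_fraction; ratio =
    observed / expected.  Ratio > ``high_thr`` -> male, < ``low_thr`` ->
    female, in between -> unassigned.  The depth gate leaves the marker
    unassigned when both the observed count and the expected count fall
    below ``min_depth`` — a female legitimately has ~0 observed reads, so
    a large *expected* count is enough evidence to call F.
    """
    expected = total_on_target * spec.expected_male_fraction
    if total_on_target == 0 or expected == 0:
        return MarkerCall(spec.marker_id, marker_reads, expected, None, UNASSIGNED)
    if marker_reads < min_depth and expected < min_depth:
        return MarkerCall(spec.marker_id, marker_reads, expected, None, UNASSIGNED)
    ratio = marker_reads / expected
    if ratio > high_thr:
        call = MALE
    elif ratio < low_thr:
        call = FEMALE
    else:
        call = UNASSIGNED
    return MarkerCall(spec.marker_id, marker_reads, expected, ratio, call)


def consensus_sex(calls: dict[str, MarkerCall], sample_id: str = "") -> SexCall:
    """Dual-marker consensus: both markers must be called and agree."""
    sexes = [c.call for c in calls.values()]
    sc = SexCall(sample_id=sample_id, markers=dict(calls))
    if UNASSIGNED in sexes:
        sc.consensus, sc.reason = UNASSIGNED, NOT_GENOTYPED
    elif len(set(sexes)) > 1:
        sc.consensus, sc.reason = UNASSIGNED, CONFLICT
    else:
        sc.consensus = sexes[0]
    return sc


def call_sample(
    sample_id: str,
    total_on_target: int,
    marker_reads: dict[str, int],
    marker_specs: dict[str, float] | None = None,
    min_depth: int = 10,
    low_thr: float = 0.1,
    high_thr: float = 0.2,
) -> SexCall:
    """Convenience wrapper: per-marker calls plus consensus for one sample."""
    specs = marker_specs if marker_specs is not None else DEFAULT_MARKERS
    calls = {
        mid: call_marker(
            total_on_target,
            marker_reads.get(mid, 0),
            SexMarkerSpec(mid, frac),
            min_depth=min_depth,
            low_thr=low_thr,
            high_thr=high_thr,
        )
        for mid, frac in specs.items()
    }
    return consensus_sex(calls, sample_id=sample_id)


def call_from_tallies(tallies: pd.DataFrame, **kwargs) -> list[SexCall]:
    """Vector form over a tally table.

    Expects columns ``sample_id``, ``total_on_target`` and one
    ``<marker>_reads`` column per sex marker (e.g. ``ddx3Y_reads``).
    """
    specs = kwargs.pop("marker_specs", None) or DEFAULT_MARKERS
    out = []
    for _, row in tallies.sort_values("sample_id").iterrows():
        reads = {mid: int(row[f"{mid}_reads"]) for mid in specs}
        out.append(
            call_sample(
                str(row["sample_id"]),
                int(row["total_on_target"]),
                reads,
                marker_specs=specs,
                **kwargs,
            )
        )
    return out


def evaluate_concordance(
    sex_calls: list[SexCall], field_sex: dict[str, str]
) -> dict[str, float | int]:
    """Compare marker-based sex to field-assigned sex.

    Samples without a field sex are excluded from every denominator.
    ``accuracy_assigned`` is matches over samples with a consensus call;
    ``accuracy_overall`` is matches over all evaluated samples.
    """
    n_total = 0
    n_conflict = 0
    n_not_genotyped = 0
    n_assigned = 0
    n_match = 0
    for sc in sex_calls:
        truth = field_sex.get(sc.sample_id)
        if truth not in (MALE, FEMALE):
            continue
        n_total += 1
        if sc.consensus == UNASSIGNED:
            if sc.reason == CONFLICT:
                n_conflict += 1
            else:
                n_not_genotyped += 1
            continue
        n_assigned += 1
        if sc.consensus == truth:
            n_match += 1
    return {
        "n_total": n_total,
        "n_unassigned": n_conflict + n_not_genotyped,
        "n_conflict": n_conflict,
        "n_not_genotyped": n_not_genotyped,
        "n_assigned": n_assigned,
        "n_match": n_match,
        "accuracy_assigned": n_match / n_assigned if n_assigned else float("nan"),
        "accuracy_overall": n_match / n_total if n_total else float("nan"),
    }
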