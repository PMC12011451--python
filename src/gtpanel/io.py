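"""Readers and writers for the formats the toolkit exchanges.

VCF parsing goes through cyvcf2, FASTA/FASTQ through Biopython (gzip
aware), SAM through pysam (see :func:`gtpanel.genotyper.reads_from_sam`).
All writers emit deterministically ordered output (sample then locus,
lexicographic) so repeated runs are byte-identical.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotyper import GenotypeCall, PanelDefinition, PanelLocus, ReplicateGroup, MISSING, PASS
from .panel_design import CandidateSnp
from .power import LocusFrequencies


# ---------------------------------------------------------------------- VCF


def read_vcf_candidates(
    vcf_path: str, pop_map: dict[str, str] | None = None
) -> tuple[list[CandidateSnp], np.ndarray, list[str]]:
    """Load biallelic SNPs from a VCF as candidates plus a dosage matrix.

    Returns (snps, loci x samples alt-dosage matrix with -1 for missing,
    sample ids).  ``pop_map`` (sample -> population) fills per-population
    alt frequencies when given.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    snps: list[CandidateSnp] = []
    rows: list[np.ndarray] = []
    dosage_of = {0: 0, 1: 1, 3: 2, 2: -1}  # cyvcf2 gt_types -> alt dosage
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        dos = np.array([dosage_of[t] for t in var.gt_types], dtype=float)
        called = dos >= 0
        n_called = int(called.sum())
        alt = float(dos[called].sum() / (2 * n_called)) if n_called else 0.0
        per_pop: dict[str, float] = {}
        if pop_map:
            for pop in sorted(set(pop_map.values())):
                members = [i for i, s in enumerate(samples) if pop_map.get(s) == pop]
                sub = dos[members]
                sub = sub[sub >= 0]
                per_pop[pop] = float(sub.sum() / (2 * len(sub))) if len(sub) else 0.0
        try:
            depth = var.format("DP")
        except KeyError:
            depth = None
        mean_depth = float(np.nanmean(depth)) if depth is not None else 0.0
        snps.append(
            CandidateSnp(
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                maf=min(alt, 1.0 - alt),
                missingness=1.0 - n_called / len(samples),
                per_pop_freq=per_pop,
                mean_depth=mean_depth,
            )
        )
        rows.append(dos)
    geno = np.vstack(rows) if rows else np.empty((0, len(samples)))
    return snps, geno, samples


def write_minimal_vcf(path: str, panel: PanelDefinition) -> None:
    """Minimal VCF of per-locus SNP positions (1-based on the amplicon)."""
    lines = ["##fileformat=VCFv4.2"]
    for locus in sorted(panel, key=lambda l: l.locus_id):
        lines.append(f"##contig=<ID={locus.locus_id},length={len(locus.reference)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for locus in sorted(panel, key=lambda l: l.locus_id):
        for off in locus.snp_offsets:
            ref = locus.reference[off]
            lines.append(
                f"{locus.locus_id}\t{off + 1}\t.\t{ref}\t.\t.\tPASS\t."
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------- FASTA/FASTQ


def _open_maybe_gz(path: str, mode: str = "rt"):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


def read_fastq(path: str) -> list[tuple[str, list[int]]]:
    """Reads (sequence, phred qualities) from a FASTQ file (.gz ok)."""
    from Bio import SeqIO

    out = []
    with _open_maybe_gz(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            out.append((str(rec.seq), list(rec.letter_annotations["phred_quality"])))
    return out


def write_fastq(path: str, reads: list[tuple[str, list[int]]], prefix: str = "read") -> None:
    with _open_maybe_gz(path, "wt") as fh:
        for i, (seq, quals) in enumerate(reads):
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{prefix}_{i + 1}\n{seq}\n+\n{qstr}\n")


def write_panel_fasta(path: str, panel: PanelDefinition) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(l.reference), id=l.locus_id, description="")
        for l in sorted(panel, key=lambda l: l.locus_id)
    ]
    SeqIO.write(records, path, "fasta")


def read_panel(csv_path: str, fasta_path: str) -> PanelDefinition:
    """Panel definition from a CSV plus a reference FASTA.

    CSV columns: locus_id, probe, snp_offsets (semicolon-joined 0-based),
    marker_class.
    """
    from Bio import SeqIO

    refs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}
    df = pd.read_csv(csv_path, dtype={"locus_id": str, "probe": str})
    loci = []
    for _, row in df.iterrows():
        offsets = (
            [int(x) for x in str(row["snp_offsets"]).split(";") if x not in ("", "nan")]
            if not pd.isna(row["snp_offsets"])
            else []
        )
        loci.append(
            PanelLocus(
                locus_id=row["locus_id"],
                reference=refs[row["locus_id"]],
                probe=row["probe"],
                snp_offsets=offsets,
                marker_class=row.get("marker_class", "diversity"),
            )
        )
    return PanelDefinition(loci=loci)


def write_panel(csv_path: str, fasta_path: str, panel: PanelDefinition) -> None:
    write_panel_fasta(fasta_path, panel)
    rows = [
        {
            "locus_id": l.locus_id,
            "probe": l.probe,
            "snp_offsets": ";".join(str(o) for o in l.snp_offsets),
            "marker_class": l.marker_class,
        }
        for l in sorted(panel, key=lambda l: l.locus_id)
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)


# -------------------------------------------------------------- CSV tables


def read_population_map(path: str) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df["sample_id"], df["population"]))


def read_plate_map(path: str) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Plate map CSV (sample_id, plate, role) -> (sample -> plate,
    plate -> negative-control sample ids)."""
    df = pd.read_csv(path, dtype=str)
    plate_of = dict(zip(df["sample_id"], df["plate"]))
    negatives: dict[str, list[str]] = {}
    for _, row in df[df["role"].str.upper() == "NEGATIVE"].iterrows():
        negatives.setdefault(row["plate"], []).append(row["sample_id"])
    return plate_of, negatives


def read_replicate_groups(path: str) -> list[ReplicateGroup]:
    """Replicate table CSV: group_id, sample_id, sample_type."""
    df = pd.read_csv(path, dtype=str)
    groups = []
    for gid, sub in df.groupby("group_id", sort=True):
        groups.append(
            ReplicateGroup(
                group_id=str(gid),
                sample_ids=list(sub["sample_id"]),
                sample_types=dict(zip(sub["sample_id"], sub["sample_type"])),
            )
        )
    return groups


def write_genotype_matrix(path: str, calls: list[GenotypeCall]) -> None:
    """Sample x locus CSV with alleles as "AC/GT"; missing cells empty."""
    samples = sorted({c.sample_id for c in calls})
    loci = sorted({c.locus_id for c in calls})
    table = {(c.sample_id, c.locus_id): c for c in calls}
    rows = []
    for s in samples:
        row: dict[str, str] = {"sample_id": s}
        for l in loci:
            c = table.get((s, l))
            row[l] = "" if c is None or c.is_missing else f"{c.allele1}/{c.allele2}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_genotype_matrix(path: str) -> list[GenotypeCall]:
    df = pd.read_csv(path, dtype=str).fillna("")
    calls = []
    loci = [c for c in df.columns if c != "sample_id"]
    for _, row in df.iterrows():
        for l in loci:
            cell = row[l]
            if cell:
                a1, a2 = cell.split("/")
                calls.append(GenotypeCall(row["sample_id"], l, a1, a2, 0, None, PASS))
            else:
                calls.append(GenotypeCall(row["sample_id"], l, MISSING, MISSING, 0, None, "LOW_DEPTH"))
    return calls


def write_frequencies(path: str, loci: list[LocusFrequencies]) -> None:
    rows = []
    for lf in sorted(loci, key=lambda l: l.locus_id):
        for a, f in zip(lf.alleles, lf.freqs):
            rows.append({"locus_id": lf.locus_id, "allele": a, "freq": float(f)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_frequencies(path: str) -> list[LocusFrequencies]:
    df = pd.read_csv(path, dtype={"locus_id": str, "allele": str})
    out = []
    for lid, sub in df.groupby("locus_id", sort=True):
        out.append(
            LocusFrequencies(str(lid), list(sub["allele"]), sub["freq"].to_numpy(dtype=float))
        )
    return out


def write_json_report(path: str, report: dict) -> None:
    """Machine-readable run report (inputs, thresholds, per-filter counts)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
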