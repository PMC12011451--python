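"""Microhaplotype calling, filter contracts, replicate error rates."""

import itertools
from collections import Counter

import numpy as np
import pytest

from gtpanel.genotyper import (
    AMBIGUOUS,
    LOW_DEPTH,
    MISSING,
    NEG_CONTROL,
    PASS,
    GenotypeCall,
    HaplotypeCounts,
    PanelDefinition,
    PanelLocus,
    ReplicateGroup,
    assign_reads,
    call_genotype,
    discover_panel_variants,
    estimate_error_rate,
    extract_haplotypes,
    locus_qc,
    reads_from_sam,
    sample_summary,
)
from gtpanel import synth


def make_locus(locus_id="LOC1", ref=None, offsets=(25, 35)):
    ref = ref or ("ACGTACGTACGTACGTACGT" + "C" * 30)
    return PanelLocus(locus_id, ref, ref[:20], list(offsets))


def hc(counts, sample="s1", locus="LOC1", total=None):
    t = total if total is not None else sum(counts.values())
    return HaplotypeCounts(sample, locus, counts, t, t)


class TestAssignReads:
    def setup_method(self):
        refa = "ACGTACGTACGTACGTACGT" + "A" * 30
        refb = "TTTTGGGGCCCCAAAATTGG" + "G" * 30
        self.panel = PanelDefinition(
            [
                PanelLocus("A", refa, refa[:20], [30]),
                PanelLocus("B", refb, refb[:20], [30]),
            ]
        )

    def test_exact_probe_assigned(self):
        read = self.panel.get("A").reference
        asn = assign_reads([(read, [40] * len(read))], self.panel)
        assert len(asn.bins["A"]) == 1 and len(asn.bins["B"]) == 0
        assert asn.n_assigned == 1

    def test_no_probe_unassigned(self):
        read = "C" * 50
        asn = assign_reads([(read, [40] * 50)], self.panel)
        assert asn.n_assigned == 0 and asn.n_ambiguous == 0

    def test_double_probe_hit_is_ambiguous(self):
        read = self.panel.get("A").probe + self.panel.get("B").probe
        asn = assign_reads([(read, [40] * len(read))], self.panel)
        assert asn.n_ambiguous == 1 and asn.n_assigned == 0

    def test_one_mismatch_tolerated(self):
        ref = self.panel.get("A").reference
        read = "G" + ref[1:]
        asn = assign_reads([(read, [40] * len(read))], self.panel)
        assert len(asn.bins["A"]) == 1

    def test_on_target_fraction_matches_synth_truth(self, small_config):
        pops, _ = synth.simulate_frequencies(small_config)
        freqs = pops["pop1"]
        truth = synth.simulate_cohort(small_config, freqs, n_founders=2)
        panel = synth.make_panel(small_config, freqs, include_sex_markers=False)
        sim = synth.simulate_reads(truth, panel, small_config, samples=["F001"])
        asn = assign_reads(sim.reads["F001"], panel, sample_id="F001")
        want = sim.true_on_target["F001"]
        n = len(sim.reads["F001"])
        tol = 3 * np.sqrt(want * (1 - want) / n) + 0.02
        assert abs(asn.on_target_fraction - want) < tol


class TestExtractHaplotypes:
    def test_counts_by_offset_bases(self):
        locus = make_locus()
        reads = []
        for _ in range(30):
            seq = list(locus.reference)
            seq[25], seq[35] = "A", "C"
            reads.append(("".join(seq), [40] * len(seq), 0))
        for _ in range(10):
            seq = list(locus.reference)
            seq[25], seq[35] = "G", "T"
            reads.append(("".join(seq), [40] * len(seq), 0))
        out = extract_haplotypes(reads, locus)
        assert out.counts == {"AC": 30, "GT": 10}

    def test_truncated_read_excluded_but_counted_on_target(self):
        locus = make_locus()
        short = (locus.reference[:30], [40] * 30, 0)
        out = extract_haplotypes([short], locus)
        assert out.counts == {}
        assert out.total_on_target == 1

    def test_low_quality_base_excludes_read(self):
        locus = make_locus()
        seq = locus.reference
        quals = [40] * len(seq)
        quals[35] = 5
        out = extract_haplotypes([(seq, quals, 0)], locus)
        assert out.counts == {}

    def test_homozygote_dominates_with_low_error(self, small_config):
        cfg = small_config
        rng = np.random.default_rng(1)
        locus = make_locus()
        reads = []
        for _ in range(500):
            seq = list(locus.reference)
            seq[25], seq[35] = "A", "C"
            seq = [
                b if rng.random() > 0.01 else "ACGT"[rng.integers(4)] for b in seq
            ]
            reads.append(("".join(seq), [40] * len(seq), 0))
        out = extract_haplotypes(reads, locus)
        assert out.counts.get("AC", 0) >= 0.95 * sum(out.counts.values())


class TestCallGenotype:
    def test_het_above_ratio(self):
        call = call_genotype(hc({"AC": 30, "GT": 4}), neg_control_depth=0)
        assert call.filter_status == PASS
        assert {call.allele1, call.allele2} == {"AC", "GT"}
        assert call.allelic_ratio == pytest.approx(4 / 34)

    def test_hom_below_ratio(self):
        call = call_genotype(hc({"AC": 30, "GT": 2}), neg_control_depth=0)
        assert (call.allele1, call.allele2) == ("AC", "AC")
        assert call.filter_status == PASS

    def test_negative_control_rule(self):
        call = call_genotype(hc({"AC": 30, "GT": 4}), neg_control_depth=20)
        assert call.filter_status == NEG_CONTROL and call.is_missing

    def test_low_depth(self):
        call = call_genotype(hc({"AC": 10}))
        assert call.filter_status == LOW_DEPTH

    def test_empty_counts_low_depth(self):
        call = call_genotype(hc({}))
        assert call.filter_status == LOW_DEPTH

    def test_third_haplotype_above_ratio_ambiguous(self):
        call = call_genotype(hc({"AC": 30, "GT": 10, "AG": 10}))
        assert call.filter_status == AMBIGUOUS and call.is_missing

    def test_n_haplotypes_never_callable(self):
        call = call_genotype(hc({"NN": 100, "AC": 25}))
        assert call.allele1 == "AC" and call.depth == 25

    def test_permutation_invariance(self, rng):
        for _ in range(100):
            haps = ["AC", "GT", "AG", "CT"]
            counts = {h: int(c) for h, c in zip(haps, rng.integers(0, 60, 4)) if c > 0}
            neg = int(rng.integers(0, 10))
            calls = []
            for perm in itertools.islice(itertools.permutations(counts.items()), 4):
                calls.append(call_genotype(hc(dict(perm)), neg_control_depth=neg))
            first = calls[0]
            assert all(
                (c.allele1, c.allele2, c.filter_status) ==
                (first.allele1, first.allele2, first.filter_status)
                for c in calls
            )

    def test_pass_contract_fuzz(self, rng):
        for _ in range(2000):
            counts = {
                h: int(c)
                for h, c in zip(["AC", "GT", "AG"], rng.integers(0, 80, 3))
                if c > 0
            }
            neg = int(rng.integers(0, 20))
            call = call_genotype(hc(counts), neg_control_depth=neg)
            if call.filter_status == PASS:
                assert call.depth >= 20
                assert call.depth > 2 * neg
                if call.allele1 != call.allele2:
                    minor = min(counts[call.allele1], counts[call.allele2])
                    assert minor / call.depth >= 0.1


class TestDiscoverPanelVariants:
    def test_rare_allele_excluded(self):
        pile = {10: Counter({"A": 995, "G": 5})}  # MAF 0.005 < 0.006
        assert discover_panel_variants(pile, "A" * 50) == []

    def test_primer_site_excluded(self):
        pile = {10: Counter({"A": 700, "G": 300})}
        assert discover_panel_variants(pile, "A" * 50, primer_mask=[(0, 19)]) == []

    def test_planted_snp_detected(self):
        pile = {
            10: Counter({"A": 700, "G": 300}),
            20: Counter({"C": 999, "T": 1}),  # sequencing noise
        }
        assert discover_panel_variants(pile, "A" * 50) == [10]

    def test_triallelic_site_skipped(self):
        pile = {10: Counter({"A": 500, "G": 300, "T": 200})}
        assert discover_panel_variants(pile, "A" * 50) == []


def _pass_call(sample, locus, a1, a2):
    return GenotypeCall(sample, locus, a1, a2, 50, None, PASS)


class TestErrorRate:
    def test_identical_replicates_zero(self):
        calls = [_pass_call(s, l, "AC", "AC") for s in ("a", "b") for l in ("L1", "L2")]
        groups = [ReplicateGroup("g", ["a", "b"], {"a": "blood", "b": "blood"})]
        res = estimate_error_rate(calls, groups)
        assert res.rate == 0.0 and res.comparisons == 2

    def test_three_member_group_pair_counting(self):
        # one discordant member at one locus: 2 mismatching pairs of 3
        calls = [
            _pass_call("a", "L1", "AC", "AC"),
            _pass_call("b", "L1", "AC", "AC"),
            _pass_call("c", "L1", "GT", "GT"),
        ]
        groups = [ReplicateGroup("g", ["a", "b", "c"])]
        res = estimate_error_rate(calls, groups)
        assert (res.mismatches, res.comparisons) == (2, 3)

    def test_unordered_genotype_comparison(self):
        calls = [_pass_call("a", "L1", "AC", "GT"), _pass_call("b", "L1", "GT", "AC")]
        res = estimate_error_rate(calls, [ReplicateGroup("g", ["a", "b"])])
        assert res.mismatches == 0

    def test_missing_calls_not_compared(self):
        calls = [
            _pass_call("a", "L1", "AC", "AC"),
            GenotypeCall("b", "L1", MISSING, MISSING, 0, None, LOW_DEPTH),
        ]
        with pytest.raises(ValueError, match="no comparable"):
            estimate_error_rate(calls, [ReplicateGroup("g", ["a", "b"])])

    def test_matches_bruteforce_oracle_and_symmetry(self, rng):
        alleles = ["AA", "AB", "BB"]
        for _ in range(20):
            samples = [f"s{i}" for i in range(5)]
            loci = [f"L{i}" for i in range(4)]
            calls = []
            table = {}
            for s in samples:
                for l in loci:
                    if rng.random() < 0.2:
                        calls.append(GenotypeCall(s, l, MISSING, MISSING, 0, None, LOW_DEPTH))
                    else:
                        g = alleles[rng.integers(3)]
                        calls.append(_pass_call(s, l, g, g))
                        table[(s, l)] = g
            groups = [
                ReplicateGroup("g1", samples[:3]),
                ReplicateGroup("g2", samples[3:]),
            ]
            res = estimate_error_rate(calls, groups)
            # brute force: enumerate every within-group pair at every locus
            mism = comp = 0
            for grp in groups:
                for l in loci:
                    members = [s for s in grp.sample_ids if (s, l) in table]
                    for x, y in itertools.combinations(members, 2):
                        comp += 1
                        mism += table[(x, l)] != table[(y, l)]
            assert (res.mismatches, res.comparisons) == (mism, comp)
            # symmetry under replicate order
            groups_rev = [
                ReplicateGroup("g1", samples[:3][::-1]),
                ReplicateGroup("g2", samples[3:][::-1]),
            ]
            res2 = estimate_error_rate(calls, groups_rev)
            assert (res2.mismatches, res2.comparisons) == (mism, comp)


class TestLocusQc:
    def test_reason_codes_and_boundary(self):
        retained, dropped = locus_qc(
            {"L1": 0.06, "L2": 0.05, "L3": 0.0},
            {"L1": 0.5, "L2": 0.5, "L3": 0.09},
        )
        assert dropped == {"L1": "ERROR_RATE", "L3": "OFF_TARGET"}
        assert retained == ["L2"]  # exactly 5% error is retained (rule is strict >)


class TestSampleSummary:
    def test_half_genotyped(self):
        calls = [_pass_call("s1", f"L{i}", "A", "A") for i in range(97)]
        df = sample_summary(calls, {}, panel_size=194)
        assert df.loc[0, "pct_loci_genotyped"] == pytest.approx(50.0)


class TestSamIngestion:
    def test_sam_reads_round_trip_to_haplotypes(self, tmp_path):
        locus = make_locus("LOC1")
        seq = list(locus.reference)
        seq[25], seq[35] = "G", "T"
        seq = "".join(seq)
        sam = tmp_path / "reads.sam"
        qual = "I" * len(seq)
        sam.write_text(
            "@HD\tVN:1.6\n"
            f"@SQ\tSN:LOC1\tLN:{len(locus.reference)}\n"
            "@RG\tID:rg1\tSM:sampleX\n"
            f"r1\t0\tLOC1\t1\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t{qual}\tRG:Z:rg1\n"
            f"r2\t0\tLOC1\t1\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t{qual}\tRG:Z:rg1\n"
        )
        binned = reads_from_sam(str(sam), PanelDefinition([locus]))
        out = extract_haplotypes(binned["sampleX"]["LOC1"], locus, sample_id="sampleX")
        assert out.counts == {"GT": 2}


class TestEndToEndRecovery:
    def test_noiseless_reads_recover_truth_exactly(self):
        cfg = synth.SimConfig(seed=21, n_loci=8, per_base_error=0.0,
                              contamination_rate=0.0, depth_mean=40.0,
                              on_target_fraction=1.0)
        pops, _ = synth.simulate_frequencies(cfg)
        freqs = pops["pop1"]
        truth = synth.simulate_cohort(cfg, freqs, n_founders=3)
        panel = synth.make_panel(cfg, freqs, include_sex_markers=False)
        sim = synth.simulate_reads(truth, panel, cfg)
        for sample in truth.genotypes:
            asn = assign_reads(sim.reads[sample], panel, sample_id=sample)
            for locus in panel:
                out = extract_haplotypes(asn.bins[locus.locus_id], locus, sample_id=sample)
                call = call_genotype(out)
                if call.filter_status == PASS:
                    want = truth.genotypes[sample][locus.locus_id]
                    assert (call.allele1, call.allele2) == want
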