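"""Filter cascade, consequence classification, privacy, adjudication."""

import numpy as np
import pytest
from Bio.Seq import Seq

from b6compare.simulate import VariantSimConfig, generate_variant_callsets
from b6compare.variants import (
    FilterThresholds,
    TranscriptModel,
    ValidationAssay,
    VariantCall,
    adjudicate_assay,
    apply_quality_filters,
    assess_privacy,
    classify_consequence,
    curation_flags,
    read_vcf,
    subtract_reference_calls,
    summarize_validation,
    write_vcf,
)


def call(chrom="1", pos=100, ref="A", alt="G", depth=40, ratio=1.0):
    return VariantCall(chrom, pos, ref, alt, depth, ratio)


class TestSubtraction:
    def test_shared_call_removed(self):
        shared = call()
        assert subtract_reference_calls([shared], [shared]) == []

    def test_empty_reference_is_identity(self):
        calls = [call(pos=p) for p in (1, 2, 3)]
        assert subtract_reference_calls(calls, []) == calls

    def test_planted_shared_keys(self):
        rng = np.random.default_rng(0)
        focal = [call(pos=int(p)) for p in rng.choice(10_000, 100, replace=False)]
        shared = [focal[i] for i in rng.choice(100, 30, replace=False)]
        result = subtract_reference_calls(focal, shared)
        # independent set-difference oracle
        expect = [c for c in focal if c.key() not in {s.key() for s in shared}]
        assert result == expect and len(result) == 70

    def test_duplicate_focal_warns_first_kept(self):
        c = call()
        with pytest.warns(UserWarning, match="duplicate"):
            out = subtract_reference_calls([c, c], [])
        assert out == [c]

    def test_indel_spelling_normalized_for_keying(self):
        # ATT>A and padded CATT>CA describe the same deletion
        a = call(pos=10, ref="ATT", alt="A")
        b = call(pos=9, ref="CATT", alt="CA")
        assert a.key() == b.key()
        assert subtract_reference_calls([a], [b]) == []


class TestQualityFilters:
    def test_boundaries_pass_strict_inequalities(self):
        retained, removed = apply_quality_filters(
            [call(ratio=0.8, depth=3), call(ratio=0.8, depth=150)]
        )
        assert len(retained) == 2 and not removed

    @pytest.mark.parametrize(
        "ratio,depth,reason",
        [(0.79, 40, "heterozygous"), (1.0, 2, "low_depth"),
         (1.0, 151, "high_depth"), (0.5, 2, "heterozygous")],  # ratio precedes depth
    )
    def test_removal_reasons(self, ratio, depth, reason):
        _, removed = apply_quality_filters([call(ratio=ratio, depth=depth)])
        assert removed[0][1] == reason

    def test_retained_and_removed_partition_input(self):
        rng = np.random.default_rng(1)
        calls = [
            call(pos=i, ratio=float(rng.uniform(0, 1)),
                 depth=int(rng.integers(0, 300)))
            for i in range(200)
        ]
        retained, removed = apply_quality_filters(calls)
        assert len(retained) + len(removed) == len(calls)
        assert {c.key() for c in retained}.isdisjoint(
            {c.key() for c, _ in removed}
        )

    def test_planted_artifact_composition(self):
        cfg = VariantSimConfig(n_true=78, n_reference_shared=0,
                               n_heterozygous_artifacts=10, n_low_depth=5,
                               n_high_depth=7, seed=11)
        focal, _, truth = generate_variant_callsets(cfg)
        retained, removed = apply_quality_filters(focal)
        assert len(retained) == 78
        reasons = {}
        for _, r in removed:
            reasons[r] = reasons.get(r, 0) + 1
        assert reasons == {"heterozygous": 10, "low_depth": 5, "high_depth": 7}

    def test_cascade_order_invariant(self):
        cfg = VariantSimConfig(seed=3)
        focal, reference, _ = generate_variant_callsets(cfg)
        t = FilterThresholds()
        a, _ = apply_quality_filters(subtract_reference_calls(focal, reference), t)
        filtered, _ = apply_quality_filters(focal, t)
        b = subtract_reference_calls(filtered, reference)
        assert {c.key() for c in a} == {c.key() for c in b}


# ---------------------------------------------------------------------------
# consequence classification


def simple_transcript(strand="+"):
    # genome coordinates 1-based; two exons 11-25 and 41-55, all coding
    genome = "T" * 10 + "ATGGCTCGATGGGGA" + "C" * 15 + "GGATTTCCCAAATAG" + "T" * 10
    exons = ((11, 25), (41, 55))
    cds = genome[10:25] + genome[40:55]
    if strand == "-":
        cds = str(Seq(cds).reverse_complement())
    tm = TranscriptModel("g", "1", strand, exons, 11, 55, cds)
    return genome, tm


class TestClassifyConsequence:
    def test_stop_gained_is_nonsense(self):
        genome, tm = simple_transcript()
        # codon 3 of exon1 is CGA (arg); C>T at its first base makes TGA
        pos = 17
        assert genome[pos - 1] == "C"
        assert classify_consequence(call(pos=pos, ref="C", alt="T"), tm) == "nonsense"

    def test_one_base_cds_deletion_is_frameshift(self):
        genome, tm = simple_transcript()
        v = call(pos=12, ref="TG", alt="T")
        assert classify_consequence(v, tm) == "frameshift"

    def test_three_base_cds_deletion_is_inframe(self):
        genome, tm = simple_transcript()
        v = call(pos=12, ref="TGGC", alt="T")
        assert classify_consequence(v, tm) == "inframe_indel"

    def test_third_position_wobble_is_synonymous(self):
        genome, tm = simple_transcript()
        # codon 5 GGA -> GGG (both glycine); third base at pos 25
        assert genome[24] == "A"
        assert classify_consequence(call(pos=25, ref="A", alt="G"), tm) == "synonymous"

    @pytest.mark.parametrize("pos", [26, 27, 39, 40])
    def test_two_intronic_bases_flanking_exons_are_splice(self, pos):
        genome, tm = simple_transcript()
        ref = genome[pos - 1]
        alt = "A" if ref != "A" else "G"
        assert classify_consequence(call(pos=pos, ref=ref, alt=alt), tm) == "splice"

    def test_deep_intron_and_outside_span_are_noncoding(self):
        genome, tm = simple_transcript()
        assert classify_consequence(call(pos=33, ref="C", alt="A"), tm) == "noncoding"
        assert classify_consequence(call(pos=5, ref="T", alt="A"), tm) == "noncoding"

    def test_reference_mismatch_raises(self):
        _, tm = simple_transcript()
        with pytest.raises(ValueError, match="mismatch"):
            classify_consequence(call(pos=11, ref="G", alt="C"), tm)

    def test_malformed_alleles_raise(self):
        _, tm = simple_transcript()
        with pytest.raises(ValueError, match="malformed"):
            classify_consequence(call(pos=11, ref="N", alt="Q"), tm)

    def test_agrees_with_haplotype_translation_oracle(self):
        """Random SNPs over random transcripts: the codon-wise classifier
        matches brute-force translation of both haplotypes."""
        rng = np.random.default_rng(42)
        bases = "ACGT"
        checked = 0
        while checked < 1000:
            genome = "".join(rng.choice(list(bases), 400))
            # 1-3 exons, all coding, total length divisible by 3
            n_ex = int(rng.integers(1, 4))
            cuts = sorted(rng.choice(np.arange(20, 380), 2 * n_ex, replace=False))
            exons = [(int(cuts[2 * i]) + 1, int(cuts[2 * i + 1])) for i in range(n_ex)]
            exonic = sum(e - s + 1 for s, e in exons)
            exons[-1] = (exons[-1][0], exons[-1][1] - exonic % 3)
            if exons[-1][0] > exons[-1][1]:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            cds = "".join(genome[s - 1 : e] for s, e in exons)
            if strand == "-":
                cds = str(Seq(cds).reverse_complement())
            tm = TranscriptModel("g", "1", strand, tuple(exons),
                                 exons[0][0], exons[-1][1], cds)
            for _ in range(25):
                pos = int(rng.integers(exons[0][0] - 5, exons[-1][1] + 5))
                pos = max(1, min(len(genome), pos))
                ref = genome[pos - 1]
                alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
                got = classify_consequence(call(pos=pos, ref=ref, alt=alt), tm)
                assert got == self._oracle(genome, tm, pos, alt)
                checked += 1

    @staticmethod
    def _oracle(genome, tm, pos, alt):
        windows = set()
        for i, (s, e) in enumerate(tm.exons):
            if i > 0:
                windows.update((s - 2, s - 1))
            if i < len(tm.exons) - 1:
                windows.update((e + 1, e + 2))
        if pos in set(tm.cds_positions()):
            mutated = genome[: pos - 1] + alt + genome[pos:]
            prots = []
            for g in (genome, mutated):
                cds = "".join(g[s - 1 : e] for s, e in tm.exons)
                if tm.strand == "-":
                    cds = str(Seq(cds).reverse_complement())
                prots.append(str(Seq(cds).translate()))
            p_ref, p_alt = prots
            if p_ref == p_alt:
                return "synonymous"
            i = next(i for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b)
            return "nonsense" if p_alt[i] == "*" and p_ref[i] != "*" else "missense"
        if pos in windows:
            return "splice"
        return "noncoding"


class TestPrivacy:
    def test_shared_with_panel_strain(self):
        v = call(chrom="7", pos=127278693, ref="G", alt="A")
        panel = {"SPRET": [v], "CAST": [call(chrom="7", pos=1)]}
        assert assess_privacy(v, panel, carrier="B6N") == "shared:SPRET"

    def test_empty_panel_is_private(self):
        assert assess_privacy(call(), {}, carrier="B6N") == "B6N"

    def test_planted_sharing_membership(self):
        calls = [call(pos=i) for i in range(1, 41)]
        panel = {"STRAIN1": calls[:5]}
        labels = [assess_privacy(v, panel, carrier="B6J") for v in calls]
        assert labels.count("shared:STRAIN1") == 5
        assert labels.count("B6J") == 35


def assay(g_j, g_n, **kw):
    return ValidationAssay("v1", "sequenom", list(g_j), list(g_n), **kw)


class TestAdjudication:
    AA, GG, AG = ("A", "A"), ("G", "G"), ("A", "G")

    def test_clean_panel_confirmed(self):
        assert adjudicate_assay(assay([self.AA] * 4, [self.GG] * 4)) == "confirmed"

    def test_heterozygous_sample_eliminates(self):
        a = assay([self.AA] * 4, [self.AG, self.GG, self.GG, self.GG])
        assert adjudicate_assay(a) == "eliminated_heterozygous"

    def test_identical_strains_not_variant(self):
        assert adjudicate_assay(assay([self.AA] * 4, [self.AA] * 4)) == "not_variant"

    def test_within_strain_disagreement(self):
        a = assay([self.AA] * 4, [self.GG, self.GG, self.AA, self.AA])
        assert adjudicate_assay(a) == "eliminated_inconsistent"

    def test_missing_call_takes_precedence(self):
        a = assay([self.AA] * 4, [None, self.AG, self.GG, self.GG])
        assert adjudicate_assay(a) == "eliminated_pcr_failure"

    def test_wrong_panel_size_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            assay([self.AA] * 3, [self.GG] * 4)

    def test_summary_matches_brute_force_recount(self):
        rng = np.random.default_rng(7)
        genos = [self.AA, self.GG, self.AG, None]
        assays = []
        for i in range(200):
            a = ValidationAssay(
                f"v{i}", "pyro",
                [genos[j] for j in rng.integers(0, 4, 4)],
                [genos[j] for j in rng.integers(0, 4, 4)],
                coding=bool(rng.integers(0, 2)), indel=bool(rng.integers(0, 2)),
            )
            adjudicate_assay(a)
            assays.append(a)
        s = summarize_validation(assays)
        # independent tally
        from collections import Counter
        counts = Counter(a.status for a in assays)
        assert s["confirmed"] == counts["confirmed"]
        assert s["eliminated"] == sum(
            v for k, v in counts.items() if k.startswith("eliminated")
        )
        assert s["remaining"] == 200 - s["eliminated"]
        assert sum(s["by_status"].values()) == 200
        assert s["confirmed_by_category"]["coding_snp"] == sum(
            1 for a in assays if a.status == "confirmed" and a.coding and not a.indel
        )

    def test_unadjudicated_assay_rejected(self):
        with pytest.raises(ValueError, match="not adjudicated"):
            summarize_validation([assay([self.AA] * 4, [self.GG] * 4)])

    def test_zero_assays_all_zero(self):
        s = summarize_validation([])
        assert s["assayed"] == s["eliminated"] == s["confirmed"] == 0


class TestCuration:
    def test_homopolymer_and_gc_flags(self):
        seq = "A" * 30 + "G" * 60
        assert "homopolymer" in curation_flags(call(pos=15), seq)
        assert "gc_rich" in curation_flags(call(pos=60), seq)
        mixed = "ACGT" * 25
        assert curation_flags(call(pos=50), mixed) == []


def test_vcf_round_trip(tmp_path):
    calls = [call(pos=10, depth=20, ratio=0.95),
             call(chrom="2", pos=5, ref="AT", alt="A", depth=7, ratio=0.85)]
    path = write_vcf(calls, tmp_path / "x.vcf")
    back = read_vcf(path)
    assert sorted(c.key() for c in back) == sorted(c.key() for c in calls)
    assert {c.depth for c in back} == {20, 7}
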