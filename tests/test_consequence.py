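"""Codon-aware consequence calling vs the translation-comparison oracle."""

import numpy as np
import pytest

from lofprev.consequence import (
    ConsequenceClass as C,
    CoordinateError,
    GeneLoF,
    ReferenceMismatchError,
    VariantCall,
    classify_indel,
    classify_snv,
    collapse_gene_alleles,
    edit_overlaps_interval,
    gene_lof_evidence,
    is_lof,
    normalized_edit,
    translation_oracle,
)
from lofprev.orf import TranscriptSeq, last_n_window, reverse_complement
from lofprev.vcfio import read_vcf, write_vcf

from conftest import make_coding_transcript


def _snv(tid, pos, ref, alt, zygosity="het"):
    return VariantCall(tid, pos, ref, alt, zygosity, depth=30, variant_qual=60, mapping_qual=60)


@pytest.fixture
def toy():
    # CCC CC | ATG TGG GCT AAA CAT TTG | TAA | GGGG  (explicit codons)
    seq = TranscriptSeq("t", "CCCCC" + "ATG" + "TGGGCTAAACATTTG" + "TAA" + "GGGG")
    from lofprev.orf import OrfAnnotation

    orf = OrfAnnotation("t", 5, 5 + 21, "+", 6)
    return seq, orf


class TestClassifySnv:
    def test_sense_to_stop_is_stopgain(self, toy):
        seq, orf = toy
        # TGG codon at CDS codon 1, third base G>A gives TGA
        assert classify_snv(orf, seq, _snv("t", 11, "G", "A")) == C.stopgain

    def test_terminal_stop_to_sense_is_stoploss(self, toy):
        seq, orf = toy
        # natural TAA at positions 24..26 (1-based), T>C gives CAA (Gln)
        assert classify_snv(orf, seq, _snv("t", 24, "T", "C")) == C.stoploss

    def test_wobble_synonymous(self, toy):
        seq, orf = toy
        # GCT codon (Ala), third base T>C gives GCC (Ala)
        assert classify_snv(orf, seq, _snv("t", 14, "T", "C")) == C.synonymous

    def test_stop_to_stop_is_synonymous(self, toy):
        seq, orf = toy
        # TAA>TGA at the terminator: synonymous-at-stop, not stopgain
        assert classify_snv(orf, seq, _snv("t", 25, "A", "G")) == C.synonymous

    def test_missense(self, toy):
        seq, orf = toy
        # AAA (Lys) first base A>G gives GAA (Glu)
        assert classify_snv(orf, seq, _snv("t", 15, "A", "G")) == C.missense

    def test_outside_cds_is_noncoding(self, toy):
        seq, orf = toy
        assert classify_snv(orf, seq, _snv("t", 2, "C", "T")) == C.noncoding

    def test_reference_mismatch_names_site(self, toy):
        seq, orf = toy
        with pytest.raises(ReferenceMismatchError, match="t:11"):
            classify_snv(orf, seq, _snv("t", 11, "C", "A"))

    def test_out_of_range_position(self, toy):
        seq, orf = toy
        with pytest.raises(CoordinateError):
            classify_snv(orf, seq, _snv("t", 999, "A", "C"))


class TestClassifyIndel:
    def test_single_base_deletion_is_frameshift(self, toy):
        seq, orf = toy
        v = VariantCall("t", 11, "GG", "G", "het", 30, 60, 60)  # drops G of GCT
        assert classify_indel(orf, seq, v) == C.frameshift

    def test_three_base_deletion_in_frame(self, toy):
        seq, orf = toy
        v = VariantCall("t", 14, "TAAA", "T", "het", 30, 60, 60)  # drops AAA codon
        assert classify_indel(orf, seq, v) == C.inframe_indel

    def test_insertion_straddling_cds_start_shifts_frame(self, toy):
        seq, orf = toy
        # anchored at the A of ATG; 2 bp inserted between A and TG
        v = VariantCall("t", 6, "A", "ACC", "het", 30, 60, 60)
        assert classify_indel(orf, seq, v) == C.frameshift
        assert translation_oracle(seq, orf, v) == C.frameshift

    def test_utr_indel_is_noncoding(self, toy):
        seq, orf = toy
        v = VariantCall("t", 1, "CC", "C", "het", 30, 60, 60)
        assert classify_indel(orf, seq, v) == C.noncoding


@pytest.mark.parametrize(
    "cls,expected",
    [
        (C.stopgain, True),
        (C.stoploss, True),
        (C.frameshift, True),
        (C.missense, False),
        (C.synonymous, False),
        (C.inframe_indel, False),
        (C.noncoding, False),
    ],
)
def test_lof_definition(cls, expected):
    assert is_lof(cls) is expected


class TestCollapse:
    def test_no_variants_is_none(self):
        assert collapse_gene_alleles("g", []).state == "none"

    def test_single_het(self):
        assert collapse_gene_alleles("g", [_snv("g", 10, "A", "T")]).state == "het_lof"

    def test_hom_takes_precedence(self):
        vs = [
            _snv("g", 10, "A", "T", "het"),
            _snv("g", 20, "C", "G", "het"),
            _snv("g", 30, "G", "A", "hom"),
        ]
        assert collapse_gene_alleles("g", vs).state == "hom_lof"


class TestOracleEquivalence:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_single_base_edits_60_codon_orf(self, strand):
        rng = np.random.default_rng(99)
        t, orf = make_coding_transcript(rng, n_codons=60, strand=strand)
        n = 0
        for pos0 in range(orf.cds_start, orf.cds_end):
            ref = t.sequence[pos0]
            for alt in "ACGT":
                if alt == ref:
                    continue
                v = _snv(t.id, pos0 + 1, ref, alt)
                assert classify_snv(orf, t, v) == translation_oracle(t, orf, v)
                n += 1
        assert n == 3 * orf.cds_length == 540

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_random_snvs_anywhere(self, strand):
        rng = np.random.default_rng(7)
        t, orf = make_coding_transcript(rng, n_codons=80, strand=strand)
        for _ in range(1500):
            pos0 = int(rng.integers(0, len(t.sequence)))
            ref = t.sequence[pos0]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            v = _snv(t.id, pos0 + 1, ref, alt)
            assert classify_snv(orf, t, v) == translation_oracle(t, orf, v)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_random_indels_in_cds_body(self, strand):
        rng = np.random.default_rng(13)
        t, orf = make_coding_transcript(rng, n_codons=80, strand=strand)
        s = t.sequence
        for _ in range(1500):
            length = int(rng.integers(1, 7))
            # keep the edit inside the CDS body, clear of start and stop codons
            lo, hi = orf.cds_start + 3, orf.cds_end - 3
            if rng.random() < 0.5:
                d0 = int(rng.integers(lo, hi - length)) if hi - length > lo else lo
                v = VariantCall(
                    t.id, d0, s[d0 - 1 : d0 + length], s[d0 - 1], "het", 30, 60, 60
                )
            else:
                g = int(rng.integers(lo + 1, hi))
                ins = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
                v = VariantCall(t.id, g, s[g - 1], s[g - 1] + ins, "het", 30, 60, 60)
            # skip edits whose left-aligned form touches the start/stop codon:
            # there the edit is equivalent to a boundary edit and the length
            # rule and the translation route answer different questions
            g2, rem, _ins = normalized_edit(t, v)
            if not (lo <= g2 and g2 + len(rem) <= hi):
                continue
            assert classify_indel(orf, t, v) == translation_oracle(t, orf, v)


def test_strand_symmetry_of_snv_classification(rng):
    t, orf = make_coding_transcript(rng, n_codons=50, strand="-")
    L = len(t.sequence)
    mirror_seq = TranscriptSeq(t.id, reverse_complement(t.sequence))
    from lofprev.orf import OrfAnnotation

    mirror_orf = OrfAnnotation(
        t.id, L - orf.cds_end, L - orf.cds_start, "+", orf.protein_length_aa
    )
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for _ in range(500):
        pos0 = int(rng.integers(0, L))
        ref = t.sequence[pos0]
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        v = _snv(t.id, pos0 + 1, ref, alt)
        mv = _snv(t.id, L - pos0, comp[ref], comp[alt])
        assert classify_snv(orf, t, v) == classify_snv(mirror_orf, mirror_seq, mv)


def test_identity_edit_rejected(toy):
    seq, orf = toy
    with pytest.raises(ValueError):
        _snv("t", 11, "G", "G")


class TestWindowFlag:
    def test_snv_window_membership(self, rng):
        t, orf = make_coding_transcript(rng, n_codons=60)
        win = last_n_window(orf, 100)
        ref = t.sequence[orf.cds_start + 3]
        alt = "A" if ref != "A" else "C"
        early = _snv(t.id, orf.cds_start + 4, ref, alt)
        late_pos0 = orf.cds_end - 2
        ref2 = t.sequence[late_pos0]
        alt2 = "A" if ref2 != "A" else "C"
        late = _snv(t.id, late_pos0 + 1, ref2, alt2)
        assert not edit_overlaps_interval(t, early, win)
        assert edit_overlaps_interval(t, late, win)


class TestGeneEvidence:
    def test_grouping_and_states(self):
        v1 = _snv("g1", 10, "A", "T", "het")
        v2 = VariantCall("g1", 20, "CA", "C", "hom", 30, 60, 60)
        ev = gene_lof_evidence(
            [(v1, C.stopgain, False), (v2, C.frameshift, True)]
        )
        g = ev["g1"]
        assert g.state() == "hom_lof"
        assert g.state(region="last100nt") == "hom_lof"
        assert g.state(variant_type="nonsense") == "het_lof"
        assert g.state(region="last100nt", variant_type="nonsense") == "none"
        assert g.types() == {"nonsense", "frameshift"}

    def test_non_lof_rejected(self):
        with pytest.raises(ValueError, match="not LoF"):
            gene_lof_evidence([(_snv("g", 1, "A", "T"), C.missense, False)])


class TestVcfRoundTrip:
    def test_write_read_preserves_calls(self, tmp_path, rng):
        t, orf = make_coding_transcript(rng, n_codons=40)
        calls = [
            _snv(t.id, 10, t.sequence[9], "A" if t.sequence[9] != "A" else "C", "het"),
            VariantCall(t.id, 20, t.sequence[19] + t.sequence[20], t.sequence[19], "hom", 25, 55.5, 41.2),
        ]
        path = tmp_path / "x.vcf"
        write_vcf(calls, path, "ind1", {t.id: len(t.sequence)})
        back = read_vcf(path)
        expected = sorted(calls, key=lambda c: (c.transcript_id, c.pos, c.alt))
        assert len(back) == len(expected)
        for got, want in zip(back, expected):
            assert (got.transcript_id, got.pos, got.ref, got.alt, got.zygosity, got.depth) == (
                want.transcript_id, want.pos, want.ref, want.alt, want.zygosity, want.depth
            )
            assert got.variant_qual == pytest.approx(want.variant_qual, abs=1e-4)
            assert got.mapping_qual == pytest.approx(want.mapping_qual, abs=1e-4)

    def test_multiallelic_decomposition(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=MQ,Number=1,Type=Float,Description="MQ">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
            "##contig=<ID=tx,length=100>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "tx\t5\t.\tA\tT,G\t50\t.\tMQ=40\tGT:DP\t1/2:22\n"
        )
        calls = read_vcf(vcf)
        assert [(c.alt, c.zygosity, c.depth) for c in calls] == [
            ("T", "het", 22),
            ("G", "het", 22),
        ]
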