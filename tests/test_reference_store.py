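"""Reference ingestion, binary reference round-trips, reconciliation, PAR."""

import numpy as np
import pytest

from phasebeam.panel import HaplotypePanel, VariantRecord
from phasebeam.qref import (
    MAGIC,
    QrefFormatError,
    read_binary_reference,
    write_binary_reference,
)
from phasebeam.reconcile import (
    PAR_REGIONS,
    MatchClass,
    reconcile_variants,
    split_par_regions,
)
from phasebeam.vcfio import read_reference_vcf, read_target_vcf, write_phased_vcf


def V(pos, ref, alt, chrom="1", af=0.5):
    return VariantRecord(chrom, pos, f"v{pos}", ref, alt, af)


class TestReferenceVcf:
    def test_transcribes_phased_genotypes(self, tiny_ref_vcf):
        panel, variants, samples = read_reference_vcf(tiny_ref_vcf)
        assert samples == ["S1", "S2"]
        assert (panel.n_haps, panel.n_sites) == (4, 3)
        # columns follow the GT fields: haplotypes S1_A,S1_B,S2_A,S2_B
        assert panel.matrix.T.tolist() == [
            [0, 1, 1, 1],
            [0, 0, 0, 1],
            [1, 0, 0, 0],
        ]
        assert [v.pos for v in variants] == [100, 200, 300]
        assert variants[0].panel_af == pytest.approx(0.75)

    def test_unphased_reference_rejected(self, tmp_path, tiny_ref_vcf):
        text = tiny_ref_vcf.read_text().replace("0|1", "0/1")
        bad = tmp_path / "bad.vcf"
        bad.write_text(text)
        with pytest.raises(ValueError, match="[Uu]nphased.*1:100"):
            read_reference_vcf(bad)

    def test_missing_genotype_rejected(self, tmp_path, tiny_ref_vcf):
        text = tiny_ref_vcf.read_text().replace("0|0", ".|.")
        bad = tmp_path / "bad.vcf"
        bad.write_text(text)
        with pytest.raises(ValueError, match="missing"):
            read_reference_vcf(bad)

    def test_multiallelic_dropped_by_default(self, tmp_path, tiny_ref_vcf):
        text = tiny_ref_vcf.read_text().replace(
            "1\t200\trs2\tG\tT", "1\t200\trs2\tG\tT,A"
        )
        p = tmp_path / "multi.vcf"
        p.write_text(text)
        panel, variants, _ = read_reference_vcf(p)
        assert panel.n_sites == 2
        assert [v.pos for v in variants] == [100, 300]

    def test_roundtrip_through_phased_writer(self, tmp_path, rng):
        mat = rng.integers(0, 2, size=(6, 10))
        variants = [V(10 * (i + 1), "A", "G") for i in range(10)]
        out = tmp_path / "panel.vcf"
        write_phased_vcf(out, variants, ["a", "b", "c"], mat)
        panel2, variants2, _ = read_reference_vcf(out)
        np.testing.assert_array_equal(panel2.matrix, mat)
        assert [v.pos for v in variants2] == [v.pos for v in variants]

    def test_target_reader_missing_and_ploidy(self, tmp_path, tiny_ref_vcf):
        text = tiny_ref_vcf.read_text().replace("0|1\t1|1", "./.\t1/1")
        p = tmp_path / "target.vcf"
        p.write_text(text)
        td = read_target_vcf(p)
        assert td.genotypes[0].tolist() == [-1, 2]
        assert td.haplotypes is None  # unphased record present


class TestBinaryReference:
    def test_empty_panel_roundtrips(self, tmp_path):
        panel = HaplotypePanel(np.zeros((4, 0), dtype=np.uint8))
        path = tmp_path / "empty.qref"
        write_binary_reference(panel, [], path, ["s0", "s1"])
        p2, v2, s2 = read_binary_reference(path)
        assert (p2.n_haps, p2.n_sites) == (4, 0)
        assert v2 == [] and s2 == ["s0", "s1"]

    @pytest.mark.parametrize("shape", [(20, 100), (7, 33), (1, 1)])
    def test_random_panel_bit_exact_roundtrip(self, tmp_path, rng, shape):
        n, m = shape
        mat = rng.integers(0, 2, size=(n, m))
        panel = HaplotypePanel(mat)
        variants = [
            VariantRecord("2", i + 1, f"id{i}", "A", "T", float(rng.random()))
            for i in range(m)
        ]
        path = tmp_path / "p.qref"
        write_binary_reference(panel, variants, path)
        p2, v2, _ = read_binary_reference(path)
        np.testing.assert_array_equal(p2.packed, panel.packed)
        np.testing.assert_array_equal(p2.matrix, mat)
        for a, b in zip(variants, v2):
            assert (a.chrom, a.pos, a.vid, a.ref_allele, a.alt_allele) == (
                b.chrom, b.pos, b.vid, b.ref_allele, b.alt_allele,
            )
            assert b.panel_af == pytest.approx(a.panel_af, abs=1e-7)  # float32

    def test_corrupted_magic_raises_format_error(self, tmp_path):
        panel = HaplotypePanel([[0, 1], [1, 0]])
        path = tmp_path / "x.qref"
        write_binary_reference(panel, [V(1, "A", "C"), V(2, "A", "C")], path)
        raw = bytearray(path.read_bytes())
        raw[:4] = b"XXXX"
        path.write_bytes(bytes(raw))
        with pytest.raises(QrefFormatError, match="magic"):
            read_binary_reference(path)

    def test_truncated_file_raises_format_error(self, tmp_path):
        panel = HaplotypePanel([[0, 1], [1, 0]])
        path = tmp_path / "x.qref"
        write_binary_reference(panel, [V(1, "A", "C"), V(2, "A", "C")], path)
        raw = path.read_bytes()
        path.write_bytes(raw[: len(MAGIC) + 10])
        with pytest.raises(QrefFormatError):
            read_binary_reference(path)


class TestReconcile:
    def test_exact_match_is_shared(self):
        aln = reconcile_variants([V(5, "A", "C")], [V(5, "A", "C")])
        assert aln.classes == [MatchClass.SHARED]
        assert not aln.flip[0]

    def test_refalt_swap_needs_flag_and_recode(self):
        t, r = [V(5, "A", "C")], [V(5, "C", "A")]
        on = reconcile_variants(t, r, allow_refalt_swap=True)
        assert on.classes == [MatchClass.SHARED_REFALT_SWAP]
        assert on.flip[0]
        off = reconcile_variants(t, r)
        assert off.classes == [MatchClass.EXCLUDED]

    def test_strand_flip_needs_flag(self):
        t, r = [V(5, "A", "C")], [V(5, "T", "G")]
        on = reconcile_variants(t, r, allow_strand_flip=True)
        assert on.classes == [MatchClass.SHARED_STRAND_FLIP]
        assert not on.flip[0]  # same 0/1 meaning, only the strand differs
        off = reconcile_variants(t, r)
        assert off.classes == [MatchClass.EXCLUDED]

    def test_swap_and_flip_needs_both_flags(self):
        t, r = [V(5, "A", "C")], [V(5, "G", "T")]
        both = reconcile_variants(t, r, allow_refalt_swap=True, allow_strand_flip=True)
        assert both.classes == [MatchClass.SHARED_SWAP_AND_FLIP]
        assert both.flip[0]
        for swap, flip in ((True, False), (False, True)):
            part = reconcile_variants(
                t, r, allow_refalt_swap=swap, allow_strand_flip=flip
            )
            assert part.classes == [MatchClass.EXCLUDED]

    @pytest.mark.parametrize("alleles", [("A", "T"), ("C", "G")])
    def test_strand_ambiguous_never_auto_flipped(self, alleles):
        ref, alt = alleles
        t = [V(5, ref, alt)]
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        r_flipped = [V(5, comp[ref], comp[alt])]
        aln = reconcile_variants(
            t, r_flipped, allow_refalt_swap=True, allow_strand_flip=True
        )
        # complement of an ambiguous SNV equals its swap: classified as swap
        assert aln.classes == [MatchClass.SHARED_REFALT_SWAP]
        aln2 = reconcile_variants(t, r_flipped, allow_strand_flip=True)
        assert aln2.classes == [MatchClass.EXCLUDED]

    def test_position_missing_from_reference_is_target_only(self):
        aln = reconcile_variants([V(5, "A", "C")], [V(9, "A", "C")])
        assert aln.classes == [MatchClass.TARGET_ONLY]

    def test_conflicting_duplicates_excluded_not_crash(self):
        ref = [V(5, "A", "C"), V(5, "C", "A")]
        aln = reconcile_variants(
            [V(5, "A", "C")], ref, allow_refalt_swap=True
        )
        assert aln.classes == [MatchClass.EXCLUDED]

    def test_symmetry_under_role_swap(self, rng):
        """Swapping target/reference roles preserves shared classes with
        the recoding inverted (an involution)."""
        bases = ["A", "C", "G", "T"]
        tv, rv = [], []
        for i in range(40):
            ref, alt = rng.choice(bases, size=2, replace=False)
            tv.append(V(10 * i + 10, str(ref), str(alt)))
            roll = rng.random()
            if roll < 0.4:
                rv.append(V(10 * i + 10, str(ref), str(alt)))
            elif roll < 0.7:
                rv.append(V(10 * i + 10, str(alt), str(ref)))
            else:
                rv.append(V(10 * i + 11, str(ref), str(alt)))
        fwd = reconcile_variants(tv, rv, allow_refalt_swap=True)
        bwd = reconcile_variants(rv, tv, allow_refalt_swap=True)
        for c1, c2, f1, f2 in zip(fwd.classes, bwd.classes, fwd.flip, bwd.flip):
            if c1.shared:
                assert c2 == c1
                assert f1 == f2


class TestParSplit:
    def test_no_x_records_pass_through(self):
        recs = [V(p, "A", "C", chrom="7") for p in (10, 20, 30)]
        slices = split_par_regions(recs)
        assert len(slices) == 1
        assert slices[0].ploidy == 2
        assert slices[0].indices.tolist() == [0, 1, 2]

    def test_x_partition_counts_and_order(self):
        par1 = PAR_REGIONS["GRCh38"]["PAR1"]
        recs = [
            V(par1[0] + 5, "A", "C", chrom="X"),
            V(par1[1] + 100, "A", "C", chrom="X"),
            V(par1[1] + 200, "G", "T", chrom="X"),
        ]
        slices = split_par_regions(recs, build="GRCh38")
        assert [s.label for s in slices] == ["X_PAR1", "X_nonPAR"]
        assert [s.ploidy for s in slices] == [2, 1]
        merged = np.concatenate([s.indices for s in slices])
        assert merged.tolist() == [0, 1, 2]  # partition/merge identity

    def test_overlapping_definitions_rejected(self):
        recs = [V(100, "A", "C", chrom="X")]
        with pytest.raises(ValueError, match="overlap"):
            split_par_regions(recs, par_definitions={"PAR1": (1, 200), "PAR2": (100, 300)})
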