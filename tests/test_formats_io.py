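"""Round-trip and normalization behaviour of the file interfaces."""

import numpy as np
import pytest

from sectormut import formats_io
from sectormut.records import (
    FormatError,
    InputError,
    MutationRecord,
    ReferenceGenome,
    normalize_variant,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadReference:
    def test_two_record_fasta(self, tmp_path):
        p = _write(tmp_path, "r.fa", ">c1\nACGT\n>c2\nNNAA\n")
        g = formats_io.read_reference(p)
        assert g.chromosomes == {"c1": "ACGT", "c2": "NNAA"}

    def test_lowercase_normalized(self, tmp_path):
        p = _write(tmp_path, "r.fa", ">c1\nacgt\n")
        assert formats_io.read_reference(p)["c1"] == "ACGT"

    @pytest.mark.parametrize(
        "text", [">c1\nAXGT\n", ">c1\nACGT\n>c1\nACGT\n", ">c1\n\n>c2\nAC\n"]
    )
    def test_bad_fasta_rejected(self, tmp_path, text):
        p = _write(tmp_path, "r.fa", text)
        with pytest.raises(FormatError):
            formats_io.read_reference(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError):
            formats_io.read_reference(tmp_path / "nope.fa")


MUT_HEADER = "sector\tchrom\tpos\tref\talt\talt_reads\tdepth\taf\tclass\n"


class TestMutationTable:
    def test_af_computed_from_counts(self, tmp_path):
        p = _write(
            tmp_path, "m.tsv", MUT_HEADER + "29-4\tc3\t101\tAT\tA\t39\t100\t\t\n"
        )
        (r,) = formats_io.read_mutation_table(p)
        assert (r.ref_allele, r.alt_allele) == ("AT", "A")
        assert r.af == pytest.approx(0.390)

    def test_af_only_row_retained(self, tmp_path):
        p = _write(tmp_path, "m.tsv", MUT_HEADER + "29-4\tc3\t101\tCA\tC\t\t\t0.391\t\n")
        (r,) = formats_io.read_mutation_table(p)
        assert r.af == 0.391 and r.alt_reads is None

    def test_alt_equals_ref_rejected(self, tmp_path):
        p = _write(tmp_path, "m.tsv", MUT_HEADER + "s\tc1\t5\tA\tA\t20\t50\t\t\n")
        with pytest.raises(FormatError):
            formats_io.read_mutation_table(p)

    def test_depth_zero_with_alt_reads_rejected(self, tmp_path):
        p = _write(tmp_path, "m.tsv", MUT_HEADER + "s\tc1\t5\tA\tT\t3\t0\t\t\n")
        with pytest.raises(FormatError):
            formats_io.read_mutation_table(p)

    def test_roundtrip_field_for_field(self, tmp_path, rng):
        records = [
            MutationRecord("s1", "c1", int(p), "A", str(alt), af=int(a) / 100,
                           alt_reads=int(a), depth=100)
            for p, alt, a in zip(
                rng.integers(1, 10_000, 20),
                rng.choice(["T", "G", "AT", "ACC"], 20),
                rng.integers(10, 80, 20),
            )
        ]
        p = tmp_path / "rt.tsv"
        formats_io.write_mutation_table(records, p)
        back = formats_io.read_mutation_table(p)
        assert [
            (r.sector_id, r.chrom, r.pos, r.ref_allele, r.alt_allele,
             r.alt_reads, r.depth, round(r.af, 6))
            for r in records
        ] == [
            (r.sector_id, r.chrom, r.pos, r.ref_allele, r.alt_allele,
             r.alt_reads, r.depth, round(r.af, 6))
            for r in back
        ]

    def test_vcf_roundtrip(self, tmp_path):
        records = [
            MutationRecord("sA", "c1", 10, "A", "T", af=0.4, alt_reads=40, depth=100),
            MutationRecord("sB", "c1", 50, "CAA", "C", af=0.3, alt_reads=30, depth=100),
        ]
        p = tmp_path / "m.vcf"
        formats_io.write_vcf(records, p)
        back = formats_io.read_vcf(p)
        key = lambda r: (r.sector_id, r.chrom, r.pos, r.ref_allele, r.alt_allele,
                         r.alt_reads, r.depth)
        assert sorted(map(key, back)) == sorted(map(key, records))


class TestNormalizeVariant:
    def test_left_alignment_of_ambiguous_deletion(self):
        # deleting ACG anywhere in the ACGACG repeat is one variant
        seq = "TTACGACGTT"
        assert normalize_variant(seq, 5, "GACG", "G") == (2, "TACG", "T")

    def test_idempotent(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        for _ in range(50):
            pos = int(rng.integers(2, 190))
            dlen = int(rng.integers(1, 6))
            ref = seq[pos - 1 : pos + dlen]
            alt = seq[pos - 1]
            once = normalize_variant(seq, pos, ref, alt)
            assert normalize_variant(seq, *once) == once

    def test_snv_passthrough(self):
        assert normalize_variant("ACGT", 2, "C", "T") == (2, "C", "T")


class TestDepthTrack:
    def test_per_position_binning(self, tmp_path):
        rows = "\n".join(f"c1\t{i}\t10" for i in range(1, 200_001))
        p = _write(tmp_path, "d.tsv", "chrom\tpos\tdepth\n" + rows + "\n")
        t = formats_io.read_depth_track(p, bin_width=100_000)
        assert list(t.depths["c1"]) == [10.0, 10.0]
        assert list(t.widths["c1"]) == [100_000, 100_000]

    def test_prebinned_passthrough(self, tmp_path):
        p = _write(
            tmp_path, "d.tsv",
            "chrom\tbin_start\tbin_width\tdepth\nc1\t1\t100000\t85\nc1\t100001\t100000\t42\n",
        )
        t = formats_io.read_depth_track(p)
        assert list(t.depths["c1"]) == [85.0, 42.0]

    def test_unsorted_rejected(self, tmp_path):
        p = _write(tmp_path, "d.tsv", "chrom\tpos\tdepth\nc1\t5\t10\nc1\t3\t10\n")
        with pytest.raises(FormatError):
            formats_io.read_depth_track(p)

    def test_unknown_chromosome_rejected(self, tmp_path, small_genome):
        p = _write(tmp_path, "d.tsv", "chrom\tpos\tdepth\nc9\t1\t10\n")
        with pytest.raises(InputError):
            formats_io.read_depth_track(p, genome=small_genome)

    def test_partial_terminal_bin_width(self, tmp_path):
        rows = "\n".join(f"c1\t{i}\t8" for i in range(1, 150_001))
        p = _write(tmp_path, "d.tsv", "chrom\tpos\tdepth\n" + rows + "\n")
        t = formats_io.read_depth_track(p, bin_width=100_000)
        assert list(t.widths["c1"]) == [100_000, 50_000]
        assert t.depths["c1"][1] == pytest.approx(8.0)


def test_breakend_roundtrip(tmp_path):
    from sectormut.records import RejoinedSite

    sites = [
        RejoinedSite("s1", "c1", 99, "+", "c1", 2000, "-", del_bp=3, ins_seq="AC",
                     sv_id="SV1"),
        RejoinedSite("s1", "c2", 500, "+", "c3", 700, "+", sv_id="T1"),
    ]
    p = tmp_path / "b.tsv"
    formats_io.write_breakend_table(sites, p)
    back = formats_io.read_breakend_table(p)
    key = lambda s: (s.sector_id, s.chrom_a, s.pos_a, s.strand_a, s.chrom_b,
                     s.pos_b, s.strand_b, s.del_bp, s.ins_seq)
    assert sorted(map(key, back)) == sorted(map(key, sites))
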