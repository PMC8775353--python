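"""Microhomology, junction typing, and template search against oracles.

The MH oracle is placement ambiguity: for a deletion of length d in a
sequence, mh_len must equal the number of distinct equal-length deletion
placements producing the identical mutated sequence, minus one. The
template-search oracle is an exhaustive all-substrings scan.
"""

import numpy as np
import pytest

from sectormut.datasets import (
    synthetic_large_deletion_sites,
    synthetic_rearrangement_sites,
    synthetic_small_medium_del_sites,
    synthetic_sv_junction_sites,
)
from sectormut.junction_analysis import (
    classify_rejoined_site,
    compute_deletion_mh,
    compute_sv_junction_mh,
    deletion_site,
    find_insertion_template,
    summarize_junction_features,
)
from sectormut.records import InputError, MutationRecord, ReferenceGenome, RejoinedSite, revcomp


def placement_ambiguity_oracle(seq: str, start: int, end: int) -> int:
    """Count equal-length deletions yielding the same mutated sequence."""
    target = seq[:start] + seq[end:]
    d = end - start
    n = sum(
        1
        for s in range(len(seq) - d + 1)
        if seq[:s] + seq[s + d :] == target
    )
    return n - 1


class TestDeletionMH:
    def test_repeat_context(self):
        g = ReferenceGenome({"c1": "TTACGACGTT"})
        mh, seq = compute_deletion_mh(g, "c1", 2, 5)  # delete "ACG"
        assert mh == 3
        assert placement_ambiguity_oracle(g["c1"], 2, 5) == 3

    def test_unrelated_flanks_zero(self):
        g = ReferenceGenome({"c1": "AACCGGTTAACC"})
        mh, seq = compute_deletion_mh(g, "c1", 4, 6)  # GG between CC and TT
        assert (mh, seq) == (0, "")

    def test_chromosome_edge(self):
        g = ReferenceGenome({"c1": "AAAT"})
        mh, _ = compute_deletion_mh(g, "c1", 0, 1)  # only right side in bounds
        assert mh == placement_ambiguity_oracle("AAAT", 0, 1) == 2

    def test_out_of_range(self, small_genome):
        with pytest.raises(InputError):
            compute_deletion_mh(small_genome, "c1", 5, 50)

    def test_oracle_equivalence_random_fixtures(self, rng):
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), 200))
            g = ReferenceGenome({"c1": seq})
            start = int(rng.integers(1, 180))
            end = start + int(rng.integers(1, 15))
            mh, mh_seq = compute_deletion_mh(g, "c1", start, end)
            assert mh == placement_ambiguity_oracle(seq, start, end)
            assert len(mh_seq) == mh

    def test_alignment_invariance(self, rng):
        """MH is identical for left- and right-aligned descriptions."""
        seq = "TTTACGACGACGTT"
        g = ReferenceGenome({"c1": seq})
        # all placements of a 3-bp deletion in the ACG repeat are equivalent
        results = {
            compute_deletion_mh(g, "c1", s, s + 3)[0]
            for s in (3, 6, 9)
            if seq[:s] + seq[s + 3 :] == seq[:3] + seq[6:]
        }
        assert len(results) == 1


class TestSVJunctionMH:
    def test_inversion_junction_with_constructed_mh(self):
        # forward end ...ACCT joined to an inverted partner whose re-oriented
        # start is CCTGAA; the left source also continues with CCT, so the
        # breakpoint can shift by 3 bp and still give the same molecule
        left = "GATTACAGGTAACCT"
        cont = "CCTAAG"
        partner_reoriented = "CCTGAA" + "GATC" * 5
        chrom = left + cont + "TTTT" + revcomp(partner_reoriented)
        g = ReferenceGenome({"c1": chrom})
        site = RejoinedSite(
            "s", "c1", len(left) - 1, "+", "c1", len(chrom) - 1, "-",
        )
        mh, seq = compute_sv_junction_mh(g, site)
        assert mh == 3 and seq == "CCT"
        # breakpoint-shift oracle: shifting both breaks inward by k <= 3
        # reproduces the identical rejoined sequence
        joined = chrom[: len(left)] + partner_reoriented
        for k in (1, 2, 3):
            shifted = chrom[: len(left) + k] + partner_reoriented[k:]
            assert shifted == joined
        shifted4 = chrom[: len(left) + 4] + partner_reoriented[4:]
        assert shifted4 != joined

    def test_blunt_random_junction(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 60))
        g = ReferenceGenome({"c1": seq})
        site = RejoinedSite("s", "c1", 14, "+", "c1", 45, "+")
        mh, _ = compute_sv_junction_mh(g, site)
        # oracle: direct prefix/suffix comparison of the joined ends
        r = 0
        while seq[45 + r] == seq[15 + r]:
            r += 1
        l = 0
        while seq[14 - l] == seq[44 - l]:
            l += 1
        assert mh == r + l

    def test_insertion_site_has_no_mh(self, small_genome):
        site = RejoinedSite("s", "c1", 3, "+", "c1", 7, "+", ins_seq="A")
        assert compute_sv_junction_mh(small_genome, site) == (0, "")


class TestSiteTyping:
    @pytest.mark.parametrize(
        "del_bp,ins,expected",
        [(0, "", "no_indel"), (2, "", "only_deletion"),
         (0, "G", "only_insertion"), (3, "AC", "indel")],
    )
    def test_four_types(self, del_bp, ins, expected):
        site = RejoinedSite("s", "c1", 10, "+", "c1", 90, "-",
                            del_bp=del_bp, ins_seq=ins)
        assert classify_rejoined_site(site) == expected

    def test_duplication_like_insertion_stays_insertion(self):
        site = RejoinedSite("s", "c1", 10, "+", "c1", 90, "-",
                            ins_seq="AC", duplication_like=True)
        assert classify_rejoined_site(site) == "only_insertion"


def brute_force_template_scan(genome, site, window, min_len):
    """Oracle: enumerate every substring placement on both strands/ends.

    Returns the best (core_len, total_len) under core-first ranking, or
    None when no placement reaches ``min_len`` in total.
    """
    ins = site.ins_seq
    best = None
    from sectormut.junction_analysis import _side_contexts

    left_flank, _, _, right_flank = _side_contexts(genome, site)
    lj, rj = left_flank[-window:], right_flank[:window]
    for end, chrom, bp in (("A", site.chrom_a, site.pos_a), ("B", site.chrom_b, site.pos_b)):
        seq = genome[chrom]
        lo, hi = max(bp - window, 0), min(bp + window + 1, len(seq))
        for strand, w in (("direct", seq[lo:hi]), ("revcomp", revcomp(seq[lo:hi]))):
            # identity placement of the junction's own flank earns no credit
            triv_l = bp + 1 - lo if (strand == "direct" and end == "A") else None
            triv_r = bp - lo if (strand == "direct" and end == "B") else None
            for t in range(len(w)):
                for s in range(len(ins)):
                    k = 0
                    while t + k < len(w) and s + k < len(ins) and w[t + k] == ins[s + k]:
                        k += 1
                    if k == 0:
                        continue
                    fl = fr = 0
                    if s == 0 and t != triv_l:
                        while fl < min(t, len(lj)) and w[t - 1 - fl] == lj[-1 - fl]:
                            fl += 1
                    if s + k == len(ins) and t + k != triv_r:
                        while (t + k + fr < len(w) and fr < len(rj)
                               and w[t + k + fr] == rj[fr]):
                            fr += 1
                    total = k + fl + fr
                    if total >= min_len and (best is None or (k, total) > best):
                        best = (k, total)
    return best


class TestTemplateSearch:
    def test_no_template_in_polyg(self):
        g = ReferenceGenome({"c1": "G" * 300})
        site = RejoinedSite("s", "c1", 149, "+", "c1", 150, "+", ins_seq="T")
        assert find_insertion_template(g, site) is None

    def test_agrees_with_bruteforce_on_random_fixtures(self, rng):
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), 400))
            g = ReferenceGenome({"c1": seq})
            ins = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 9))))
            site = RejoinedSite("s", "c1", 180, "+", "c1", 220, "+", del_bp=39,
                                ins_seq=ins)
            hit = find_insertion_template(g, site, window=80)
            oracle = brute_force_template_scan(g, site, window=80, min_len=4)
            got = (hit.core_len, hit.total_len) if hit else None
            assert got == oracle

    def test_recovers_planted_template_with_flanks(self):
        rng = np.random.default_rng(5)
        seq = list("".join(rng.choice(list("ACGT"), 400)))
        # junction at [180, 220); plant a template equal to ins + 1-base
        # right-flank homology 30 bp downstream of the right breakpoint
        ins = "TTGACGTAGCGAT"  # 13 bp
        t0 = 250
        seq[t0 : t0 + len(ins)] = list(ins)
        seq[t0 + len(ins)] = seq[220]  # one base of flank homology
        seq[t0 + len(ins) + 1] = "A" if seq[221] != "A" else "C"
        g = ReferenceGenome({"c1": "".join(seq)})
        site = RejoinedSite("s", "c1", 179, "+", "c1", 220, "+", del_bp=40,
                            ins_seq=ins)
        hit = find_insertion_template(g, site)
        assert hit is not None
        assert hit.core_len == len(ins)
        assert hit.total_len >= len(ins) + 1

    def test_requires_insertion(self, small_genome):
        site = RejoinedSite("s", "c1", 3, "+", "c1", 7, "+")
        with pytest.raises(InputError):
            find_insertion_template(small_genome, site)


class TestFeatureTable:
    def test_published_inventory_counts(self):
        sites = synthetic_rearrangement_sites() + synthetic_small_medium_del_sites()
        t = summarize_junction_features(sites)
        assert t.row("rearrangement")["ins_pos"] == 11
        assert t.row("rearrangement")["total"] == 33
        assert t.row("small_del")["ins_neg_mh_neg"] == 24
        assert t.row("small_del")["total"] == 77
        assert t.row("medium_del")["ins_neg_mh_pos"] == 30

    def test_zero_class_rows(self):
        t = summarize_junction_features([])
        assert all(v == 0 for row in t.counts.values() for v in row.values())

    def test_missing_size_class_rejected(self):
        s = RejoinedSite("s", "c1", 10, "+", "c1", 90, "+", del_bp=2)
        with pytest.raises(InputError):
            summarize_junction_features([s])

    def test_sv_fixture_site_types(self):
        from collections import Counter

        c = Counter(s.site_type for s in synthetic_sv_junction_sites())
        assert (c["no_indel"], c["only_deletion"], c["only_insertion"], c["indel"]) == (
            6, 11, 1, 8,
        )

    def test_deletion_record_to_site(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        g = ReferenceGenome({"c1": seq})
        ref = seq[99:110]  # anchor at 1-based pos 100, delete 10 bp
        r = MutationRecord("s", "c1", 100, ref, ref[0], af=0.3)
        site = deletion_site(g, r)
        assert site.del_bp == 10
        assert site.site_type == "only_deletion"
        assert site.mh_len == placement_ambiguity_oracle(seq, 100, 110)
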