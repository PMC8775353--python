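"""Published aggregate counts and synthetic stand-in fixtures.

The counts here are the printed per-sector mutation tallies and junction
feature frequencies from a whole-genome study of anthocyanin-less M1
sectors of gamma-irradiated heterozygous Arabidopsis (seven sectors, 769
mutations, 85× mean coverage). The study's full per-mutation supplementary
tables are not redistributed; the ``synthetic_*`` builders below construct
stand-in record sets that reproduce every printed marginal count exactly
(class totals per sector, Ti:Tv, junction-type counts, feature and
MH-length splits) while all positions, alleles and identifiers are
invented. They exercise the same code paths the real tables would.
"""

from __future__ import annotations

from .records import MutationRecord, RejoinedSite

__all__ = [
    "SECTORS",
    "TABLE_COUNTS",
    "SBS_CLASS_COUNTS",
    "FEATURE_COUNTS",
    "MH_GE3_COUNTS",
    "GENOME_LENGTH_BP",
    "table_mutation_records",
    "synthetic_sv_junction_sites",
    "synthetic_large_deletion_sites",
    "synthetic_small_medium_del_sites",
    "synthetic_rearrangement_sites",
]

SECTORS = ("5-3", "8-5", "13-2", "15-4", "22-3", "27-4", "29-4")

#: Mutation counts per sector and class (rows sum to the 769 grand total).
TABLE_COUNTS = {
    "SBS":     (72, 73, 75, 64, 90, 42, 51),
    "INS1":    (2, 4, 3, 4, 5, 4, 2),
    "DEL1":    (10, 14, 8, 15, 15, 15, 5),
    "INS2_99": (1, 0, 0, 1, 1, 2, 1),
    "DEL2_99": (31, 15, 9, 15, 20, 13, 8),
    "DEL100":  (1, 1, 3, 2, 1, 3, 1),
    "SV":      (0, 1, 3, 1, 4, 4, 0),
    "COMPLEX": (16, 9, 8, 5, 5, 3, 8),
}

#: SBS strand-collapsed class totals. The published figure reports the six
#: class heights graphically with Ti:Tv = 0.97 over 467 SBSs and names
#: A:T>T:A, G:C>A:T and A:T>G:C as the majors; these integer totals are a
#: synthetic allocation consistent with those constraints
#: (230 transitions / 237 transversions = 0.97).
SBS_CLASS_COUNTS = {
    "A:T>T:A": 120,
    "A:T>G:C": 100,
    "A:T>C:G": 37,
    "G:C>A:T": 130,
    "G:C>T:A": 45,
    "G:C>C:G": 35,
}

#: Junction feature counts per size class: (INS+, INS-MH+, INS-MH-, total).
FEATURE_COUNTS = {
    "rearrangement": (11, 20, 2, 33),
    "medium_del": (0, 30, 4, 34),
    "small_del": (5, 48, 24, 77),
}

#: MH-length split among MH-positive sites: (>=3 bp, MH-positive total).
MH_GE3_COUNTS = {
    "rearrangement": (9, 20),
    "medium_del": (17, 30),
    "small_del": (12, 48),
}

#: Haploid Arabidopsis reference length used as the mutation-frequency
#: denominator (~119 Mb).
GENOME_LENGTH_BP = 119_000_000

_BASES = "ACGT"
_ALT_FOR = {
    ("A", "A:T>T:A"): "T", ("T", "A:T>T:A"): "A",
    ("A", "A:T>G:C"): "G", ("T", "A:T>G:C"): "C",
    ("A", "A:T>C:G"): "C", ("T", "A:T>C:G"): "G",
    ("G", "G:C>A:T"): "A", ("C", "G:C>A:T"): "T",
    ("G", "G:C>T:A"): "T", ("C", "G:C>T:A"): "A",
    ("G", "G:C>C:G"): "C", ("C", "G:C>C:G"): "G",
}


def _mk(sector, chrom, pos, ref, alt, mclass, af=0.35):
    return MutationRecord(
        sector_id=sector, chrom=chrom, pos=pos, ref_allele=ref,
        alt_allele=alt, af=af, mclass=mclass,
    )


def table_mutation_records() -> "list[MutationRecord]":
    """769 deterministic records matching the per-sector class totals.

    SBS classes follow :data:`SBS_CLASS_COUNTS`; deletion sizes split the
    2–99 bp class into 77 small (2–9 bp) and 34 medium (10–99 bp) events as
    observed. Positions and alleles are synthetic placeholders.
    """
    records: "list[MutationRecord]" = []
    # cycle SBS classes so per-sector and per-class totals both hold
    sbs_queue: "list[str]" = []
    for cls, n in SBS_CLASS_COUNTS.items():
        sbs_queue += [cls] * n
    sbs_i = 0
    small_left, medium_left = 77, 34
    pos_counter = 1000
    for si, sector in enumerate(SECTORS):
        chrom = f"chr{si % 5 + 1}"
        for mclass, per_sector in TABLE_COUNTS.items():
            for k in range(per_sector[si]):
                pos_counter += 500
                pos = pos_counter
                if mclass == "SBS":
                    cls = sbs_queue[sbs_i]
                    sbs_i += 1
                    ref = "A" if cls.startswith("A:T") else "G"
                    records.append(_mk(sector, chrom, pos, ref, _ALT_FOR[(ref, cls)], "SBS"))
                elif mclass == "INS1":
                    records.append(_mk(sector, chrom, pos, "A", "AT", "INS1"))
                elif mclass == "DEL1":
                    records.append(_mk(sector, chrom, pos, "CA", "C", "DEL1"))
                elif mclass == "INS2_99":
                    records.append(_mk(sector, chrom, pos, "G", "G" + "AC" * 3, "INS2_99"))
                elif mclass == "DEL2_99":
                    # alternate small/medium while quotas remain
                    if small_left and (not medium_left or (small_left * 34 >= medium_left * 77)):
                        size = 2 + (k % 8)
                        small_left -= 1
                    else:
                        size = 10 + (k % 90)
                        medium_left -= 1
                    records.append(
                        _mk(sector, chrom, pos, "T" + "A" * size, "T", "DEL2_99")
                    )
                elif mclass == "DEL100":
                    size = 400 + 100_000 * k
                    records.append(
                        _mk(sector, chrom, pos, "T" + "A" * size, "T", "DEL100")
                    )
                elif mclass == "SV":
                    records.append(_mk(sector, chrom, pos, "A", "<INV>", "SV"))
                elif mclass == "COMPLEX":
                    records.append(_mk(sector, chrom, pos, "AG,C", "TG,CA", "COMPLEX"))
    return records


def _site(sector, sv_id, del_bp, ins_seq, mh_len, size_class=None):
    return RejoinedSite(
        sector_id=sector, chrom_a="chr1", pos_a=1000, strand_a="+",
        chrom_b="chr1", pos_b=2000, strand_b="-",
        del_bp=del_bp, ins_seq=ins_seq, mh_len=mh_len, mh_seq="A" * mh_len,
        sv_id=sv_id, size_class=size_class,
    )


def synthetic_sv_junction_sites() -> "list[RejoinedSite]":
    """Synthetic stand-in for the 26 SV junctions (13 SVs, 2 each).

    Reproduces the printed junction accounting: 6 no-indel, 11
    only-deletion (all with MH), 1 only-insertion, 8 indel sites; 9 of 19
    junction deletions and 6 of 9 insertions are ≤5 bp, so 16 of 26 sites
    carry 0–5 bp indels; among only-deletion sites five have MH ≥3 bp.
    Coordinates and sequences are placeholders.
    """
    sites: "list[RejoinedSite]" = []
    mk = lambda i, d, ins, mh: sites.append(_site("svfix", f"SV{(i // 2) + 1}", d, ins, mh))
    i = 0
    for _ in range(6):  # no-indel
        mk(i, 0, "", 0); i += 1
    # only-deletion: all MH-positive; deletion sizes 6 small (<=5), 5 large
    only_del = [(3, 1), (2, 1), (5, 2), (4, 2), (1, 2), (5, 2),
                (800, 3), (1200, 3), (60, 3), (2500, 4), (150, 5)]
    for d, mh in only_del:
        mk(i, d, "", mh); i += 1
    mk(i, 0, "G", 0); i += 1  # only-insertion (potential duplication)
    # indel sites: (del, ins); 3 with both <=5; insertions >5 bp: 13/15/17
    indel = [(2, "AC"), (3, "A"), (4, "TG"), (40, "GT"), (700, "CA"),
             (9, "T" * 13), (300, "G" * 15), (25, "C" * 17)]
    for d, ins in indel:
        mk(i, d, ins, 0); i += 1
    assert len(sites) == 26
    return sites


def synthetic_large_deletion_sites() -> "list[RejoinedSite]":
    """Synthetic stand-in for the 14 ≥100 bp deletion junctions.

    Three sites carry insertions (3, 3 and 13 bp; 21.4%), nine of the
    remaining eleven have MH (64.3% overall MH), two have neither.
    """
    sites = []
    specs = [(0, "AAC"), (0, "GTT"), (0, "A" * 13)]
    specs += [(m, "") for m in (1, 2, 2, 2, 2, 3, 3, 3, 4)]
    specs += [(0, ""), (0, "")]
    for j, (mh, ins) in enumerate(specs):
        sites.append(_site("delfix", f"LD{j + 1}", 0, ins, mh, "rearrangement"))
    assert len(sites) == 14
    return sites


def synthetic_small_medium_del_sites() -> "list[RejoinedSite]":
    """Synthetic 77 small-deletion and 34 medium-deletion rejoined sites.

    Feature and MH-length tallies match :data:`FEATURE_COUNTS` and
    :data:`MH_GE3_COUNTS` exactly.
    """
    sites = []

    def build(size_class, n_ins, mh_lens, n_none, del_bp):
        for j in range(n_ins):
            sites.append(_site("fix", f"{size_class}-i{j}", del_bp, "T", 0, size_class))
        for j, m in enumerate(mh_lens):
            sites.append(_site("fix", f"{size_class}-m{j}", del_bp, "", m, size_class))
        for j in range(n_none):
            sites.append(_site("fix", f"{size_class}-n{j}", del_bp, "", 0, size_class))

    small_mh = [3] * 12 + [1] * 20 + [2] * 16  # 12 of 48 >= 3 bp
    build("small_del", 5, small_mh, 24, 4)
    medium_mh = [3] * 10 + [4] * 7 + [1] * 6 + [2] * 7  # 17 of 30 >= 3 bp
    build("medium_del", 0, medium_mh, 4, 30)
    return sites


def synthetic_rearrangement_sites() -> "list[RejoinedSite]":
    """The 33-site deletion-associated rearrangement inventory.

    19 deletion-associated SV junctions (only-deletion + indel) merged with
    the 14 large-deletion junctions; no-indel and only-insertion SV sites
    are excluded. MH ≥3 bp holds at 9 of the 20 MH-positive sites.
    """
    from .junction_analysis import assemble_rearrangement_sites

    return assemble_rearrangement_sites(
        synthetic_sv_junction_sites(), synthetic_large_deletion_sites()
    )
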