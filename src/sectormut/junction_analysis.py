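"""Rejoined-site characterization for rearrangements and deletions.

A rearrangement junction joins two double-strand-break ends. Its repair
signature is read from three features:

* **microhomology (MH)** — identical sequence shared by the two joined ends
  that makes the breakpoint placement ambiguous. Quantified here as
  placement ambiguity: mh_len equals the number of alternative equal-length
  breakpoint placements producing the identical rejoined molecule, computed
  by extending the match in both directions from the junction.
* **site type** — no_indel, only_deletion, only_insertion, or indel,
  from the deleted bases and inserted sequence at the junction.
* **templated insertions** — inserted sequence copied from a nearby stretch
  of the reference (direct or reverse-complement strand), the signature of
  polymerase-θ-mediated end joining. The search covers ±window bp around
  both joined ends and lets the match extend from the insertion into its
  junction flanks (flank homology), mirroring how such templates are
  reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .records import (
    InputError,
    MutationRecord,
    ReferenceGenome,
    RejoinedSite,
    revcomp,
)

__all__ = [
    "compute_deletion_mh",
    "compute_sv_junction_mh",
    "classify_rejoined_site",
    "find_insertion_template",
    "TemplateHit",
    "JunctionFeatureTable",
    "summarize_junction_features",
    "deletion_site",
    "assemble_rearrangement_sites",
    "annotate_sites",
]

SIZE_CLASSES = ("rearrangement", "medium_del", "small_del")

_MAX_MH_SCAN = 500  # MH extension cap; no biological junction approaches this


def _common_prefix(a: str, b: str, limit: int = _MAX_MH_SCAN) -> int:
    n = min(len(a), len(b), limit)
    k = 0
    while k < n and a[k] == b[k]:
        k += 1
    return k


def _common_suffix(a: str, b: str, limit: int = _MAX_MH_SCAN) -> int:
    n = min(len(a), len(b), limit)
    k = 0
    while k < n and a[-1 - k] == b[-1 - k]:
        k += 1
    return k


def junction_mh(
    left_flank: str, left_cont: str, right_precede: str, right_flank: str
) -> "tuple[int, str]":
    """MH of a junction given its four sequence contexts.

    ``left_flank``/``right_flank`` are the joined sequences entering and
    leaving the junction; ``left_cont`` continues past the left break in its
    source molecule and ``right_precede`` precedes the right break in its
    source. MH extends rightward while the joined right flank still matches
    the left source, and leftward symmetrically.
    """
    r = _common_prefix(right_flank, left_cont)
    l = _common_suffix(left_flank, right_precede)
    seq = (left_flank[len(left_flank) - l :] if l else "") + right_flank[:r]
    return l + r, seq


def compute_deletion_mh(
    genome: ReferenceGenome, chrom: str, del_start: int, del_end: int
) -> "tuple[int, str]":
    """MH of a plain deletion, 0-based half-open interval.

    Equals the placement-ambiguity count: (number of equal-length deletion
    placements yielding the identical mutated chromosome) − 1. Windows never
    cross chromosome ends.
    """
    seq = genome[chrom]
    if not (0 <= del_start < del_end <= len(seq)):
        raise InputError(
            f"deletion [{del_start}, {del_end}) out of range for {chrom!r}"
        )
    return junction_mh(seq[:del_start], seq[del_start:], seq[:del_end], seq[del_end:])


def _side_contexts(genome: ReferenceGenome, site: RejoinedSite) -> "tuple[str, str, str, str]":
    """Sequence contexts of the two joined ends in joined orientation."""
    seq_a, seq_b = genome[site.chrom_a], genome[site.chrom_b]
    if site.strand_a == "+":
        left_flank, left_cont = seq_a[: site.pos_a + 1], seq_a[site.pos_a + 1 :]
    else:
        left_flank = revcomp(seq_a[site.pos_a :])
        left_cont = revcomp(seq_a[: site.pos_a])
    if site.strand_b == "+":
        right_precede, right_flank = seq_b[: site.pos_b], seq_b[site.pos_b :]
    else:
        right_precede = revcomp(seq_b[site.pos_b + 1 :])
        right_flank = revcomp(seq_b[: site.pos_b + 1])
    return left_flank, left_cont, right_precede, right_flank


def compute_sv_junction_mh(
    genome: ReferenceGenome, site: RejoinedSite
) -> "tuple[int, str]":
    """MH between the two joined ends of an SV junction.

    The inverted partner is reverse-complemented before comparison. A site
    carrying an insertion has no MH by definition and returns ``(0, "")``.
    """
    if site.ins_seq:
        return 0, ""
    return junction_mh(*_side_contexts(genome, site))


def classify_rejoined_site(site: RejoinedSite) -> str:
    """Four-way junction typing from deleted bases and inserted sequence.

    Short (1–2 bp) insertions complementary to the opposite side of an
    inverted fragment are typed as insertions (``duplication_like`` flags
    them as potential duplications).
    """
    return site.site_type


@dataclass
class TemplateHit:
    """Best local template explaining an inserted sequence."""

    strand: str  # direct | revcomp
    end: str  # A | B — which joined end's neighbourhood holds the template
    offset_bp: int  # template start relative to the junction breakpoint
    core_len: int  # inserted bases matched by the template
    flank_left: int  # homology extending into the left junction flank
    flank_right: int  # homology extending into the right junction flank
    template_seq: str = ""

    @property
    def total_len(self) -> int:
        return self.core_len + self.flank_left + self.flank_right


def _scan_window(
    window_seq: str,
    window_offset: int,
    strand: str,
    end: str,
    ins: str,
    left_join: str,
    right_join: str,
    max_flank: int,
    trivial_left_t: Optional[int] = None,
    trivial_right_tk: Optional[int] = None,
) -> "list[TemplateHit]":
    """All maximal exact matches of insertion substrings within one window.

    ``trivial_left_t`` / ``trivial_right_tk`` mark the window positions where
    a flank extension would compare the junction flank against its own source
    bases (an identity placement); such extensions explain nothing about the
    insertion and earn no flank credit.
    """
    hits = []
    m = len(ins)
    n = len(window_seq)
    for t in range(n):
        for s in range(m):
            if window_seq[t] != ins[s]:
                continue
            # maximality: extend from (t, s) and only keep starts
            if t > 0 and s > 0 and window_seq[t - 1] == ins[s - 1]:
                continue
            k = 0
            while t + k < n and s + k < m and window_seq[t + k] == ins[s + k]:
                k += 1
            fl = fr = 0
            if s == 0 and t != trivial_left_t:
                fl = _common_suffix(window_seq[:t], left_join, limit=max_flank)
            if s + k == m and t + k != trivial_right_tk:
                fr = _common_prefix(window_seq[t + k :], right_join, limit=max_flank)
            hits.append(
                TemplateHit(
                    strand=strand,
                    end=end,
                    offset_bp=window_offset + t,
                    core_len=k,
                    flank_left=fl,
                    flank_right=fr,
                    template_seq=window_seq[t - fl : t + k + fr],
                )
            )
    return hits


def find_insertion_template(
    genome: ReferenceGenome,
    site: RejoinedSite,
    window: int = 100,
    min_len: int = 4,
) -> Optional[TemplateHit]:
    """Longest local template for the insertion at a rejoined site.

    Searches ±``window`` bp of both joined ends, on the direct and
    reverse-complement strands, for the longest exact match to the inserted
    sequence; the match may extend into the sequence flanking the insertion
    in the rejoined molecule (flank homology). A template must first explain
    the insertion: candidates are ranked by core length (inserted bases
    covered), then total length, ties broken by smaller \\|offset\\|, then the
    direct strand. Hits shorter than ``min_len`` in total are suppressed.
    ``None`` when no qualifying template exists.
    """
    if not site.ins_seq:
        raise InputError("site carries no insertion")
    ins = site.ins_seq
    left_flank, _, _, right_flank = _side_contexts(genome, site)
    left_join = left_flank[-window:]
    right_join = right_flank[:window]

    candidates: "list[TemplateHit]" = []
    ends = (
        ("A", site.chrom_a, site.pos_a, site.strand_a),
        ("B", site.chrom_b, site.pos_b, site.strand_b),
    )
    for end, chrom, bp, strand_src in ends:
        seq = genome[chrom]
        lo, hi = max(bp - window, 0), min(bp + window + 1, len(seq))
        w = seq[lo:hi]
        # identity placements of the junction's own flanks (see _scan_window)
        d_left = bp + 1 - lo if (end == "A" and strand_src == "+") else None
        d_right = bp - lo if (end == "B" and strand_src == "+") else None
        r_left = hi - bp if (end == "A" and strand_src == "-") else None
        r_right = hi - 1 - bp if (end == "B" and strand_src == "-") else None
        candidates += _scan_window(
            w, lo - bp, "direct", end, ins, left_join, right_join, window,
            trivial_left_t=d_left, trivial_right_tk=d_right,
        )
        candidates += _scan_window(
            revcomp(w), bp - hi + 1, "revcomp", end, ins, left_join, right_join, window,
            trivial_left_t=r_left, trivial_right_tk=r_right,
        )
    candidates = [h for h in candidates if h.total_len >= min_len and h.core_len >= 1]
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda h: (-h.core_len, -h.total_len, abs(h.offset_bp), h.strand != "direct"),
    )


def deletion_site(genome: ReferenceGenome, record: MutationRecord) -> RejoinedSite:
    """Convert a deletion (or delins) call into its rejoined site.

    Uses the VCF anchor-base representation: the deleted interval starts at
    the base after ``pos``; alt bases beyond the anchor are junction
    insertions.
    """
    ref, alt = record.ref_allele, record.alt_allele
    if len(ref) <= len(alt):
        raise InputError("record is not a deletion")
    del_start = record.pos  # 0-based: first deleted base
    del_end = record.pos - 1 + len(ref)
    ins = alt[1:] if alt[0] == ref[0] else alt
    mh_len, mh_seq = (0, "")
    if not ins:
        mh_len, mh_seq = compute_deletion_mh(genome, record.chrom, del_start, del_end)
    return RejoinedSite(
        sector_id=record.sector_id,
        chrom_a=record.chrom,
        pos_a=del_start - 1,
        strand_a="+",
        chrom_b=record.chrom,
        pos_b=del_end,
        strand_b="+",
        del_bp=del_end - del_start,
        ins_seq=ins,
        mh_len=mh_len,
        mh_seq=mh_seq,
        sv_id=f"{record.sector_id}:{record.chrom}:{record.pos}",
    )


def annotate_sites(
    genome: ReferenceGenome, sites: Iterable[RejoinedSite]
) -> "list[RejoinedSite]":
    """Fill MH for insertion-free sites from the reference."""
    out = []
    for s in sites:
        if not s.ins_seq and s.mh_len == 0:
            mh_len, mh_seq = compute_sv_junction_mh(genome, s)
            s = RejoinedSite(**{**s.__dict__, "mh_len": mh_len, "mh_seq": mh_seq})
        out.append(s)
    return out


def assemble_rearrangement_sites(
    sv_junctions: Sequence[RejoinedSite],
    large_del_junctions: Sequence[RejoinedSite],
) -> "list[RejoinedSite]":
    """Deletion-associated rearrangement site inventory.

    SV junctions of type only_deletion or indel, plus every junction of a
    ≥100 bp deletion; no_indel and only_insertion SV junctions are excluded
    so the inventory reflects deletion-associated rejoining.
    """
    kept = [
        s for s in sv_junctions if s.site_type in ("only_deletion", "indel")
    ] + list(large_del_junctions)
    out = []
    for s in kept:
        d = dict(s.__dict__)
        d["size_class"] = "rearrangement"
        out.append(RejoinedSite(**d))
    return out


@dataclass
class JunctionFeatureTable:
    """Per-size-class junction feature tallies (three exclusive categories)."""

    counts: "dict[str, dict[str, int]]"

    @classmethod
    def empty(cls) -> "JunctionFeatureTable":
        return cls(
            {
                c: {"ins_pos": 0, "ins_neg_mh_pos": 0, "ins_neg_mh_neg": 0,
                    "mh_le2": 0, "mh_ge3": 0, "total": 0}
                for c in SIZE_CLASSES
            }
        )

    def row(self, size_class: str) -> "dict[str, int]":
        return self.counts[size_class]

    def contingency(self, class_a: str, class_b: str, feature: str) -> "list[list[int]]":
        """2×2 table: feature-positive vs rest, class_a vs class_b.

        ``feature`` is one of ``ins`` (any insertion), ``mh`` (no insertion,
        MH present), ``none`` (neither), ``mh_ge3`` (MH length ≥3 among
        MH-positive sites).
        """
        rows = []
        for c in (class_a, class_b):
            r = self.counts[c]
            if feature == "ins":
                pos, tot = r["ins_pos"], r["total"]
            elif feature == "mh":
                pos, tot = r["ins_neg_mh_pos"], r["total"]
            elif feature == "none":
                pos, tot = r["ins_neg_mh_neg"], r["total"]
            elif feature == "mh_ge3":
                pos, tot = r["mh_ge3"], r["mh_le2"] + r["mh_ge3"]
            else:
                raise InputError(f"unknown feature {feature!r}")
            rows.append([pos, tot - pos])
        return rows

    def as_dict(self) -> dict:
        return {c: dict(v) for c, v in self.counts.items()}


def summarize_junction_features(sites: Iterable[RejoinedSite]) -> JunctionFeatureTable:
    """Tally INS(+), INS(−)MH(+), INS(−)MH(−) and the MH-length split.

    Every site must carry a size class. MH(+) means mh_len ≥ 1; sites with
    insertions count as MH(−), keeping the three categories exclusive. The
    MH-length split partitions MH-positive sites at the 2/3 bp boundary.
    """
    table = JunctionFeatureTable.empty()
    for s in sites:
        if s.size_class not in SIZE_CLASSES:
            raise InputError(f"site {s.sv_id!r} lacks a size class")
        row = table.counts[s.size_class]
        row["total"] += 1
        if s.has_insertion:
            row["ins_pos"] += 1
        elif s.has_mh:
            row["ins_neg_mh_pos"] += 1
            row["mh_ge3" if s.mh_len >= 3 else "mh_le2"] += 1
        else:
            row["ins_neg_mh_neg"] += 1
    return table
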