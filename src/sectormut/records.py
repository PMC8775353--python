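"""Core domain records shared by every pipeline stage.

Coordinates are 0-based half-open internally; every file interface is
1-based inclusive (VCF convention). A :class:`MutationRecord` stores the
1-based leftmost affected position as read from or written to files; helper
properties expose the 0-based affected interval used by interval arithmetic
(complex-event chaining, junction analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

__all__ = [
    "MCLASSES",
    "ReferenceGenome",
    "MutationRecord",
    "RejoinedSite",
    "SVRecord",
    "DepthTrack",
    "revcomp",
    "normalize_variant",
]

#: The nine-group mutation taxonomy plus the pre-classification placeholder.
MCLASSES = (
    "SBS",
    "INS1",
    "DEL1",
    "INS2_99",
    "DEL2_99",
    "INS100",
    "DEL100",
    "SV",
    "COMPLEX",
    "UNCLASSIFIED",
)

_ALPHABET = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMP)[::-1]


class FormatError(ValueError):
    """Malformed external representation (bad row, bad alphabet, duplicate name)."""


class InputError(ValueError):
    """Invalid argument or out-of-range request."""


@dataclass
class ReferenceGenome:
    """An ordered mapping of chromosome name to uppercase nucleotide string."""

    chromosomes: "dict[str, str]"

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise FormatError(f"chromosome {name!r} is empty")
            bad = set(seq) - _ALPHABET
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains characters outside ACGTN: {sorted(bad)}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __getitem__(self, chrom: str) -> str:
        return self.chromosomes[chrom]

    @property
    def names(self) -> "list[str]":
        return list(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice, clipped to the chromosome bounds."""
        seq = self.chromosomes[chrom]
        return seq[max(start, 0) : min(end, len(seq))]


def normalize_variant(
    chrom_seq: str, pos: int, ref: str, alt: str
) -> "tuple[int, str, str]":
    """Left-align and trim an indel against the reference (VCF convention).

    ``pos`` is 1-based; the returned position is 1-based. SNVs and balanced
    substitutions pass through unchanged. Idempotent.
    """
    if ref == alt:
        raise InputError("ref and alt alleles are identical")
    # shift left while the trailing bases agree; re-extend from the reference
    # when an allele empties (classic vt-normalize algorithm)
    while ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        trimmed_ref, trimmed_alt = ref[:-1], alt[:-1]
        if not trimmed_ref or not trimmed_alt:
            if pos <= 1:
                break  # pinned at the chromosome start
            prev = chrom_seq[pos - 2]
            ref, alt, pos = prev + trimmed_ref, prev + trimmed_alt, pos - 1
        else:
            ref, alt = trimmed_ref, trimmed_alt
    # trim the shared prefix down to the anchor base
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class MutationRecord:
    """One called mutation in one sector."""

    sector_id: str
    chrom: str
    pos: int  # 1-based leftmost affected position
    ref_allele: str
    alt_allele: str
    af: float
    alt_reads: Optional[int] = None
    depth: Optional[int] = None
    mclass: str = "UNCLASSIFIED"
    members: "tuple[MutationRecord, ...]" = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.af <= 1.0:
            raise InputError(f"af must lie in [0, 1], got {self.af}")
        if self.ref_allele == self.alt_allele:
            raise InputError("ref and alt alleles are identical")
        if self.mclass not in MCLASSES:
            raise InputError(f"unknown mutation class {self.mclass!r}")
        if self.depth is not None:
            if self.depth <= 0:
                if (self.alt_reads or 0) > 0:
                    raise InputError("alt_reads > 0 with depth 0")
                raise InputError("depth must be positive")
            if self.alt_reads is not None:
                if abs(self.af - self.alt_reads / self.depth) > 0.005:
                    raise InputError(
                        f"af {self.af} inconsistent with {self.alt_reads}/{self.depth}"
                    )

    @property
    def variant_key(self) -> "tuple[str, int, str, str]":
        """Cross-sample recurrence key (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def affected_start(self) -> int:
        """0-based start of the affected reference interval."""
        if self.mclass == "COMPLEX" and self.members:
            return min(m.affected_start for m in self.members)
        if len(self.ref_allele) > len(self.alt_allele) or len(self.ref_allele) < len(
            self.alt_allele
        ):
            # anchor-base representation: the first base is unchanged context
            return self.pos  # pos-1 is the anchor; affected starts at pos
        return self.pos - 1

    @property
    def affected_end(self) -> int:
        """0-based exclusive end of the affected reference interval."""
        if self.mclass == "COMPLEX" and self.members:
            return max(m.affected_end for m in self.members)
        if len(self.ref_allele) > len(self.alt_allele):  # deletion
            return self.pos - 1 + len(self.ref_allele)
        if len(self.ref_allele) < len(self.alt_allele):  # insertion: point event
            return self.pos
        return self.pos - 1 + len(self.ref_allele)

    @property
    def affected_bp(self) -> int:
        """Number of reference/alt bases this event touches (complex: sum of members)."""
        if self.mclass == "COMPLEX" and self.members:
            return sum(m.affected_bp for m in self.members)
        return max(self.affected_end - self.affected_start, self.indel_len)

    @property
    def indel_len(self) -> int:
        return abs(len(self.alt_allele) - len(self.ref_allele))

    def with_class(self, mclass: str) -> "MutationRecord":
        return replace(self, mclass=mclass)


@dataclass
class RejoinedSite:
    """One junction of a rearrangement: two reference ends joined together.

    ``chrom_a``/``pos_a``/``strand_a`` is the end contributing the upstream
    (left) flank of the joined molecule; ``+`` means the flank runs in
    reference orientation, ``-`` means it was reverse-complemented. Positions
    are 0-based breakpoints: for the left end the break falls just AFTER
    ``pos_a`` bases of flank; for the right end the joined sequence resumes AT
    ``pos_b``.
    """

    sector_id: str
    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    del_bp: int = 0
    ins_seq: str = ""
    mh_len: int = 0
    mh_seq: str = ""
    sv_id: str = ""
    size_class: Optional[str] = None  # rearrangement | medium_del | small_del
    duplication_like: bool = False

    def __post_init__(self) -> None:
        if self.del_bp < 0:
            raise InputError("del_bp must be non-negative")
        if self.mh_len and self.ins_seq:
            raise InputError("mh_len > 0 is only meaningful when ins_seq is empty")
        if len(self.mh_seq) != self.mh_len:
            raise InputError("mh_seq length must equal mh_len")

    @property
    def site_type(self) -> str:
        if self.del_bp == 0 and not self.ins_seq:
            return "no_indel"
        if self.del_bp > 0 and not self.ins_seq:
            return "only_deletion"
        if self.del_bp == 0 and self.ins_seq:
            return "only_insertion"
        return "indel"

    @property
    def has_insertion(self) -> bool:
        return bool(self.ins_seq)

    @property
    def has_mh(self) -> bool:
        return self.mh_len >= 1


@dataclass
class SVRecord:
    """A structural variation (inversion or reciprocal translocation)."""

    sector_id: str
    sv_type: str  # inversion | translocation
    junctions: "list[RejoinedSite]"
    span_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sv_type not in ("inversion", "translocation"):
            raise InputError(f"unknown sv_type {self.sv_type!r}")
        if len(self.junctions) != 2:
            raise InputError("an SV carries exactly 2 junctions")
        if self.sv_type == "inversion":
            chroms = {j.chrom_a for j in self.junctions} | {
                j.chrom_b for j in self.junctions
            }
            if len(chroms) != 1:
                raise InputError("inversion junctions must lie on one chromosome")


class DepthTrack:
    """Per-chromosome read-depth arrays, per-position or pre-binned.

    ``bin_width`` is 1 for per-position tracks. ``widths`` records the true
    width of each bin (the terminal bin of a chromosome may be partial).
    """

    def __init__(
        self,
        depths: Mapping[str, Iterable[float]],
        bin_width: int = 1,
        widths: Optional[Mapping[str, Iterable[int]]] = None,
    ) -> None:
        import numpy as np

        self.bin_width = int(bin_width)
        self.depths = {c: np.asarray(list(v), dtype=float) for c, v in depths.items()}
        for c, arr in self.depths.items():
            if (arr < 0).any():
                raise FormatError(f"negative depth on chromosome {c!r}")
        if widths is None:
            self.widths = {
                c: np.full(len(arr), self.bin_width, dtype=int)
                for c, arr in self.depths.items()
            }
        else:
            self.widths = {c: np.asarray(list(v), dtype=int) for c, v in widths.items()}

    @property
    def chroms(self) -> "list[str]":
        return list(self.depths)
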