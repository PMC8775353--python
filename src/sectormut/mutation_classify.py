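"""Mutation taxonomy, complex-event merging, and spectrum summaries.

Every mutation is assigned to one of nine groups: SBS, 1-bp insertion and
deletion, 2–99 bp insertion and deletion, ≥100 bp insertion and deletion,
structural variation (SV), and complex. A complex event is a chain of
nearby calls — at least one SBS plus other SBSs or small indels separated
by less than 10 bp — merged into a single record, since such clusters
likely arise from one local repair event rather than independent hits.

Spectrum summaries report counts per class, single-base substitutions in
the six strand-collapsed classes, the transition:transversion ratio, and
the deletion size histogram (1, 2–9, 10–99, ≥100 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

from .records import InputError, MutationRecord, SVRecord

__all__ = [
    "SBS_CLASSES",
    "TRANSITION_CLASSES",
    "classify_mutation",
    "classify_all",
    "sbs_class",
    "merge_complex",
    "size_class_of",
    "SpectrumSummary",
    "summarize_spectrum",
]

#: Strand-collapsed single-base-substitution classes, keyed by (ref, alt)
#: on the purine-normalized strand.
SBS_CLASSES = (
    "A:T>T:A",
    "A:T>G:C",
    "A:T>C:G",
    "G:C>A:T",
    "G:C>T:A",
    "G:C>C:G",
)
TRANSITION_CLASSES = frozenset({"A:T>G:C", "G:C>A:T"})

_COLLAPSE = {
    ("A", "T"): "A:T>T:A",
    ("T", "A"): "A:T>T:A",
    ("A", "G"): "A:T>G:C",
    ("T", "C"): "A:T>G:C",
    ("A", "C"): "A:T>C:G",
    ("T", "G"): "A:T>C:G",
    ("G", "A"): "G:C>A:T",
    ("C", "T"): "G:C>A:T",
    ("G", "T"): "G:C>T:A",
    ("C", "A"): "G:C>T:A",
    ("G", "C"): "G:C>C:G",
    ("C", "G"): "G:C>C:G",
}


def sbs_class(ref: str, alt: str) -> str:
    """Strand-collapsed class of a single-base substitution."""
    try:
        return _COLLAPSE[(ref, alt)]
    except KeyError as exc:
        raise InputError(f"not a single-base substitution: {ref}>{alt}") from exc


def classify_mutation(record: Union[MutationRecord, SVRecord]) -> str:
    """Assign the taxonomy class from the alleles (or SV status)."""
    if isinstance(record, SVRecord):
        return "SV"
    if record.mclass == "COMPLEX":
        return "COMPLEX"
    ref, alt = record.ref_allele, record.alt_allele
    if "," in alt:
        raise InputError("multiallelic record; split before classification")
    if len(ref) == len(alt):
        if len(ref) == 1:
            return "SBS"
        return "COMPLEX"  # multi-base balanced substitution
    n = abs(len(ref) - len(alt))
    if len(alt) > len(ref):
        return "INS1" if n == 1 else ("INS2_99" if n < 100 else "INS100")
    return "DEL1" if n == 1 else ("DEL2_99" if n < 100 else "DEL100")


def classify_all(records: Iterable[MutationRecord]) -> "list[MutationRecord]":
    return [r.with_class(classify_mutation(r)) for r in records]


def _separation(prev: MutationRecord, nxt: MutationRecord) -> int:
    """1-based distance between last affected base of prev and first of nxt."""
    prev_last = prev.affected_end  # 0-based exclusive end == 1-based last base
    nxt_first = nxt.affected_start + 1
    return nxt_first - prev_last


def merge_complex(
    records: Sequence[MutationRecord], gap_max: int = 10
) -> "list[MutationRecord]":
    """Chain nearby calls into complex events.

    Within one sector and chromosome, records whose affected intervals are
    separated by fewer than ``gap_max`` bases are chained transitively. A
    chain of two or more records containing at least one SBS becomes one
    COMPLEX record spanning the chain; pure-indel chains are left unmerged.
    """
    recs = sorted(records, key=lambda r: (r.sector_id, r.chrom, r.pos))
    out: "list[MutationRecord]" = []
    chain: "list[MutationRecord]" = []

    def flush() -> None:
        if len(chain) >= 2 and any(
            classify_mutation(m) == "SBS" for m in chain
        ):
            first = chain[0]
            merged = MutationRecord(
                sector_id=first.sector_id,
                chrom=first.chrom,
                pos=first.pos,
                ref_allele=",".join(m.ref_allele for m in chain),
                alt_allele=",".join(m.alt_allele for m in chain),
                af=sum(m.af for m in chain) / len(chain),
                mclass="COMPLEX",
                members=tuple(chain),
            )
            out.append(merged)
        else:
            out.extend(chain)
        chain.clear()

    for r in recs:
        if chain and (
            r.sector_id != chain[-1].sector_id
            or r.chrom != chain[-1].chrom
            or _separation(chain[-1], r) >= gap_max
        ):
            flush()
        chain.append(r)
    flush()
    return out


def size_class_of(record: Union[MutationRecord, SVRecord]) -> Optional[str]:
    """Rearrangement / medium / small deletion size class, else None.

    Deletions of 2–9 bp are small, 10–99 bp medium; SVs and deletions of
    ≥100 bp count as rearrangements.
    """
    if isinstance(record, SVRecord):
        return "rearrangement"
    mclass = record.mclass if record.mclass != "UNCLASSIFIED" else classify_mutation(record)
    if mclass == "DEL100":
        return "rearrangement"
    if mclass == "DEL2_99":
        return "medium_del" if record.indel_len >= 10 else "small_del"
    return None


@dataclass
class SpectrumSummary:
    """Counts per class, SBS spectrum, Ti:Tv, and deletion size histogram."""

    class_counts: "dict[str, int]"
    sbs_counts: "dict[str, int]"
    ti_tv: float
    deletion_sizes: "dict[str, int]"  # keys: "1", "2-9", "10-99", ">=100"
    total: int

    @property
    def proportions(self) -> "dict[str, float]":
        if self.total == 0:
            return {k: 0.0 for k in self.class_counts}
        return {k: v / self.total for k, v in self.class_counts.items()}

    def as_dict(self) -> dict:
        return dict(
            class_counts=self.class_counts,
            sbs_counts=self.sbs_counts,
            ti_tv=self.ti_tv,
            deletion_sizes=self.deletion_sizes,
            total=self.total,
            proportions=self.proportions,
        )


def summarize_spectrum(
    records: Iterable[Union[MutationRecord, SVRecord]]
) -> SpectrumSummary:
    """Tabulate the mutation spectrum of a classified record set."""
    class_counts = {c: 0 for c in ("SBS", "INS1", "DEL1", "INS2_99", "DEL2_99",
                                   "INS100", "DEL100", "SV", "COMPLEX")}
    sbs_counts = {c: 0 for c in SBS_CLASSES}
    del_sizes = {"1": 0, "2-9": 0, "10-99": 0, ">=100": 0}
    total = 0
    for r in records:
        mclass = classify_mutation(r) if not isinstance(r, SVRecord) else "SV"
        if isinstance(r, MutationRecord) and r.mclass in class_counts:
            mclass = r.mclass
        class_counts[mclass] += 1
        total += 1
        if mclass == "SBS" and isinstance(r, MutationRecord):
            sbs_counts[sbs_class(r.ref_allele, r.alt_allele)] += 1
        if mclass in ("DEL1", "DEL2_99", "DEL100") and isinstance(r, MutationRecord):
            n = r.indel_len
            if n == 1:
                del_sizes["1"] += 1
            elif n < 10:
                del_sizes["2-9"] += 1
            elif n < 100:
                del_sizes["10-99"] += 1
            else:
                del_sizes[">=100"] += 1
    transitions = sum(sbs_counts[c] for c in TRANSITION_CLASSES)
    transversions = sum(v for c, v in sbs_counts.items() if c not in TRANSITION_CLASSES)
    ti_tv = transitions / transversions if transversions else float("inf")
    return SpectrumSummary(class_counts, sbs_counts, ti_tv, del_sizes, total)
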