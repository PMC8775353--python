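"""Candidate-mutation selection for mosaic M1 sectors.

A mutation called in a chimeric sector is kept as a candidate when its
allele frequency falls in a window consistent with a heterozygous mutation
carried by a subpopulation of cells (default 0.1–0.8), it is supported by
enough reads (default ≥10), it is not recurrent across sectors (shared
calls are treated as systematic artifacts), and it is absent from the
parental lines.

Rules are applied in a fixed order — read support, AF window, recurrence —
and each removed record is attributed to the first rule that rejected it,
so :class:`FilterReport` counts are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Set, Tuple

from .records import MutationRecord

__all__ = ["FilterConfig", "FilterReport", "apply_candidate_filters", "subtract_parental"]

VariantKey = Tuple[str, int, str, str]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the candidate-selection cascade."""

    af_min: float = 0.1
    af_max: float = 0.8
    af_other_max: float = 0.05
    min_reads: int = 10
    max_samples_shared: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.af_min < self.af_max <= 1:
            raise ValueError("require 0 <= af_min < af_max <= 1")
        if self.af_other_max >= self.af_min:
            raise ValueError("af_other_max must be below af_min")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


@dataclass
class FilterReport:
    """Per-rule removal counts; removed + retained equals the input count."""

    input: int = 0
    read_support: int = 0
    af_window: int = 0
    recurrent: int = 0
    parental: int = 0
    retained: int = 0

    def as_dict(self) -> dict:
        return dict(
            input=self.input,
            read_support=self.read_support,
            af_window=self.af_window,
            recurrent=self.recurrent,
            parental=self.parental,
            retained=self.retained,
        )


def apply_candidate_filters(
    records: Sequence[MutationRecord], config: FilterConfig = FilterConfig()
) -> "tuple[list[MutationRecord], FilterReport]":
    """Run the selection cascade over calls from one or more sectors.

    A record is retained iff its AF lies in ``[af_min, af_max]``, it has
    ``alt_reads >= min_reads``, and no record with the same variant key
    reaches ``af_other_max`` in any other sector. A record absent from
    another sector counts as AF 0 there. Recurrence removes every record
    sharing the key, in all sectors involved.
    """
    report = FilterReport(input=len(records))

    # sector sets per variant key, counting only records at or above
    # af_other_max in their own sector
    key_sectors: "dict[VariantKey, set[str]]" = {}
    for r in records:
        if r.af >= config.af_other_max:
            key_sectors.setdefault(r.variant_key, set()).add(r.sector_id)

    retained: "list[MutationRecord]" = []
    for r in records:
        if r.alt_reads is not None and r.alt_reads < config.min_reads:
            report.read_support += 1
            continue
        if not (config.af_min <= r.af <= config.af_max):
            report.af_window += 1
            continue
        others = key_sectors.get(r.variant_key, set()) - {r.sector_id}
        if len(others) + 1 > config.max_samples_shared:
            report.recurrent += 1
            continue
        retained.append(r)
    report.retained = len(retained)
    return retained, report


def subtract_parental(
    records: Iterable[MutationRecord], parental_variants: Set[VariantKey]
) -> "list[MutationRecord]":
    """Drop records whose variant key occurs in the parental lines.

    Keys must be normalized with the same convention as the records
    (left-aligned indels). Order is preserved.
    """
    return [r for r in records if r.variant_key not in parental_variants]
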