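"""Allele-frequency distribution analysis of chimeric sectors.

A sector descended from a single mutated ancestral cell carries its
heterozygous mutations in every cell, giving AF ≈ 0.5; when that lineage
makes up only a fraction f of the sector, the expected AF is f/2 (for
f = 0.33, AF ≈ 0.17). The modal peak of the AF histogram therefore
estimates the carrier fraction of the dominant lineage, and mutations
inside the major-peak window (AF 0.25–0.5 by default) are attributed to a
single ancestral cell. Dividing their count by the haploid genome length
gives the per-base-pair mutation frequency of that cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import InputError, MutationRecord

__all__ = [
    "expected_af",
    "AFPeakSummary",
    "af_peak_summary",
    "MutationFrequencyEstimate",
    "estimate_mutation_frequency",
]


def expected_af(carrier_fraction: float) -> float:
    """Expected AF of a heterozygous mutation carried by fraction f of cells."""
    return 0.5 * carrier_fraction


@dataclass
class AFPeakSummary:
    bin_edges: "np.ndarray"
    histogram: "np.ndarray"
    peak_af: float
    major_set: "list[MutationRecord]"
    carrier_fraction: float

    def as_dict(self) -> dict:
        return dict(
            bin_edges=[float(x) for x in self.bin_edges],
            histogram=[int(x) for x in self.histogram],
            peak_af=self.peak_af,
            n_major=len(self.major_set),
            carrier_fraction=self.carrier_fraction,
        )


def af_peak_summary(
    records: Sequence[MutationRecord],
    bin_width: float = 0.05,
    major_lo: float = 0.25,
    major_hi: float = 0.5,
    af_max: float = 0.8,
) -> AFPeakSummary:
    """Histogram the AFs, locate the modal peak, select the major set.

    The peak is the midpoint of the modal histogram bin (ties resolved
    toward the higher-AF bin); the carrier fraction of the dominant lineage
    is 2 × peak AF, clipped to [0, 1]. The major set holds records with
    ``major_lo <= af <= major_hi``.
    """
    if not records:
        raise InputError("no records with AF values")
    afs = np.array([r.af for r in records])
    nbins = int(round(af_max / bin_width))
    edges = np.linspace(0.0, af_max, nbins + 1)
    hist, _ = np.histogram(afs, bins=edges)
    peak_bin = int(np.flatnonzero(hist == hist.max())[-1])  # ties -> higher AF
    # modal-bin midpoint, clipped into the observed AF range so a degenerate
    # single-value sample reports that value exactly
    peak_af = float(
        np.clip((edges[peak_bin] + edges[peak_bin + 1]) / 2, afs.min(), afs.max())
    )
    major = [r for r in records if major_lo <= r.af <= major_hi]
    return AFPeakSummary(
        bin_edges=edges,
        histogram=hist,
        peak_af=peak_af,
        major_set=major,
        carrier_fraction=float(np.clip(2 * peak_af, 0.0, 1.0)),
    )


@dataclass
class MutationFrequencyEstimate:
    sector_id: str
    n_major: int
    genome_length: int
    freq_per_bp: float


def estimate_mutation_frequency(
    major_set: Iterable[MutationRecord], genome_length: int, sector_id: str = ""
) -> MutationFrequencyEstimate:
    """Per-bp mutation frequency of the inferred single ancestral cell.

    The denominator is the haploid reference length.
    """
    if genome_length <= 0:
        raise InputError("genome_length must be positive")
    major = list(major_set)
    if not sector_id and major:
        sector_id = major[0].sector_id
    return MutationFrequencyEstimate(
        sector_id=sector_id,
        n_major=len(major),
        genome_length=int(genome_length),
        freq_per_bp=len(major) / genome_length,
    )
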