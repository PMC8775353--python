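"""Bin-based relative read depth (RRD) and low-dosage region calling.

Read depth pooled into non-overlapping 100-kb bins and normalized by the
genome-wide median bin depth gives the relative read depth. A heterozygous
deletion carried by a fraction f of cells removes one of two copies in
those cells, so the expected RRD over the deleted bins is 1 − f/2. Runs of
bins with RRD below 0.9 are candidate large deletions; per-chromosome mean
RRD screens for whole-chromosome aneuploidy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import DepthTrack, InputError

__all__ = [
    "BinDosage",
    "LowDosageRegion",
    "compute_rrd",
    "call_low_dosage_regions",
    "chromosome_dosage_summary",
    "expected_rrd",
]


def expected_rrd(carrier_fraction: float) -> float:
    """Expected RRD over a heterozygous deletion carried by fraction f of cells."""
    return 1.0 - carrier_fraction / 2.0


@dataclass
class BinDosage:
    chrom: str
    bin_start: int  # 0-based
    bin_width: int
    depth: float
    rrd: float

    def __post_init__(self) -> None:
        if self.rrd < 0:
            raise InputError("rrd must be non-negative")


@dataclass
class LowDosageRegion:
    chrom: str
    start_bin: int
    end_bin: int  # inclusive bin index
    start: int  # 0-based bp
    end: int  # 0-based exclusive bp
    mean_rrd: float
    n_bins: int
    candidate: bool = True  # False for the secondary 0.9 <= rrd < 0.97 tier


def compute_rrd(track: DepthTrack, bin_width: int = 100_000) -> "list[BinDosage]":
    """Normalize per-bin depth by the genome-wide median bin depth.

    Partial terminal bins are already depth-normalized by their true width
    at read time, so they enter the median on equal footing.
    """
    if track.bin_width == 1:  # per-position: pool into bins first
        depths, widths = {}, {}
        for chrom in track.chroms:
            arr = track.depths[chrom]
            n = len(arr)
            nbins = (n + bin_width - 1) // bin_width
            w = np.full(nbins, bin_width, dtype=int)
            w[-1] = n - (nbins - 1) * bin_width
            sums = np.add.reduceat(arr, np.arange(0, n, bin_width))
            depths[chrom] = sums / w
            widths[chrom] = w
        track = DepthTrack(depths, bin_width=bin_width, widths=widths)
    elif track.bin_width != bin_width:
        raise InputError(f"track binned at {track.bin_width}, requested {bin_width}")
    all_depths = np.concatenate([track.depths[c] for c in track.chroms])
    if not len(all_depths) or float(np.max(all_depths)) == 0.0:
        raise InputError("all-zero depth track cannot be normalized")
    median = float(np.median(all_depths))
    bins = []
    for chrom in track.chroms:
        start = 0
        for d, w in zip(track.depths[chrom], track.widths[chrom]):
            bins.append(
                BinDosage(chrom, start, int(w), float(d), float(d) / median)
            )
            start += int(w)
    return bins


def call_low_dosage_regions(
    bins: Sequence[BinDosage],
    rrd_threshold: float = 0.9,
    min_bins: int = 1,
    secondary_threshold: float = 0.97,
) -> "list[LowDosageRegion]":
    """Maximal runs of consecutive low-RRD bins, never spanning chromosomes.

    Primary candidates are runs with every bin below ``rrd_threshold``.
    Runs whose bins all fall below ``secondary_threshold`` but not below the
    primary threshold are reported with ``candidate=False`` — potential
    deletions too shallow to call.
    """
    regions: "list[LowDosageRegion]" = []

    def flush(chrom: str, run: "list[tuple[int, BinDosage]]", candidate: bool) -> None:
        if len(run) < min_bins:
            return
        idx = [i for i, _ in run]
        bs = [b for _, b in run]
        regions.append(
            LowDosageRegion(
                chrom=chrom,
                start_bin=idx[0],
                end_bin=idx[-1],
                start=bs[0].bin_start,
                end=bs[-1].bin_start + bs[-1].bin_width,
                mean_rrd=float(np.mean([b.rrd for b in bs])),
                n_bins=len(bs),
                candidate=candidate,
            )
        )

    by_chrom: "dict[str, list[BinDosage]]" = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, chrom_bins in by_chrom.items():
        chrom_bins = sorted(chrom_bins, key=lambda b: b.bin_start)
        run: "list[tuple[int, BinDosage]]" = []
        run_primary = False
        for i, b in enumerate(chrom_bins):
            primary = b.rrd < rrd_threshold
            secondary = b.rrd < secondary_threshold
            if not secondary:
                if run:
                    flush(chrom, run, run_primary)
                    run = []
                continue
            if run and primary != run_primary:
                flush(chrom, run, run_primary)
                run = []
            run_primary = primary
            run.append((i, b))
        if run:
            flush(chrom, run, run_primary)
    return regions


def chromosome_dosage_summary(bins: Iterable[BinDosage]) -> "dict[str, dict]":
    """Mean RRD per chromosome; values outside [0.9, 1.1] flagged."""
    acc: "dict[str, list[float]]" = {}
    for b in bins:
        acc.setdefault(b.chrom, []).append(b.rrd)
    return {
        c: {
            "mean_rrd": float(np.mean(v)),
            "n_bins": len(v),
            "flagged": not (0.9 <= float(np.mean(v)) <= 1.1),
        }
        for c, v in acc.items()
    }
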