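"""Readers and writers for every external representation.

Formats handled:

* reference genome — FASTA (via Bio.SeqIO)
* mutation tables — TSV dialect with header
  ``sector chrom pos ref alt alt_reads depth af class`` and a minimal VCF
  subset (CHROM POS REF ALT plus per-sample AD/DP), read via cyvcf2
* SV breakends — BEDPE-like TSV
  ``sector chromA posA strandA chromB posB strandB svtype ins_seq``
  (optional trailing ``sv_id`` and ``del_bp`` columns)
* depth tracks — TSV ``chrom pos depth`` (per-position) or
  ``chrom bin_start bin_width depth`` (pre-binned)

File coordinates are 1-based inclusive throughout; the in-memory model is
0-based half-open (see :mod:`sectormut.records`).
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .records import (
    DepthTrack,
    FormatError,
    InputError,
    MutationRecord,
    ReferenceGenome,
    RejoinedSite,
    normalize_variant,
)

__all__ = [
    "read_reference",
    "write_reference",
    "read_mutation_table",
    "write_mutation_table",
    "read_vcf",
    "write_vcf",
    "read_breakend_table",
    "write_breakend_table",
    "read_depth_track",
    "write_depth_track",
]

MUTATION_COLUMNS = [
    "sector",
    "chrom",
    "pos",
    "ref",
    "alt",
    "alt_reads",
    "depth",
    "af",
    "class",
]

BREAKEND_COLUMNS = [
    "sector",
    "chromA",
    "posA",
    "strandA",
    "chromB",
    "posB",
    "strandB",
    "svtype",
    "ins_seq",
]


def read_reference(path: os.PathLike) -> ReferenceGenome:
    """Parse a FASTA file into a :class:`ReferenceGenome`.

    Sequences are uppercased; duplicate record names, empty records, or
    characters outside A/C/G/T/N are rejected.
    """
    if not os.path.exists(path):
        raise InputError(f"reference FASTA not found: {path}")
    chroms: "dict[str, str]" = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise FormatError(f"duplicate chromosome name {rec.id!r}")
        chroms[rec.id] = str(rec.seq).upper()
    if not chroms:
        raise FormatError(f"no FASTA records in {path}")
    return ReferenceGenome(chroms)


def write_reference(genome: ReferenceGenome, path: os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _finalize_record(
    sector: str,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    alt_reads: Optional[int],
    depth: Optional[int],
    af: Optional[float],
    mclass: str,
    genome: Optional[ReferenceGenome],
    line_no: int,
) -> MutationRecord:
    if depth is not None and depth == 0:
        if alt_reads and alt_reads > 0:
            raise FormatError(f"line {line_no}: alt_reads > 0 with depth 0")
        depth = None
        alt_reads = None
    if af is None or (isinstance(af, float) and math.isnan(af)):
        if depth is None or alt_reads is None:
            raise FormatError(f"line {line_no}: neither af nor read counts present")
        af = alt_reads / depth
    if genome is not None and chrom in genome and len(ref) != len(alt):
        pos, ref, alt = normalize_variant(genome[chrom], pos, ref, alt)
    try:
        return MutationRecord(
            sector_id=sector,
            chrom=chrom,
            pos=int(pos),
            ref_allele=ref,
            alt_allele=alt,
            af=float(af),
            alt_reads=None if alt_reads is None else int(alt_reads),
            depth=None if depth is None else int(depth),
            mclass=mclass,
        )
    except InputError as exc:
        raise FormatError(f"line {line_no}: {exc}") from exc


def read_mutation_table(
    path: os.PathLike,
    dialect: str = "tsv",
    genome: Optional[ReferenceGenome] = None,
) -> "list[MutationRecord]":
    """Read a mutation table in the TSV dialect or the minimal VCF subset.

    With a reference supplied, indel alleles are left-aligned. ``af`` is
    computed as alt_reads/depth when not given; ``class`` defaults to
    UNCLASSIFIED.
    """
    if dialect == "vcf-min":
        return read_vcf(path, genome=genome)
    if dialect != "tsv":
        raise InputError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError as exc:
        raise InputError(str(exc)) from exc
    missing = [c for c in MUTATION_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FormatError(f"mutation table lacks columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()

        def _num(col, cast):
            v = d.get(col, "")
            return cast(v) if v not in ("", ".", None) else None

        try:
            records.append(
                _finalize_record(
                    d["sector"],
                    d["chrom"],
                    int(d["pos"]),
                    d["ref"].upper(),
                    d["alt"].upper(),
                    _num("alt_reads", int),
                    _num("depth", int),
                    _num("af", float),
                    d.get("class") or "UNCLASSIFIED",
                    genome,
                    i,
                )
            )
        except (ValueError, KeyError) as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"line {i}: malformed row ({exc})") from exc
    return records


def write_mutation_table(records: Iterable[MutationRecord], path: os.PathLike) -> None:
    rows = [
        {
            "sector": r.sector_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref_allele,
            "alt": r.alt_allele,
            "alt_reads": "" if r.alt_reads is None else r.alt_reads,
            "depth": "" if r.depth is None else r.depth,
            "af": f"{r.af:.6g}",
            "class": r.mclass,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_vcf(path: os.PathLike, genome: Optional[ReferenceGenome] = None) -> "list[MutationRecord]":
    """Read the minimal VCF subset: CHROM POS REF ALT + per-sample AD/DP."""
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise InputError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: "list[MutationRecord]" = []
    for i, var in enumerate(vcf, start=1):
        for alt in var.ALT:
            for si, sample in enumerate(samples):
                ad = var.format("AD")
                dp = var.format("DP")
                alt_reads = int(ad[si][1]) if ad is not None else None
                depth = int(dp[si][0]) if dp is not None else None
                if depth is not None and depth <= 0:
                    continue
                if alt_reads is not None and alt_reads < 0:
                    continue  # missing genotype for this sample
                records.append(
                    _finalize_record(
                        sample,
                        var.CHROM,
                        var.POS,
                        var.REF.upper(),
                        alt.upper(),
                        alt_reads,
                        depth,
                        None,
                        "UNCLASSIFIED",
                        genome,
                        i,
                    )
                )
    return records


def write_vcf(records: Sequence[MutationRecord], path: os.PathLike) -> None:
    """Write records as a minimal single-sample-per-sector VCF."""
    sectors = sorted({r.sector_id for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sectors)
            + "\n"
        )
        order = {s: i for i, s in enumerate(sectors)}
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            cells = ["./.:.,.:."] * len(sectors)
            ar = r.alt_reads if r.alt_reads is not None else round(r.af * (r.depth or 100))
            dp = r.depth if r.depth is not None else 100
            cells[order[r.sector_id]] = f"0/1:{dp - ar},{ar}:{dp}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\tPASS\t.\t"
                f"GT:AD:DP\t" + "\t".join(cells) + "\n"
            )


def read_breakend_table(path: os.PathLike) -> "list[RejoinedSite]":
    """Read junctions from the BEDPE-like breakend TSV (1-based positions)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError as exc:
        raise InputError(str(exc)) from exc
    missing = [c for c in BREAKEND_COLUMNS if c not in df.columns and c != "ins_seq"]
    if missing:
        raise FormatError(f"breakend table lacks columns {missing}")
    sites = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            sites.append(
                RejoinedSite(
                    sector_id=d["sector"],
                    chrom_a=d["chromA"],
                    pos_a=int(d["posA"]) - 1,
                    strand_a=d["strandA"],
                    chrom_b=d["chromB"],
                    pos_b=int(d["posB"]) - 1,
                    strand_b=d["strandB"],
                    del_bp=int(d.get("del_bp") or 0),
                    ins_seq=(d.get("ins_seq") or "").upper().replace(".", ""),
                    sv_id=d.get("sv_id", "") or d.get("svtype", ""),
                )
            )
        except (ValueError, KeyError) as exc:
            raise FormatError(f"line {i}: malformed breakend row ({exc})") from exc
    return sites


def write_breakend_table(sites: Iterable[RejoinedSite], path: os.PathLike) -> None:
    rows = [
        {
            "sector": s.sector_id,
            "chromA": s.chrom_a,
            "posA": s.pos_a + 1,
            "strandA": s.strand_a,
            "chromB": s.chrom_b,
            "posB": s.pos_b + 1,
            "strandB": s.strand_b,
            "svtype": s.sv_id,
            "ins_seq": s.ins_seq or ".",
            "sv_id": s.sv_id,
            "del_bp": s.del_bp,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=BREAKEND_COLUMNS + ["sv_id", "del_bp"]).to_csv(
        path, sep="\t", index=False
    )


def read_depth_track(
    path: os.PathLike,
    bin_width: int = 100_000,
    genome: Optional[ReferenceGenome] = None,
) -> DepthTrack:
    """Read a depth TSV, aggregating per-position input into fixed bins.

    Per-position rows (``chrom pos depth``) are pooled into non-overlapping
    bins of ``bin_width`` starting at position 1; a trailing partial bin keeps
    its true width. Pre-binned rows (``chrom bin_start bin_width depth``) pass
    through.
    """
    df = pd.read_csv(path, sep="\t")
    if set(df.columns) >= {"chrom", "bin_start", "bin_width", "depth"}:
        depths: "dict[str, list[float]]" = {}
        widths: "dict[str, list[int]]" = {}
        declared = int(df["bin_width"].iloc[0]) if len(df) else bin_width
        for chrom, sub in df.groupby("chrom", sort=False):
            if genome is not None and chrom not in genome:
                raise InputError(f"chromosome {chrom!r} absent from reference")
            depths[chrom] = sub["depth"].astype(float).tolist()
            widths[chrom] = sub["bin_width"].astype(int).tolist()
        return DepthTrack(depths, bin_width=declared, widths=widths)
    if not set(df.columns) >= {"chrom", "pos", "depth"}:
        raise FormatError("depth track needs (chrom,pos,depth) or binned columns")
    if (df["depth"] < 0).any():
        raise FormatError("negative depth values")
    depths, widths = {}, {}
    seen: "list[str]" = []
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom in seen:
            raise FormatError("depth track not sorted by chromosome")
        seen.append(chrom)
        pos = sub["pos"].to_numpy()
        if (np.diff(pos) <= 0).any():
            raise FormatError(f"unsorted positions on chromosome {chrom!r}")
        if genome is not None and chrom not in genome:
            raise InputError(f"chromosome {chrom!r} absent from reference")
        dep = sub["depth"].to_numpy(dtype=float)
        length = int(pos.max())
        if genome is not None:
            length = len(genome[chrom])
        nbins = (length + bin_width - 1) // bin_width
        idx = (pos - 1) // bin_width
        sums = np.bincount(idx, weights=dep, minlength=nbins)
        w = np.full(nbins, bin_width, dtype=int)
        w[-1] = length - (nbins - 1) * bin_width
        depths[chrom] = (sums / w).tolist()
        widths[chrom] = w.tolist()
    return DepthTrack(depths, bin_width=bin_width, widths=widths)


def write_depth_track(track: DepthTrack, path: os.PathLike) -> None:
    rows = []
    for chrom in track.chroms:
        w = track.widths[chrom]
        start = 0
        for d, width in zip(track.depths[chrom], w):
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": start + 1,
                    "bin_width": int(width),
                    "depth": f"{d:.6g}",
                }
            )
            start += int(width)
    pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_width", "depth"]).to_csv(
        path, sep="\t", index=False
    )
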