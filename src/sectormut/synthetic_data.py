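"""Synthetic chimeric-sector generator with full ground truth.

Emulates the observable signals of a diploid leaf sector composed of K cell
populations: each heterozygous mutation carried by a population of fraction
f is observed with alt reads ~ Binomial(depth, f/2) at site depth ~
Poisson(depth_mean); heterozygous deletions depress the binned read depth
toward 1 − f/2 of the genome-wide median; deletion and SV junctions carry
implanted microhomology, insertions, and local templates so that every
junction statistic has an exact truth value.

All randomness flows from the single seed in :class:`SimConfig`; no global
state. Re-running with the same seed reproduces byte-identical fixture
files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .records import (
    DepthTrack,
    InputError,
    MutationRecord,
    ReferenceGenome,
    RejoinedSite,
    revcomp,
)
from .junction_analysis import compute_deletion_mh, compute_sv_junction_mh

__all__ = [
    "SimConfig",
    "JunctionModel",
    "SectorSimTruth",
    "random_genome",
    "simulate_sector",
    "simulate_suite",
    "synthesize_deletion_junction",
    "synthesize_sv_junction",
    "emit_fixture_suite",
]

#: Mutation-class probabilities defaulting to the observed proportions over
#: 769 mutations in seven gamma-irradiated M1 sectors (SBS 467, +1 INS 24,
#: −1 DEL 82, 2–99 INS 6, 2–99 DEL 111, ≥100 DEL 12, SV 13, complex 54).
DEFAULT_SPECTRUM = {
    "SBS": 467 / 769,
    "INS1": 24 / 769,
    "DEL1": 82 / 769,
    "INS2_99": 6 / 769,
    "DEL2_99": 111 / 769,
    "DEL100": 12 / 769,
    "SV": 13 / 769,
    "COMPLEX": 54 / 769,
}

#: Strand-collapsed SBS class probabilities (transitions : transversions
#: balanced near 1, majors A:T>T:A, G:C>A:T, A:T>G:C).
DEFAULT_SBS_PROBS = {
    "A:T>T:A": 120 / 467,
    "A:T>G:C": 100 / 467,
    "A:T>C:G": 37 / 467,
    "G:C>A:T": 130 / 467,
    "G:C>T:A": 45 / 467,
    "G:C>C:G": 35 / 467,
}

_ALT_FOR = {
    ("A", "A:T>T:A"): "T", ("T", "A:T>T:A"): "A",
    ("A", "A:T>G:C"): "G", ("T", "A:T>G:C"): "C",
    ("A", "A:T>C:G"): "C", ("T", "A:T>C:G"): "G",
    ("G", "G:C>A:T"): "A", ("C", "G:C>A:T"): "T",
    ("G", "G:C>T:A"): "T", ("C", "G:C>T:A"): "A",
    ("G", "G:C>C:G"): "C", ("C", "G:C>C:G"): "G",
}


@dataclass
class JunctionModel:
    """Per-size-class junction feature probabilities.

    Defaults follow the observed feature frequencies at rejoined sites:
    insertions at 11/33 of rearrangement sites, 0/34 medium, 5/77 small;
    among insertion-free sites, MH at 20/22, 30/34, and 48/72; MH lengths
    drawn per class so that the ≥3 bp share lands near 45% / 57% / 25%.
    """

    ins_prob: "dict[str, float]" = field(
        default_factory=lambda: {
            "rearrangement": 11 / 33,
            "medium_del": 0.0,
            "small_del": 5 / 77,
        }
    )
    mh_prob: "dict[str, float]" = field(
        default_factory=lambda: {
            "rearrangement": 20 / 22,
            "medium_del": 30 / 34,
            "small_del": 48 / 72,
        }
    )
    mh_len_probs: "dict[str, dict[int, float]]" = field(
        default_factory=lambda: {
            "rearrangement": {1: 0.30, 2: 0.25, 3: 0.20, 4: 0.15, 5: 0.10},
            "medium_del": {1: 0.20, 2: 0.23, 3: 0.27, 4: 0.20, 5: 0.10},
            "small_del": {1: 0.45, 2: 0.30, 3: 0.15, 4: 0.10},
        }
    )
    ins_len_probs: "dict[str, dict[int, float]]" = field(
        default_factory=lambda: {
            "rearrangement": {1: 0.2, 2: 0.2, 3: 0.2, 4: 0.1, 6: 0.1, 13: 0.2},
            "medium_del": {1: 1.0},
            "small_del": {1: 1.0},
        }
    )
    template_prob: float = 0.8
    template_window: int = 100


@dataclass
class SimConfig:
    """Study conditions of a simulated sector suite.

    ``populations`` lists (cell fraction, mutation count) per sector; the
    default is one dominant single-cell-derived lineage (f = 0.7, peak AF
    0.35) plus a minor one, totalling ~110 mutations per sector as in the
    observed sectors. ``depth_mean`` defaults to the 85× study coverage.
    """

    seed: int
    genome: Optional[ReferenceGenome] = None
    n_chrom: int = 3
    chrom_len: int = 700_000
    n_sectors: int = 1
    populations: "tuple[tuple[float, int], ...]" = ((0.7, 80), (0.2, 30))
    spectrum: "dict[str, float]" = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    sbs_probs: "dict[str, float]" = field(default_factory=lambda: dict(DEFAULT_SBS_PROBS))
    junction: JunctionModel = field(default_factory=JunctionModel)
    depth_mean: float = 85.0
    bin_width: int = 100_000
    noise_rate: float = 0.1
    marker_loci: int = 1
    at_fraction: float = 0.5
    large_del_range: "tuple[int, int]" = (100_000, 160_000)
    medium_del_range: "tuple[int, int]" = (10, 99)
    small_del_range: "tuple[int, int]" = (2, 9)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InputError("seed is mandatory")
        for fracs in (self.populations,):
            if sum(f for f, _ in fracs) > 1 + 1e-9:
                raise InputError("population fractions must sum to <= 1")
        tot = sum(self.spectrum.values())
        if abs(tot - 1) > 1e-6:
            raise InputError("spectrum probabilities must sum to 1")


@dataclass
class SectorSimTruth:
    """Ground truth of one simulated sector."""

    sector_id: str
    populations: "list[tuple[float, int]]"
    mutations: "list[dict]"  # per implanted mutation: class, fraction, locus, junction truth
    deleted_regions: "list[tuple[str, int, int, float]]"  # chrom, start, end, fraction
    sv_junctions: "list[RejoinedSite]"
    marker_loci: "list[tuple[str, int]]" = field(default_factory=list)
    noise: "list[dict]" = field(default_factory=list)


def random_genome(
    rng: np.random.Generator,
    n_chrom: int = 2,
    chrom_len: int = 500_000,
    at_fraction: float = 0.5,
) -> ReferenceGenome:
    """I.i.d. random genome; ``at_fraction`` sets the A+T share."""
    p_at = at_fraction / 2
    p_gc = (1 - at_fraction) / 2
    probs = [p_at, p_gc, p_gc, p_at]
    chroms = {}
    for i in range(n_chrom):
        arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=chrom_len, p=probs)
        chroms[f"chr{i + 1}"] = arr.tobytes().decode()
    return ReferenceGenome(chroms)


def _draw_len(rng: np.random.Generator, probs: "dict[int, float]") -> int:
    lens = sorted(probs)
    p = np.array([probs[k] for k in lens], dtype=float)
    return int(rng.choice(lens, p=p / p.sum()))


class _Occupancy:
    """Tracks implanted intervals so mutations never overlap."""

    def __init__(self) -> None:
        self.used: "dict[str, list[tuple[int, int]]]" = {}

    def reserve(self, chrom: str, start: int, end: int, pad: int = 25) -> bool:
        return self.reserve_many(chrom, [(start, end)], pad)

    def reserve_many(
        self, chrom: str, intervals: "list[tuple[int, int]]", pad: int = 25
    ) -> bool:
        """Reserve all intervals atomically; none are kept on conflict."""
        ivs = self.used.setdefault(chrom, [])
        for start, end in intervals:
            for s, e in ivs:
                if start - pad < e and s < end + pad:
                    return False
        ivs.extend(intervals)
        return True

    def release_last(self, chrom: str, n: int) -> None:
        for _ in range(n):
            self.used[chrom].pop()


def synthesize_deletion_junction(
    seq: "list[str]",
    chrom: str,
    rng: np.random.Generator,
    size_class: str,
    del_len: int,
    model: JunctionModel,
    occupancy: _Occupancy,
    max_tries: int = 200,
    avoid: "Optional[list[tuple[str, int, int]]]" = None,
) -> "dict":
    """Implant a deletion junction with controlled MH / insertion / template.

    ``avoid`` lists (chrom, start, end) spans the deletion interval must not
    intersect — used to keep heterozygous large deletions disjoint so their
    dosage signals stay additive per region.

    Mutates ``seq`` in place (the reference context around the chosen
    breakpoints is rewritten to realize the requested MH exactly); resamples
    the locus when the context accidentally creates longer MH than
    requested. Returns the truth dict including the VCF-style record alleles.
    """
    n = len(seq)
    want_ins = rng.random() < model.ins_prob.get(size_class, 0.0)
    want_mh = (not want_ins) and rng.random() < model.mh_prob.get(size_class, 0.0)
    mh_len = _draw_len(rng, model.mh_len_probs[size_class]) if want_mh else 0
    ins_len = _draw_len(rng, model.ins_len_probs[size_class]) if want_ins else 0

    for _ in range(max_tries):
        s = int(rng.integers(200, n - del_len - 300))
        e = s + del_len
        if avoid and any(
            ac == chrom and s < ae and as_ < e for ac, as_, ae in avoid
        ):
            continue
        # only the two breakpoint neighbourhoods are rewritten; interior
        # bases of a large deletion may host other (independent) mutations
        jwin = [(s - mh_len - 2, min(s + mh_len + 2, e)),
                (max(e - mh_len - 2, s), e + mh_len + 2)]
        if not occupancy.reserve_many(chrom, jwin):
            continue
        # realize the requested MH: copy m bases across the junction, then
        # break the match at both boundaries
        bases = "ACGT"
        for i in range(mh_len):
            seq[e + i] = seq[s + i]
        seq[e + mh_len] = rng.choice([b for b in bases if b != seq[s + mh_len]])
        seq[s - 1] = rng.choice([b for b in bases if b != seq[e - 1]])
        genome_view = ReferenceGenome({chrom: "".join(seq)})
        got, mh_seq = compute_deletion_mh(genome_view, chrom, s, e)
        if got != mh_len:
            occupancy.release_last(chrom, 2)
            continue

        ins_seq, template = "", None
        if want_ins:
            if rng.random() < model.template_prob:
                strand = "direct" if rng.random() < 0.5 else "revcomp"
                margin = max(9, model.template_window - ins_len - 1)
                for _t in range(20):
                    off = int(rng.integers(8, margin))
                    side = str(rng.choice(["left", "right"]))
                    t0 = s - off - ins_len if side == "left" else e + off
                    if occupancy.reserve(chrom, t0, t0 + ins_len, pad=2):
                        break
                else:
                    side, t0 = "right", e + 8
                frag = "".join(seq[t0 : t0 + ins_len])
                ins_seq = frag if strand == "direct" else revcomp(frag)
                template = {"strand": strand, "start": t0, "len": ins_len, "side": side}
            else:
                ins_seq = "".join(rng.choice(list("ACGT"), size=ins_len))
        rec_pos = s  # 1-based anchor = s (0-based s-1)
        ref_allele = "".join(seq[s - 1 : e])
        alt_allele = seq[s - 1] + ins_seq
        return {
            "kind": "deletion",
            "chrom": chrom,
            "del_start": s,
            "del_end": e,
            "pos": rec_pos,
            "ref": ref_allele,
            "alt": alt_allele,
            "size_class": size_class,
            "mh_len": mh_len,
            "mh_seq": mh_seq,
            "ins_seq": ins_seq,
            "template": template,
        }
    raise InputError(
        f"could not place a {size_class} deletion of {del_len} bp "
        f"with mh_len {mh_len} after {max_tries} tries"
    )


def synthesize_sv_junction(
    seq: "list[str]",
    chrom: str,
    rng: np.random.Generator,
    site_type: str,
    model: JunctionModel,
    occupancy: _Occupancy,
    mh_len: int = 0,
    ins_len: int = 0,
    max_tries: int = 200,
) -> RejoinedSite:
    """Implant one inversion-style junction (forward end joined to a
    reverse-complemented end) of the requested site type.

    For insertion-free sites the requested MH is realized exactly in the
    reference; loci producing accidental extra MH are resampled.
    """
    n = len(seq)
    bases = "ACGT"
    for _ in range(max_tries):
        a = int(rng.integers(200, n // 2 - 300))
        b = int(rng.integers(n // 2 + 300, n - 300))
        if not occupancy.reserve(chrom, a - 5, a + mh_len + 5):
            continue
        if not occupancy.reserve(chrom, b - mh_len - 5, b + 5):
            continue
        del_bp = 0
        ins_seq = ""
        if site_type in ("only_deletion", "indel"):
            del_bp = int(rng.integers(1, 6))
        if site_type in ("only_insertion", "indel"):
            k = ins_len or int(rng.integers(1, 4))
            ins_seq = "".join(rng.choice(list(bases), size=k))
        site = RejoinedSite(
            sector_id="",
            chrom_a=chrom,
            pos_a=a,
            strand_a="+",
            chrom_b=chrom,
            pos_b=b,
            strand_b="-",
            del_bp=del_bp,
            ins_seq=ins_seq,
        )
        if not ins_seq:
            # right-extension MH: comp(seq[b - i]) must equal seq[a + 1 + i]
            for i in range(mh_len):
                seq[b - i] = revcomp(seq[a + 1 + i])
            seq[b - mh_len] = rng.choice(
                [x for x in bases if x != revcomp(seq[a + 1 + mh_len])]
            )
            # block left extension: seq[a] must differ from comp(seq[b + 1])
            if seq[a] == revcomp(seq[b + 1]):
                seq[b + 1] = rng.choice([x for x in bases if x != revcomp(seq[a])])
            genome_view = ReferenceGenome({chrom: "".join(seq)})
            got, mh_seq = compute_sv_junction_mh(genome_view, site)
            if got != mh_len:
                occupancy.release_last(chrom, 2)
                continue
            site = RejoinedSite(
                **{**site.__dict__, "mh_len": got, "mh_seq": mh_seq}
            )
        return site
    raise InputError(
        f"could not place an SV junction of type {site_type!r} after {max_tries} tries"
    )


def _draw_sbs(
    seq: "list[str]", chrom: str, rng: np.random.Generator,
    sbs_probs: "dict[str, float]", occupancy: _Occupancy, n: int
) -> "tuple[int, str, str, str]":
    classes = sorted(sbs_probs)
    p = np.array([sbs_probs[c] for c in classes])
    for _ in range(500):
        cls = str(rng.choice(classes, p=p / p.sum()))
        want = "AT" if cls.startswith("A:T") else "GC"
        pos = int(rng.integers(100, n - 100))
        if seq[pos] not in want:
            continue
        if not occupancy.reserve(chrom, pos, pos + 1):
            continue
        return pos, seq[pos], _ALT_FOR[(seq[pos], cls)], cls
    raise InputError("could not place an SBS")


def simulate_sector(
    config: SimConfig,
    sector_id: str = "sim-1",
    rng: Optional[np.random.Generator] = None,
    occupancy: Optional[_Occupancy] = None,
) -> "tuple[SectorSimTruth, list[MutationRecord], DepthTrack, ReferenceGenome]":
    """Simulate one sector.

    Returns (truth, observable mutation table, depth track, reference
    genome after junction-context implanting).
    """
    rng = rng or np.random.default_rng(config.seed)
    genome = config.genome or random_genome(
        rng, config.n_chrom, config.chrom_len, config.at_fraction
    )
    seqs = {c: list(s) for c, s in genome.chromosomes.items()}
    occupancy = occupancy or _Occupancy()
    chrom_names = list(seqs)

    truth = SectorSimTruth(sector_id, list(config.populations), [], [], [])
    classes = sorted(config.spectrum)
    probs = np.array([config.spectrum[c] for c in classes])
    probs = probs / probs.sum()

    for frac, n_mut in config.populations:
        draw = rng.multinomial(n_mut, probs)
        for cls, count in zip(classes, draw):
            for _ in range(count):
                chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                seq = seqs[chrom]
                n = len(seq)
                entry: dict
                if cls == "SBS":
                    pos, ref, alt, sbs_cls = _draw_sbs(
                        seq, chrom, rng, config.sbs_probs, occupancy, n
                    )
                    entry = {
                        "kind": "SBS", "chrom": chrom, "pos": pos + 1,
                        "ref": ref, "alt": alt, "sbs_class": sbs_cls,
                    }
                elif cls == "COMPLEX":
                    pos, ref, alt, _ = _draw_sbs(
                        seq, chrom, rng, config.sbs_probs, occupancy, n
                    )
                    gap = int(rng.integers(1, 9))
                    pos2 = pos + gap
                    alt2 = str(rng.choice([b for b in "ACGT" if b != seq[pos2]]))
                    occupancy.reserve(chrom, pos2, pos2 + 1)
                    entry = {
                        "kind": "COMPLEX", "chrom": chrom,
                        "members": [
                            {"pos": pos + 1, "ref": ref, "alt": alt},
                            {"pos": pos2 + 1, "ref": seq[pos2], "alt": alt2},
                        ],
                    }
                elif cls in ("INS1", "INS2_99"):
                    k = 1 if cls == "INS1" else int(rng.integers(2, 12))
                    for _try in range(200):
                        pos = int(rng.integers(100, n - 100))
                        if occupancy.reserve(chrom, pos, pos + 1):
                            break
                    ins = "".join(rng.choice(list("ACGT"), size=k))
                    entry = {
                        "kind": cls, "chrom": chrom, "pos": pos + 1,
                        "ref": seq[pos], "alt": seq[pos] + ins,
                    }
                elif cls == "DEL1":
                    for _try in range(200):
                        pos = int(rng.integers(100, n - 100))
                        if occupancy.reserve(chrom, pos, pos + 2):
                            break
                    entry = {
                        "kind": "DEL1", "chrom": chrom, "pos": pos + 1,
                        "ref": seq[pos] + seq[pos + 1], "alt": seq[pos],
                    }
                elif cls in ("DEL2_99", "DEL100"):
                    if cls == "DEL100":
                        size_class = "rearrangement"
                        lo, hi = config.large_del_range
                    else:
                        # small vs medium split per the observed 77:34 ratio
                        if rng.random() < 77 / 111:
                            size_class = "small_del"
                            lo, hi = config.small_del_range
                        else:
                            size_class = "medium_del"
                            lo, hi = config.medium_del_range
                    del_len = int(rng.integers(lo, hi + 1))
                    avoid = (
                        [(c, s0, e0) for c, s0, e0, _ in truth.deleted_regions]
                        if cls == "DEL100"
                        else None
                    )
                    j = synthesize_deletion_junction(
                        seq, chrom, rng, size_class, del_len, config.junction,
                        occupancy, avoid=avoid,
                    )
                    entry = {
                        "kind": cls, "chrom": chrom, "pos": j["pos"],
                        "ref": j["ref"], "alt": j["alt"],
                        "junction": {
                            k2: v for k2, v in j.items()
                            if k2 in ("del_start", "del_end", "mh_len", "mh_seq",
                                      "ins_seq", "template", "size_class")
                        },
                    }
                    if cls == "DEL100":
                        truth.deleted_regions.append(
                            (chrom, j["del_start"], j["del_end"], frac)
                        )
                elif cls == "SV":
                    site_type = str(
                        rng.choice(
                            ["no_indel", "only_deletion", "only_insertion", "indel"],
                            p=[6 / 26, 11 / 26, 1 / 26, 8 / 26],
                        )
                    )
                    mh = 0
                    if site_type in ("no_indel", "only_deletion"):
                        mh = (
                            _draw_len(rng, config.junction.mh_len_probs["rearrangement"])
                            if rng.random() < config.junction.mh_prob["rearrangement"]
                            else 0
                        )
                    site = synthesize_sv_junction(
                        seq, chrom, rng, site_type, config.junction, occupancy, mh_len=mh
                    )
                    site = RejoinedSite(**{**site.__dict__, "sector_id": sector_id,
                                           "sv_id": f"{sector_id}_SV{len(truth.sv_junctions) + 1}",
                                           "size_class": "rearrangement"})
                    truth.sv_junctions.append(site)
                    entry = {
                        "kind": "SV", "chrom": chrom,
                        "site_type": site_type, "mh_len": site.mh_len,
                        "pos_a": site.pos_a, "pos_b": site.pos_b,
                    }
                else:  # pragma: no cover
                    raise InputError(f"unhandled class {cls}")
                entry["fraction"] = frac
                entry["class"] = cls
                truth.mutations.append(entry)

    # marker loci: ordinary heterozygous loci flagged for LOH bookkeeping
    for i in range(config.marker_loci):
        if truth.deleted_regions:
            chrom, s, e, _ = truth.deleted_regions[0]
            truth.marker_loci.append((chrom, (s + e) // 2))
        else:
            chrom = chrom_names[0]
            truth.marker_loci.append((chrom, int(rng.integers(0, len(seqs[chrom])))))

    final_genome = ReferenceGenome({c: "".join(s) for c, s in seqs.items()})

    # ---- observables -----------------------------------------------------
    records: "list[MutationRecord]" = []
    for entry in truth.mutations:
        frac = entry["fraction"]
        member_list = entry.get("members", [entry])
        if entry["kind"] == "SV":
            continue  # SVs are observed through the breakend table
        for m in member_list:
            depth = max(int(rng.poisson(config.depth_mean)), 1)
            alt_reads = int(rng.binomial(depth, frac / 2))
            if alt_reads == 0:
                alt_reads = 1  # a called mutation has at least one alt read
            records.append(
                MutationRecord(
                    sector_id=sector_id,
                    chrom=entry["chrom"],
                    pos=m["pos"],
                    ref_allele=m["ref"],
                    alt_allele=m["alt"],
                    af=alt_reads / depth,
                    alt_reads=alt_reads,
                    depth=depth,
                )
            )

    n_noise = int(round(config.noise_rate * len(records)))
    for _ in range(n_noise):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        seq = seqs[chrom]
        pos = int(rng.integers(100, len(seq) - 100))
        ref = seq[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        depth = max(int(rng.poisson(config.depth_mean)), 10)
        alt_reads = max(int(rng.binomial(depth, float(rng.uniform(0.01, 0.06)))), 1)
        while alt_reads / depth >= 0.1:
            alt_reads -= 1
        rec = MutationRecord(
            sector_id=sector_id,
            chrom=chrom,
            pos=pos + 1,
            ref_allele=ref,
            alt_allele=alt,
            af=alt_reads / depth,
            alt_reads=alt_reads,
            depth=depth,
        )
        records.append(rec)
        truth.noise.append({"chrom": chrom, "pos": pos + 1, "alt": alt})

    records.sort(key=lambda r: (r.chrom, r.pos))

    # ---- depth track -----------------------------------------------------
    depths: "dict[str, list[float]]" = {}
    widths: "dict[str, list[int]]" = {}
    for chrom, seq in seqs.items():
        n = len(seq)
        nbins = (n + config.bin_width - 1) // config.bin_width
        d = []
        w = []
        for b in range(nbins):
            lo = b * config.bin_width
            hi = min(lo + config.bin_width, n)
            width = hi - lo
            dosage = 1.0
            for dchrom, ds, de, frac in truth.deleted_regions:
                if dchrom != chrom:
                    continue
                overlap = max(0, min(de, hi) - max(ds, lo))
                dosage -= (overlap / width) * (frac / 2)
            lam = config.depth_mean * width * dosage
            d.append(rng.poisson(lam) / width)
            w.append(width)
        depths[chrom] = d
        widths[chrom] = w
    track = DepthTrack(depths, bin_width=config.bin_width, widths=widths)

    truth_genome = final_genome
    truth.mutations.sort(key=lambda e: (e["chrom"], e.get("pos", e.get("pos_a", 0))))
    return truth, records, track, truth_genome


def simulate_suite(config: SimConfig):
    """Simulate ``config.n_sectors`` sectors from one seed.

    Returns (genome, list of (sector_id, truth, records, track)). All
    sectors share one reference genome (junction implants accumulate on it).
    """
    rng = np.random.default_rng(config.seed)
    genome = config.genome or random_genome(
        rng, config.n_chrom, config.chrom_len, config.at_fraction
    )
    out = []
    shared = genome
    occupancy = _Occupancy()
    for i in range(config.n_sectors):
        sector_id = f"sim-{i + 1}"
        cfg = SimConfig(**{**asdict_shallow(config), "genome": shared})
        truth, records, track, shared = simulate_sector(cfg, sector_id, rng, occupancy)
        out.append((sector_id, truth, records, track))
    return shared, out


def asdict_shallow(config: SimConfig) -> dict:
    d = dict(config.__dict__)
    return d


def emit_fixture_suite(config: SimConfig, out_dir: os.PathLike) -> "list[str]":
    """Write FASTA, mutation TSV + VCF, SV breakends, depth TSV, truth JSON.

    Deterministic: re-running with the same seed reproduces byte-identical
    files. Returns the list of paths written.
    """
    from . import formats_io

    os.makedirs(out_dir, exist_ok=True)
    genome, sectors = simulate_suite(config)
    paths = []

    def _p(name: str) -> str:
        p = os.path.join(out_dir, name)
        paths.append(p)
        return p

    formats_io.write_reference(genome, _p("reference.fa"))
    all_records = [r for _, _, recs, _ in sectors for r in recs]
    formats_io.write_mutation_table(all_records, _p("mutations.tsv"))
    formats_io.write_vcf(all_records, _p("mutations.vcf"))
    all_sites = [s for _, t, _, _ in sectors for s in t.sv_junctions]
    formats_io.write_breakend_table(all_sites, _p("breakends.tsv"))
    for sector_id, truth, _, track in sectors:
        formats_io.write_depth_track(track, _p(f"depth_{sector_id}.tsv"))
    truth_obj = {
        sector_id: {
            "populations": truth.populations,
            "mutations": truth.mutations,
            "deleted_regions": truth.deleted_regions,
            "marker_loci": truth.marker_loci,
            "sv_junctions": [s.__dict__ for s in truth.sv_junctions],
            "noise": truth.noise,
        }
        for sector_id, truth, _, _ in sectors
    }
    with open(_p("truth.json"), "w") as fh:
        json.dump(truth_obj, fh, indent=1, sort_keys=True, default=str)
    return paths
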