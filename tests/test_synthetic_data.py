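"""Generator contracts: determinism, observable statistics, junction truth."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from sectormut.junction_analysis import (
    compute_deletion_mh,
    compute_sv_junction_mh,
    deletion_site,
    find_insertion_template,
)
from sectormut.records import InputError, MutationRecord, ReferenceGenome
from sectormut.synthetic_data import (
    JunctionModel,
    SimConfig,
    _Occupancy,
    emit_fixture_suite,
    random_genome,
    simulate_sector,
    synthesize_deletion_junction,
    synthesize_sv_junction,
)


def checksums(paths):
    return {
        Path(p).name: hashlib.sha256(Path(p).read_bytes()).hexdigest() for p in paths
    }


class TestDeterminism:
    def test_same_seed_identical_files(self, tmp_path):
        cfg = dict(seed=42, n_chrom=1, chrom_len=200_000,
                   populations=((0.7, 25),), marker_loci=0)
        a = emit_fixture_suite(SimConfig(**cfg), tmp_path / "a")
        b = emit_fixture_suite(SimConfig(**cfg), tmp_path / "b")
        assert checksums(a) == checksums(b)

    def test_different_seed_differs(self, tmp_path):
        a = emit_fixture_suite(
            SimConfig(seed=1, n_chrom=1, chrom_len=200_000, populations=((0.7, 20),)),
            tmp_path / "a",
        )
        b = emit_fixture_suite(
            SimConfig(seed=2, n_chrom=1, chrom_len=200_000, populations=((0.7, 20),)),
            tmp_path / "b",
        )
        assert checksums(a) != checksums(b)

    def test_zero_mutation_config(self, tmp_path):
        paths = emit_fixture_suite(
            SimConfig(seed=3, n_chrom=1, chrom_len=100_000, populations=((0.7, 0),),
                      noise_rate=0.0, marker_loci=0),
            tmp_path / "z",
        )
        truth = json.loads((tmp_path / "z" / "truth.json").read_text())
        assert truth["sim-1"]["mutations"] == []
        mut_tsv = (tmp_path / "z" / "mutations.tsv").read_text().strip().splitlines()
        assert len(mut_tsv) == 1  # header only


class TestObservables:
    def test_pure_clone_af_near_half(self):
        cfg = SimConfig(
            seed=9, n_chrom=1, chrom_len=300_000, populations=((1.0, 50),),
            spectrum={"SBS": 1.0}, noise_rate=0.0, marker_loci=0,
        )
        truth, records, track, genome = simulate_sector(cfg)
        afs = [r.af for r in records]
        assert abs(np.mean(afs) - 0.5) < 0.03

    def test_one_third_carrier_theoretical_af(self):
        assert 0.5 * 0.33 == pytest.approx(0.165)
        cfg = SimConfig(
            seed=10, n_chrom=1, chrom_len=300_000, populations=((0.33, 60),),
            spectrum={"SBS": 1.0}, noise_rate=0.0, marker_loci=0,
        )
        _, records, _, _ = simulate_sector(cfg)
        assert abs(np.mean([r.af for r in records]) - 0.165) < 0.03

    def test_implanted_deletion_rrd(self):
        """500-kb-scale heterozygous deletion at f = 0.8 gives RRD ~ 0.6."""
        from sectormut.dosage_analysis import compute_rrd

        cfg = SimConfig(
            seed=12, n_chrom=3, chrom_len=800_000, populations=((0.8, 1),),
            spectrum={"DEL100": 1.0}, large_del_range=(400_000, 500_000),
            noise_rate=0.0, marker_loci=0,
        )
        truth, _, track, _ = simulate_sector(cfg)
        assert truth.deleted_regions
        bins = compute_rrd(track)
        chrom, s, e, f = truth.deleted_regions[0]
        inside = [
            b.rrd for b in bins
            if b.chrom == chrom and b.bin_start >= s and b.bin_start + b.bin_width <= e
        ]
        assert inside and abs(np.mean(inside) - 0.6) < 0.05

    def test_noise_records_below_af_window(self):
        cfg = SimConfig(
            seed=13, n_chrom=1, chrom_len=300_000, populations=((0.7, 40),),
            spectrum={"SBS": 1.0}, noise_rate=0.25, marker_loci=0,
        )
        truth, records, _, _ = simulate_sector(cfg)
        assert truth.noise
        noise_keys = {(n["chrom"], n["pos"]) for n in truth.noise}
        for r in records:
            if (r.chrom, r.pos) in noise_keys:
                assert r.af < 0.1

    def test_truth_traceability(self):
        cfg = SimConfig(seed=14, n_chrom=1, chrom_len=400_000,
                        populations=((0.7, 30),), marker_loci=0)
        truth, records, _, _ = simulate_sector(cfg)
        truth_loci = set()
        for e in truth.mutations:
            for m in e.get("members", [e]):
                if "pos" in m:
                    truth_loci.add((e["chrom"], m["pos"]))
        noise_loci = {(n["chrom"], n["pos"]) for n in truth.noise}
        for r in records:
            assert (r.chrom, r.pos) in truth_loci | noise_loci


class TestJunctionSynthesis:
    @pytest.mark.parametrize("mh", [0, 1, 2, 3, 4])
    def test_deletion_mh_realized_exactly(self, rng, mh):
        genome = random_genome(rng, 1, 50_000)
        seq = list(genome["chr1"])
        model = JunctionModel(
            ins_prob={"medium_del": 0.0},
            mh_prob={"medium_del": 1.0 if mh else 0.0},
            mh_len_probs={"medium_del": {mh or 1: 1.0}},
        )
        j = synthesize_deletion_junction(
            seq, "chr1", rng, "medium_del", 50, model, _Occupancy()
        )
        g = ReferenceGenome({"chr1": "".join(seq)})
        got, _ = compute_deletion_mh(g, "chr1", j["del_start"], j["del_end"])
        assert got == mh

    def test_template_copy_round_trip(self, rng):
        genome = random_genome(rng, 1, 60_000)
        seq = list(genome["chr1"])
        model = JunctionModel(
            ins_prob={"rearrangement": 1.0},
            mh_prob={"rearrangement": 0.0},
            ins_len_probs={"rearrangement": {6: 1.0}},
            template_prob=1.0,
        )
        j = synthesize_deletion_junction(
            seq, "chr1", rng, "rearrangement", 500, model, _Occupancy()
        )
        assert j["template"] is not None and len(j["ins_seq"]) == 6
        g = ReferenceGenome({"chr1": "".join(seq)})
        rec = MutationRecord("s", "chr1", j["pos"], j["ref"], j["alt"], af=0.35)
        hit = find_insertion_template(g, deletion_site(g, rec))
        assert hit is not None and hit.core_len >= 6

    @pytest.mark.parametrize("site_type", ["no_indel", "only_deletion",
                                           "only_insertion", "indel"])
    def test_sv_junction_site_types(self, rng, site_type):
        genome = random_genome(rng, 1, 40_000)
        seq = list(genome["chr1"])
        site = synthesize_sv_junction(
            seq, "chr1", rng, site_type, JunctionModel(), _Occupancy(), mh_len=0
        )
        assert site.site_type == site_type

    def test_sv_junction_mh_realized(self, rng):
        genome = random_genome(rng, 1, 40_000)
        seq = list(genome["chr1"])
        site = synthesize_sv_junction(
            seq, "chr1", rng, "no_indel", JunctionModel(), _Occupancy(), mh_len=3
        )
        g = ReferenceGenome({"chr1": "".join(seq)})
        assert compute_sv_junction_mh(g, site)[0] == 3


class TestConfigValidation:
    def test_fractions_must_sum_below_one(self):
        with pytest.raises(InputError):
            SimConfig(seed=1, populations=((0.7, 10), (0.5, 10)))

    def test_spectrum_must_normalize(self):
        with pytest.raises(InputError):
            SimConfig(seed=1, spectrum={"SBS": 0.5})
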