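# sectormut

Genome-wide mutation characterization in chimeric M1 sectors of
gamma-irradiated *Arabidopsis thaliana*.

## The problem

Whole-genome mutation calling in directly mutagenized (M1) plants is hard
because M1 tissue is a mosaic: each cell lineage carries its own mutation
set, so variant allele frequencies are far below the 0.5/1.0 expected from
germline heterozygotes, and large structural changes — the mutations most
likely to be purged before the next generation — are exactly the ones
standard M2-generation studies miss. One workaround is to sequence clonal
sectors marked by loss of heterozygosity (e.g., anthocyanin-less patches on
plants heterozygous for pigment genes): a sector descends from one or a few
mutated meristem cells, so its mutations sit at predictable allele
frequencies.

`sectormut` implements the full analysis that turns per-sector mutation
calls, SV breakends, and read-depth tracks into the biology:

* **candidate filtering** for mosaic tissue — AF window 0.1–0.8 in the
  focal sector, AF < 0.05 elsewhere, ≥10 supporting reads, cross-sector
  recurrence and parental subtraction;
* **mutation taxonomy** — SBS, ±1 bp indels, 2–99 bp indels, ≥100 bp
  indels, SV, and complex events (SBS-containing clusters separated by
  <10 bp), with spectrum summaries (six strand-collapsed SBS classes,
  Ti:Tv, deletion size histogram);
* **rejoined-site analysis** — junction typing (no-indel / only-deletion /
  only-insertion / indel), microhomology quantified as breakpoint placement
  ambiguity, and a ±100 bp search for insertion templates on both strands
  (the polymerase-θ signature);
* **dosage analysis** — read depth in 100-kb bins normalized by the
  genome-wide median (RRD); a heterozygous deletion carried by a cell
  fraction *f* gives RRD = 1 − *f*/2, and runs of bins with RRD < 0.9 are
  deletion candidates;
* **AF-peak chimerism inference** — the modal AF peak estimates the
  dominant lineage's carrier fraction (*f* = 2 × peak AF); mutations in the
  major peak (AF 0.25–0.5) are attributed to a single ancestral cell and
  converted to a per-bp mutation frequency;
* **exact contingency contrasts** — two-sided Fisher tests for the
  junction-feature differences between rearrangements, medium deletions
  (10–99 bp), and small deletions (2–9 bp);
* **a synthetic-sector generator** — diploid sectors of K cell populations
  with binomial allele sampling at Poisson depth (default 85×), implanted
  junctions whose microhomology, insertions, and templates are known
  exactly, and dosage-consistent depth tracks, so every stage is testable
  against ground truth.

## Worked example

Run the numbered analyses (each writes its tables under `results/`):

```bash
python analysis/01_simulate_sectors.py
python analysis/02_filter_candidates.py
python analysis/04_junction_features.py
python analysis/06_af_inference.py
```

Output from a run at seed 1:

```
7 sectors, 770 implanted mutations, 19 heterozygous large deletions
retained 680 of 889 calls (read_support 209, af_window 0, recurrent 0)
noise calls surviving the cascade: 0 of 81
insertions: rearrangement vs small_del: p = 0.0006229
MH: medium_del vs small_del: p = 0.006554
sim-1: peak AF 0.325, carrier 0.65 (true 0.7), 84 major mutations
```

Reading this: all 81 injected sequencing-error-like calls (AF < 0.1) were
rejected by the cascade; the low-support removals are real minor-lineage
mutations whose expected alt count at 85× is below 10 reads — the same
trade-off the filter makes on real sectors. Insertions are significantly
enriched at rearrangement junctions relative to small deletions, and
microhomology at medium-deletion junctions relative to small ones — the
two signatures separating polymerase-θ-mediated and
microhomology-mediated end joining from classical NHEJ. The AF peak of
each sector recovers the simulated 0.7 carrier fraction within one
histogram bin.

As a library:

```python
from sectormut.junction_analysis import compute_deletion_mh
from sectormut.records import ReferenceGenome

g = ReferenceGenome({"c1": "TTACGACGTT"})
compute_deletion_mh(g, "c1", 2, 5)   # -> (3, 'ACG'): 3 bp of microhomology
```

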