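# Methods

## The chimerism model

A sector is modeled as a diploid tissue composed of K cell populations
with fractions f₁…f_K (Σf ≤ 1). A heterozygous mutation private to
population *i* is present on one of two chromosome copies in a fraction
f_i of cells, so its expected variant allele frequency is

    AF = f_i / 2

and its observed alt-read count at a site of depth D is
Binomial(D, f_i/2), with D ~ Poisson(depth_mean). A heterozygous deletion
removes one copy in the carrier cells, so the expected relative read depth
over the deleted interval is

    RRD = 1 − f_i / 2.

These two relations connect every observable the pipeline consumes
(mutation AFs, binned depth) to the underlying cell-population structure,
and they are the basis of both the candidate filter (AF window 0.1–0.8
targets mutations carried by ≳20% of cells) and the inference stages
(carrier fraction = 2 × modal AF; deletion candidates at RRD < 0.9,
mirroring the AF ≥ 0.1 calling floor).

Assumptions: populations are clonal (no sub-lineage AF structure within a
population beyond binomial sampling); mutations are heterozygous
(a gamma-ray hit converts one allele); depth is position-independent apart
from dosage; read sampling is unbiased between alleles.

## Microhomology as placement ambiguity

The literature rarely defines junction microhomology operationally. Here
MH is defined as breakpoint placement ambiguity: for a deletion of length
d at 0-based interval [s, e), mh_len is the number of alternative
equal-length deletions producing the identical mutated chromosome, minus
one. This is computed by two-sided extension —

    R = max k : ref[s .. s+k) == ref[e .. e+k)
    L = max k : ref[s−k .. s) == ref[e−k .. e)
    mh_len = L + R

— and the equivalence of the two formulations is enforced by a property
test over random fixtures. The same extension applies to SV junctions
after re-orienting the inverted partner (reverse complement), using the
four sequence contexts of the two joined ends. The definition makes MH
invariant under left- vs right-alignment of the deletion interval, which
matters because recurrence filtering relies on left-aligned variant keys.

A junction carrying an insertion has no MH by definition; the three
feature categories INS(+), INS(−)MH(+), INS(−)MH(−) are therefore
mutually exclusive and exhaustive. MH presence means mh_len ≥ 1; the
MH-length split partitions MH-positive sites at the 2/3 bp boundary.

## Insertion templates

Inserted sequence at a junction is searched for within ±100 bp of both
joined ends, on the direct and reverse-complement strands. A candidate
template is a maximal exact match to a substring of the insertion; when
the match reaches the insertion's boundary it may extend into the
junction's flanking sequence (flank homology), excluding the degenerate
identity placement where a flank would be "explained" by its own source
bases. Candidates are ranked by core length (inserted bases covered)
first, then total length — a template must explain the insertion before
flank homology is credited; ties break toward smaller breakpoint offset,
then the direct strand. Hits below 4 bp total are suppressed
(configurable); matching is exact, so imperfect multi-stretch templates
are reported as their longest exact core plus exact flank homology.

## Size classes and the rearrangement inventory

Deletions of 2–9 bp are small, 10–99 bp medium. Rearrangements are
mis-rejoinings of two distal double-strand-break ends: SV junctions and
deletions ≥100 bp. The deletion-associated rearrangement site inventory
contains SV junctions of type only-deletion or indel plus every ≥100 bp
deletion junction; no-indel and only-insertion SV junctions are excluded,
so insertion-frequency and MH contrasts compare like with like
(deletion-associated rejoining only).

## Complex events

Calls within one sector whose affected reference intervals are separated
by fewer than 10 bp (first affected base of the next minus last affected
base of the previous, 1-based) are chained transitively; a chain of ≥2
calls containing at least one SBS becomes a single complex event. Chains
of pure indels are left unmerged — the complex category requires an SBS
component. The 10-bp rule is applied uniformly to SBS–SBS and SBS–indel
pairs; chaining is strict (<10), so two SBSs 10 bp apart stay separate.

## Statistics

Fisher's exact test, two-sided by the standard convention: the sum of
hypergeometric point probabilities (same margins) not exceeding the
observed table's probability, within relative tolerance 1e-7. The
implementation wraps `scipy.stats.fisher_exact`; tests verify it against
an independent explicit enumeration built from log-binomial coefficients,
exhaustively for all margin configurations with N ≤ 30 and on a seeded
sample of margins up to N = 200. No multiple-testing correction is
applied; contrasts are reported as raw p-values. Under a simulated null
(two Binomial(50, 0.5) proportions, 2000 replicates) the measured type-I
error at α = 0.05 is ≈0.03–0.04 — the exact test is conservative.

With this two-sided convention, the medium-deletion vs rearrangement MH
contrast lands marginally above 0.01 (p ≈ 0.012); the medium- vs
small-deletion contrast is robustly below 0.01.

## The synthetic-sector generator

`synthetic_data.SimConfig` defaults encode the study conditions the
package is built around: sequencing depth 85× (Poisson), 100-kb dosage
bins, a mutation spectrum drawn from the observed proportions over 769
mutations (SBS 60.7%, 1-bp deletions 10.7%, 2–99 bp deletions 14.4%
split 77:34 small:medium, large deletions 1.6%, SVs 1.7%, complex 7.0%,
insertions rare), junction feature probabilities per size class matching
the observed site inventories, one dominant lineage at f = 0.7 (peak AF
0.35) plus a minor one at f = 0.2, ~110 mutations per sector, and a 10%
admixture of sequencing-error-like noise calls at AF < 0.1.

Junctions are implanted by rewriting the reference context so the
requested MH length is realized exactly (verified against the placement
oracle; accidental longer MH triggers resampling), and insertion
templates are copied from a nearby reference window on either strand.
Ground truth records every implanted mutation, carrier fraction, junction
feature, template origin, and deleted region; every observable row traces
to a truth record or a labeled noise record. All randomness flows from
the single config seed; fixture emission is byte-deterministic.

Synthetic genomes default to i.i.d. uniform bases. An AT-bias option
exists (Arabidopsis is ~64% AT) but defaults stay uniform so the MH null
distribution has a clean analytic form. Genome size defaults to 3 × 700 kb
— large enough that several ≥100 kb deletions fit disjointly and the
median-based RRD normalization is uncontaminated, small enough that the
full suite simulates in seconds; the real genome's ~119 Mb haploid length
is used as the denominator for mutation-frequency arithmetic
(`datasets.GENOME_LENGTH_BP`).

What the generator does *not* emulate: read-level artifacts (mapping
error, strand bias, duplicates), AF correlation along chromosomes,
centromere depth structure, mutation hot/cold spots, and selection against
deleterious lineages during sector growth. Passing recovery tests
therefore demonstrate the correctness of the inference arithmetic under
the stated sampling model, not robustness to alignment pathology.

## Published-count fixtures

The per-sector class count table, junction feature tallies, and
MH-length splits are transcribed constants. The full per-mutation
supplementary tables are not redistributed; `datasets.synthetic_*`
builders construct stand-in record sets that reproduce every printed
marginal exactly (769 records with per-sector class totals; 26 SV
junctions typed 6/11/1/8 with 16 carrying 0–5 bp indels; 14 large-deletion
junctions with 3 insertions and 9 MH) while positions and alleles are
invented. SBS class totals are a synthetic allocation constrained to
Ti:Tv = 0.97 over 467 SBSs (230 transitions / 237 transversions) with the
three observed major classes.

## Numerical and design choices

* Coordinates: 0-based half-open internally, 1-based inclusive in files
  (VCF convention). Indels are left-aligned with the anchor-base
  representation; recurrence keys are (chrom, pos, ref, alt) after
  normalization.
* Filter rule order is read support → AF window → recurrence, and each
  removed record is attributed to the first rule that rejected it, making
  report counts deterministic. Recurrence removes all records sharing the
  key; a record absent from another sector counts as AF 0 there.
* AF histograms use bin width 0.05 over [0, 0.8]; the peak is the modal
  bin's midpoint (ties toward higher AF), clipped into the observed AF
  range so a degenerate single-value sample reports that value. No kernel
  smoothing — the estimator is exactly reproducible.
* Dosage: partial terminal bins are depth-normalized by their true width;
  low-dosage runs never span chromosomes; minimum run length is 1 bin
  (a single 100-kb bin can hold a real deletion). Regions with
  0.9 ≤ mean RRD < 0.97 are reported in a secondary "potential" tier.
* Mutation frequency denominator is the haploid reference length; with
  ~76 major-peak mutations this yields ~6.4 × 10⁻⁷ /bp, consistent with
  the published per-sector range.
* Degenerate inputs raise typed errors (`InputError`, `FormatError`)
  rather than returning sentinels: empty AF sets, zero genome length,
  all-zero depth tracks, out-of-range deletion intervals, multiallelic
  records.

## Known limitations

* SV observables are call-level (breakend tables); reads and split-read
  evidence are out of scope, as is SV discovery itself.
* Template matching is exact; diverged templates (mismatches inside the
  core) are under-reported relative to a scoring aligner.
* The AF-peak estimator reports a single dominant lineage; sectors with
  two close peaks (as real sectors sometimes show) are summarized by the
  higher mode, not deconvolved.
* The L2-layer biology connecting sector cell fractions to visible
  phenotype is not modeled; carrier fractions are reported as sequence
  dosage only.
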