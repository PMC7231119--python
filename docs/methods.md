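# Methods

## The mapping model

`bulkseg` implements bulked-segregant analysis for an F2 population derived
from two fully inbred parents, under a single-locus recessive model.  The
reference genome is taken to be the non-selected parent's side, so every
informative marker has the selected (female) parent homozygous for the alt
allele and the reference (male) parent homozygous ref.  At a marker with
bulk allele depths `(AD_ref, AD_alt)` the SNP-index is `AD_alt / (AD_ref +
AD_alt)`; delta is `index_low − index_high`, where "low" is the bulk of
recessive-phenotype individuals.  Under the recessive model the low bulk is
fixed at the causal locus (index = 1) and the high bulk segregates
PH:HH = 2:1, giving E[index] = (2·0.5 + 1·0)/3 = 1/3 and E[Δ] = 2/3.
The delta sign is configurable; the default makes the causal excursion
positive.

Sites where genotyped parents are *not* opposite homozygotes are excluded
as uninformative (they cannot be polarized); where the female parent is
homozygous reference, polarity is flipped so the index always counts the
female-parent allele.  Whether a real analysis restricts to
parent-informative sites is often unstated in practice; the exclusion rule
here is a pinned package decision and can be disabled
(`require_informative=False`).

## The synthetic experiment

The generator emulates the study design end to end with known ground truth:

- **Parents/markers.** Marker positions are uniform at `marker_density` per
  Mb (default 50/Mb); ~25% are emitted as 1–3 bp indels; a SNP is forced at
  the causal position.  Parents are homozygous and divergent at every
  marker.
- **Recombination.** Gametes recombine under the Haldane model (Poisson
  crossover count with mean equal to the map length, uniform positions, no
  interference) at `recomb_rate_cM_per_Mb` (default 4 cM/Mb, a typical
  plant-genome map density).  Each F2 is the sum of two independent
  gametes, so single-marker genotypes segregate 1:2:1.
- **Population and bulks.** Default F2 size 300 with bulks of 30 per tail,
  matching the canonical costing example for BSA designs; the recessive
  bulk is drawn from individuals homozygous for the causal allele.
- **Sequencing.** Per-marker depth is Poisson(`mean_depth`, default 32,
  the ~31–33× scale of the motivating experiment); reads sample a uniform
  chromosome copy of the pool and are miscalled with `base_error_rate`
  (default 0.001), which collapses to `alt ~ Binomial(depth, p(1−e) +
  (1−p)e)`.
- **Annotations.** FS/MQ/QD and per-sample GQ are drawn from passing
  distributions, except a configurable 5% of sites that receive one
  deliberately failing annotation so the filter stage has real work.
  Bulk genotype calls are naive depth-ratio calls (alt fraction ≤0.1 →
  hom-ref, ≥0.9 → hom-alt, else het); parents carry their true genotypes.
- **FASTQ.** Paired 4-line Phred+33 records with random bases at Q40,
  optionally with injected low-quality 3′ tails, exist purely to exercise
  the trimmer; there is no insert-size or alignment realism, and no adapter
  contamination (adapter clipping is out of scope).
- **Toy annotated genome.** A separate small generator emits a FASTA +
  GFF3 with multi-exon genes on both strands whose CDS contain no internal
  stop codons, for validating the effect classifier.

What the generator does *not* emulate: real error profiles (quality decay,
context-dependent miscalls), mapping artefacts (repeats, multi-mapping,
reference bias), linked-marker ascertainment, or structural variation.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to alignment pathology.

## Read trimming

The trimmer scans 5′→3′; position `i` stops the scan when `qual[i] < 2` or
the mean quality of the window of 5 bases *starting* at `i` is < 20
(trailing windows shorter than 5 use their actual length), and bases
`[0, i)` are kept.  Anchoring the window at the scan position lets the two
stop conditions share one index; the behaviour is pinned exactly by an
exhaustive brute-force oracle in the test suite.  Pairs are discarded when
either trimmed mate is ≤ 50 bases; zero-length reads are retained until
pair filtering so mate bookkeeping stays aligned.  One consequence of
truncated tail windows is that trimming is *not* idempotent (a kept prefix
may fail its own, now-shorter, tail window on a second pass); re-trimming
can only shorten, and the suite freezes a counterexample.  Whether the
window mean is an integer or real mean is unspecified in common
descriptions of this rule; the real mean is used.

## Variant filtering

SNPs pass with FS < 60, MQ > 40, QD > 4 (all strict); indels with FS ≤ 200
and QD ≥ 4 (inclusive).  GQ is per-sample in VCF while the rule is a single
"GQ > 20": here a sample's genotype is masked where its GQ ≤ 20, and a site
passes the GQ condition iff **both bulk samples** keep genotypes — parents
may drop out without killing a site, because the index is computed from
bulk depths.  Multi-allelic records are split into bi-allelic rows on
reading (AD re-expressed against each alt in turn).  The per-site filter
reports the first violated rule; relaxing any threshold can only grow the
pass set (property-tested).

## Windows

Sliding windows start at 1, 1+step, … (defaults 1 Mb / 50 kb), truncated at
the chromosome end so every base is covered.  Window means are unweighted
averages over member sites — no depth weighting, no kernel smoothing —
and windows without sites report missing means with `n_variants = 0`.

## The null distribution and confidence bands

One null replicate at depth `d` draws, for each bulk independently, 30 F2
genotypes from (¼, ½, ¼), forms the bulk's true alt frequency
`p = (2·n_PP + n_PH)/60`, draws `alt ~ Binomial(d, p)`, and takes the
difference of the two indices.  Bulk composition is re-drawn every
replicate: under the null, who enters a bulk is itself random.  As
`d → ∞` only composition noise remains and `Var(Δ) → 2·0.25/(2·30) =
1/(4·30) ≈ 0.0083`; this limit is asserted in the tests.

Because `Δ` at equal finite depths lives on the lattice `k/d`, a plain
interpolated quantile compared with strict inequality systematically
under-covers the nominal exceedance (measured ≈0.8% for a nominal 1%
band).  Thresholds are therefore placed midway between the two adjacent
attainable values whose empirical strict-tail probability is closest to
the nominal rate.  The realized two-sided exceedance at the 99% level is
≈0.85–0.95% under depth mixing; the small remaining shortfall is the
irreducible lattice granularity and errs conservative.  Tables are built
per integer depth (default grid 5–100×) with ≥10,000 replicates (100,000
where calibration itself is being measured) and linearly interpolated in
depth; depths below the grid clamp to its smallest entry with a warning.

## Region calling

A site is above threshold when its delta exceeds the **upper** band
(one-sided by default — the recessive design puts the causal excursion on
one side; two-sided is available).  The lookup depth is the smaller of the
two bulk depths, a conservative choice that lets the noisier bulk set the
band.  Above-threshold sites within `merge_gap_bp` (default 1 Mb, one
window) merge into a region bounded by its outermost member sites;
coordinates are 1-based inclusive, pinned by `span = end − start + 1`, with
BED6 (0-based half-open) export for interoperability.  The "top" region is
the one with the highest mean member delta.

## Effect classification

Only the longest-CDS transcript per gene is used.  Coding SNVs are
classified by translating the reference and alternate codons with the
standard genetic code (NCBI table 1 — plant nuclear genes), strand-aware
via reverse complement; coding indels by whether `len(alt) − len(ref)` is
divisible by 3 (in-frame) or not (frameshift).  Non-coding positions inside
a gene are splice-adjacent when within 2 bp of a CDS boundary on the intron
side, otherwise intronic; positions outside every gene are intergenic.
Variants overlapping several categories take the most severe (frameshift >
stop_gain > stop_loss > nonsynonymous > inframe_indel > splice_adjacent >
synonymous > intronic > intergenic).  "Impact" variants — the set counted
in region summaries — are {nonsynonymous, stop_gain, stop_loss,
frameshift}.  A reference-base mismatch between the variant record and the
genome is an error naming the position, not a silent skip.

## Numerical and degenerate-input choices

- Report percentages use exact decimal arithmetic with half-up rounding to
  two decimals; a zero denominator yields a missing value, not an error.
- `snp_index` at zero total depth raises; the pipeline excludes such sites
  before indexing.
- Empty reads trim to empty reads; empty variant tables produce empty index
  tables and empty region lists.
- All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; identical configurations give byte-identical outputs
  (hashed in the run manifest).

## Problem sizes

The validation suite uses one 20 Mb chromosome at 50 markers/Mb with bulks
of 30 from an F2 of 300 at 30× — recovery of the causal position by the
top-delta region is measured over 100 seeded runs; null calibration uses
20,000 independent no-signal sites against 100,000-replicate threshold
tables; analytic anchors use fixed extreme bulks at 10,000× with zero
error.  These sizes give the binomial assertions 3σ resolution of a few
tenths of a percent.

## Known limitations

- With a single short chromosome (~0.8 Morgan at the defaults) every
  marker is partially linked to the causal locus, so candidate regions are
  broad; interval resolution in the simulation — as in a real cross — is
  governed by map length, bulk size and depth.
- The null model treats sites independently; genome-wide, linked sites
  share bulk-composition noise, so the *count* of band exceedances on one
  chromosome is overdispersed relative to independent-site expectations
  even though the per-site rate is calibrated.
- Thresholds assume equal-depth bulks at a site; the min-depth lookup makes
  unequal-depth sites conservative.
- No support for RIL/backcross designs, depth-weighted or kernel-smoothed
  index variants, or analytic (non-Monte-Carlo) confidence intervals.
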