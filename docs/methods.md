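# Methods

## Locus partition

Transcripts are grouped by gene symbol — no coordinate-overlap merging —
and each locus is labelled from its isoform coding flags: coding-only,
non-coding-only, or bifunctional (both present). The coding flag comes from
the annotation's CDS columns when present (`cdsStart == cdsEnd` means
non-coding); the RefSeq accession prefix is used only as a cross-check, and
a contradiction (an `NR_` accession with a CDS) is logged with the CDS
winning, since explicit CDS coordinates are stronger evidence than a name.
Predicted accessions (`XM_`/`XR_`) and unknown-prefix transcripts without
CDS evidence are excluded from the census by default, with a logged count:
the census is defined on curated coding status, and transcripts whose
status cannot be resolved would otherwise silently dilute it.

Internally all coordinates are 0-based half-open on the forward strand
(genePred's native convention); GTF input (1-based closed) is converted on
read, so the same gene models parse identically from either dialect.
Percentages are `100·count/total` rounded half-away-from-zero to one
decimal — the convention that reproduces 60.2 / 30.6 / 9.2 from the counts
16,879 / 8,583 / 2,586.

## Probe matching

The hybridization model is deliberately minimal: a probe hits a transcript
iff it occurs as an exact, ungapped, full-length substring of the spliced
transcript sequence. No mismatches, no thermodynamics, no genomic
(unspliced) background. This is the conservative, reproducible reading of
perfect-match probe design; anything richer would require a hybridization
model the analysis does not depend on. The default `sense_mode="both"`
searches the probe and its reverse complement, making the tool agnostic to
whether the probe table stores probe-strand or target-strand sequence; the
mode is recorded in output headers.

The matcher builds one hash index per distinct probe length over all
k-mers of the spliced sequences; it is property-tested to be exactly
equivalent to a naive scan over every (probe, transcript, offset) triple.
A probe is *ambiguous* when its hit set contains both coding and non-coding
isoforms. The array-level headline is the percentage of ambiguous probes
among probes hitting bifunctional loci (no-hit probes are excluded from the
denominator and counted separately). At gene level both readings are
reported: genes with *any* ambiguous probe and genes with *all* probes
ambiguous. The census unit is the individual probe; probe-set roll-up is a
reporting option, not the default.

## Rank-sum test

`mann_whitney` computes U from midranks of the pooled sample. When
`C(n1+n2, n1) ≤ 200,000` the p-value is exact: all assignments of pooled
values to the first group are enumerated and
`p = min(1, 2·min(P(U'≤U), P(U'≥U)))`; ties are handled naturally because
the enumeration is over the observed midranks. Otherwise the normal
approximation is used with the tie-corrected variance
`n1·n2/12·[(N+1) − Σ(t³−t)/(N(N−1))]` and a 0.5 continuity correction.
Exact and approximate p agree to ~0.01 in the tails; near p ≈ 0.5 the
discrete point mass P(U=u) itself is of order 0.01 for n1=n2=8, which
bounds the achievable agreement there. All values tied across both groups
is reported as p = 1 with a degenerate flag. Type-I error at α = 0.05 is
calibrated to 0.05 ± 0.02 over 1,000 null replicates.

Two group-selection rules are provided for the coding vs non-coding
comparison. The default takes, among bifunctional loci, genes whose probes
are all coding-specific vs all non-coding-specific. Under the generator's
per-probe Bernoulli placement this rule selects almost nothing (the chance
that all 11 probes of a gene avoid shared exons is 0.333¹¹), so synthetic
runs use the `locus_class` rule: probes of coding-only vs non-coding-only
loci. Per-probe values are reduced across samples by the median (mean and
no-reduction are options).

**Clustering caveat.** Probes of one gene share a gene-level mean, so
probe-level values are not independent; a probe-level rank test treats ~11
correlated values as 11 observations and overstates significance even when
group means are equal. The calibrated unit is the per-gene summary (median
of the gene's probe medians), and the equal-means regime is verified at
that level: with no planted shift the per-gene test is non-significant in
≥ 90% of replicated expression draws, while a planted one-SD shift at
≥ 50 probes per group is detected essentially always.

## Enrichment

Overrepresentation is the one-sided hypergeometric upper tail (Fisher
exact enrichment) computed in log space via log-gamma and `logsumexp`,
with Benjamini–Hochberg adjustment across sets and ties broken by set
name. This is an intentional substitution for web-service combined scores,
whose rank-based background cannot be reproduced offline. The default
universe is the union of library genes; an explicit universe (e.g. all
array genes) is the statistically proper background when the query derives
from an array and can be supplied with `--universe`. Normalization of the
pmf holds to 1e-12 for universes up to a few hundred genes; at N in the
thousands log-gamma accumulation limits it to ~1e-11, far below any
decision threshold.

## Synthetic-data generator

The generator emits a complete, internally consistent study:

- **Gene models.** Each locus draws its class from the configured
  fractions (defaults 60.2% / 30.6% / 9.2%, matching the census the
  pipeline emulates). A bifunctional locus is realised as the
  alternative-isoform architecture: 2–4 shared exons plus one exon unique
  to the `NM_` isoform and one unique to the `NR_` isoform, interleaved so
  the isoforms share flanking structure. Exons are 80–160 bp, introns
  60–140 bp, strand random; coding transcripts get a CDS trimmed 5 bp
  inside their terminal exons. Single-class loci may carry a second
  isoform that skips one internal exon.
- **Genome.** Uniform random A/C/G/T of exactly the required length.
  Accidental 25-mer collisions have probability ≈ L²·4⁻²⁵ and are
  negligible at the scales used.
- **Probes.** 11 per gene (one array probe set), 25 nt, cut directly from
  the spliced sequence of a source isoform. For bifunctional loci each
  probe lands on a shared exon with probability 0.667 (intended ambiguous)
  or on an isoform-specific exon (intended specific); the intended verdict,
  source isoform and transcript offset are recorded as ground truth.
- **Expression.** Log-scale intensities: gene mean ~ N(7, 1), per-value
  noise SD 0.5, 60 samples. A shift δ (default 0, the equal-means regime)
  is planted between coding- and non-coding-specific probe groups as ±δ/2.
- **Gene sets.** 20 random sets of 5–30 genes over the gene universe.

One seeded `numpy` generator drives everything; identical seeds give
byte-identical output files. `verify()` re-reads the emitted files, re-runs
the census and the matcher, and enumerates any divergence from ground
truth.

What the generator does **not** emulate: hybridization noise and
cross-hybridization, mismatch tolerance, probe-sequence biases, real exon
length and isoform-count distributions, correlated gene-set structure, and
sample-level covariance (cell-line lineages). Passing tests therefore
demonstrate correctness of the pipeline's logic and statistics on data
satisfying its assumptions, not robustness to array artefacts.

## Problem sizes and determinism

Default simulation sizes (2,000 loci in the worked example, 1,500 in the
acceptance script, 28,048 for the census-recovery check, 1,000 replicates
for test calibration) were chosen so the full suite and the acceptance
script each run in well under a minute on one core while leaving the
statistical checks adequately powered. All randomness flows from explicit
seeds; tests are deterministic.

## Known limitations

- Gene symbols are taken at face value as locus keys; symbol collisions
  across chromosomes would merge loci (the census groups by name, so this
  mirrors the procedure it implements).
- The exact rank test enumerates combinations and is exponential; the cap
  keeps it to ≤ 2·10⁵ enumerations, beyond which the normal approximation
  is used.
- GFF3 and BED12 are not read; GEO SOFT files must be exported to the TSV
  matrix layout (row ids in the first column, sample names in the header).
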