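# Methods

This note documents the models implemented in `wgbskit`, the parameters
that matter, what the synthetic generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Methylation levels

The level of one cytosine is `C_i / (C_i + T_i)` (methylated-supporting
over total reads). The level of a region is the **unweighted mean** of
per-site levels over its `n` covered cytosines. The unweighted mean was
kept even where pooling counts would be statistically more powerful,
because it is the quantity the rest of the pipeline (DMR effect sizes,
CpG-island levels, element profiles) is defined on; mixing definitions
would make effect-size thresholds incomparable across stages. A useful
identity (tested): the region level of a union of disjoint site sets is
the n-weighted mean of the parts' levels.

## Conversion rate and site calling

The conversion rate r is estimated from a fully unmethylated spike-in
(lambda phage) as converted / total cytosine read observations. The null
for site calling is `p₀ = 1 − r`: a truly unmethylated cytosine yields a
C read only on conversion failure. This is the standard bisulfite null
and the only one derivable from the conversion model; sequencing error
beyond conversion failure is not modeled (it would be unidentifiable
from aggregated counts).

The test is the exact one-sided upper binomial tail — only an excess of
methylated reads is evidence of methylation. FDR control is
Benjamini–Hochberg across all tested sites of a sample (not stratified
by chromosome or context); BH was chosen as the default FDR procedure
absent a stated alternative. Screens: coverage ≥ 4 to test a site,
q < 0.05 to call it. Sites below the coverage screen are returned
untested rather than dropped, so downstream tallies can still see them.
A conversion rate of 0 makes the null probability 1 and the test
degenerate; it is rejected with an error.

## Contexts

CG / CHG / CHH are typed from the two bases 3′ of the cytosine on its
own strand (minus-strand lookups reverse-complement the upstream plus
strand bases). Cytosines whose context runs off the chromosome end are
N-padded and fall into CHH with the N visible in the reported
trinucleotide. File-supplied contexts are trusted unless a genome is
given, in which case the genome-derived context wins and disagreements
are logged — this keeps reports self-sufficient but verifiable.

## Functional-element profiles

Each covered cytosine within a gene span ± 3 kb (strand-oriented flanks)
is assigned to exactly one of seven categories: upstream, first exon,
first intron, inner exon, inner intron, last exon, downstream. The
seven-way scheme maps all introns after the first to "inner intron";
single-exon genes populate only the first exon, and two-exon genes have
no inner exon. Positional curves use 20 equal-width bins per element
(elements shorter than 20 bp fall back to one bin), are oriented 5′→3′
along the transcript, and are averaged **per gene first, then across
genes**, so long genes do not dominate the curve; the alternative
(pooling sites before binning) was rejected for that reason.

## 9-mer sequence preferences

For every methylated cytosine, the strand-oriented 9-mer with the mC at
position 4 (3 bases upstream, 5 downstream) is tallied into a per-context
position × base frequency matrix; position 4 is pure C by construction
and position 5 is pure G for the CG context. The modal dinucleotide at
positions 5–6 summarizes the dominant downstream motif (e.g. CAG for
CHG sites). Sites whose 9-mer would leave the chromosome, or spans an N,
are skipped.

## CpG islands

Detection follows Gardiner-Garden–Frommer: 200 bp windows slid 1 bp at a
time must satisfy GC ≥ 0.5 and observed/expected CpG ≥ 0.6
(`obs/exp = n_CpG · L / (n_C · n_G)`); overlapping qualifying windows are
merged, each merged segment is trimmed to its outermost CpG
dinucleotides, and the trimmed interval is kept only if it itself meets
all three criteria including length ≥ 200 bp. The trim step prevents
window margins from dragging flanking AT-rich sequence into the island
(without it, a pure CG repeat reports GC ≈ 0.5 instead of 1.0). All
thresholds are exposed as parameters.

An island is **hypermethylated** when its CG region level exceeds 0.7 —
except when fewer than 10% of its CG cytosine positions carry
high-confidence calls, where "high confidence" reuses the calling
coverage screen (≥ 4×) rather than inventing a second threshold. With a
genome available the denominator of that fraction is the island's true
CG-position count on both strands; otherwise it falls back to the
positions present in the calls table.

## DMR detection

Replicates are pooled within each group (Fisher's exact test needs a
single 2×2 table; pooling is the only reading compatible with it). Sites
need pooled coverage **strictly greater than 10** in each group — the
bound is read literally as an exclusive inequality — and sites present
in only one group are dropped with a logged tally. Per-site Fisher
p-values are computed by a vectorized two-sided exact test
(`fisher_exact_many`, chunked hypergeometric enumeration with the
standard 1 + 1e−7 tie tolerance), verified in tests against both the
scalar scipy route and an exact integer enumeration oracle.

Candidate regions are maximal runs of same-context, same-sign sites with
per-site |Δ| past the context threshold (0.3 CG, 0.2 CHG/CHH), allowing
at most 100 bp between consecutive qualifying sites. Region construction
is not prescribed by the DMR definition itself, so its knobs (`max_gap`,
`min_sites`, the per-site reuse of the region thresholds) are explicit
parameters. A candidate becomes a DMR iff it holds ≥ 3 qualifying sites,
the region-level difference (computed over **all** coverage-qualified
same-context sites inside the bounds, not only the qualifying ones)
exceeds the context threshold in absolute value, and Fisher's exact
p < 0.05 on region-pooled counts. The level-difference threshold is
enforced both per site (run membership) and per region, resolving the
ambiguity of which the definition governs by requiring both. No
multiple-testing correction is applied across regions by default (the
screen is on raw p); a BH option exists. DMR bounds are the first and
last qualifying site positions, and `width = end − start + 1` on 1-based
inclusive coordinates.

Annotation assigns each DMR the highest-priority overlapping category —
promoter ≤ 1 kb > promoter 1–2 kb > promoter 2–3 kb > 5′UTR > 3′UTR >
first exon > other exon > first intron > other intron — across all genes
within span ± 3 kb; ties break by TSS distance then gene id. A DMR
touching none of those intervals (including one lying only in a
downstream flank) is distal intergenic, carrying the nearest gene by TSS
distance. A gene counts as a DMR-related gene (DMG) when at least one
non-distal DMR maps to it; a switch includes distal-linked genes.

## Enrichment

Over-representation of DMGs in user-supplied gene sets is the central
hypergeometric upper tail `P(X ≥ k)` for a set of size K in a universe
of size N with n DMGs, BH-corrected across sets. Length-bias weighting
(Wallenius-style) is deliberately out of scope: it needs per-gene length
or count weights that are not part of this pipeline's inputs, and the
output metadata records the method so results are not mistaken for
bias-corrected ones.

## qPCR validation

Technical replicates are averaged per sample; `ΔCt = Ct_target −
Ct_ref`; `ΔΔCt` subtracts the **calibrator group's mean** ΔCt (not a
single calibrator sample), so calibrator ΔΔCt values average to exactly
zero and the calibrator RQ has geometric mean 1; `RQ = 2^−ΔΔCt`. RQ is
invariant to adding a constant to all Ct values of a sample (reference
normalization cancels plate shifts) — a tested property. Groups are
compared with an equal-variance independent-samples t-test (Welch
optional), flagged `*` / `**` at 0.05 / 0.01; the test runs on RQ
values. Two constant but different groups are degenerate (zero variance)
and are reported with p = 0 rather than raised. Methylation/expression
concordance uses the inverse convention — hypermethylation paired with
lower expression is concordant — and genes whose DMRs disagree in sign
are flagged `mixed` and excluded from the concordance fraction.

## Synthetic methylome

The generator emulates a two-group (3 vs 3) WGBS experiment at
aggregated-count level; it does not simulate reads, PCR duplicates,
mappability, M-bias or sequencing error, so passing recovery tests
demonstrate correctness of the analysis arithmetic under the stated
sampling model, not robustness to alignment artifacts.

Defaults (the study conditions): one 1 Mb chromosome at GC 0.42 with 5
CpG-island-like GC/CpG-rich patches; 40 non-overlapping genes of
2–6 kb with ≥ 3 exons; mean coverage 15× (Poisson per site and
replicate — the simplest depth model with realistic dispersion);
conversion rate 0.994; per-context Beta-distributed site levels with
means CG 0.7, CHG 0.01, CHH 0.01 and concentration 10 (bounded,
unimodal, standard for methylation fractions; the concentration is a
free parameter exposed in config because within-group biological
variance has no canonical value); 20 planted CG DMRs of 1 kb and effect
size 0.5; a 48,502 bp unmethylated spike-in.

The per-site biological level is a property of the site: both groups
share it everywhere except inside planted DMRs, where one group's level
is lowered by the planted delta (direction alternating across DMRs, so
both signs are exercised; truth records the signed effect). Drawing the
two groups' background levels independently would plant genuine
group differences of sd ≈ 0.2 at every site and make any
false-positive bound on "flat background" unattainable, so the
shared-background model is the one under which the caller's false-call
rate is meaningful. Observed methylation probability at a site with
level m is `m + (1 − m)(1 − r)` — conversion failures create false
methylation signal — and the spike-in is generated with m = 0
everywhere, so its observed methylated fraction estimates `1 − r`.
Planted DMRs are placed in disjoint chromosome compartments, each
guaranteed ≥ 3 cytosines of its context (resampled if needed). Zero or
unit context means are treated as degenerate (no Beta spread) so
boundary configurations behave exactly. Identical config and seed give
byte-identical outputs.

An optional `promoter_level` plants a distinct (typically low) CG mean
around TSSs to reproduce the characteristic dip of CG methylation near
the transcription start relative to gene bodies.

qPCR simulation: the reference gene sits at a fixed Ct; a target with
fold change f has its Ct lowered by log2(f) in the non-calibrator group;
Gaussian noise of configurable sd is added per well; 3 biological × 3
technical replicates per group.

## Problem sizes in tests

The default end-to-end run used by the test-suite and the acceptance
script is the 1 Mb default configuration above (~420k cytosines × 6
samples), which exercises every stage at full default conditions while
keeping a complete run in the tens of seconds. Unit tests use 20–250 kb
genomes; the null-FDR check uses 10⁵ sites at ~10×; the Fisher oracle
comparison enumerates all 246,016 tables with row margins ≤ 30.

## Known limitations

- The DMR caller implements the printed operational definition, not a
  beta-binomial model; between-replicate dispersion is absorbed by
  pooling, so it is anti-conservative when replicates disagree strongly.
- Long planted DMRs spanning CpG-sparse stretches can be split into
  adjacent calls when qualifying sites sit more than `max_gap` apart.
- CGI detection is the classical window heuristic, not an HMM.
- Enrichment ignores gene length bias (see above).
- BED12/GFF3 ingestion covers gene/exon/UTR structure only; no
  transcript-level isoform handling (one model per gene).
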