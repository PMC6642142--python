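# Methods

## Data model and conventions

Intensities are stored linear-scale; log2 happens inside the tests.
Genomic intervals are 0-based half-open internally (GTF converts at the
I/O boundary), so interval arithmetic needs no ±1 corrections.  The
signed fold change is the linear-scale treated/control mean ratio when
≥ 1 and the negated reciprocal otherwise, so |FC| ≥ 1 always and the
conventional gate is |FC| ≥ 1.5 with raw p ≤ 0.05 (a BH-adjusted q is
always computed and reported; gating on q is available via
`DEFilter(use_adjusted=True)` but off by default, matching common
microarray practice of filtering on raw p).

Slash-joined gene labels (e.g. `MAGEA3/MAGEA6`, probes that cannot
distinguish paralogs) are kept as single opaque identifiers and count
as one network node.

## Microarray leg

Quantile normalization forces every sample onto the common distribution
of cross-sample sorted-row means; ties receive the mean of the tied
reference quantiles.  Differential expression uses the equal-variance
two-sample t-test on log2(x + 1) — the pseudocount of 1 is negligible
at array intensities (hundreds to tens of thousands) and guards zeros.
Whether the original array software tested log or linear scale is not
knowable from its outputs; log2 is the defensible default and is
recorded in the run manifest.  Fold changes are computed from the
*linear* group means, not the log means.  `raw_intensity`, used by the
sponge gate, is the larger of the two linear group means — a
conservative reading of "raw signal intensity" that a candidate passes
if it is well expressed in either condition.

## Small-RNA leg

miRNA counts are modeled negative-binomial with variance μ + φμ².  The
test is an exact conditional test on the two group sums: counts are
scaled to the mean library size, a single common dispersion is
estimated by the method of moments across features (φ = (s² − μ)/μ²
pooled within groups, floored at 1e−8), and the two-sided p sums the
probabilities of all partitions of the total whose probability does not
exceed the observed one (minimum-likelihood rule).  Group sums of n
i.i.d. NB(μ, φ) variables are NB(nμ, φ/n).  In the φ → 0 limit the
procedure reduces exactly to the two-sided binomial test at π = n₁/(n₁+n₂),
which the test suite verifies by enumeration.

This is a deliberate simplification of full NB-GLM fitting with
empirical-Bayes tagwise dispersions.  The fidelity target is
*calibration*, not output matching: on 2000 simulated null features the
rejection rate at α = 0.05 stays within 0.05 ± 0.01 (slightly above
0.05 because the plug-in common dispersion ignores estimation error).
A cross-check test asserts strong p-value rank agreement with the
reference exact-test implementation in the edgeR R package.

Hierarchical clustering (Euclidean distance, Ward linkage) is delegated
to scipy; ties break deterministically by smallest index.

## Genomic context

Classification priority: exonic overlap on the opposite strand →
natural antisense; fully inside an intron on the opposite strand →
intronic antisense; any same-strand overlap → sense overlap;
non-overlapping head-to-head TSSs within 1 kb → bidirectional; else
intergenic.  Genes without exon records are treated as single-exon, so
intronic classes are then unreachable.  Proximity pairing uses the
*body gap* (closest interval ends, 0 on overlap), not TSS–TSS distance,
with a strict `< 300000` bp cutoff and strand ignored; antisense
pairing requires opposite-strand interval overlap of at least 1 bp.
Both are checked against an O(n²) scan on random annotations.

## Association and network gates

The concordance filter keeps a reference co-expression pair when both
members are significant, 0.6 ≤ |r| ≤ 0.8 (inclusive band; the range is
configurable), and — in the default `sign_concordant` mode — sign(r)
equals sign(lnc_FC · mrna_FC).  The band is applied to |r| because
curated co-expression tables may report negative correlations; `any`
mode disables the sign requirement since curated candidate lists
sometimes retain discordant pairs.

Sponge selection applies the intensity floor (strictly > 100 linear
units) and the annotation whitelist only to the up-regulated (forward)
direction; the reverse network is gated by significance alone,
mirroring how such analyses are usually reported.  Triad construction
is a pure conjunction of necessary conditions, so decoy interaction
edges can add false triads (precision < 1) but can never remove a true
one — recall against planted truth is 1 by construction whenever all
three members pass their tests.

## Enrichment and validation statistics

Over-representation uses the right-tail hypergeometric p
P[X ≥ k], X ~ Hypergeom(N, K, n), each set intersected with the
universe first; the default universe is the assay platform (all tested
features), not the genome.  BH adjustment is the standard step-up rule.
Group validation uses Kruskal–Wallis on midranks with tie correction
(all-identical input degenerates to H = 0, p = 1) and Dunn's z with
tie-corrected pooled variance and two-sided normal p, BH-adjusted
across the requested comparisons only; an exhaustive permutation oracle
(N ≤ 9) bounds the approximation error in the tests.  Fold presentation
divides group means by the control mean, pinning the control at exactly 1.

## Synthetic generator

The generator emulates a two-group (control vs combined-treatment)
design with triplicate samples — the replication level of the kind of
cell-culture study this pipeline targets — and writes every artifact
through the same I/O layer the pipeline reads.

* **Annotation**: coding genes (three 1 kb exons, 7 kb introns) on a
  700 kb grid across six 45 Mb chromosomes, plus lncRNAs planted per
  class: intergenic far (mid-gap, > 300 kb from any gene), intergenic
  near (gap drawn inside the window and recorded), natural antisense
  (overlapping a host exon, opposite strand), intronic antisense,
  sense overlap.  Default class mix approximates the published
  distribution of dys-regulated lncRNAs (72 % intergenic, 12 % natural
  antisense, 9 % intronic antisense).
* **Intensities**: log2 x ~ Normal(base + 1[treated]·log2 FC, σ) with
  σ = 0.3 by default, exponentiated; 300 coding and 200 lncRNA
  features by default (array-like density keeps quantile-normalization
  quantile gaps small).  Planted-feature bases are clamped to
  mid-distribution ranks: a shared between-group shift at the extreme
  rank of a sample is invisible to quantile normalization, which is a
  property of the method, not of the data.
* **Counts**: NB(lib·π·FC^1[treated], φ) with φ = 0.1 and a 50 k
  library; planted miRNAs get at least average abundance so planted
  ratios are detectable at n = 3.
* **Effects**: the |FC| grid is {1.5, 2, 4}; features anchoring planted
  sponge triads always receive the grid maximum, because a 1.5-fold
  effect at triplicate replication is near the detection floor and a
  "recoverable truth" requires detectable anchors.  One planted-up
  lncRNA is kept dim (~16 linear units) to exercise the intensity gate.
* **Interactions**: planted triads are written into the binding and
  target tables; decoy edges are added uniformly at random at a
  configurable background density; co-expression rows for DE proximity
  pairs carry |r| ~ U(0.6, 0.8) signed by the fold-change product.

Child RNG streams derive from the master seed by fixed offsets, so each
stage is independently reproducible and whole runs are byte-identical.

What the generator does **not** emulate: probe-level array effects,
batch and hybridization artifacts, sequencing-read simulation,
correlated noise between features, and annotation ambiguity.  Passing
recovery tests therefore demonstrates correctness of the gating and
assembly logic under the stated noise model, not robustness to real
microarray pathologies.

Even under the stated model, recovery is statistical: with n = 3,
σ = 0.3 and φ = 0.1, a 4-fold planted effect is missed by its test in
roughly 0.1 % of draws, so a few per cent of random seeds lose one
planted triad member.  The recovery tests run three fixed seeds; the
acceptance script reports recovery averaged over three derived seeds.

## Numerical choices

* Exact-test tail comparison uses a 1 + 1e−10 relative slack when
  collecting partitions "at most as probable" (floating-point pmf ties).
* Signed-FC ratios guard zero means with a 1e−12 floor.
* BH is order-preserving and capped at 1; q = p when a single test is
  adjusted.
* Ward linkage heights and leaf order come from scipy's deterministic
  implementation.

## Limitations

* The common-dispersion exact test under-propagates dispersion
  uncertainty (slightly anti-conservative at small feature counts).
* Genomic-context classification is gene-level: transcript isoforms
  are not modeled, and "bidirectional" uses a fixed 1 kb TSS window.
* Reference co-expression and disease tables are consumed as given; no
  attempt is made to recompute correlations from the study's own
  samples (n = 3 per group is far too small for that).
* The bundled published candidate tables print lncRNA and miRNA
  statistics but not per-mRNA statistics; loader-built mRNA records
  therefore carry direction-only nominal values, which is sufficient
  for network assembly and gate demonstrations but not for re-testing
  those mRNAs.
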