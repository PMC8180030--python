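# Methods

This note documents the models, parameter choices and numerical decisions
behind `ptcore`, and what the synthetic-data verification does and does
not demonstrate about real data.

## Coordinate and tag model

All coordinates are 0-based half-open. Sequencing reads are reduced to
5'-anchored *tags* `(chrom, pos5, strand)`. This is exact for Pt-exo
(the 5' end is the exonuclease stop, i.e. the adduct position) and a
deliberate simplification for ATAC, where it corresponds to cut-site
counting; fragment spans are not retained. Duplicates are defined as
identical `(chrom, pos5, strand)` triples. ATAC tags are deduplicated
and blacklist-filtered before analysis; Pt-exo tags are *not*
deduplicated, because under the 5'-anchor model many genuine adducts at
one site produce identical tags and collapsing them would destroy the
count statistics the windowed ratio needs (real pipelines deduplicate on
full read coordinates, which carry distinct 3' ends).

## Window tiling

Windows start on a regular grid (0, step, 2·step, …); a truncated
terminal window is emitted when ≥ 100 bp would otherwise remain
uncovered. With 1-kb windows at 900-bp steps this convention tiles the
packaged hg19 table (93 sequences, 3,137,161,264 bp) into 3,485,761
windows, within 0.0006% of the 3,485,781 used in comparable published
analyses; the residual difference reflects an unstated end-of-chromosome
convention and is treated as approximate.

## Depth filter

Windows pass when mean RPKM across the samples of the comparison is > 1
and below `median + 1·SD`, both statistics computed over windows with
non-zero mean and recorded in the result metadata. "Depth" is read as
the cross-sample mean; per-sample filtering is a coarser alternative the
data model does not need. Note that very open regions (promoter-scale
accessibility) can exceed the upper bound and drop out of the analysed
universe; that is a property of the published filter, not a bug.

## Moderated differential model

Counts are transformed to log2-CPM with a 0.5 pseudocount and
library-size normalisation. When precision weights are on, a lowess
trend (span 0.5, 3 robustness iterations) of `sqrt(residual SD)` against
average log2 count is evaluated at per-observation fitted log-counts and
inverted to weights (predicted-SD⁻⁴). Per-feature weighted least squares
is followed by empirical-Bayes variance shrinkage with `(d0, s0²)`
estimated by moment matching of log-variances: the trigamma equation is
inverted by Newton iteration (tolerance 1e-8) with an infinite-`d0`
fallback when the log-variance spread is at or below its sampling
expectation. `d0 = 0` disables shrinkage and reproduces the ordinary
per-feature *t* exactly (tested against a least-squares oracle).
Default calls: ATAC windows |log2FC| > 2 ∧ FDR < 0.001; genes
|log2FC| > 2 ∧ FDR < 0.05.

Differential damage between lines is also tested with the moderated
(variance-shrunk) two-group *t* on the per-window replicate signals;
with three replicates per line a plain per-window *t* has ~4 residual
degrees of freedom and essentially no genome-wide power at FDR < 0.05,
whereas pooling variance information across ~10⁴ windows restores it.
A plain Welch option is kept (`method="welch"`).

## Exact tests

Fisher's exact two-sided *p* sums hypergeometric probabilities not
exceeding the observed table's probability (relative slack 1e-7 against
floating-point ties); this matches exhaustive integer-arithmetic
enumeration to < 1e-12 on every table with total ≤ 40. The odds ratio is
the cross-product `ad/bc`, with Haldane's 0.5-per-cell correction (for
both OR and the Wald logit CI) only when a cell is zero. Wilcoxon
rank-sum uses midranks; exact enumeration is used while `C(n+m, m)` ≤
200,000, otherwise a normal approximation with continuity and tie
corrections.

Rank-product *p* values are permutation-based (ranks permuted
independently per pair, null RPs pooled over genes, +1 smoothing) rather
than gamma-approximate, so they are exact in the limit and testable
against full enumeration at four genes. Direction (up/down), permutation
count and seed are explicit arguments.

## Peaks and COREs

Peaks: tags extended to 200-bp fragments in the strand direction;
per-bp coverage tested against Poisson with
`lambda = max(genome, 5-kb, 10-kb centered means)`; significant runs
≥ 50 bp merged across gaps ≤ 100 bp; summit = leftmost maximal-coverage
base. The Poisson model ignores biological overdispersion, which costs a
small number of false positives at genome scale — acceptable for the
cluster analysis that consumes the peaks.

COREs: all inter-peak gaps (edge-to-edge) are pooled genome-wide, and a
within-cluster gap threshold is chosen by the split of the log-gap
distribution minimising total within-class variance (one-dimensional
Otsu). The split is accepted when the two classes are clearly separated
(class medians ≥ 4× apart and a ≥ 1.3× jump at the boundary), otherwise
the distribution is treated as unimodal and a plain quantile (default
0.25) is used. A pure low-quantile threshold is not usable as the
primary rule: whenever clustered peaks contribute more than the quantile
fraction of all gaps — which they do under any realistically dense
cluster landscape — the quantile lands *inside* the within-cluster gap
distribution and splits clusters. COREs are maximal runs of ≥ 3
consecutive peaks with every internal gap ≤ the threshold (inclusive).
For two-line comparisons the pipeline pools gaps from both peak sets so
one shared threshold keeps CORE calls comparable. The algorithm is
cluster-of-elements–inspired, not a reimplementation of any published
tool. Cross-line labels use ≥ 1 bp span overlap; gene linkage anchors at
the TSS with a ±100 kb span, `[start − 100000, end + 100000)`.

## Pt-exo read-out

Offset-*k* dinucleotides are read in read-strand orientation (offset 0 =
the 5' base and its successor; minus-strand tags reverse-complement);
dinucleotides containing N or crossing a sequence end are excluded and
counted. The target set is {GG, AG} on the read strand, matching the
1,2-intrastrand crosslink chemistry; it is configurable.

The windowed damage signal is `log2((RPKM_treated + c) / (mean mock
RPKM + c))` with pseudocount c = 0.5 (bounded at empty windows,
symmetric in treated/mock), on 1-kb / 900-bp sliding windows restricted
to those overlapping ATAC-pass windows. RPKM normalisation makes the
signal invariant to uniform depth scaling; because treated libraries
contain adduct tags in addition to background, the *absolute* level of
the signal has an arbitrary offset — all downstream use is relative
(ranks, between-line differences).

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed, and
recovery claims below refer to them.

* **Genome**: 2 × 5 Mb i.i.d. sequence at GC 0.41; CpG-rich islands
  (800 bp, GC 0.65) at 30% of promoters; 400 non-overlapping genes
  (2–8 kb, 1–5 exons, first/last 200 bp as UTRs); 2 blacklist regions
  per chromosome simulated with 20× anomalous coverage.
* **Accessibility**: defined at 100-bp resolution — baseline 0.2,
  promoters (TSS ± 1 kb) and peaks ×8. Per line: 600 peaks, of which
  ~200 sit in 40 clustered templates (3–10 peaks, internal gaps
  500–1100 bp); 25% of templates exist only in the resistant line
  (gained), 25% only in the sensitive (lost). Isolated elements are
  placed ≥ 4.5 kb apart so clustered and background gap scales are
  separable, as they are for genuine regulatory-element clusters.
* **Planted differential windows**: 2% of 1-kb bins at log2 effect 3,
  split symmetrically (×2^1.5 in one line, ×2^−1.5 in the other) so the
  planted log2FC is exactly 3 while mean depth stays inside the upper
  depth filter; a one-sided 8× elevation would be removed by the
  published filter itself.
* **ATAC tags**: per-bin negative binomial (size 10) around depth ×
  accessibility share (10⁶ tags/sample), placed multinomially on the
  100-bp profile within the bin.
* **Pt-exo**: every GG/AG position (both strands) is an adduct site with
  probability `adduct_rate × dose × (accessibility/mean)^alpha ×
  damage-multiplier`, clipped at 0.9; each sampled adduct emits
  Poisson(2.5) tags at its 5' base. Treated libraries add uniform
  background (0.01/bp); dose-0 (mock) libraries are pure background
  sequenced to the standard per-sample depth (10⁶ tags), as
  depth-matched control libraries are in practice. Damage regions
  (2% of bins, in 2-kb blocks so at least one sliding window is fully
  contained regardless of grid phase) carry a symmetric log2-3 damage
  difference. The per-site rates are scaled up relative to real cells so
  that a 10-Mb desk-scale genome carries the information content of a
  genome-scale experiment; they are dose-linear by construction below
  the clip.
* **RNA**: per-gene NB counts (mean 100 × lognormal gene factor,
  size 10); every gene with a TSS within 100 kb of a gained (lost)
  template is up (down) at log2 effect 3 in the resistant line.
  `de_promoter_boost` optionally couples DE genes' promoter
  accessibility to their expression direction (default 1 = uncoupled,
  matching the weak promoter–expression coupling seen in resistant
  lines).

Seeding: one global seed; each sample's stream is
`default_rng([seed, crc32(sample label)])`, so outputs are byte-stable
and adding samples never perturbs existing ones.

### What passing recovery tests does not show

The simulator omits mappability and GC amplification bias, fragment-size
structure, sequencing errors, diploid genotypes, exonuclease pause-site
background structure (background is uniform), and DNA repair kinetics
(adduct signal is net formation-minus-repair). Recovery on this
generator demonstrates the *statistical machinery* is correct and
calibrated at realistic noise levels — not that the biological
conclusions transfer to any particular real dataset.

## Verification design choices

* Differential-damage recovery is scored on a configuration with CORE
  gain/loss and accessibility-difference fractions set to zero, so that
  planted damage windows are the *only* true between-line differences;
  in the full default study, accessibility-coupled damage differences at
  changed COREs are genuine signal and would be miscounted as false
  positives against the damage-truth table alone.
* The coupling null (alpha = 0) is run with no planted damage
  differences; calibration there means the differential-damage stage
  calls (almost) nothing.
* The mock-versus-mock null is scored as |median signal| ≈ 0 (bias), the
  invariant the signal definition actually guarantees; the per-window
  scatter of that null is set by Poisson counting noise and shrinks with
  mock depth.

## Known limitations

* The window grid is fixed per run; analyses mixing window sizes must
  re-count.
* `annotate_windows` assigns one class per window by midpoint with a
  fixed precedence (CpG island > promoter-TSS > 5'UTR > 3'UTR > exon >
  TTS > intron > intergenic); boundary windows inherit the midpoint's
  class only.
* The CORE caller assumes peak sets dense enough to estimate the gap
  distribution (≥ ~20 peaks per genome for a stable threshold).
* `rank_product` needs ≥ 2 independent pair comparisons and is therefore
  skipped in the single-pair end-to-end pipeline.
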