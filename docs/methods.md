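# Methods

## Coordinate conventions and interval algebra

All genomic features live on 0-based, half-open intervals (BED convention);
every reader converts on ingestion. Overlap means ≥ 1 shared base by
default (`min_bp` is exposed; no reciprocal-fraction rule is applied).
Abutting intervals do not overlap. Window tilings emit a partial terminal
window per chromosome; partial windows are excluded from window-scale
statistics by default because their shorter length would bias both the
bp-weighted rate and the covered-CpG counts.

Interval sets are array-backed and queried with sorted-array bisection, so
the resampling nulls (millions of control intervals) stay in NumPy. The
brute-force pairwise scan serves as the oracle for the overlap machinery in
the test suite.

## Fractional methylation

A covered cytosine's methylation is C/(C+T) over its bisulfite reads; a
region's methylation is the *unweighted* mean of site fractions over the
CpGs it covers (read-weighted pooling is available behind a flag, default
off — the unweighted mean treats each cytosine as the unit of observation
and is robust to coverage heterogeneity between sites). Sites need total
depth ≥ 1 (configurable at track construction); regions and windows need a
minimum number of covered CpGs (default 5 for window tables, 1 for
hotspot-scale regions, both configurable) below which the value is
undefined (NaN) and the row is dropped listwise from model fits.
CpGs are counted on the plus strand; plus/minus calls of one CpG can be
pooled at ingestion (`merge_strands`, default off).

## Window response and predictors

The window recombination rate is the bp-weighted mean of the piecewise-
constant map segments overlapping the window — invariant to splitting a
segment into equal-rate pieces. Sequence predictors are G+C content
(ambiguous bases excluded from numerator and denominator), CpG dinucleotide
count, CpG O/E = n_CpG·L/(n_C·n_G) with L the unambiguous length, and the
fraction of window bases covered by the union of repeat annotations.

## Statistics

* **Correlation**: sample Pearson r with the t-distribution (n−2 df)
  two-sided p. Correlations are reported on raw and Box–Cox-transformed
  values; which the user interprets is their choice.
* **Box–Cox**: (x^λ−1)/λ (ln x at λ = 0); automatic λ maximizes the profile
  log-likelihood over the grid −3…3 in steps of 0.01. When zeros are
  present (rates can be exactly 0) a shift of half the smallest positive
  value is applied first; transforming both the response and continuous
  predictors is the default, restrictable by the caller.
* **Regression**: OLS on z-scored response and predictors (standardized β,
  comparable across predictors and invariant to rescaling), per-predictor
  VIF = 1/(1−R²_j) with intercepts in the auxiliary regressions, adjusted
  R². Backward stepwise removes the largest-p predictor while it exceeds
  α = 0.05 (an AIC criterion is available behind a flag). Exact
  collinearity reports VIF = ∞ with a warning.
* **Fisher's exact 2×2**: probability-mass two-sided rule — the sum of
  hypergeometric probabilities of all tables with the observed margins that
  are no more probable than the observed table — computed with exact
  integer arithmetic (numerators share one denominator, so tie comparisons
  are exact integer comparisons, not floating-point fuzz). SciPy's
  implementation is the independent cross-check in the tests, not the
  implementation.
* **t test**: Welch (unequal variances) by default. **ANOVA**: classical
  one-way F. Group summaries use normal-approximation 95% CIs.
* p-values are reported raw throughout; the pipeline applies no
  multiple-testing correction.

## Synteny projection

A synteny map is an ordered list of equal-length aligned block pairs,
non-overlapping on the source genome; negative-strand blocks reverse
coordinates within the block, and strand is otherwise ignored. An interval
projects iff ≥ `min_fraction` (default 0.95, mirroring liftOver's default
match requirement) of its bases lie in blocks agreeing on destination
chromosome and strand; the output is the min–max span of projected base
coordinates, so destination insertions widen the span exactly as liftOver's
span semantics do. Full UCSC chain parsing is out of scope.

## Cross-species hotspot classes

A hotspot is **common** iff its projection overlaps a partner hotspot and —
by default — the overlap also holds in the reverse direction (reciprocal
mode; one-directional mode is a flag, since either convention is defensible
and reciprocal is the stricter, orthology-style call). Hotspots that fail
projection are *unmappable*: counted and reported separately, and included
among species-specific (they cannot be shared). The classification
partitions each input set exactly; the projections of each genome's
specific hotspots into the partner genome form the syntenic region class.

For the SNP/DSB comparison, SNP–DSB is counted on the DSB side (DSB
hotspots overlapping ≥ 1 SNP hotspot) and SNP-only on the SNP side; the two
sides differ exactly when one SNP hotspot carries several DSB hotspots, so
both `snp_dsb` and `snp_overlapped` are reported.

## Control regions and enrichment

Control regions are length-matched resamples of the feature set placed in
excluded-region-free sequence: the eligible start positions for a length L
are enumerated per gap and one is drawn uniformly (capacity-weighted over
gaps), which realizes the uniform placement distribution exactly, with no
rejection loop; a length with zero eligible positions raises a placement
failure naming the length. When the number of controls equals the template
size the length multiset is reproduced exactly.

Enrichment reports observed = hotspots overlapping ≥ 1 peak; expected = the
mean overlap count over `n_controls` control sets, each of the feature set's
size; fold = observed/expected. Significance is reported two ways: a Fisher
exact p on the 2×2 table of observed versus *rounded* expected (documented
as an approximation, since the expected count is an average), and the
direct Monte-Carlo p — the fraction of control sets reaching the observed
overlap, with +1 correction. An analytic whole-genome-placement
expectation (`expected_genome`) is also reported so the two definitions of
"expected" can be compared. If the expected count is 0, the fold is flagged
undefined rather than reported as ∞.

## Bootstrap divergence null

The null distribution for the mean interspecies methylation difference at
hotspots is built from B bootstrap means (sample size = number of hotspot
differences, drawn with replacement from the control differences); the
empirical two-sided p is (1 + #{|draw| ≥ |observed|})/(B+1), so it is
bounded below by 1/(B+1). B < 1,000 warns. The absolute-value rule
presumes differences centered near zero, which holds for the
human-minus-chimp style differences it serves; the calibration test
verifies 3–7% rejection at the nominal 5% level over 1,000 null runs.

## Distance profiles

Each rate segment is assigned to a distance bin by the distance of its
midpoint to the nearest peak (midpoints make the assignment unambiguous for
segments spanning bin edges); per-bin rates are bp-weighted means. Default
bins are 0–100 kb in 5-kb steps plus an open-ended final bin.

## Synthetic data: what is emulated, what is planted

The generators reproduce the *statistical shape* the analyses assume, with
every estimand planted at a known value:

* **Genomes**: equal-length chromosomes; optional i.i.d. sequence at a set
  G+C (no repeat structure, no CpG islands, no motifs).
* **Synteny maps**: colinear alignments — aligned blocks with geometric
  lengths (mean 1/indel_rate, default rate 1e-5/bp) separated by
  insertions/deletions uniform on 1–50 bp. Forward and reverse maps are
  mutually inverse on aligned bases. No inversions or translocations, which
  is what makes footprint-avoidance in the hotspot generator sufficient for
  exact class counts.
* **Hotspots**: lengths uniform on 1–3 kb (a typical hotspot scale; no
  empirical length distribution is modeled), placed disjointly by batch
  rejection. Cross-genome pairs are constructed so that exactly `n_shared`
  hotspots classify as common (shared partners sit at the actual synteny
  projections, verified round-trip; all other placements avoid the
  margin-expanded projection footprint of the partner set). The
  published-scale presets are `humanchimp_paper` (9,300 / 5,037 / 131) and
  `mouse_paper` (47,068 SNP, 9,874 DSB, 2,571 DSB hotspots on 2,570
  distinct SNP hotspots — the class sizes force one doubly-hit SNP
  hotspot, which the generator builds explicitly).
* **Methylome/rate pair**: per-window true methylation
  m_w = clip(0.7 + 0.08·z₁, .01, .99) and rate
  r_w = max(0.05, 1 + 0.35·z₂) cM/Mb for latent bivariate-normal (z₁, z₂).
  Both links are affine outside far tails, so the measured window
  correlation equals the latent correlation up to binomial read-noise
  attenuation, which is corrected analytically:
  ρ_latent = ρ_target·√(s² + m(1−m)/(d·k))/s for site variance at depth d
  and k CpGs per window. CpGs sit on a jittered grid (default one per
  10 kb at 500-kb windows, i.e. 50 per window), depth is Poisson(30)
  floored at 1, C-counts are Binomial(depth, m_w). Real methylomes'
  bimodality, CpG-island structure and spatial autocorrelation within
  windows are *not* emulated — passing tests show estimator correctness
  under the planted model, not robustness to those features.
* **Peaks**: `n_in` peaks sit fully inside distinct hotspots (observed
  overlap = n_in exactly) and the rest are uniform over hotspot-free gaps.
  The control-resampling expectation E for the free peaks is computed
  exactly from the gap geometry (per-gap counting of overlapping
  start-position pairs), and n_in = round(fold·E) is solved by fixed-point
  iteration; an unattainable fold raises with the attainable maximum.
* **Recombination maps**: piecewise-constant per-window background times a
  hotspot multiplier (default 10×) inside hotspots.

Problem sizes in the test suite are chosen so the full run completes in a
few minutes on one core: the planted-correlation check uses 5,000 windows
of 500 kb at depth 30 over 20 seeds; the planted-fold check uses 5,000
hotspots with 1,000 control sets; null calibrations use 20 seeds (fold) and
1,000 runs (bootstrap). The published-scale presets use 100 Mb (two
chromosomes) for the human/chimp pair and 500 Mb (five chromosomes) for
mouse, keeping hotspot density below ~25% so disjoint placement mixes well.

## Numerical and degenerate-input choices

Zero-variance inputs, zero-margin tables, samples below minimum sizes, and
underdetermined regressions raise typed errors rather than returning NaN;
undefined *values* (uncovered regions, sub-threshold windows) are NaN and
propagate to listwise deletion. Empty subject sets in distance queries warn
and return all-NaN. Control-placement randomness, enrichment, bootstrap
and generator seeds are explicit everywhere and recorded in outputs; the
end-to-end run derives stage seeds from one master seed and reproduces its
output tables byte-for-byte.

## Known limitations

* Synteny is colinear-only; rearranged regions are simply unmappable.
* The Fisher p for enrichment treats the rounded expected count as a second
  observed sample; the Monte-Carlo p is the cleaner quantity and both are
  reported.
* Window-scale inference ignores spatial autocorrelation between adjacent
  windows (as the modeled analyses do); p-values at small window sizes are
  anti-conservative in that respect.
* The bootstrap divergence null resamples regions independently, ignoring
  any spatial clustering of methylation divergence.
* Sequence-based predictors require a supplied FASTA (or generated
  sequence); no annotation-aware features (genes, promoters, chromatin
  states) are computed, though any such interval set can be fed to the
  generic enrichment operation.
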