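# Methods

This note documents the statistical models and conventions implemented in
`perichrom`, the defaults chosen where the underlying methods are commonly
left unspecified, what the synthetic generators do and do not emulate, and
the package's numerical choices.

## Coordinate and data model

All genomic intervals are 0-based, half-open (BED convention) and
strandless, validated against an explicit `Genome` (ordered chromosome
names and lengths). Canonical order is (chromosome order, start, end).
Abutting intervals merge: `[0,100)` + `[100,200)` → `[0,200)`. Intervals on
chromosomes absent from the genome (unlocalized contigs and the like) are
dropped with a logged count by default; a strict mode raises instead.

Images are 2-D (maximum projections); nucleus masks are integer label
images (0 = background), either produced by the built-in segmentation or
supplied externally and used verbatim. Point coordinates are `(x, y)` with
x the column index.

## Binding-site reduction

* **Control subtraction** operates at peak level: a peak is dropped whole
  if it shares at least `min_overlap_bp` (default 1) bases with the merged
  control set. Only peak calls are consumed, so read-level subtraction is
  out of scope by design.
* **Replicate consensus** emits, for every reciprocally overlapping pair of
  replicate peaks, the union span of the pair, then merges the spans. This
  "union of common sites" reading is the default; since the convention is
  ambiguous in the literature, `intersection`, `rep1` and `rep2` coordinate
  modes are exposed. The operator is symmetric in its arguments (for the
  symmetric modes) and reduces to `merge` when both replicates are equal.

## Enrichment statistics

**Membership.** A peak belongs to a region class by its midpoint base
(default — unambiguous, assigns each peak exactly once) or by ≥ 1 bp
overlap (`any_overlap`). Under uniform placement the midpoint rule's chance
probability equals the coverage fraction exactly, which is why it pairs
with the coverage-based expectation below.

**Expected by chance** is the base-pair coverage fraction of the (merged)
target regions. `fold = f_obs / f_exp`.

**Permutation null.** Each of `n_perm` permutations (default 1000) redraws
every peak with its length preserved, start uniform over valid positions,
on its own chromosome (default; preserves chromosome composition) or
genome-wide with chromosomes weighted by the number of valid placements.
The p-value uses the add-one rule `p = (1 + #{null ≥ obs}) / (1 + n_perm)`,
so `p ≥ 1/(1+n_perm)` and the test is valid (super-uniform) for any
`n_perm`. Because the statistic is an integer count, ties between null and
observed counts make the rule mildly conservative; the effect shrinks as
the count's granularity grows (more peaks, larger target coverage). The
exact rejection rate at α = 0.05 with `n_perm = 199` ranges over ≈
0.041–0.048 for the configurations exercised in the tests. A binomial
upper tail `P(Bin(n_total, f_exp) ≥ n_obs)` is reported alongside; it
ignores peak-length effects and is the cruder of the two nulls.

**Subtelomeric windows** are `[0, w)` and `[L − w, L)` per chromosome
(default `w` = 500 kb, both ends), clipped and merged when `L < 2w`. Window
width, and whether one or both ends count, are parameters.

**Fisher exact test.** Implemented by direct hypergeometric enumeration.
The two-sided p sums all tables (at the observed margins) whose point
probability is at most that of the observed table, with relative tolerance
1e-7 for ties — the convention shared by the common exact-test
implementations. The test suite checks agreement with an independent exact
rational enumeration to 1e-12 over every 2×2 table with margins ≤ 20, and
against `scipy.stats.fisher_exact` on random tables.

**Annotation and co-occurrence tables.** The chance baseline for Fisher
tables is a pool of length-matched, same-chromosome, uniformly redrawn
peaks (`n_shuffle` copies; defaults 10 for annotation, 1–2 for
co-occurrence). This controls for peak length and chromosome composition.
The table is `[[obs_in, obs_out], [pool_in, pool_out]]`. Feature tracks
named `TSS`/`TES` are treated as point features and expanded by
`tss_flank_bp` (default 2000 bp) on each side. Raw p-values are the primary
readout; Benjamini–Hochberg adjusted values are reported alongside for
multi-feature tables.

## Nuclear geometry

**Segmentation** (a declared default, since masking recipes are rarely
reported): global Otsu threshold → hole filling → 8-connected components →
areas below `min_area_px` removed → labels renumbered by descending area.
A blank image yields zero nuclei with a warning.

**Equal-area shells.** The Euclidean distance transform from the mask
boundary is computed for every in-mask pixel; pixels are binned into
`n_shells` (default 5) equal-area shells by area quantiles of the distance,
shell 1 outermost. Whole tie classes (pixels at exactly equal distance) are
assigned to the outer shell determined by the count of strictly smaller
distances, so the maximal area deviation is one tie class — below 2% of
mask area for masks ≥ 10⁴ px. Equal-area was chosen over fixed-width
erosion because it makes the uniform null exactly 1/K per shell and is
resolution-robust; fixed-width binning is available (`mode="equal_width"`).
The partition commutes with 90° rotations exactly (the distance transform
is exact on the square grid).

**Shell comparison.** Per shell s, a two-sided Fisher test on
`[[a_s, A − a_s], [b_s, B − b_s]]`; overall, a chi-square test of
homogeneity on the K×2 table (all-zero shells dropped to keep the statistic
defined).

## Intensity readouts

**Line profile.** Sampled at unit-pixel steps by bilinear interpolation
along the mask's major principal axis through the intensity centroid
(default; minor axis or explicit endpoints as options), trimmed to the
in-mask extent plus a 2 px margin. Background is subtracted first and
negatives clamped to zero — the enrichment ratio is scale-invariant but not
offset-invariant, so background handling is part of the statistic. An
integration width (`line_width_px`, odd, default 1) averages that many
parallel offset lines, as in standard profile tools; widths around 15–25 px
suppress pixel noise while leaving a rim ridge intact (the averaging runs
along the rim tangent, where the rim is locally constant). With raw
single-pixel profiles, the edge maxima of a noisy flat profile are biased
upward by extreme-value statistics (≈ +1.5–2 noise SD), so noisy data
should always be profiled with an integration width.

**Peripheral enrichment.** With `v` the in-mask samples (≥ 8 required):
`max1 = max(v[:k])`, `max2 = max(v[-k:])` with `k = round(edge_fraction·n)`
(default `edge_fraction` = 0.25), plateau = central 50% of `v`, and
`ratio = 0.5·(max1 + max2) / median(plateau)`. The edge and plateau windows
are conventions (configurable); a flat profile gives exactly 1.0.

**Three-circle ratio.** Equal circles (default radius 3 px) at the tethered
spot, a nuclear reference and an out-of-cell background position must be
disjoint; `ratio = (mean_spot − mean_out) / (mean_nuc − mean_out)`. A
non-positive denominator is an error, not a value.

**Particle density** divides in-mask point counts by mask area in μm²;
compartment masks must be disjoint.

## Spot detection

Scale-normalized negative Laplacian-of-Gaussian responses are computed over
a geometric ladder of scales (`sigma_min`–`sigma_max` px, default 1–4,
6 scales). Local maxima in (scale, y, x) are accepted if their response
exceeds `threshold_z` (default 5) robust-z units — median and 1.4826·MAD of
the in-mask response at that scale. Out-of-mask pixels are filled with the
in-mask median before filtering so the nuclear rim step does not fire the
detector. Overlapping candidates are suppressed greedily in decreasing z
order (centers closer than the larger detection radius √2·σ), which makes
the detected count monotone non-increasing in the threshold. The reported
σ of each detection is the scale maximizing the raw normalized response at
the kept center (the per-scale z renormalization would bias scale
selection, since noise power varies across scales). Precision/recall
against planted truth uses greedy nearest-neighbour matching within 2 px,
each truth spot matched once.

"Peripheral" spots are those in shell 1 of a 5-shell equal-area partition —
chosen for consistency with the positioning analysis, so uniform spots are
peripheral with probability 0.2; a fixed distance-to-boundary rule is
available.

## Synthetic generators

The generators are first-class, tested code; their defaults are the
conditions under which the pipeline is validated.

**Peaks.** Midpoints fall in the subtelomeric windows with probability
`fold × coverage` (uniform within windows), else uniformly in the
complement; the midpoint-based fold estimator is therefore unbiased for the
planted fold. Lengths are geometric with mean 200 bp (positive, memoryless;
a constant-length mode supports exact-arithmetic tests); intervals are
clipped to chromosome bounds, which can displace a midpoint by at most half
a peak length. The toy genome used throughout testing is 10 chromosomes of
20 Mb, giving the 500-kb windows 5% coverage.

**Replicates.** `simulate_replicate_peaks` draws one true site set, then
observes it twice with per-site retention (default 0.9), ±50 bp boundary
jitter and uniformly placed false-positive peaks. Consensus of two
*independent* enriched peak sets would roughly square the planted fold
(overlap probability is density-weighted), so replicate data must share an
underlying site set for consensus to recover the planted enrichment — as it
does for real replicates.

**Mark tracks.** Both tracks start as uniformly placed fixed-length
intervals (default 5 kb, genome-wide density 0.3 — of the order of broad
repressive-mark coverage in differentiated cells) independent of the peaks
and of each other; this *is* the odds-ratio-1 case, so the co-occurrence
test's null is exchangeable by construction and its Fisher p is uniform up
to discreteness. Association is planted by relocating marks of track B
between peaks (B-only donor → A-only recipient raises the odds ratio;
double-positive → double-negative lowers it) until the joint hit count
reaches the target given by the Plackett joint probability at the realized
marginals. Each relocation preserves both marginal hit counts, so only the
association is planted. The procedure requires peaks to be sparse relative
to the mark length and fails loudly otherwise. `mark_density = 1` tiles the
genome completely (uniform placement would only cover ≈ 63%).

**Images.** Elliptical nuclei; in-mask intensity is
`nucleoplasm + rim_amplitude · exp(−(d − d₀)²/(2σ_rim²))` with `d` the
distance to the mask boundary, plus Gaussian spots, plus Gaussian or
Poisson noise. Spots can be planted uniformly or on a chosen distance
quantile contour (quantile q maps to shell `⌊qK⌋+1` by construction);
planted spots keep a minimum separation (default 4σ) so they are resolvable
— two merged puncta would count as one in any detector. Rim tests use
`d₀ = 3` px so the rim peak sits inside the mask where bilinear profile
sampling captures it to ≈ 1%; with `d₀ = 0` the peak sits on the boundary
pixel (distance 1) and edge interpolation clips a few percent off.
The generators do **not** emulate: optics (PSF, chromatic shift), uneven
illumination, autofluorescence, 3-D structure, nucleoli, or non-elliptical
nuclei. Passing tests therefore demonstrate correctness of the estimators
under the stated model, not robustness to every real-data artefact; masks
and spot lists from real pipelines can be imported to bypass the built-in
segmentation and detection.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` validate at: n = 2000 peaks for
fold recovery (planted folds 1, 2, 5, 9; mean over 5 seeds, since a single
draw's binomial error at 5% coverage is ~7–10% relative); n = 500 for
permutation power (p ≤ 0.01 for fold ≥ 2); 400 null replicates at
`n_perm = 199` for type-I calibration (2000 peaks, 20% window coverage —
the least-discrete configuration, see the tie discussion above); 200 seeds
for Fisher-p uniformity and 20 seeds for odds-ratio-4 power at n = 1000
peaks; 20 seeds of 50 planted spots at SNR 5 for detector precision/recall;
and 100 noise realizations for the rim-free profile ratio. These sizes were
chosen so each check's sampling error is small against its tolerance.

## Reproducibility

Every stochastic function takes an explicit seed and builds one local
`numpy.random.Generator`; there is no global RNG state. Identical
(parameters, seed) give bit-identical outputs. CLI outputs carry the tool
version, a hash of the effective config and the seed; re-running a config
reproduces its files byte for byte.

## Known limitations

* Interval operations are exact but not optimized for million-interval
  sets (the consensus operator is O(n·m) per chromosome in the worst case).
* Peak-level control subtraction cannot reproduce read-level subtraction
  when a control overlaps only part of a peak's signal.
* The line profile is a single chord (optionally width-averaged); it does
  not integrate over the whole rim, so per-nucleus ratios are noisier than
  whole-rim estimators but match the common manual practice.
* Shell areas are equal only up to distance-tie classes; very small or very
  thin masks can deviate more than 2%.
* The mark-track generator plants association at peaks only; it does not
  model broad-domain autocorrelation of real chromatin marks.
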