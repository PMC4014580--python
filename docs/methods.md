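# Methods

## Scope and data model

The package analyses a fixed-window hourly grid. Every series is an
`HourlySeries`: a regular whole-hour UTC timestamp grid, one float
per slot, NaN marking a missing observation. The reference sampling
design is a 23-day continuous deployment — 559 hourly slots from
2011-10-07 08:00 to 2011-10-30 14:00 UTC with 23 unusable slots
(536 usable) — and a filmed area of ~0.0355 m² for converting frame
counts to densities (ind/m²). Nothing is ever interpolated: the
periodogram and all tests consume the missing mask directly.

## Whittaker-Robinson periodogram

For candidate period *T* (integers 2 … ⌊n/2⌋; the grid is hourly so
non-integer candidates are not examined), the series is folded into a
Buys-Ballot table by slot index mod *T*. The amplitude *B(T)* is the
standard deviation of the column means; columns with no observation
are excluded. The sample (n−1) standard deviation is the default —
the definition only says "standard deviation", so a `ddof=0` switch
allows population-sd cross-checks against other implementations.

Significance is a one-sided permutation test (large amplitude =
periodic structure). Each permutation shuffles the observed values
over the observed slots, leaving the missing pattern fixed, so the
per-column observation counts — and hence the information loss
structure — are identical across permutations. This also allows the
whole permutation stack to be folded with a single reshape, keeping a
559-slot, 999-permutation periodogram under a second. The p-value
uses the add-one convention (1 + #{B* ≥ B})/(n_perm + 1); an exact
mode enumerates all permutations for tiny series and is tested
against independent brute-force enumeration. No multiple-testing
correction is applied across periods: each period is flagged at its
own p < α (default 0.05), which is how such periodograms are
conventionally read; the association module's Holm routine can be
applied by a caller who wants family-wise control.

Stationarity screening is the caller's duty and is provided as an
OLS slope t-test on the slot index (α = 0.05), with `detrend`
returning OLS residuals at the observed slots. The slot index, not
wall-clock seconds, is the regression abscissa.

### Power at the semi-diurnal band

A genuinely tidal (12.42 h) signal examined on an integer-period grid
drifts 0.42 h per fold cycle; over 559 slots the fold at *T* = 12
accumulates ~1.6 cycles of drift, attenuating the folded amplitude
roughly five-fold, while *T* = 25 (≈ 2 × 12.42) accumulates only
~0.14 cycles and retains nearly full amplitude. Consequently, with a
signal amplitude twice the noise sd, the 12-h period is detected in
only a minority of realizations, whereas 25 h and 37 h are detected
almost always — the harmonic ladder is the robust signature. The
acceptance script therefore reports, per band, the modal significant
winner over 21 simulated deployments; realizations in which no period
in the band reaches significance contribute nothing to the mode.
Twenty-one repeats keep the probability of an empty semi-diurnal pool
below 1 %.

## Synthetic data generator

`generate_series` draws
value(t) = base + slope·t + Σ amp·sin(2πt/period + φ) + AR(1) noise,
with φ uniform on [0, 2π) per component (pinnable for tests), AR(1)
noise initialized at its stationary variance noise_sd²/(1−ρ²), and
exactly `n_missing` slots removed uniformly without replacement. The
`poisson-count` family clamps the latent mean at zero before Poisson
sampling, since densities are nonnegative counts per area. Gap
positions are re-drawn per seed: the real deployment's gap positions
are unknown, and uniform placement is the neutral choice (verified by
a chi-square goodness-of-fit property test).

`generate_point_pattern` produces per-frame labelled points as
Gaussian clusters around per-taxon parent locations that stay fixed
across frames (persistent home ranges — the structure the pooled
segregation analysis is designed to detect). Parents are uniform
within a 10 % frame margin, or pinned explicitly via `centers` when a
test needs controlled geometry. Points are clipped into the frame and
per-taxon counts are exact.

The default `study_bundle` emulates the deployment: four faunal
Poisson count series with tidal forcing at 12.42 h and 24.84 h and
small trends, a sparse visitor series that is near-all-zero, five
temperature probes with probe-specific tidal amplitude (one probe
nearly arrhythmic, one cool and weakly coupled), and a three-taxon
clustered point pattern. What the generator does *not* emulate:
observation error in annotation, zoom changes (the per-epoch filmed
area), cross-taxon interaction dynamics, and non-sinusoidal tide
shapes. Passing tests therefore demonstrate correctness of the
statistical machinery under the design's sampling structure, not
ecological realism of any particular series.

## Spatial analyses

Heat maps tile the frame with square bins of side
⌈√(bin_area/pixel_area)⌉ pixels from the top-left origin, bins
left-/top-closed so edge points belong to the smaller-index bin;
counts are conserved by construction. The ~1.125 cm² default bin
area follows the reference design; the exact grid shape depends on
the pixel calibration supplied by the user.

Nearest neighbours are Euclidean with ties broken by lowest record
index (pixel-quantized coordinates make exact ties realistic, and the
rule keeps results reproducible). Duplicate coordinates are legal.
The segregation index per ordered pair is Dixon's log odds ratio; the
pooled-over-frames variant sums per-frame observed and expected
counts and forms odds as ΣN/(Σn − ΣN) against ΣE/(Σn − ΣE). On a
single frame these pooled expected odds reduce algebraically to
Dixon's closed forms ((n_A−1)/(N−n_A) conspecific, n_B/(N−1−n_B)
heterospecific), so pooling strictly generalizes the single-frame
index. Degenerate odds (a taxon whose neighbours are all, or never,
conspecific) are reported as NaN with a flag rather than ±∞.
Significance testing of S (Dixon's z-tests) is out of scope;
label-permutation checks are exercised in the test suite.

## Association tests

Pearson r over mutually observed slots, permutation p (999 default,
two-tailed, add-one convention), Holm step-down within a family. The
family is all pairs tested at one sampling frequency — the natural
grouping when the same hypothesis set is re-examined at 4/6/12-h
subsamples — and is configurable via an explicit pair list. Pearson
rather than Spearman: the permutation test already frees the
inference from normality, and r keeps effect sizes on the familiar
scale. Subsampling keeps every k-th slot from an anchor (default the
first slot) and never interpolates.

## Temporal eigenfunctions and variation partitioning

dbMEM construction: pairwise time distances of the retained
(complete-case) slots, truncation at t = the largest gap between
adjacent retained slots (the smallest threshold keeping the series
connected), distances beyond t replaced by 4t, Gower double-centring
of −D²/2, eigendecomposition, positive-eigenvalue axes kept and
returned unit-norm in decreasing-eigenvalue order. On a complete
regular grid these are discrete sinusoids ordered low to high
frequency, and they reproduce a matching sinusoid with R² > 0.999.

Explained variation is the canonical R² (trace of fitted sums of
squares over total, all response columns centred) with the Ezekiel
adjustment 1 − (1−R²)(n−1)/(n−m−1). For the union of two predictor
sets, m is the effective rank of the combined design (SVD-based), so
sets that share information — or even literal columns — partition
cleanly instead of erroring; within a single user-supplied set,
exact collinearity is still an error naming the problem.

Forward selection uses the double stopping criterion plus a global
pre-test: selection only starts if the all-candidates model is
significant under row permutation of Y (without this guard, testing
only the best of many candidates at each step inflates the
family-wise inclusion rate under the null far above α). Each step
then admits the candidate with the largest additional explained
variance if its residual-permutation p < α, and the search ends once
the cumulative adjusted R² crosses the all-candidates cap (the
crossing variable is kept).

The partition reports [a] = [abc]−[bc], [c] = [abc]−[ab],
[b] = [ab]+[bc]−[abc], [d] = 1−[abc]. Adjusted fractions can be
slightly negative and are reported unclipped with a warning.
Permutation p-values attach to the five testable fractions ([ab],
[bc], [abc] by row permutation; [a], [c] by residual permutation
under the conditioning model). [b] is a difference of adjusted R²s,
not the fit of any model, and deliberately carries no p-value.

## Imagery metrics

Cover is 100 · white/total pixels of a binary mask (grayscale input
is binarized at the midpoint). The luminosity index defaults to mean
HSL lightness scaled 0–255, pinning the endpoints exactly (all-black
frame → 0, all-white → 255); an `hsl-mean` mode averages all three
HSL channels instead, under which an all-black frame scores ≤ 85
because hue and saturation are 0 but lightness dominates the
endpoint behaviour. Both modes are monotone in uniform lightness
change, which is the property that matters for tracking gradual
darkening of a deployment; the precise channel combination is
otherwise a free design choice.

## Problem sizes and numerical choices

Test-suite simulations use reduced sizes chosen to keep Monte-Carlo
error well inside the asserted bands: 99–199 permutations for
property checks, 999 for headline recoveries; 60–100 seeds for
type-I-error rates; 60-frame point patterns. The full 559-slot,
999-permutation periodogram runs in under a second, so the acceptance
procedure (2 bands × 21 deployments) completes in about half a
minute. Permutation p-values use the add-one convention throughout,
so 99 permutations give p on a 1/100 grid (attained level 0.04 at
nominal 0.05 — visible in the type-I checks). Ties in amplitude
comparisons are absorbed with a 1e-12 slack in the ≥ direction
(conservative). Random number use is always through seeded
`numpy.random.Generator` objects; pipeline stages spawn independent
child generators so stage order never perturbs another stage's
stream.

## Known limitations

- Integer candidate periods only; a 12.42-h signal is read through
  its 12-h fold and its 25/37/50-h near-multiples (see the power note
  above). No Fourier/Lomb-Scargle option and no decomposition into
  named tidal constituents.
- Pooled segregation assumes the per-frame random-labelling null;
  no z-test or envelope inference on S.
- Complete-case alignment in variation partitioning drops every slot
  with any missing value across Y and predictors.
- The CLI's `run-all` treats each variable independently for
  detrending decisions; no shared-trend modelling.
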