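# Methods

## The measurement model

Each trial is one mucus application to an organ-bath preparation: a 10-min
control recording, a 5-min pause while the extract takes effect, and a
10-min response recording. Three high-contrast markers (diverticulum,
copulatory canal, atrium) are tracked through the video; the analysis
series is the Euclidean displacement of a marker between successive
positions on a 5-s grid, so a 600-s segment contributes 120 displacement
values. The pause is dropped; each retained interval is labelled by the
segment containing its start.

A contraction is a displacement excursion that satisfies three rules,
applied to the whole trial (control and response jointly, which keeps the
two segments comparable within a trial):

1. **relative threshold** `T = d_min + 0.25 (d_max − d_min)` over the
   trial's displacement values — only samples above `T` count;
2. **duration cutoff** — a maximal run above `T` lasting more than 180 s is
   discarded (slow repositioning, not a contraction). Run duration is the
   number of suprathreshold samples times the 5-s step, i.e. the time the
   series stays above `T`; a 180-s run is retained, anything longer is not;
3. **peak separation** — each run contributes its maximum as the peak;
   peaks closer than 15 s are merged, keeping the larger peak and the union
   of run extents. Peaks exactly 15 s apart stay separate.

Runs cannot bridge the pause (blocks are split at time discontinuities).
Runs truncated by a block edge are retained if their observed duration is
within the cutoff (`keep_boundary=False` drops them instead). Events are
attributed to the segment containing their peak. A trace whose total range
is below `range_epsilon` (default 0.05 displacement units, well below any
contraction amplitude) is treated as quiescent and yields no events: a
relative threshold is meaningless on an essentially flat trace.

Scores per trial: `induced = n_response − n_control` (an integer, possibly
negative), `intensity = max(d)` over the whole trial, and
`responded = n_response > n_control` (strict).

Two identified ambiguities are resolved as switches: the threshold is
computed on the displacement series (not the raw coordinate excursion), and
the threshold basis spans both segments jointly; both choices are the
defaults and the alternatives are one-line changes at the call site
(`detect_contractions` arguments / a pre-transformed trace).

## The synthetic experiment

The generator produces every input the pipeline consumes, with known
ground truth, under the study's design constants: 29 experimental days; per
day, two focal-species positive controls bracketing up to five donor
species drawn without replacement in random order; 5-s analysis sampling of
600/300/600-s segments; a 2.2-mg extract portion carried as an annotation.
The webcam's native frame rate is not part of the protocol, so the frame
interval is a parameter (default 1 s) and only the 5-s grid is analysed.

A planted contraction is a raised-cosine displacement pulse — smooth,
single-peaked, with controllable duration (default 30 s, well inside the
180-s cutoff) — with amplitude drawn from a normal distribution (mean 1.0,
SD 0.15 displacement units) truncated at ±2 SD, so planted peaks always
clear the 25% threshold. Events are placed with at least 20 s between the
end of one and the start of the next and a 15-s margin from segment edges.
Event counts per segment are Poisson: 1.0 expected spontaneous contraction
per 10-min control segment, and a per-species response rate (default 3.0
for the focal extract, so the planted induced count averages 2; weak
extracts near 1.0). Weak extracts also scale response amplitudes down.

The baseline is a small linear drift plus a slow sinusoid (amplitude 0.005
du, period 600 s) and a smooth wobble: Gaussian-kernel-filtered white noise
(10-s correlation) passed through a soft saturation at 2.5 SD. The
saturation encodes that a resting preparation wobbles within a limited
envelope rather than producing spike-like excursions; it is what makes the
relative-threshold rules well-posed on noisy baselines. Consequences worth
knowing: (i) with the default noise (5% of the mean amplitude) and even at
10% noise, planted counts are recovered exactly in ≈99% of trials; (ii) a
trial with *no* real contraction in either segment and visible noise is the
pathological case for a relative threshold — the 25% line slices through
the noise and both segments pick up spurious balanced peaks. Such trials
are rare at the default rates (<2%) and bias the induced count only
slightly. Real data differ from this generator in ways the tests cannot
probe: correlated motion between the three markers (one organ dragging
another), non-stationary responsiveness within a day beyond the optional
control-2 inflation, and heavy-tailed tracking failures.

Trial directions, marker offsets and all randomness derive from
`SimulationParams.seed` through per-trial `SeedSequence` streams, so
identical parameters give byte-identical outputs.

Paired length measurements: each organ has a true resting length
`L0 ~ N(29.1, 2.0²) mm` (the 29.1-mm default makes the strongest planted
effect, a 19.6% reduction, equal 5.7 mm); six digitized measurements
(three per side) are taken at time 0 and fifteen minutes later around
`L0` and `L0(1 − effect)` with 1.0-mm measurement noise. The per-species
effect defaults follow the magnitudes of the significant reported
reductions (5.4–19.6%), with zero for species without a significant effect.
The record keeps the grand mean of the six measurements per time point;
averaging per side first differs only under unequal replicate counts.

## Inference layer

**Steel many-one rank test.** For each treatment, the pooled
(control, treatment) sample is midranked; the statistic is the treatment
rank sum `R`, standardized with the tie-corrected variance
`Var(R) = n₀n₁(N+1)/12 − n₀n₁ Σ(t³−t)/(12N(N−1))` and a 1/2 continuity
correction. The sign convention puts suppressed treatments at negative Z.
Family-wise two-sided p-values use the equicorrelated multivariate-normal
bound: the k statistics share the control sample, giving pairwise
correlation `ρ_jl = sqrt(n_j n_l/((n_j+n₀)(n_l+n₀)))` (= 1/2 at equal n); a
common ρ (the mean off-diagonal) enters the one-factor integral
`P(max|Z| ≤ z)`, evaluated by 80-node Gauss–Hermite quadrature. A Šidák
fallback and a joint-permutation mode (max-|Z| null over label
permutations, p with the observed arrangement counted) are provided; the
permutation mode is the internal oracle for the normal mode. Measured
under the null (k = 8, n = 19, 5000 simulations) the family-wise type-I
error at α = 0.05 is ≈ 0.04–0.05.

**Mixed (split-plot) ANOVA.** Log-length with Time (two levels, repeated)
and Species (between, unbalanced group sizes allowed). With two
within-subject levels the split-plot strata reduce exactly to an analysis
of per-subject means (between stratum) and differences (within stratum),
which is how the sums of squares are computed. The Time test uses the
unweighted (Type-III-style) marginal mean of the per-species difference
means so that unequal group sizes do not leak the Species margin into the
Time test; the interaction tests equality of the per-species difference
means. Simple effects of Time within species are Fisher-LSD paired
contrasts against the pooled within-subject error — deliberately
unadjusted across species, which is what LSD means. Subjects missing a
time point are dropped with a warning.

**GLMs.** Poisson log-link for counts and Gaussian log-link for intensity,
via statsmodels IRLS; the Gaussian log-link fit is initialized from an OLS
fit to `log(max(y, ε))` (ε = 10⁻³) since intensities can be near zero.
`AICc = AIC + 2k(k+1)/(n−k−1)` with k counting the intercept, factor
levels, and the Gaussian scale. The order-effect check compares
`response ~ Species` against `response ~ Species + PreviousSpecies`; lower
AICc wins.

**Blomberg's K.** With `V[i,j]` the root-to-MRCA path length,
`â = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹x`, `MSE₀ = (x−â)ᵀ(x−â)/(n−1)`,
`MSE = (x−â)ᵀV⁻¹(x−â)/(n−1)`:

    K = (MSE₀/MSE) / [(tr V − n/(1ᵀV⁻¹1))/(n−1)]

K = 1 matches Brownian resemblance among relatives (on a star tree with
equal branch lengths K is identically 1; over Brownian replicates on a
structured tree the mean K is 1 within Monte-Carlo error); K < 1 weaker,
K > 1 stronger. K is invariant to affine trait transforms, tip order and
tree rescaling. The randomization p shuffles trait values across tips
(default 1000 permutations) and counts the observed arrangement in both
numerator and denominator, so p ≥ 1/(n_rand+1); under an exchangeable null
the p-value is uniform. Zero-length terminal branches are nudged by
10⁻⁸ of the tree height to keep V invertible; a constant trait is an
error. The implementation agrees with an independent GLS reference to
10⁻⁸ on shared fixtures. The species tree shipped with the generator is a
synthetic stand-in topology (congeners grouped, the bradybaenid as
outgroup), not an estimated phylogeny — tree inference is outside this
package's scope, and K values on synthetic traits say nothing about the
real species.

The trait used for "shortening" is the per-species mean Δmm; response
traits default to per-species means of the daily-control-relative
responses (raw means are equally accepted).

## Normalization and exclusions

Relative response: a trial's induced count minus the day's control mean
(controls of a day average exactly 0); intensity as a 0–100 scale anchored
at the day's mean control intensity (100) and a configured zero-response
baseline (0; default 0 du for synthetic data, where a truly quiet
preparation produces essentially zero displacement). Responder
percentages: share of trials with strictly more response- than
control-period contractions; the focal species' two daily time points are
tallied separately and averaged. The atrium stream is excluded by default
(very low reaction); days on which an organ responded to nothing can be
dropped by flag.

## Numerical and design notes

* Detector ties: the peak of a run is its first maximal sample; merging
  keeps the larger peak's time and value and unions extents; a merged pair
  may exceed 180 s jointly (the cutoff applies to runs, matching the rules'
  order: discard long runs, then merge close peaks).
* Displacement is translation- and rotation-invariant by construction;
  scaling coordinates by c > 0 leaves counts unchanged and scales intensity
  by c (above the degeneracy epsilon).
* Tracking uses Otsu segmentation on inverted intensity (invariant to
  global affine intensity rescaling), intensity-weighted centroids over a
  1-px-grown bounding box (sub-pixel recovery; round-trip error ≈ 0.1 px
  against rendered stacks), globally optimal nearest-neighbour assignment
  with a search radius, linear interpolation across ≤ 3 lost frames, and an
  unusable flag beyond that or above 10% total gaps.
* Problem sizes in the shipped drivers and calibration runs (29-day
  experiments; 500-trial fidelity batches; 5000 null simulations for the
  Steel test; 1000 Brownian replicates and 200 × 199 randomizations for K)
  were chosen to make Monte-Carlo error small relative to the quantities
  reported while keeping each run in seconds on one CPU.

## Known limitations

The tracker is a minimal stand-in: no deformable models, no camera
calibration, single-scale segmentation. The generator's noise envelope
makes near-threshold contraction amplitudes rare by design; real weak
responses near the 25% line would be scored less reliably than the
fidelity numbers suggest. The Steel test's normal mode relies on the
equicorrelated approximation (exact only at equal sample sizes); the
permutation mode is the safe fallback at very small n. Exact small-sample
Steel critical tables and Pagel's λ are out of scope.
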