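# Methods

This note documents the models and procedures implemented in `mmtrack`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open.

## Setting

A mother machine holds bacteria in dead-end growth channels in single file:
the "mother" cell sits at the closed end, daughters are pushed toward the
open end and eventually out into the main flow channel. Imaging yields, per
growth channel and time point, a cropped image segment (100 px wide by
default) containing the channel. All analysis works on these per-channel
stacks, oriented with the open end at row 0; intervals are half-open
`[top, bottom)` in 0-based pixels.

## Joint segmentation and tracking (ILP)

Segmentation and tracking are solved jointly as one global optimization.
Because the device confines cells to a 1D column, segmentation reduces to
partitioning the channel's vertical intensity profile (row means over the
central columns of the phase-contrast image). Candidate cell intervals are
over-generated: atomic intervals are delimited by local maxima of the
profile (bright seams between dark cells) whose prominence exceeds a
threshold, and a containment hierarchy is built by removing boundaries in
order of increasing prominence, each removal merging two adjacent intervals
into a parent. `k` boundaries produce `2k + 1` hypotheses; any two
hypotheses on one root-to-leaf path overlap in pixels and are mutually
exclusive.

Candidate links between consecutive frames are of three kinds: *mapping*
(one successor), *division* (two vertically adjacent, disjoint successors),
and *exit* (the cell leaves through the open end). Every variable carries a
cost; the solution minimizes the summed cost of active variables subject to

- **continuity** — every active segment at an internal frame takes part in
  exactly one incoming and one outgoing assignment (a past and a future);
  the first frame needs only the outgoing constraint and the last only the
  incoming one;
- **conflict-freeness** — at most one active hypothesis per containment
  path.

Segmentation variables are eliminated by substitution: a segment is active
exactly when one assignment in its right neighborhood is selected (left
neighborhood on the final frame). The objective coefficient of an assignment
therefore folds in its source segment's cost (and its targets' costs on the
final frame pair), so each active segment is counted exactly once.

The resulting binary program is solved to proven optimality with HiGHS
(through `scipy.optimize.milp`); the formulation is solver-agnostic, and an
exhaustive brute-force oracle (`tracking.brute_force_solve`, feasible for
instances up to 25 assignment variables) provides an independent optimality
check in the test suite. A `warm_start` argument is accepted as a hint from
a previous solution; the returned objective is identical to a cold solve.
Determinism comes from deterministic model construction (fixed variable
order) and a deterministic solver; the brute-force oracle breaks cost ties
lexicographically.

### Costs

Segment cost: `w_int * (mean interior - mean flank)/range + w_len *
log(length/typical)^2`. Dark interiors with bright flanks score negative, so
selecting true cells is profitable and the empty solution is never optimal
on occupied channels. Mapping cost penalizes the squared deviation of the
log-size change from the expected per-frame growth increment and the squared
centre displacement; division cost adds a daughter-asymmetry term and a
fixed proposal penalty; exit cost is `gamma_exit` per hypothesis between the
segment and the open end, so a deep cell can only leave by pushing out
everything above it. Defaults (`HypothesisParams`): `w_int = 4`, `w_len =
0.5`, `w_growth = 8`, `w_shift = 2`, `div_penalty = 0.2`, `gamma_exit = 1`,
typical length 45 px, expected per-frame log growth 0.026 (0.75 dbl/h at
3 min/frame), centre-shift gate 0.5 typical lengths, size-ratio gate
[0.4, 2.5]. These weights shape which optimum is selected but the solved
optimum is exact for whatever costs are given.

### Curation directives

Manual corrections are linear constraints, so one edit re-optimizes the
whole channel and propagates to neighboring frames: force/ban a segment
(its activity sum = 1/0), force/ban a single assignment, fix the number of
cells at a frame, or clamp all assignments outside a frame window to a
previous solution (for fast local re-optimization). Directives come from a
versioned JSON file; a pixel coordinate can stand in for a hypothesis id and
resolves to the smallest containing hypothesis. Contradictory directives
surface as solver infeasibility, not as errors at directive time.

## Growth quantification

Cell size is the vertical extent of the selected segment (bounding-box
height). Elongation is exponential to excellent approximation, so the
per-cycle growth rate is the slope `a` of a linear regression of
`x(t) = log s(t)` on time, restricted to complete cycles (birth and
division both observed; note this per-cycle weighting slightly favours
fast-growing cells, which complete more cycles per unit time). The posterior
sd of the slope after marginalizing the birth size is

    sigma(a) = sqrt( var(x) (1 - r^2) / ((T - 1) var(t)) )

with `r` the Pearson correlation and `T` the number of points; this is
calibrated (empirical-to-predicted sd ratio within 10% at T = 30, 2.5% size
noise) and yields 1-3% relative errors at typical settings. Exponential and
linear growth models are compared via squared Pearson correlations; the
log-likelihood exponent `-T log(1 - r^2)` makes the comparison quantitative
(for T = 30, r^2 = 0.99 vs 0.98 the likelihood ratio exponent is 20.8).
Either variance convention (ddof 0 or 1) gives the same sigma(a) provided it
is used consistently, since the factors cancel.

Lag times after a nutrient switch are the delay until the (conversion-
scaled) molecule count first exceeds a threshold of 150 molecules (middle of
the 100-200 detectability range), followed through descendants and censored
at a horizon. Kin correlations are Pearson correlations over unordered cell
pairs whose most recent common ancestor is exactly k generations back
(k = 1: siblings), computed by ancestor grouping; values are symmetrized so
pair order does not matter.

## Fluorescence quantification

Fluorescence spreads far beyond the cell, well described by a Cauchy
(Lorentzian) peak on a flat background. Column sums `c_i` over a cell's
rows are fitted with

    c_i = noise + B + A / (1 + ((i - i_mid)/w)^2)

by an EM loop: initialize `B = c_min`, `A = c_max - c_min`, `w = 5.5`,
`i_mid` at the profile centre; iterate the multiplicative background and
amplitude reassignments, then update `i_mid` and `w` by finding the zero of
the corresponding stationarity condition with a bracketed root search around
the current value (if no sign change is found in the expanding bracket the
previous value is kept and the event logged). Convergence is declared when
the largest relative parameter change drops below 1e-6 (at most 500
iterations); non-convergence is flagged on the result, never raised.
The amplitude `A` is proportional to the cell's total fluorophore content.
The fit assumes the column sums are dominated by the focal cell; when
vertical neighbours differ in brightness by orders of magnitude this
assumption degrades, which is a known validity limit.

**Auto-fluorescence.** On reporter-free cells the amplitude is proportional
to cell size. Per cell, fitting `A_t = a S~_t` (with `S~_t` the sizes from
the cell's exponential fit, which are more accurate than raw sizes) under
Gaussian noise of unknown scale gives the closed forms
`a* = <A S~>/<S~^2>` and `sigma_a = sqrt((1/T)(<A^2>/<S~^2> - a*^2))`.
Population-level estimates combine cells either by precision weighting or by
maximizing a Gaussian-inlier / uniform-outlier mixture over the common value
`alpha` and the inlier fraction, with outlier support `W = max(a*) -
min(a*)`; the mixture is maximized by a coarse grid scan followed by
Nelder-Mead polish. A floor of `1e-6 * median(a*)` keeps precision weights
finite for degenerate perfect fits. The corrected level is
`A~ = A - alpha * S` (negative values permitted and logged — they are noise
around zero signal).

**Bleaching/degradation.** During production-free (glucose) phases the
signal decays exponentially at a combined rate mu. Analysis windows run from
30 min after each switch to the repressing condition until the next
induction; cells need at least 10 observations inside the windows. Per-cell
rates come from regressing log-level on time; the combined rate is their
precision-weighted mean. Decay-fit residuals, binned by level, give the
measurement-error profile of the fluorescence estimates; under shot noise
the squared relative error scales as 1/G (log-log slope -1).

## Conversion factor lambda (fluorescence -> molecules)

At division the mother's fluorophores partition binomially, so sibling
fluctuation statistics carry absolute-number information. The naive
estimator `lambda = 1/<(x-y)^2/(x+y)>` ignores daughter-size fluctuations
and therefore decreases systematically with total fluorescence (severalfold
across the simulated range) — the binned variant (bin width 5000) makes this
diagnostic visible. The full model treats the measured fluorescence fraction
`q_i` as a noisy observation of the measured size fraction `rho_i` with
variance `v + rho_i(1 - rho_i)/(lambda (x_i + y_i))`; the joint
log-likelihood is summed over pairs, and the posterior over lambda
marginalizes the unknown noise variance v numerically (uniform prior,
trapezoidal quadrature with log-sum-exp stabilization; the v grid's upper
bound is set data-adaptively to 10 var(q - rho) and is reported in the
output for sensitivity checks). Defaults: lambda log-spaced over [1e-4, 1]
(241 points), v linear (121 points). The reported point estimate is the
grid MAP under the uniform prior; the "95% interval" is read as equal-tailed
(2.5/97.5 posterior quantiles). Birth fluorescence of each daughter is the
average of its corrected levels rescaled back to birth time by
`exp(+mu dt)`; birth size is back-extrapolated from the log-length fit;
pairs qualify when both daughters pass the decay-analysis criteria.

## Synthetic data generator

The generator (`simdata`) is the package's ground truth. It emulates:
exponential single-cell growth with per-cell rates drawn lognormally (mean
0.75 dbl/h, CV 0.17 — lognormal for positivity); division on doubling the
birth length with a cytoplasm split drawn around 0.5 (sd 0.035); exact
binomial partitioning of integer fluorophore counts; bleaching as binomial
thinning with per-frame survival `exp(-5.3e-5 s^-1 * 180 s)` (integer counts
preserved); GFP production at 4000 molecules/h in the inducing condition and
0 otherwise, on a 4 h glucose / 4 h lactose alternating schedule; Cauchy
lateral spread (width 5.5 px) with amplitude `27.7 * molecules +
421.8 * length_um` over a flat per-pixel background of 50; and shot-noise-
like pixel noise with sd equal to the square root of the pixel value. The
geometry is a 384 px (25 um at 0.065 um/px) channel inside a 100 px wide
segment; frames are 3 min apart, 480 frames by default (a 24 h movie).
Phase contrast is rendered schematically — dark rectangles with bright 1 px
seams, Gaussian-blurred — because only the vertical profile matters
downstream. A cell exits once its midpoint passes the open end; the
remainder of such cells is not rendered.

Not emulated: realistic point-spread functions, focus drift, rotation or
stage jitter beyond rigid translation (the preprocess module handles
synthetic rigid shifts), growth arrest after nutrient switches, filamentous
or lysing cells, and inter-channel cross-talk. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
assumptions, not robustness to every real-data pathology; the tracking
model's robustness margin on real data is carried by the curation-directive
mechanism.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale studies chosen to
exercise every claim while staying cheap: 200 random small ILP instances
(rejection-sampled to at most 25 assignment variables so the exhaustive
oracle stays feasible) with four directive variants each; 100 EM profile
fits per noise condition; 1000 simulated growth tracks (T = 30, 2.5% size
noise); 357 sibling pairs per replicate, 50 replicates, for the lambda
posterior; one 480-frame end-to-end movie (~35k-40k assignment variables,
solved to proven optimality in seconds). Tolerances: ILP-vs-oracle
objectives to 1e-6; EM convergence 1e-6 relative; posterior normalization
1e-8. Degenerate inputs are handled explicitly: flat profiles yield a single
full-interval hypothesis; constant profiles fit as pure background; empty
channels produce empty (feasible) models via exits.

## Known limitations

- The hypothesis generator and cost functional are this package's own
   1D-profile design; alternative segmenters could be swapped in behind the
  same forest interface.
- Exit costs encode dead-end-channel physics heuristically; a cell deep in
  the channel disappearing (lysis) is expensive to explain and will usually
  need a directive.
- The lambda model approximates binomial variance with measured quantities
  and assumes a single common measurement variance v across pairs.
- Per-cycle growth statistics are cycle-weighted (see above), a property
  shared by any per-cycle analysis.
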