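# Methods

This note records the models the toolkit implements, the assumptions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the design decisions taken where the assay description
leaves the implementation open.

## Movement quantification

The motility readout is deliberately crude: it does not track larvae, count
them, or distinguish swimming from jumping from resting. A 30-frame sequence
at 10 ms intervals is reduced to the per-pixel **population** variance of
frames 1, 11 and 21 (1-based positions, configurable), and a pixel counts as
"moved" when its variance strictly exceeds the image-wide mean by three
image-wide standard deviations. The movement index of a well is the count of
such pixels in its region.

Properties that the implementation relies on and the tests enforce:

- **Affine invariance.** Replacing every intensity P by a·P + b (a > 0)
  multiplies all variances by a², and the mean + 3σ cutoff by the same a²,
  so the binary map is unchanged. Camera gain and offset therefore cannot
  change an index.
- **Divisor indifference.** Sample instead of population variance multiplies
  every pixel's variance by the uniform factor T/(T−1), which cancels in the
  scale-free threshold. Population variance is used throughout for
  consistency with the streaming recurrence.
- **Conservation.** Indices over a partition of the image sum to the
  whole-image count, so per-well and whole-plate readouts agree.
- **Operating regime.** The mean + 3σ rule presumes moving pixels are a
  small minority. With a two-point variance distribution (fraction p of
  pixels at high variance V, the rest near zero), the cutoff
  V·(p + 3√(p(1−p))) rises above V once p exceeds ≈ 8%, at which point the
  index collapses. Real plate images sit well inside the regime (larvae
  cover ~5% of a well and drift a fraction of their own width between
  sampled frames); the synthetic generator is built to the same densities.

The threshold statistics are computed over the whole image by default (the
assay computes a single mean variance), with a per-well alternative
available (`ParagonParams.threshold_scope`). A consequence of the global
default is mild coupling between wells: a plate on which many wells are
immobilized has a lower cutoff, inflating the remaining wells' counts. At
realistic densities the moving-pixel variance sits far above the cutoff and
the effect is small.

Normalization divides each well's post-compound index by the **same well's**
pre-compound baseline (median across baseline sequences), cancelling
per-well differences in larva number. A zero baseline (empty or motionless
well) makes the normalized value undefined; it is flagged as NaN and
excluded from medians and fits rather than propagated as infinity. Several
image sequences recorded at one timepoint are aggregated by median, the same
rule used for biological replicates.

## Concentration–response model

The normalized movement index M is modelled as the two-parameter Hill
(log-logistic) curve M(C) = 1/(1 + 10^((C − I)·H)) with C and I in log10
molar and the slope H constrained positive, so the curve falls with dose and
M = 0.5 exactly at C = I; pIC50 = −I by construction. The printed form of
the exponent in the assay description, (I − C)·H, would rise with dose for
positive H; the implemented orientation is the same curve family with the
sign absorbed into H and matches the observed decreasing responses. The
scale of I and C inside the exponent (log10 molar) is likewise an
implementation decision, chosen so that pIC50 = −I falls out exactly.

Fitting is bounded least squares (`scipy.optimize.least_squares`, function
and parameter tolerances 1e-10): initial midpoint at the concentration whose
response is nearest 0.5, initial slope 1, midpoint bounded within ±3 decades
of the tested range and slope in (0, 20]. Responses are not clipped —
normalized indices above 1 occur and are tolerated. Mortality data are
fitted with the rising mirror curve D = 1 − M(C); the midpoint is then the
LC50 and its −log10 is reported on the same convention as the pIC50
(algebraically, fitting mortality D equals fitting movement 1 − D).

A fit is flagged unconverged when the optimizer fails, when the responses
are flat (range < 0.1), or when the **fitted** curve spans less than 0.1
across the tested concentrations — the last catches noisy-but-flat data
where the optimizer parks the midpoint outside the tested window; no potency
claim is supportable in that case. Uncertainties are not estimated from the
fit; replicate spread is the intended error measure.

## Streaming variance

Low-power cameras cannot buffer sequences, so mean and variance are updated
per frame: M_n = M_{n−1} + (P − M_{n−1})/n and
V_n = ((n−1)·V_{n−1} + (P − M_{n−1})(P − M_n))/n, with M₁ = P and V₁ = 0.
The recurrence as printed in the assay description writes V_n on both sides;
the implementation reads the right-hand V as V_{n−1} — the only terminating
interpretation — and the tests verify the result equals the two-pass
population variance to 1e-9 relative on arbitrary feeds. Measurement runs in
reset-per-cycle mode (a fresh accumulator per cycle, default 60 frames every
10 s, matching ~2 s of capture at 30 fps on 320×240 frames); a continuously
accumulating or sliding-window mode would also be consistent with the
description, but reset-per-cycle is what "2 s measurements every 10 s"
implies. Partial trailing cycles are discarded with a warning. Exports are
stamped at the capture midpoint of their cycle.

## Decay model and resistance calls

Per-well variance traces after insecticide addition are fitted with
V(t) = A + B·exp(−k(t − T)) for t ≥ T and the plateau A + B before T. The
pre-onset plateau is an implementation decision (the formula's intent for
t < T is unstated; observed traces are flat before the compound arrives).
T may be fixed to the known addition time (e.g. 200 s) or fitted.
Initialization: A = min(V), B = range(V), T at the end of the plateau (last
time within 5% of the top), k from a log-linear regression of V − A on the
post-onset tail; bounds keep B, k ≥ 0. Flat traces (range ≈ 0 relative to
magnitude) are returned unconverged with amplitude ~0 — k is unidentifiable
without a decline.

Groups of fitted rates are compared with a one-tailed unpaired
pooled-variance (Student) t-test of H1: mean k(susceptible) >
mean k(resistant). The pooled test is used, rather than Welch, because the
reported df convention is n₁ + n₂ − 2 (two groups of three → df = 4). The
reported decay-rate magnitudes in the source description ("×10³ s⁻¹")
contradict its ~1000-s time axis (most plausibly a 10⁻³ typo) and are not
used as reference values anywhere; recovery is checked against planted
ground truth instead. Classification of a single well is by threshold on k
(susceptible above, resistant below, indeterminate for unconverged fits or
vanishing amplitude); where no absolute field threshold exists, the
geometric mean of reference susceptible and resistant rates is provided as a
relative threshold.

## Library screen

Each compound's replicate values are the defined normalized indices of its
wells across replicate plates at the assay timepoint (default 240 min after
dosing); the per-compound median is ranked ascending, rank 1 being the
strongest motility reduction. Ties are broken lexicographically by compound
id so rankings are deterministic. Compounds whose normalized indices are all
undefined (zero baselines throughout) are excluded with a warning rather
than imputed. Vehicle (DMSO) control wells are used for QC only — each well
is normalized to its own baseline, not to the controls. Hit confirmation
refits the Hill curve per compound on ≥ 4 concentrations of median
normalized indices.

## Synthetic data generator

The generator emulates the features of larval plate videos that the
measurement keys on, not their appearance. Each well of a plate (default
8×12 at 80 px/well, i.e. the ~80 px/well optics of a 2560×2160 sensor
cropped to a plate) holds 5–10 larvae drawn as bright ellipses
(~16×3 px, emulating 1–2 day old first/second instars at that scale) on a
dark background. Motion per frame is Gaussian drift (SD 0.3 px/frame, so a
step of roughly a larva width per 10-frame sampling gap — slow
filter-feeding drift) plus sporadic jumps (Poisson, 0.01/frame/larva,
~20 px — a body-length lunge), with reflection at well walls. Gaussian
sensor noise (SD 2 intensity levels) is added before 8-bit quantization.
These magnitudes were chosen once as a realistic emulation of the filmed
assay: they put moving pixels at ~5–7% of the image, inside the threshold's
operating regime, exactly as the real optics do.

A dosed well's whole motion process — drift SD and jump rate together — is
scaled by the Hill factor M(C) at its concentration, closing the loop so
that fitting the measured indices is a well-posed recovery of the planted
(I, H). Scaling only the drift would leave a dose-independent jump floor
under the index, which paralysis does not do. `simulate_series` renders a
baseline acquisition and a post-compound acquisition of the *same* larvae
(counts and positions carry over), each as 5 repeated sequences per
timepoint by default (the filming protocol records 5–10 back to back);
repeats are medianed by the measurement pipeline and damp the Poisson jump
shot-noise that dominates single-sequence variability. Every generator is a
pure function of (parameters, seed): identical seeds give bit-identical
output.

What the generator does not emulate — and what passing tests therefore do
not show about real data: optics (blur, meniscus shadows, illumination
gradients), hydrodynamics and wall-following behaviour, larva size
variation, death versus paralysis, plate-edge effects, and well-to-well
cross-contamination. Tests against it validate the measurement and fitting
machinery, not biological effect sizes.

`SimulationConfig.reduced()` is a quarter-resolution variant (20 px wells;
a full plate fits in 160×240 px; larvae 5×1 px, drift 0.075 px/frame) that
preserves larva density and the drift-to-size ratio. Bulk experiments — the
20-screen planted-hit study and the 10-seed end-to-end pIC50 recovery in the
test suite and acceptance script — use it so that hundreds of plate videos
render in minutes; single-plate unit tests that need low index noise (e.g.
flatness detection in hit confirmation) use the full resolution.

## I/O and geometry conventions

Image input is multi-page TIFF or a directory of single-frame TIFF/PNG
images ordered by natural (numeric-aware) filename sort, so differing
zero-padding cannot shuffle frames; color input is reduced to grayscale by
unweighted channel mean (the reference camera is monochrome, so this only
affects smartphone-sourced frames). Time is measured in seconds relative to
compound addition; baseline acquisitions carry negative times. Pixel
coordinates are 0-based with half-open rectangles and origin top-left; wells
are labelled row-major from "A1". Well delineation is by declared
rectangular grid (integer-division remainders absorbed by the last row and
column, so the grid tiles the box exactly); the variance-driven alternative
segments pixels above a configurable quantile (default 0.95, minimum area
20 px, 8-connected) of a variance map — quantile thresholding makes it
gain-invariant — and assigns components to wells by centroid containment,
falling back to the grid rectangle for wells with no component. Input
images are assumed already framed to the plate; plate detection and
perspective correction are out of scope.

## Problem sizes used in validation

The acceptance script (`scripts/acceptance.py`) and the heavier tests use:
100 random 60-frame 8×8 feeds for the streaming identity; 8 concentrations
× 3 replicates × 100 seeds (σ = 0.05) for noisy sigmoid recovery; 300-point
traces for decay recovery (5% amplitude noise for the noisy case); 20
reduced-resolution 42-well screens of 40 compounds with 5 planted actives
(motility factor 0.05 at 10⁻⁵ M) for hit recovery; and 10 seeds of
full-96-well reduced-resolution experiments (8 concentrations × 12 wells ×
3 replicate plates, 5 sequences per timepoint) for end-to-end pIC50
recovery against a planted pIC50 of 7.0. These sizes are the package's own
validation choices; the generator's full-resolution defaults remain the
reference conditions.
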