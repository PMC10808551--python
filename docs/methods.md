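# Methods notes

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data tests do and do not
establish.

## Signal model and ΔF/F

Raw fluorescence per cell is modeled (and, in the generator, produced) as

    F(t) = B · (1 + d(t)) · (1 + a · Σ_k κ(t − t_k)) + ε(t)

with photon baseline `B`, slow multiplicative drift `d(t)` (stationary
AR(1), default SD 0.1 of baseline, 60-s timescale), a unit-peak
difference-of-exponentials indicator kernel `κ` (rise 0.1 s, decay 0.7 s —
GCaMP6f-like; the kernel constants are conventions, not measured values,
and are fully configurable), per-spike amplitude `a` (default 1 ΔF/F
unit) and Gaussian shot noise (default SD 0.15 ΔF/F units). The kernel is
truncated at 25 decay constants, where the tail is below 1e-10 of the
peak, so single-spike responses match the closed form to numerical
precision.

**Principal-cell ΔF/F** subtracts a sliding 8th-percentile baseline
computed in an ~8-s window around each sample and divides the corrected
trace by the initial baseline estimate — the mean of all raw samples not
exceeding 3 SD of the total signal. The order (subtract drift, then
divide by one scalar baseline) is the only one in which the subsequent
SD-based event logic is scale-consistent; the procedure is equivariant to
positive rescaling of the raw trace, which is asserted by a property
test. Windows are truncated at the trace edges (no padding) and
recording-gap samples are excluded from the window statistics.

**Interneuron ΔF/F** divides each contiguous recording segment by the 8th
percentile of its own fluorescence distribution — division only, so the
quiet baseline sits near 1 rather than 0. Interneuron traces skip
transient detection entirely and are analyzed as continuous rate proxies:
at interneuron firing rates individual events are not separable at a 10-Hz
effective sampling rate. A consequence worth knowing: the per-cell
normalization factor includes the cell's own activity floor, so ΔF/F
slopes are attenuated by a cell-specific factor. Cross-cell comparisons of
slope magnitude inherit this attenuation (sign and ordering are
preserved); this is a property of ΔF/F itself, not of the implementation.

## Transient detection and false-positive calibration

An event starts where the trace exceeds `baseline + θ·SD`, must stay above
threshold for at least the minimum duration, and ends when the trace
decays below `offset_fraction` (default 0.5) of the threshold level.
Detection is two-pass: a first pass with the initial 3-SD baseline
estimate, then baseline and SD are recomputed from transient-free samples
and detection is re-run once with the definitive values.

Calibration walks a grid of `(θ, min_duration)` pairs — θ ∈ {2, 2.5, 3,
3.5, 4} SD × duration ∈ {0.2, 0.3, 0.5, 1.0} s, from permissive to
stringent — and returns the least stringent point whose ratio of
negative-going to positive-going transients (the same detector applied to
the sign-inverted, baseline-centered trace) is below 5%. The grid is a
documented stand-in: the protocol this mirrors cites a parameter family
without printing it. On data without genuine events no grid point can
qualify (the ratio hovers near 1 by symmetry) and calibration raises
rather than returning uncalibrated parameters — the guarantee is "below
5% or an explicit error", never silent failure.

## Behavior, maps and tuning metrics

Movement is speed ≥ 2 cm/s outside recording gaps; slower frames count as
immobility because position-sensor jitter makes a strictly-zero criterion
unusable. Track bins are half-open `[k·w, (k+1)·w)` with w = 5 cm for all
tuning metrics and w = 10 cm only for population vectors; at a fixed
sampling rate the per-bin frame mean equals the time mean, so `λ̄ = Σ p_i
λ_i` holds as an exact identity (asserted to 1e-12).

Spatial information uses the convention `0·log 0 = 0`; negative ΔF/F bin
means (possible after drift correction) are clamped to zero before the
logarithm, since the weighted-information form is undefined for negative
rates. Cells with `λ̄ ≤ 0` are flagged inactive (NaN) rather than scored.
The normalized variant divides by mean activity and is invariant under
positive rescaling of the map. Coherence correlates each bin with the
mean of its two nearest neighbors, with wraparound on circular tracks;
vector tuning is the activity-weighted circular resultant (length exactly
`I₁(κ)/I₀(κ)` for a von-Mises map of concentration κ, which the tests
check against the Bessel ratio). Split-half stability is the zero-lag
Pearson correlation of first/second-half maps over jointly occupied bins;
"zero-lag Pearson" is the only reading of a cross-correlation that yields
one number per cell. Sessions are split at the median trial boundary per
context; odd trial counts give the extra trial to the first half.

## Circular-shuffle significance

Activity and behavior are concatenated across the runs of one condition;
each shuffle rotates the behavior arrays (position, movement mask, half
labels) forward against the fixed activity trace, with the values falling
off the end re-entering at the start. Shifts are drawn uniformly with
replacement from `[min_shift, T − min_shift]` with `min_shift` = 10 s of
frames; near-zero and near-full shifts are excluded because they
replicate the true alignment. One shift sequence is shared across the
metrics of a cell, so all metrics see the same null alignment.
Significance requires the true value to exceed strictly more than 95% of
null values. True values and nulls are computed by one vectorized code
path, which a test pins against the scalar public metric functions to
1e-10 — the null can therefore not drift away from the statistic it is a
null for. Restricting the shift support breaks exact group-invariance of
the permutation test by a fraction min_shift/T; at the default session
lengths the type-I error stays inside the 95% binomial CI of 0.05, which
the acceptance suite measures directly on 500 untuned cells.

Population-level tuning draws one random null value per cell and compares
the drawn distribution against the true values with a paired two-sided
Wilcoxon signed-rank test. Place cells require shuffle-significant SI and
at least 1 transient per minute of movement.

## Remapping

Per-cell field correlations use 5-cm maps over jointly occupied bins
(10-cm bins are reserved for population vectors, with a config switch).
Population-vector correlations z-score each cell's map over space first,
so rate-only changes (same field, scaled amplitude) leave pv_corr ≈ 1 —
the measure isolates the spatial pattern, and a test asserts exactly this
contract. Sessions with fewer than 5 place cells in either condition are
excluded. Undefined per-cell correlations (too few joint bins, zero
variance) propagate as NaN and are excluded from group statistics with
reported counts, never zero-filled.

## Statistics layer

Outlier fences are `[Q1 − 3·IQR, Q3 + 3·IQR]`, applied in a single pass
with fences from the original sample; with IQR = 0 the fences collapse
onto the point and an all-equal sample is left intact. Normality is
tested with a Kolmogorov–Smirnov test against a Gaussian with plug-in
sample mean and SD — the classical procedure; note that plug-in
parameters make the test anti-conservative in the Lilliefors sense, which
is accepted here as a documented property of the protocol rather than
corrected. Paired comparisons skip per-group outlier removal, which would
break pair alignment.

## The synthetic world

The generator's defaults state the recording conditions: 10 Hz effective
sampling per plane, a 400-cm circular track, 60-s alternating
familiar/novel blocks (10 min per context) separated by ~5-s blanked
teleports carrying no behavior, or fixed 15-lap blocks for the
chemogenetic-style design. Running is an Ornstein–Uhlenbeck speed walk
with a run/pause switch tuned to a mean moving speed of ~14 cm/s (the
10–20 cm/s range typical of trained head-fixed mice); exact kinematics
are a modeling choice, not a measured quantity. Firing follows

    rate(t) = max(0, b + m·v(t)) · (1 + g·f_vM(x(t))) · c(context)

with baseline `b`, speed slope `m` (positive, negative or zero by mixture
fraction), a unit-peak von-Mises place field `f_vM` parameterized by FWHM
in cm, and a multiplicative novel-context gain `c`. Negative modulation
is a negative slope on a positive baseline with clipping at zero. Spikes
are inhomogeneous Poisson at frame resolution with uniform within-frame
jitter.

Default per-cell distributions emulate sparse principal-cell populations
(baseline rate log-normal, median 0.3 events/s; slope median 0.02
(events/s)/(cm/s); 30% place-coding with gamma field gains of mean 3;
field FWHM log-normal around 40 cm). Interneuron-like simulations in the
tests override baseline to ~2 events/s and slope magnitudes to a median
0.06 (events/s)/(cm/s) so that modulation is comparable to baseline at
the top of the speed range — i.e. the tuning stays in the approximately
linear regime that the linear-fit analysis assumes; rate clipping then
distorts only the tail of the population. SNR is exposed through
`shot_noise_sd` rather than fixed, since no quantitative SNR is specified
for the different compartment types.

What the generator does **not** emulate: motion artifacts and their
correction residues, neuropil contamination, indicator saturation and
nonlinearity (transients add linearly), bursting beyond Poisson
variability, theta-timescale structure, slow representational drift, and
reward-related activity. A green recovery test therefore establishes that
the pipeline is correct for its stated signal model, not that it is
robust to every artifact of real recordings.

## Known limitations

* Multi-plane interleaving is reduced to one effective sampling rate.
* ΔF/F slope magnitudes are attenuated per cell by the normalization
  factor (see above); across-cell slope correlations saturate around
  r ≈ 0.93 in the recovery tests for this reason.
* The shuffle null assumes joint stationarity under rotation within a
  condition; strong within-session nonstationarity of behavior would
  weaken its calibration.
* Per-cell shuffle tests are reported uncorrected for multiple
  comparisons, matching the protocol; corrections are opt-in.
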