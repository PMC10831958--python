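# Methods

This note documents the models, estimators and numerical choices behind
`wavescan`, and what the synthetic benchmark does and does not show.

## Data model

A recording is a matrix of channels on a rectangular integer grid
(0 ≤ x < n_x, 0 ≤ y < n_y; empty sites allowed, inactive sites masked
but never renumbered) with a sampling rate in Hz and an inter-site
spacing in mm.  All times are seconds, distances mm, velocities mm/s;
unit conversion happens only at I/O boundaries.  Every processing block
appends one record (name + full parameter set) to an append-only
history, so any artifact can be traced to the exact block sequence that
produced it.  The noise label for unclustered triggers is −1.

## Synthetic data

The generator defines the study conditions for every downstream test.

**Calcium-like recordings** place a causal difference-of-exponentials
transient `k(t) ∝ exp(−t/τ_d) − exp(−t/τ_r)` (peak-normalized) at each
channel's true wave-arrival time, plus white Gaussian noise.  Defaults:
τ_r = 0.1 s, τ_d = 0.5 s (the order of GCaMP6f indicator dynamics),
20×20 grid, 0.05 mm spacing, 25 Hz, noise sd 0.05 of the unit transient
amplitude, waves every 4 s.  The kernel peaks `peak_lag` after onset
(reported so tests can compensate) and its support is defined at the
0.1 % decay point; wave trains whose arrivals overlap within the support
are rejected so the ground truth stays unambiguous.  Planar waves reach
site (x, y) at `onset + (x·cosθ + y·sinθ)·scale/v0`; radial waves at
`onset + ‖site − origin‖/v0`.  Radial waves from the grid centre serve
as the complex, low-planarity fixture: their outward flow vectors cancel
almost exactly in the planarity sum.

**MUA-like recordings** model micro-ECoG input to the logMUA estimator:
a band-limited (200–1500 Hz) Gaussian noise component — the multi-unit
activity — whose sd is multiplied by `up_gain` for `d_up` seconds after
each wave arrival, on top of a stationary broadband background
(default sd 2.5× the MUA sd).  The background stands in for the
non-spiking contributions to an extracellular signal.  It is essential:
for a purely gain-modulated broadband process the in-band and
full-spectrum powers scale together and their ratio carries no state
information at all, so no spectral up-state estimator could work on such
a surrogate.  With the background present, the band/full power ratio
alternates between two levels about 0.4 log-units apart at gain 5,
roughly 15 standard errors of the per-window Welch estimate.  The 2.5
factor was chosen analytically (it maximizes the contrast of the ratio:
a much weaker background cancels out of the ratio, a much stronger one
drowns the numerator).  With `background_sd = 0` the surrogate is a pure
amplitude-modulated band-limited process and the up/down variance ratio
is exactly `up_gain²`.

Same seed ⇒ bit-identical output (single `numpy` Generator per call).

What the surrogates do **not** emulate: 1/f spectra, pink noise,
spatially correlated noise, indicator nonlinearities and bleaching,
hemodynamic contamination, non-stationary anesthesia depth, spiral or
colliding waves.  Passing the benchmark therefore shows the estimators
are correct and well calibrated under these idealized conditions, not
that they are robust to every artifact of real recordings.

## logMUA estimation

For each output sample (rate 100 Hz) a 0.3 s window centred on the
output time is taken (edge windows truncated, never zero-padded; flagged
in the history).  Its Welch PSD uses `nperseg = round(fs / f_low)`
samples per segment — rounding to nearest where the quotient is not an
integer — 50 % overlap rounded down, a Hann window and linear
detrending.  The MUA value is the mean in-band power over the mean power
of the whole spectrum of that same window, and the output is its natural
logarithm (the base only shifts/scales the bimodal distribution, so the
threshold fits are invariant to it).  The window must satisfy
`window_size ≥ 1/f_low` and `mua_rate ≥ 1/window_size`.

## Trigger detection

*Threshold*: upward/downward crossings of a per-channel threshold with
linear interpolation between samples.  The bimodal variant fits a sum of
two Gaussians to the amplitude histogram (Freedman–Diaconis bins by
default; means initialized by 2-means on the samples, equal weights) and
puts the threshold at the minimum of the fitted mixture between the two
means; the fit is rejected as "no bimodal structure" when the means are
closer than the sum of the fitted widths, in which case the caller may
fall back to the left-peak variant: locate the first dominant histogram
peak (prominence ≥ 25 % of the maximum to ignore counting noise,
quadratic sub-bin refinement), fit a Gaussian to the left flank, return
mean + sd·SIGMA_FACTOR.  Thresholding assumes channel-wise
quasi-stationarity of the two state levels; non-stationary recordings
should be segmented first or analysed with the minima method.  A
companion filter removes up/down states shorter than user minima while
preserving alternation.

*Hilbert phase*: the analytic-signal phase is taken in (−π, π] with
phase 0 at the signal peak, so the default threshold −π/2 marks the
beginning of the upstroke.  Crossings are linearly interpolated and kept
only when the phase reaches 0 before the next threshold crossing, which
rejects sub-cycle wobbles; input must be detrended and z-scored.

*Minima*: weak local minima (the last point of a flat stretch counts, so
an onset from a noise-free baseline is detectable) are accepted when
(1) the following maximum exceeds a relative height threshold within a
moving window, (2) accepted maxima are separated by a minimum distance,
and (3) the signal rises strictly for a required interval after the
minimum; among several candidates the last minimum before the good
maximum wins.  Minima are reported at sample resolution.  The
moving-window length has no universal default and is a required
parameter.

## Wave detection

Triggers are embedded at (x, y, t_frames · ratio) and clustered with
DBSCAN (ε = NEIGHBOUR_DISTANCE, min_samples = MIN_SAMPLES_PER_WAVE);
wave ids are renumbered by onset.  The scaling ratio is
`v0 / (sampling_rate · spatial_scale)` — grid units per frame at the
expected propagation velocity.  Because detected trigger times carry
jitter σ_t (≈ 6 ms for the Hilbert detector on band-passed signals at
the benchmark noise level), the scaled temporal scatter of a wavefront
is σ_t · fs · ratio and grows with the ratio; the calibrated-parameter
helper therefore sets ε = max(4, hypot(2√2, 3·σ_t·fs·ratio)) with 10
minimum samples.  Spurious triggers form either isolated noise points or
faint "echo" clusters that track the true waves and share their
kinematics.  Within a wave each channel keeps only its earliest trigger
(configurable), so the delay map is single-valued.

Optical flow uses Horn–Schunck with quadratic penalties: spatial
derivatives from a 3×3 Scharr-weighted stencil, evaluated on the unit
phasor `exp(i·phase)` so all differences are circular and the ±π seam is
invisible (adding 2π to the field leaves the flow unchanged); masked
sites are handled by renormalizing the stencil over valid neighbours,
and sites with an empty stencil side are NaN.  The field is spatially
pre-smoothed (Gaussian, σ = 1 site, on the phasor) before
differentiation — without it the per-site phase gradient of a fast wave
(which crosses the whole grid in about one frame at the benchmark's
30 mm/s) is dominated by noise.  Iterations run until the mean-square
update falls below 1e−6 or 500 iterations (non-convergence returns a
flagged result with a warning), and the vector field is finally smoothed
with a Gaussian of 1 frame × 1 site (spatial only when a frame subset is
computed).  α = 1.5 weighs smoothness against brightness constancy.
Flow can be restricted to the frames around trigger events — exactly
where directions are sampled — which cuts the cost roughly by the duty
cycle of the waves.

Wave modes: k-means (10 restarts, fixed seed) on the [waves × channels]
matrix of trigger delays since wave onset; channels a wave never reached
are imputed with the wave's maximum delay ("late"), configurable to
mean-imputation; mode ids are ordered by cluster size.  The number of
modes is a user choice.

## Characterization

The delay map T(x, y) of a wave is the trigger time minus the wave's
earliest trigger; its gradient gives the local slowness, and
`v = 1/‖∇T‖` the local speed.  Two gradient stencils are provided:
central differences (one-sided at boundaries and NaN edges; exact for a
linear delay map, which anchors the closed-form tests) and a local
least-squares plane fit over a 5×5 window.  The plane fit is used by the
noisy-recovery studies because trigger jitter (≈ 6 ms) exceeds the
inter-site delay (scale/v0 = 1.7–10 ms over the benchmark velocities),
which biases ‖∇T‖ of raw differences upward and hence speeds downward.
Sites with a vanishing gradient are reported NaN (undefined, not
infinite), and reported velocity distributions are capped at 120 mm/s —
near-identical delays at distant sites otherwise produce arbitrarily
large values — while raw values stay in the table with a flag.

Directions are the flow vectors at the trigger events (a delay-gradient
direction, −∇T, is available as a clearly labelled alternative);
planarity is the resultant length `P = ‖Σ v_i‖/Σ‖v_i‖` (clamped to 1
against float round-off); the interwave interval is the per-channel
difference between consecutive wave passages.  Wave-wise rows aggregate
channel values: mean of capped velocities, circular-mean direction (NaN
plus a flag when opposing vectors cancel).  Hedges' effect size uses the
(N−1)-weighted pooled standard deviation; KDE summaries use Scott's rule
except interwave intervals, which use a fixed kernel of 0.2 sample
standard deviations.

## Pipeline orchestration

A native orchestrator executes the configured stages in order, writing
each stage's artifact plus a JSON log (block sequence, parameters,
package version, elapsed time) and reusing cached outputs whose
timestamps are newer than both the config file and the upstream
artifact.  Per-stage config files are resolved from a profile name by
the hierarchical lookup: try the full name first (keeping any
`|variation` suffix while stripping `_subcategories` one at a time);
only when the bare `config|variation.yaml` is absent is the variation
dropped and the stripping restarted; the final fallback is
`config.yaml`.  Because `|` is awkward in shells, `@` is accepted as an
equivalent separator in file names.  Global parameters (including the
RNG seed handed to all stochastic blocks) override stage parameters.
QC plots are best-effort: a plotting failure warns and never fails the
run.  The two stage-5 variants (wave-wise and channel-wise tables) are
selected per run.

## Benchmark problem sizes

The study-scale suites run at: 20×20 grid, 25 Hz, 5 waves per run for
the planar/radial recovery study (velocities 5/15/30 mm/s, seeds 1–5,
noise sd 0.05; statistics pooled over seeds per condition); 2 planar +
6 radial waves for the downsampling trend (factors 1, 2, 4); 4×4 to 8×8
grids at 5 kHz for roughly 8–10 s for the logMUA studies.  These sizes
make the whole suite run in a few minutes while keeping every statistic
comfortably away from small-sample noise.

## Known limitations

Direction recovery by optical flow degrades at velocities where a wave
crosses the field of view within about one frame (here ≥ 30 mm/s at
25 Hz over 1 mm): per-run mean directions scatter by several degrees
even though they are unbiased across runs.  The minima detector cannot
mark a first wave that rises from a strictly monotone baseline segment
with no minimum.  Stage caching is timestamp-based, not content-based.
Critical-point analysis of the flow field (sources, sinks, spirals) and
spiral-wave surrogates are out of scope.
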