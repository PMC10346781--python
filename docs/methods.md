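# Methods

This note documents the models behind `wearagree`: what the synthetic
cohort generator emulates, how each processing stage is defined, the
numerical choices that matter, and what the tests do and do not establish
about real recordings.

## Study design being emulated

The analysis assumes a validation design in which every subject is recorded
simultaneously by three device classes during three consecutive 90-s
resting sessions, and all comparisons happen on a common 30-s feature grid
(the consumer device's output cadence), giving 9 paired points per subject
per feature. The laboratory device samples raw PPG and EDA at 64 Hz; the
research wearable samples raw PPG at 64 Hz and raw EDA at 4 Hz; the
consumer device emits only an integer HR (bpm) and an "EDA responses"
count per window. The raw PPG rate of the research wearable is a
configurable default (64 Hz), since wrist wearables differ here.

## Synthetic cohort generator

The generator is first-class, tested code: its role is to provide the exact
statistical structure the analysis assumes, plus a truth channel for
scoring every downstream stage.

**Cardiac.** Beat times follow 60/HR(t), where HR(t) drifts as a smoothed
random walk with within-session SD 2 bpm around a subject mean drawn from
Normal(70, 7) bpm, plus white beat-to-beat jitter (SD 0.02 s). The pulse
waveform is a two-Gaussian template (systolic peak σ = 60 ms; dicrotic bump
at +280 ms, σ = 90 ms, relative amplitude 0.35) — the minimal morphology
with one dominant local maximum per beat. The train starts at 0.4 s so the
first pulse is rendered whole; a recording naturally begins mid-cycle,
never mid-peak.

**Electrodermal.** EDA = tonic + phasic: the tonic level starts at a
subject baseline drawn from LogNormal(ln 5, 0.3) µS and drifts linearly
(slope ~ Normal(0, 0.3) µS/min); phasic activity is a homogeneous Poisson
stream of SCRs (2/min at rest) with amplitudes uniform on 0.1–0.6 µS,
each shaped by a unit-peak Bateman kernel with τ1 = 0.75 s, τ2 = 2.0 s.
Truth records event times and the exact per-window mean tonic.

**Device models.** Each raw device resamples the master 64-Hz physiology
(polyphase, anti-aliased, line-padded), adds Gaussian sensor noise, and
injects Poisson-placed motion artifacts: additive spikes (3–5× the median
2-s-window amplitude, 60 ms), dropouts (signal forced to 0 for 0.5–1.5 s)
and step discontinuities (0.8–1.5× median amplitude for 1–3 s). Every
injected interval is logged in the truth channel. Artifacts are injected
into the PPG modality only (profile-configurable): the analysis chain
removes artifacts only from PPG, so injecting uncorrectable EDA dropouts
would corrupt SCL by construction rather than test anything.

Default sensor-noise levels are 1% (laboratory) and 3% (research wearable)
of the unit pulse amplitude for PPG, and 5/10 mµS for EDA: resting-state
blood-volume pulse is clean at rest, and the premise of the artifact chain
is that *motion artifacts*, not broadband noise, are the dominant
corruption. The consumer emulator reports true window HR plus bias
(default 0) and Gaussian error (SD 3 bpm), rounded to integer, and the true
SCR count per window plus rounded miscount noise (SD 0.5), clipped at 0;
no public error model exists for that device, so these are documented
knobs.

What the generator does **not** emulate: optical/biomechanical sensor
physics, accelerometer-correlated artifact structure, nonstationary SCR
rates, ectopic beats, or respiratory sinus arrhythmia spectra. Passing
recovery tests therefore shows the chain is correct *under the stated
model*, not that it is robust to everything real skin and motion produce.

## PPG artifact chain

Filtering is zero-phase (forward–backward) 5th-order Butterworth, 1–15 Hz,
so pulse apices are not delayed; the effective order is doubled. Polarity
is decided once per recording from sample skewness (band-passed pulse waves
have sharp upward peaks, hence positive skew). Windows are 2 s,
non-overlapping; a trailing short window is kept but excluded from artifact
statistics and IBI estimation.

The amplitude criterion flags a window whose local maximum exceeds 2× the
median of all full-window maxima (single pass, no robustification) or
fails to exceed 5% of that median (the "no signal recorded" case; the
reference value is a configurable fraction because an absolute threshold
"around 0" cannot be scale-free).

The derivative criterion standardizes and squares the first difference
(scaled by the sampling rate). The 0.15-s convolution window enters in one
of two implemented orders: the default takes the 0.15-s moving average of
the squared z-scores and thresholds it at 9; the alternative thresholds
each squared sample at 9 and dilates detections over 0.15 s. The default
was chosen because a genuine discontinuity dominates its whole 0.15-s
neighbourhood, whereas isolated noise excursions above 3σ — which occur at
a 0.3% rate on *any* noisy recording, by definition of the threshold — are
averaged away; the per-sample variant is kept behind `deriv_mode="dilate"`
for sensitivity studies. Both detectors are exactly invariant under
positive rescaling of the signal (median and z-scores are
scale-covariant), which the property tests assert.

## Beat detection and heart rate

The detector follows the classic derivative → squaring → moving-window
integration (0.15 s) → adaptive dual-threshold scheme with a 0.25-s
refractory period, with the already-applied 1–15 Hz filter as its band-pass
stage and running signal/noise peak estimates updated with weight 1/8.
It runs independently on each contiguous run of clean 2-s windows, so a
rejected spike can never inflate the adaptive threshold of the clean data
around it. Accepted candidates are refined to the pulse apex with
sub-sample parabolic interpolation (at 64 Hz, plain grid snapping alone
would contribute ~0.2 bpm of window-level quantization error).

Inter-beat intervals are consecutive differences; an interval is invalid if
it lies outside 0.25–2.0 s (a 30–240 bpm physiological gate; the lower
rate bound mirrors the windowing premise that at least one beat occurs per
2 s) or if its span intersects any rejected window. HR per 30-s window is
the mean of 60/IBI over valid intervals assigned by interval midpoint —
unambiguous and shift-equivariant. Windows with no valid interval are
reported missing, never dropped.

## Continuous decomposition of EDA

After a zero-phase 4th-order 1 Hz low-pass, the recording is decimated to
an 8-Hz working grid (EDA is band-limited to 1 Hz here, so nothing is
lost and the deconvolution stays small; a 4-Hz input stays at 4 Hz). The
model is

    y(t) = tonic(t) + (driver ⊛ bateman_{τ1,τ2})(t) + residual(t),
    driver ≥ 0,

with the Bateman kernel normalized to unit peak, so a driver impulse of
value *a* reconvolves to an SCR of peak amplitude *a* µS. The kernel is
pushed through the same processing path as the data (low-pass at the input
rate, then decimation) so its sampled shape matches what the recording
actually contains.

The tonic baseline is a clamped cubic B-spline with 10-s knots fitted to a
morphological opening (1.5-s median prefilter, 20-s min–max opening,
odd-reflection edge padding) — the opening passes monotone tonic trends
unchanged while stripping phasic bumps narrower than its window, i.e. it
selects the driver-quiet level everywhere. Stretches where the signal sits
above the opened trace (phasic activity, extended ~4 s rightward to cover
sub-threshold decay tails) are bridged by interpolating the baseline from
quiet regions; a run touching a recording edge is extrapolated with the
global quiet-baseline slope, and the baseline is clamped to never exceed
the median-filtered signal.

The driver is then recovered by Lawson–Hanson nonnegative least squares on
the Toeplitz convolution operator with Tikhonov regularization (ridge
1e−3) — the active-set method exploits the driver's sparsity, and the
recovered driver is a handful of impulses at SCR onsets. Tonic and driver
are refined by two Gauss–Seidel passes: the spline is refit to
(y − phasic) with a mild curvature penalty (weight 3 on coefficient second
differences; exact for constant or linear tonic) and the driver re-solved.
The refit works because a tonic set too high leaves a *negative* residual
the nonnegative driver cannot absorb. Optionally τ1, τ2 are refined by
Nelder–Mead on the residual norm within (0.05, 30) s; the default keeps
them fixed at the conventional initial values 0.75/2.0 s.

The residual is defined as input − tonic − phasic on the input grid, so
conservation is exact by construction; the solver's quality shows in the
residual's size (relative norm ~0.03% on default synthetic sessions, <5%
asserted). All stages (min/max/median filters, least squares, NNLS with
fixed ridge) commute with positive rescaling, giving exact amplitude
covariance. SCRs are counted per 30-s window from driver bursts: local
maxima within a burst separate overlapping responses, detections closer
than 1 s are merged (sparse deconvolution can split one SCR across
neighbouring impulses), and responses below 0.01 µS (configurable stand-in
for the consumer device's proprietary criterion) are discarded.

## Agreement statistics

Per-subject Pearson r uses the product-moment formula with a two-sided p
from the t transform on n−2 degrees of freedom (scipy); subjects with a
constant series get r = NaN, not 0, and p is only computed from n ≥ 3.
The repeated-measures correlation fits value_B ~ subject intercepts +
common slope × value_A by least squares; SS_measure is the residual
reduction gained by the slope term over the intercepts-only model,
r_rm = sign(slope)·√(SS_measure/(SS_measure+SS_error)), df = N_total −
N_subjects − 1, and p comes from the F(1, df) tail. Subjects with fewer
than 2 complete pairs or constant predictor values carry no within-subject
information and are excluded and reported. Missing windows are deleted
pairwise within subject. The per-subject significance tally (r > 0,
p < 0.05) is raw — no multiple-testing correction — and every report says
so; this mirrors standard practice in small validation cohorts and is a
deliberate, flagged limitation.

The canonical comparisons pair each device against the laboratory
reference: HR for both comparison devices, SCL for the research wearable,
and — since the consumer device has no SCL — its response *count* against
laboratory SCL, which is a cross-feature association one should expect to
be weak (a count of phasic events is not a level).

## Problem sizes and determinism

Default analyses use 12-subject cohorts (36 sessions, 216 raw-device
feature windows); the test suite uses 3–6 subjects per fixture, which is
sufficient because every assertion is on per-window or per-session
quantities. A single 90-s decomposition solves three ~720-variable NNLS
problems in ~0.3 s; a 12-subject end-to-end run takes ~30 s. Everything is
driven by explicit integer seeds through `numpy.random.default_rng`;
identical seeds give bit-identical cohorts, feature tables and reports.

## Known limitations

* The detector constants (refractory 0.25 s, 1/8 update weight, 2-s
  threshold initialisation) are standard values scaled to pulse waves, not
  fitted; heavily bradycardic or tachycardic edge cases outside 45–120 bpm
  subject means are not exercised by the generator.
* The consumer "EDA responses" emulation is an explicit stand-in — the
  real device's criterion is proprietary; conclusions about that metric
  transfer only to the extent the stand-in resembles it.
* Tonic/phasic attribution is inherently ill-posed during long SCR
  clusters; the quiet-region bridging and refinement keep window-level SCL
  errors below ~0.005 µS under the generator's linear-drift tonic, but
  strongly curved tonic under dense clusters would be smoothed.
* rmcorr assumes a common within-subject slope; heterogeneous slopes show
  up as reduced r_rm, not as a diagnostic.
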