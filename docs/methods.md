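# Methods

`gammamap` implements a complete analysis chain for task-locked broadband
gamma activity (BGA) in stereo-EEG, from raw multichannel voltage to
population-level cortical maps, together with a synthetic data generator
that provides ground truth for every stage. This note documents the models,
the parameters that matter, the numerical choices, and what the synthetic
validation does and does not establish.

## Signal model and envelope extraction

BGA is the analytic amplitude of the 70–150 Hz band, used as a proxy for
local population firing. The estimator is a frequency-domain bandpass
Hilbert transform: the signal's FFT is converted to the analytic spectrum
(negative frequencies zeroed, positive doubled), multiplied by a band
filter built from paired logistic flanks,

  w(f) = σ((f − f_lo)/h) · σ((f_hi − f)/h),  h = 1.5 Hz,

inverse transformed, and the magnitude taken. The FFT length equals the
signal length (no padding) and the flank half-width is fixed in Hz
regardless of length. The envelope is then smoothed with a third-order
Savitzky–Golay FIR of 151 ms frame length (frame converted to the nearest
odd sample count: 301 samples at 2 kHz). The first and last half-frame are
edge-contaminated; `spectral.edge_mask` flags them and statistics windows
avoid them.

Line noise is removed beforehand with zero-phase (forward–backward)
second-order Butterworth band-stops at the mains frequency and its
harmonics, with a 2 Hz default half-width. The 120 Hz stop band sits inside
the gamma band; because it removes the same narrow slice from baseline and
response periods alike, percent-change estimates are unaffected (the
envelope-calibration scenario runs the notch and recovers the injected
amplitude). Channels are re-referenced to the common average of the
retained channels (the channel itself included); the operation is
idempotent and excluded channels are left untouched.

## Epoching and baseline normalization

Epoch windows are half-open in samples: a window of L ms at sampling rate
fs contains exactly round(L·fs/1000) samples. BGA is expressed as percent
change from the mean envelope in a −500 to −100 ms pre-stimulus baseline,
pooled across trials per channel. Because responses in production tasks
are aligned to speech onset while the baseline is defined relative to
stimulus onset, the pipeline epochs every trial under both alignments and
carries the stimulus-aligned baseline into speech-aligned percent change.

## Group statistics

Group time courses use hierarchical (two-stage) averaging: electrodes are
averaged within each subject, and the across-subject mean and SE carry the
inference; this bounds the influence of any single high-amplitude
electrode. Per-timepoint activation is a one-tailed (activation above
baseline) one-sample t-test across subjects, corrected with the
Benjamini–Hochberg step-up procedure at q = 0.05 over timepoints.
Zero-variance timepoints are guarded (p = 0.5 at zero mean, flagged).

Single-electrode window statistics are z-scores of the window of interest
against the baseline period: per trial the window mean and baseline mean
are computed, and z = (mean of window means − mean of baseline means) /
SD of baseline means, with a two-tailed normal p — two-tailed because
deactivations are admissible in principle. Electrode sets are FDR-corrected
together. Fewer than five trials (or zero baseline variability) flags the
statistic as unstable.

Paired condition contrasts use the Wilcoxon signed-rank test on
per-subject means, dropping zero differences (Wilcoxon's original
convention), with the exact null distribution for n ≤ 25 and the normal
approximation above. Event-related potentials are computed from 0.1–50 Hz
zero-phase fourth-order Butterworth band-passed voltage, trial-averaged,
Savitzky–Golay smoothed, and passed through the same hierarchical group
machinery. The 0.1 Hz corner has a transient of roughly 10 s; ERP inputs
must be long recordings and edge windows are excluded.

## Surface-based mixed-effects multilevel maps

Electrodes are indexed to the nearest vertex (Euclidean; ties to the
lowest index) of a shared triangulated surface. Per analysis window, each
electrode contributes a within-subject estimate — the across-trial mean of
its window-mean percent change — with variance equal to its squared SEM.
Each subject's electrode estimates are spread over the surface with a
geodesic Gaussian kernel (default FWHM 3 mm, σ = FWHM/2.355, support
truncated at 4σ), weights normalized per vertex over that subject's
electrodes, so multiple electrodes of one subject combine fixed-effect
before the between-subject model. Geodesic distances are shortest paths on
the mesh edge graph (Dijkstra), which bounds the error by one edge length;
at 3 mm FWHM this requires a mesh with edges of ~2.5 mm or finer
(icosphere subdivision ≥ 4 in the generator), otherwise the kernel
degenerates to the identity.

Each vertex with at least two contributing subjects is fit with a
two-level random-effects model: the group effect is the inverse-variance-
weighted mean with between-subject variance τ² estimated by REML (bounded
scalar optimization of the restricted likelihood; DerSimonian–Laird on
non-convergence), t = effect/SE with n−1 degrees of freedom, two-tailed p.
With all within-subject variances zero this reduces exactly to the
one-sample t-test on subject estimates, which is the tested contract; the
parameter-recovery simulation (μ = 30 %, τ = 10 %, 12 subjects, 500
repetitions) recovers the mean within the sampling error and gives 95 % CI
coverage within Monte-Carlo tolerance.

Family-wise error is controlled by cluster-extent thresholding: white
noise with the dimension of the analysis (one value per vertex) is
geodesically smoothed at the analysis FWHM, re-standardized to unit
variance per vertex, thresholded two-tailed at the vertex alpha (0.01),
and the maximal edge-connected supra-threshold cluster inside the
coverage mask is recorded per iteration (5000 by default; 500 in the test
scenarios, which widens the Monte-Carlo error accordingly). The returned
minimum extent k is the smallest cluster size whose null exceedance
probability is at or below the FWER alpha. Static maps additionally
require patient coverage (≥ 3 patients with an electrode within 10 mm
geodesic radius — the radius is a modeling choice for the electrode
"recording zone") and an absolute group effect above 10 %. Movie frames
(150 ms windows, 10 ms spacing; floor((extent − 150)/10) + 1 frames) use
uncorrected p < 0.01 with a 15 % floor and the coverage mask, without the
cluster test. The effect floors apply to the group effect, not to
individual subjects.

Vertices with exactly two subjects deserve a caveat: the random-effects t
has one degree of freedom there and cannot cross p = 0.01 two-tailed
(|t| > 63.7), so they are evaluated but effectively untestable. The
spatial-recovery scenario therefore scores map recovery (Dice overlap
with the ground-truth region) over the analysis's own support: vertices
with at least three contributing subjects inside the coverage mask.

## Pair correlations

Volume conduction between adjacent structures is assessed by correlating
band-limited (70–150 Hz) voltage traces — the filtered voltage, not its
envelope — between electrode pairs. The band filter applies the same
logistic weights symmetrically in the frequency domain, so it is zero
phase and its analytic amplitude matches the envelope estimator. Pearson
correlations are computed per trial window per lag (±100 ms default,
1-sample steps) and averaged across trials through the Fisher z
transform; the peak lag maximizes |mean r|. An instantaneously mixed pair
peaks at 0 ms; a lagged-coupling pair peaks at the injected delay (the
validation recovers a 5 ms delay exactly). Group inference takes one
summary correlation per subject (the closest pair spanning the two
regions, Euclidean separation) and applies the Wilcoxon signed-rank test
of Fisher-z values against zero.

## The synthetic generator

The generator emulates the statistical structure the analyses assume, not
the biophysics. Per channel:

  x(t) = b(t) + l(t) + g(t)·[1 + a(t)] + s(t)

- b: Gaussian background with PSD ∝ 1/f^β (default β = 1, RMS 10 µV,
  spectrum flattened below 1 Hz);
- l: line noise at 60 Hz plus harmonics (default 8 µV, decaying 1/k);
- g: the gamma carrier — bandpass-filtered white noise (70–150 Hz, RMS
  30 µV), so the "broadband" label is honest and phase is random across
  trials (induced, not evoked: the ERP of a pure gamma effect is flat,
  which is tested);
- a: the task-locked fractional envelope gain — per trial a raised-cosine
  ramped (50 ms) plateau with region-specific amplitude (percent),
  latency and duration relative to stimulus or speech onset, with
  optional per-trial amplitude jitter;
- s: optional inter-ictal-like biphasic transients (derivative-of-Gaussian,
  ~80 ms) for trial-rejection tests; their shape is invented.

The carrier-to-background ratio matters for calibration: the background
contributes in-band power incoherently, biasing measured percent change
toward zero by 100·(√((1+a)² + ρ²)/√(1 + ρ²) − 1) − 100a for in-band
amplitude ratio ρ; at the defaults ρ ≈ 0.13 and the bias at a 50 % effect
is below 1 % absolute. Response times are truncated-normal (floor 200 ms)
with reading defaults 978 ± 221 ms (object naming: 1192 ± 245 ms);
stimulus onsets use a 3000 ms inter-stimulus interval. The listening task
has no speech-onset column, forcing stimulus alignment downstream.

Meshes are icospheres scaled to a 40 mm radius with a contiguous geodesic
Voronoi parcellation. Probes are straight chords of the bounding sphere
with contacts at a fixed pitch (probe geometry: 2.0 mm contacts with
1.5–2.43 mm gaps, hence 3.5–4.43 mm center-to-center); chords close to
the probe span keep contacts within a few mm of the surface. By default
entries are uniform over the sphere, which yields almost no cross-patient
vertex overlap; `target_regions` aims probes at named regions with ~6–8°
angular scatter, emulating clinical trajectories that target shared
anatomy — multi-patient MEMA coverage requires it.

What the generator does not emulate: dipole geometry and volume-conduction
physics, spatial correlation of background noise across channels,
non-stationary artifacts beyond spikes, oscillatory (narrowband) rhythms,
and behavioral error structure beyond uniform flags. Passing tests
therefore demonstrate that the pipeline recovers what it is designed to
measure under its own statistical assumptions — not that those
assumptions hold in any particular real recording.

## Problem sizes in the validation scenarios

Chosen to exercise every stage end to end at desk scale: envelope
calibration uses one channel, 200 trials at 2 kHz; spatial recovery uses
12 patients × 3 targeted probes × 8 contacts at 1 kHz, 30 trials, with
500 Monte-Carlo iterations for the extent threshold; the null error-rate
scenarios use 200 repetitions at the statistics level plus 10 full-pipeline
null runs; the dissociation reproduction runs 20 independent studies of
8 patients × 6 electrodes × 2 tasks. The `AnalysisConfig` default for
Monte-Carlo iterations remains 5000.

## Known limitations

- EDF input/output is not implemented (no writer available in the
  dependency set); signals travel as HDF5, which round-trips exactly.
- The REML fit treats the spread per-subject variances as known; no
  outlier down-weighting beyond the random-effects variance is applied.
- Cluster-extent simulation takes the smoothness as the applied FWHM;
  residual-based smoothness estimation is not implemented.
- Geodesic distances are graph shortest paths, biased upward by up to one
  edge length relative to exact polyhedral geodesics.
- The CLI exposes `simulate` and `analyze`; intermediate stages are
  library calls by design.
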