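# Methods

`thetahd` analyzes single-unit recordings from rodents foraging in an open
arena: animal tracking at 50 Hz (position in cm, head direction in
degrees), a local field potential (LFP) at 250 Hz, and per-cell spike
times, organized as multi-trial session bundles. Its metrics characterize
the classic spatial/temporal firing correlates of limbic neurons — head
direction (HD) tuning, place fields, theta phase locking and rhythmicity,
theta skipping, phase precession, linear and angular velocity modulation,
and anticipatory directional firing — and classify cells into functional
types against shuffle-based nulls. A synthetic-session generator produces
sessions with all of these correlates programmed, so every stage of the
pipeline is testable against ground truth without any recordings.

## Data model and kinematics

A trial holds a `TrackingSeries` (uniform 50 Hz; positions within a square
arena, default side 90 cm; head direction in [0, 360)), an `LfpSeries`
(uniform 250 Hz, arbitrary voltage units) and a list of `SpikeTrain`s.
Bundles are directories of comma-separated text tables plus a YAML
metadata file — diff-able and language-agnostic. Missing tracking samples
are blank fields; gaps of at most 5 samples (100 ms) are linearly
interpolated (circularly for head direction), longer gaps stay missing and
are excluded downstream. Running speed is the distance between consecutive
positions divided by the 20-ms step, assigned to the earlier sample;
angular head velocity (AHV) is the shortest signed circular difference of
consecutive head directions divided by the step, with clockwise positive.
Spikes are aligned to tracking by nearest 20-ms sample.

## Synthetic sessions

The generator is an inhomogeneous-Poisson model whose conditional
intensity multiplies independent factors (each normalized so that turning
a factor off leaves the rate unchanged):

    lambda(t) = r0 * exp(k_hd cos(hd(t + ati) - mu_hd)) / I0(k_hd)
                   * (1 + gain * exp(-|p(t) - c|^2 / 2 sigma_p^2))
                   * exp(k_phi cos(phi(t) - mu_phi(t))) / I0(k_phi)
                   * (1 + s_gain * speed(t)) * (1 + a_gain * |ahv(t)|)

with phi(t) the instantaneous theta phase of the simulated LFP (recovered
by the package's own Butterworth/Hilbert estimator, so generation and
analysis share one phase convention). Spikes are drawn on a 1-ms grid
(counts Poisson(lambda dt), jittered within bins), then thinned by a 2-ms
absolute refractory period with an exponential (3-ms) recovery — without
refractoriness the exponential inter-spike-interval mode sits at zero lag
and untuned cells read as bursting. The intensity is rescaled by the
expected thinning so `r0` keeps its delivered-rate meaning. Bursting
appends 2-4 extra spikes at 4-ms intervals after a configurable fraction
of spikes; theta skipping attenuates alternate theta cycles by
`skip_depth`; phase precession advances the preferred phase backwards at
`intrinsic_freq_offset` cycles per second (an intrinsic oscillator faster
than the LFP); anticipation drives the cell from the head direction `ati`
seconds in the future; an optional preferred-direction random walk
(deg per sqrt-minute) models drifting HD cells.

Note one simplification: precession is implemented as a global phase
drift, so a precessing synthetic cell's whole-trial phase histogram is
near-uniform (low IC). Real place cells precess within field traversals
and can remain phase-locked on average; tests that need both locking and
precession use small offsets.

The trajectory is a mean-reverting speed process (mean 18 cm/s,
relaxation 2 /s — foraging bouts of roughly half a second) and a heading
that integrates a mean-reverting angular velocity whose long-run diffusion
matches a random walk of scale `turn_sd` deg/sqrt(s) (default 60, giving a
rat-like AHV spread of ~70 deg/s). Walls reflect the heading, but the turn
is executed continuously at <= 600 deg/s while the animal slides along the
wall: an instantaneous flip would inject physically impossible AHV samples
that poison every AHV-conditioned analysis. With the defaults a 480-s
trial covers >= 80% of the 2-cm occupancy bins. The LFP is
`(a0 + beta_a * speed) * cos(2 pi \int f dt) + noise` with
`f = f0 + beta_f * speed`; the defaults (f0 = 8.5 Hz, beta_f = 0.02 Hz per
cm/s) put the session-average theta near 8.9 Hz, inside the 5-9 Hz band
the autocorrelogram models can represent. The behavioral statistics
(speeds, turn persistence) are plausible for foraging rats but are not fit
to any dataset; passing recovery tests shows the estimators are correct
under this model, not that real data meet its assumptions (real tracking
has occlusions, non-stationary behavior and electrode drift that the
generator does not emulate).

Randomness uses numpy's PCG64 `default_rng`; every public entry point
takes a seed and reproduces bit-identically.

## Maps and tuning

Locational ratemaps bin position and spikes in 2 x 2 cm bins and smooth
the spike and dwell maps separately with a truncated Gaussian (sigma
5 cm, zero weight beyond 10 cm) before dividing; rates are defined on
visited bins only. Place fields are 8-connected components of bins at or
above 20% of the map peak, kept when they span at least 9 bins and the
peak is at least 1 Hz. Directional tuning uses 60 bins of 6 degrees,
rate = spikes/dwell per bin, then a circular 5-bin boxcar; the R-vector,
preferred direction, width (two circular standard deviations) and von
Mises concentration are computed from the smoothed, rate-weighted curve
(the boxcar caps R at ~0.989 even for perfectly concentrated firing).
Information per spike and sparsity follow the standard occupancy-weighted
definitions; because the results prose sometimes describes sparsity as
the fraction of the arena over which a cell fires, that reading is exposed
separately as `firing_area_fraction`.

The position-by-direction (pxd) factorization removes the
occupancy-coupling artifact that lets purely locational cells look
directional (and vice versa): unsmoothed joint counts on 64 position x 60
direction bins are modelled as Poisson with rate `p_i d_j`, maximized by
alternating multiplicative updates (`p_i <- sum_j n_ij / sum_j d_j t_ij`,
then the analogous `d_j` update), with the scale degeneracy resolved by
holding `d` at mean 1. Iteration stops when the relative log-likelihood
change falls below 1e-8 or after 500 sweeps (a non-convergence flag is
returned rather than raising). The log-likelihood is non-decreasing at
every sweep, and on toy grids the solution matches a direct numerical
maximization to well under 0.1%. Corrected information/sparsity are
computed from the fitted factors with the marginal occupancies. The
residual corrected information is a Poisson noise floor of roughly
`n_bins / (2 ln2 N)` bits for `N` spikes, so artifact-isolation claims
need spike-rich sessions.

## Theta metrics

Trial spectra are Welch estimates (8-s segments, half overlap), z-scored
across frequencies within the trial and smoothed with a 0.5-Hz-sigma
Gaussian; theta power is the peak z in 6-12 Hz and theta frequency the
(parabolically interpolated) peak location. The theta/delta ratio uses
2-4 Hz as delta. Instantaneous phase comes from a zero-phase (forward-
backward) 4th-order Butterworth band-pass at 6-12 Hz and the Hilbert
transform, with cosine peaks at 0/360 degrees and troughs at 180; spike
phases interpolate the unwrapped phase. The phase-coupling index IC is the
resultant length of spike phases binned at 6 degrees (a raw-phase variant
is available), with Rayleigh statistics and a von Mises kernel density
whose bandwidth follows the Taylor plug-in rule.

Autocorrelograms are built over +/- 500 ms in 10-ms bins, self-pairs
excluded, max-normalized, and smoothed with a 3-bin (30 ms) boxcar — a
window comparable to the theta period would flatten the modulation and pin
the rhythmicity index at zero for every cell. The index of rhythmicity IR
contrasts the theta peak (value in 120-130 ms) with the trough (60-70 ms):
(peak - trough)/(peak + trough), positive for rhythmic cells. The readout
windows assume ~8-Hz theta and are deliberately not adapted to the
measured frequency.

Theta skipping is quantified by fitting, over +/- 400 ms,

    y(x) = [a1 (cos wx + 1) + a2 (cos 0.5 wx + 1) + b] exp(-|x|/tau1)
           + c exp(-x^2/tau2^2)

with a1, a2, b in [0, m], c in [-m, m] (m the autocorrelogram maximum),
w in [10 pi, 18 pi] rad/s, tau1 in [0, 5] s, tau2 in [0, 0.05] s, using
bounded least squares with a 4-point multi-start over w. The skipping
index TS = (h2 - h1)/max(h1, h2) takes h1 and h2 as the fitted curve's
maxima near one and two fitted periods (naively taking the first two local
maxima can pick up the rim of a fitted negative center Gaussian); a cell
is flagged theta-skipping when r^2 > 0.7, IR >= 0.001 and TS > 0.1. The
intrinsic rhythm is a single decaying sinusoid over +/- 500 ms with
w in [6, 12] Hz and a 5-start w grid; its slow-envelope decay constant is
bounded by 5 s like the matching constant of the two-cosine model (a 50-ms
bound would zero the model over 90% of the window and break every fit). A
cell precesses when its intrinsic frequency strictly exceeds the trial's
LFP theta frequency. Refit to their own noiseless output, both models
recover all parameters to well under 1%.

## Self-motion and anticipation

The instantaneous rate is the 20-ms binned spike count smoothed with a
250-ms-wide Gaussian (read as +/- 2 sigma, so sigma = 62.5 ms) and divided
by 0.02 s; smoothing conserves total spike count. The speed score is the
Pearson correlation between 2-cm/s speed-bin centers (2-50 cm/s) and the
mean rate per bin; AHV scores are the analogous correlations over the
signed half-ranges +/-(2-50) deg/s and over |AHV| bins, with (-2, 2) deg/s
discarded as non-turning. Cells are called tuned above |0.3|; a cell is
"symmetric" when the two half-range slopes mirror in sign with a ratio
within [0.5, 2] (our rule). Note a statistical caveat: a Pearson r over
~24 bin means has a null standard deviation of at least 1/sqrt(23) ~ 0.21,
so at desk-scale trial lengths the fixed 0.3 cutoff has a substantial null
exceedance; the calibrated gate for classification is the cell's own
shuffle-percentile threshold, and the fixed cutoff is reported alongside.

The anticipatory time interval (ATI) partitions spikes into clockwise
(centered AHV at the spike sample > 60 deg/s) and counter-clockwise
(< -60 deg/s) sets — the centered difference matters, since the
forward-difference AHV series is assigned to the earlier sample and would
judge the turn 10 ms in the future. For each shift delta in -160..160 ms
(20-ms steps) both spike sets are re-evaluated at `t + delta`, their
peak-normalized tuning curves circularly cross-correlated in 6-degree
steps with parabolic sub-bin interpolation of the best rotation (the raw
lag grid alone quantizes the ATI by ~20 ms), and the best rotation
(counter-clockwise curve relative to clockwise, positive for anticipatory
cells at zero shift) regressed on the shift. The ATI is the fitted line's
zero crossing, refined by a second local fit within +/- 60 ms of the first
crossing: mean reversion of the head's angular velocity makes the
rotation-shift relation saturate asymmetrically about the crossing, which
biases a single global line outward. Results are suppressed when the
zero-shift cross-correlation peak is below 0.7. On 16-minute synthetic
trials with a high-rate, sharply tuned cell the estimator recovers a
programmed 40-ms lead with per-cell noise of ~10 ms and negligible bias.

## Drift

A sweep is a pass of the head through the preferred direction: a
contiguous epoch with smoothed instantaneous rate above 50% of the
intra-trial peak (epochs closer than 0.5 s merge), extended over adjacent
spikes while the head stays within +/- 50 degrees of the heading at the
threshold crossing; sweeps with fewer than 5 spikes are dropped. Each
sweep's spike head directions get a von Mises kernel density (Taylor
plug-in bandwidth, 1-degree grid) whose peak location and width at half
height are summarized per cell: mean width (inherent tuning breadth),
SEM of peak locations (drift), both as angular deviations about the
circular mean.

## Classification and nulls

Null distributions circularly time-shift the spike train by U(20 s,
T - 20 s) relative to the unshifted behavior/LFP and recompute the metric;
the 95th/99th percentiles use the conservative next-higher order statistic
(linear interpolation would let a null cell beat its own 99th-percentile
threshold ~1.5x more often than nominal at a few hundred shuffles). The
production default is 10,000 shuffles; tests and the acceptance runs use
200 and document the thresholds as approximate. Calibration was verified
directly: for untuned Poisson cells the empirical p-values of the observed
metric within its own shuffle distribution are uniform.

A cell is theta-modulated when IC is at or above its 99th-percentile null
and IR >= 0.001; HD-modulated when the tuning R-vector is at or above its
null and the smoothed directional peak exceeds 1 Hz; a place cell when
0.1 < mean rate < 10 Hz, locational peak > 1 Hz, locational information
> 0.8 bits/spike and sparsity < 0.2. The composite label gives place
precedence, then Theta-by-HD (both theta and HD), non-rhythmic HD, theta,
else unclassified; all flags are preserved so conjunction tallies can be
rebuilt either way. On the standard 40-cell synthetic cohort (10 cells
per archetype, 480-s trial, 200 shuffles) the pipeline recovers >= 90%
of the programmed labels.

ISI metrics bin intervals at 2 ms over 0-250 ms; a cell bursts when the
modal ISI is under 6 ms, and the burst index is the fraction of spikes
sharing an ISI < 6 ms with a neighbor. Waveform width is the peak-to-
trough time on the largest-amplitude channel at 48 kHz; waveforms whose
global minimum precedes the maximum are discarded. Population typology
fits a two-component Gaussian mixture to the widths; the narrow/broad
cutoffs are the points of 10:1 posterior odds between the weighted
components (the literal CDF-ratio reading degenerates — for a symmetric
mixture both cutoffs land on the midpoint — whereas posterior odds leave
the intermediate class in the dip of the bimodal distribution, as
described). Bimodality is tested with Hartigan's dip statistic — computed
exactly via the band-feasibility characterization (smallest half-width d
admitting a convex-then-concave CDF through the ECDF band, evaluated by
convex-hull sweeps and verified in tests against an independent
linear-programming oracle) — calibrated by bootstrap from the
maximum-likelihood Gaussian fit (1,000 draws by default).

## Cohort statistics

2x2 contingency tables of cell counts use the Pearson chi-square without
continuity correction — the reading verified by reproducing all of the
published statistics (9.28, 9.06, 9.33, 3.46, 30.88, 1.42, 8.80) exactly
from the printed counts. The Rayleigh test reports R, z = nR^2 and the
standard large-n p approximation. `cohort_summary` tabulates counts,
mean +/- SEM of the standard metrics and flag proportions per class and
group tag; generic nonparametric comparisons are delegated to scipy.

## Problem sizes

Validation experiments use 8-min (480 s) trials — one of the recording
protocol's two trial lengths — with 16-min (960 s) trials where an
estimator's noise floor requires it (ATI, IC at >= 5,000 spikes, drift,
pxd artifact isolation), 200-shuffle nulls, a 40-cell cohort for label
recovery, and 100 seeded runs for null calibration. These are the same
conditions exercised by `tests/test_acceptance.py` and recomputed from
scratch by `scripts/acceptance.py`.

## Known limitations

- The generator's behavior model is stationary; it has no rests, grooming
  bouts, tracking dropouts or light/dark differences (dark trials differ
  only by their condition tag).
- Precession is a whole-trial phase drift (see above), not
  traversal-locked precession.
- The IR readout windows and the skipping model's frequency band assume
  theta near 8 Hz; sessions with theta at the band edges will bias both.
- The 0.3 speed/AHV score cutoff is reported for comparability but is not
  size-controlled at desk-scale trial lengths; use the shuffle thresholds
  for inference.
- Anatomical subfield assignment is read from metadata when present; no
  histology-based localization is attempted.
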