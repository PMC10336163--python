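"""LFP theta analysis and spike-theta coupling.

Covers: trial power spectra (z-scored, Gaussian-smoothed), instantaneous
theta phase via a zero-phase 4th-order Butterworth band-pass (6-12 Hz) and
the Hilbert transform, per-spike phase assignment, phase-coupling (IC),
autocorrelogram rhythmicity (IR), theta-skipping and intrinsic-frequency
model fits, and speed-theta relations.

Phase convention: theta peaks at 0/360 degrees, troughs at 180 degrees.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from ._circular import mean_vector, rayleigh_test, taylor_bandwidth, vonmises_kde
from .session import LfpSeries, SpikeTrain, TrackingSeries

THETA_BAND = (6.0, 12.0)
DELTA_BAND = (2.0, 4.0)  # for the theta/delta ratio; the band is our choice


@dataclasses.dataclass
class Autocorrelogram:
    lags_ms: np.ndarray       # bin centers, symmetric about 0
    values: np.ndarray        # normalized to max 1 after smoothing
    bin_ms: float
    smooth_bins: int


@dataclasses.dataclass
class ThetaSkippingFit:
    a1: float
    a2: float
    b: float
    c: float
    omega: float              # angular frequency, rad/s, in [10*pi, 18*pi]
    tau1: float
    tau2: float
    r2: float
    ts_index: Optional[float]


@dataclasses.dataclass
class IntrinsicRhythmFit:
    a: float
    b: float
    c: float
    omega: float              # Hz, in [6, 12]
    t1: float
    t2: float
    r2: float


@dataclasses.dataclass
class ThetaProfile:
    ic: float
    preferred_phase: float
    rayleigh_z: float
    rayleigh_p: float
    ir: float
    ts_index: Optional[float]
    ts_fit_r2: Optional[float]
    theta_skipping: bool
    intrinsic_freq: Optional[float]
    lfp_theta_freq: float
    precessing: Optional[bool]


# ------------------------------------------------------------------ spectrum

def lfp_spectrum(lfp: LfpSeries, segment_s: float = 8.0):
    """Welch power spectrum of one trial, z-scored across frequencies.

    Power is z-scored within the trial and smoothed with a Gaussian kernel
    (sigma = 0.5 Hz). Returns (freqs, z_power, theta_power_z, theta_freq,
    theta_delta_ratio) where theta_power_z is the max z within 6-12 Hz and
    theta_freq the frequency at that peak.
    """
    v = np.asarray(lfp.v, dtype=float)
    fs = lfp.fs
    if v.size / fs < 60.0:
        raise ValueError("trial too short for spectral analysis (< 60 s)")
    nper = int(segment_s * fs)
    freqs, pxx = signal.welch(v, fs=fs, nperseg=nper, noverlap=nper // 2)
    keep = freqs <= 25.0
    freqs, pxx = freqs[keep], pxx[keep]
    z = (pxx - pxx.mean()) / pxx.std()
    df = freqs[1] - freqs[0]
    z = gaussian_filter1d(z, sigma=0.5 / df)
    band = (freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1])
    i_peak = np.flatnonzero(band)[np.argmax(z[band])]
    # quadratic interpolation around the peak for sub-bin frequency
    if 0 < i_peak < freqs.size - 1:
        y0, y1, y2 = z[i_peak - 1:i_peak + 2]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        theta_freq = float(freqs[i_peak] + np.clip(delta, -0.5, 0.5) * df)
    else:
        theta_freq = float(freqs[i_peak])
    theta_power = float(z[i_peak])
    delta_band = (freqs >= DELTA_BAND[0]) & (freqs <= DELTA_BAND[1])
    ratio = float(pxx[band].mean() / pxx[delta_band].mean())
    return freqs, z, theta_power, theta_freq, ratio


def instantaneous_theta(lfp: LfpSeries):
    """Instantaneous theta phase (deg), frequency (Hz) and amplitude.

    Zero-phase (forward-backward) 4th-order Butterworth 6-12 Hz, then the
    analytic signal. The returned wrapped phase is in [0, 360) with cosine
    peaks at 0/360 and troughs at 180; the unwrapped phase (deg) is also
    returned for interpolation at spike times.
    """
    v = np.asarray(lfp.v, dtype=float)
    fs = lfp.fs
    sos = signal.butter(4, THETA_BAND, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, v)
    analytic = signal.hilbert(filt)
    unwrapped = np.rad2deg(np.unwrap(np.angle(analytic)))
    phase = np.mod(unwrapped, 360.0)
    freq = np.gradient(unwrapped, 1.0 / fs) / 360.0
    amplitude = np.abs(analytic)
    return phase, freq, amplitude, unwrapped


def spike_phases(spikes: SpikeTrain, lfp_t, unwrapped_phase_deg):
    """Theta phase of each spike by linear interpolation of unwrapped phase.

    Spikes outside the LFP time range are excluded; the count of exclusions
    is returned alongside the wrapped phases.
    """
    t = np.asarray(spikes.times, dtype=float)
    lfp_t = np.asarray(lfp_t, dtype=float)
    inside = (t >= lfp_t[0]) & (t <= lfp_t[-1])
    ph = np.interp(t[inside], lfp_t, unwrapped_phase_deg)
    return np.mod(ph, 360.0), int(np.sum(~inside))


def phase_coupling(phases_deg, bin_deg: float = 6.0, min_spikes: int = 50,
                   binned: bool = True, compute_kde: bool = True):
    """Spike-theta coupling: IC, preferred phase, Rayleigh statistics, KDE.

    The IC is the mean vector length of the spike phases binned at 6 degrees
    (the raw-phase variant is available with ``binned=False``). Returns a
    dict with keys ic, preferred_phase, rayleigh_z, rayleigh_p, kde_grid,
    kde_density, low_n.
    """
    ph = np.asarray(phases_deg, dtype=float)
    low_n = ph.size < min_spikes
    if ph.size < 2:
        raise ValueError("need at least 2 spike phases")
    if binned:
        edges = np.arange(0.0, 360.0 + bin_deg, bin_deg)
        counts, _ = np.histogram(np.mod(ph, 360.0), bins=edges)
        centers = edges[:-1] + bin_deg / 2
        ic, pref = mean_vector(centers, weights=counts)
    else:
        ic, pref = mean_vector(ph)
    _, z, p = rayleigh_test(ph)
    grid = dens = None
    if compute_kde:
        grid, dens = vonmises_kde(ph, bandwidth=taylor_bandwidth(ph))
    return {
        "ic": float(ic), "preferred_phase": float(pref),
        "rayleigh_z": float(z), "rayleigh_p": float(p),
        "kde_grid": grid, "kde_density": dens, "low_n": bool(low_n),
    }


# ---------------------------------------------------------- autocorrelogram

def spike_autocorrelogram(spikes: SpikeTrain, window_ms: float = 500.0,
                          bin_ms: float = 10.0, smooth_bins: int = 3) -> Autocorrelogram:
    """Spike-train autocorrelogram, max-normalized and boxcar-smoothed.

    Pair lags within +/- window are histogrammed in `bin_ms` bins; self
    pairs (zero lag of a spike with itself) are excluded. The default
    boxcar spans 30 ms: a smoothing window comparable to the ~120 ms theta
    period would average the modulation away and pin the rhythmicity index
    near zero for every cell, so only mild smoothing is applied before the
    trough (60-70 ms) and peak (120-130 ms) windows are read out.
    """
    t = np.asarray(spikes.times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 spikes")
    w = window_ms / 1000.0
    edges = np.arange(-window_ms, window_ms + bin_ms, bin_ms)
    counts = np.zeros(edges.size - 1)
    # positive lags only, mirrored (autocorrelogram is symmetric)
    j = 0
    lags = []
    for i in range(t.size):
        k = np.searchsorted(t, t[i] + w, side="right")
        d = t[i + 1:k] - t[i]
        if d.size:
            lags.append(d)
    if lags:
        d = np.concatenate(lags) * 1000.0
        pos, _ = np.histogram(d, bins=edges)
        neg, _ = np.histogram(-d, bins=edges)
        counts = (pos + neg).astype(float)
    if smooth_bins and smooth_bins > 1:
        counts = uniform_filter1d(counts, size=smooth_bins, mode="nearest")
    m = counts.max()
    if m > 0:
        counts = counts / m
    centers = edges[:-1] + bin_ms / 2
    return Autocorrelogram(lags_ms=centers, values=counts,
                           bin_ms=bin_ms, smooth_bins=smooth_bins)


def index_of_rhythmicity(ac: Autocorrelogram) -> float:
    """IR = (peak - trough) / (peak + trough) of the theta modulation.

    Trough is the autocorrelogram value with lag center in [60, 70] ms
    (half a theta cycle at ~8 Hz), peak in [120, 130] ms (one full cycle),
    mirror-averaged. Sign is oriented so that theta-rhythmic cells score
    positive and values lie in [-1, 1]. Returns 0 when the sum is 0.
    """
    lag = np.abs(ac.lags_ms)
    trough = ac.values[(lag >= 60.0) & (lag <= 70.0)].mean()
    peak = ac.values[(lag >= 120.0) & (lag <= 130.0)].mean()
    s = peak + trough
    if s <= 0:
        return 0.0
    return float((peak - trough) / s)


# ------------------------------------------------------------------ fitting

def _ts_model(x, a1, a2, b, c, omega, tau1, tau2):
    # x in seconds; two-cosine (theta + half-frequency) with exponential decay
    core = (a1 * (np.cos(omega * x) + 1) + a2 * (np.cos(0.5 * omega * x) + 1) + b)
    return core * np.exp(-np.abs(x) / tau1) + c * np.exp(-x**2 / tau2**2)


def theta_skipping_fit(ac: Autocorrelogram, ir: float,
                       window_ms: float = 400.0):
    """Fit the two-cosine decaying model and derive the theta-skipping index.

    TS = (h2 - h1)/max(h1, h2) where h1, h2 are the heights of the first
    and second side peaks of the fitted curve. A cell is flagged as
    theta-skipping when r2 > 0.7, IR >= 0.001 and TS > 0.1.
    """
    keep = np.abs(ac.lags_ms) <= window_ms
    x = ac.lags_ms[keep] / 1000.0
    y = ac.values[keep]
    m = float(y.max())
    lo = [0, 0, 0, -m, 10 * np.pi, 1e-6, 1e-6]
    hi = [m, m, m, m, 18 * np.pi, 5.0, 0.05]
    best = None
    for om0 in np.linspace(11 * np.pi, 17 * np.pi, 4):
        p0 = [m / 4, m / 4, m / 4, 0.0, om0, 0.2, 0.02]
        try:
            res = least_squares(lambda p: _ts_model(x, *p) - y, p0,
                                bounds=(lo, hi), max_nfev=4000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return None, False
    p = best.x
    yhat = _ts_model(x, *p)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    # first and second theta-cycle peaks of the fitted curve: the maxima in
    # windows around one and two fitted periods (a naive first-two-local-
    # maxima rule can pick up the rim of a fitted negative center Gaussian)
    xf = np.linspace(0, window_ms / 1000.0, 2000)
    yf = _ts_model(xf, *p)
    period = 2 * np.pi / p[4]
    ts = None
    heights = []
    for k in (1, 2):
        sel = (xf >= k * period - period / 3) & (xf <= k * period + period / 3)
        if sel.any():
            heights.append(float(yf[sel].max()))
    if len(heights) == 2:
        h1, h2 = heights
        ts = (h2 - h1) / max(h1, h2) if max(h1, h2) > 0 else 0.0
    fit = ThetaSkippingFit(a1=p[0], a2=p[1], b=p[2], c=p[3], omega=p[4],
                           tau1=p[5], tau2=p[6], r2=r2, ts_index=ts)
    flag = bool(ts is not None and r2 > 0.7 and ir >= 0.001 and ts > 0.1)
    return fit, flag


def _intrinsic_model(x, a, b, c, omega, t1, t2):
    # single decaying sinusoid; sin(2 pi omega x + pi/2) = cos(2 pi omega x)
    return ((a * (np.sin(2 * np.pi * omega * x + np.pi / 2) + 1) + b)
            * np.exp(-np.abs(x) / t1) + c * np.exp(-x**2 / t2**2))


def intrinsic_frequency_fit(ac: Autocorrelogram) -> Optional[IntrinsicRhythmFit]:
    """Fit a decaying sinusoid to the autocorrelogram; omega (Hz) in [6, 12].

    Multi-start over 5 omega initializations; the best-r2 fit is kept.
    The slow-envelope decay constant t1 is bounded by [0, 5] s like the
    matching constant of the two-cosine theta-skipping model: a bound of
    50 ms would force the model to zero beyond a tenth of the +/- 500 ms
    autocorrelogram and make the fit fail on any real cell.
    """
    x = ac.lags_ms / 1000.0
    y = ac.values
    m = float(y.max())
    lo = [0, 0, 0, 6.0, 1e-6, 1e-6]
    hi = [np.inf, np.inf, 0.8, 12.0, 5.0, 0.05]
    best = None
    for om0 in np.linspace(6.5, 11.5, 5):
        p0 = [m / 2, m / 4, 0.2, om0, 0.5, 0.02]
        try:
            res = least_squares(lambda p: _intrinsic_model(x, *p) - y, p0,
                                bounds=(lo, hi), max_nfev=4000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return None
    p = best.x
    yhat = _intrinsic_model(x, *p)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return IntrinsicRhythmFit(a=p[0], b=p[1], c=p[2], omega=float(p[3]),
                              t1=p[4], t2=p[5], r2=r2)


def precession_flag(intrinsic_freq: float, lfp_theta_freq: float) -> bool:
    """A cell phase-precesses when its intrinsic rhythm outpaces LFP theta."""
    return bool(intrinsic_freq > lfp_theta_freq)


# ------------------------------------------------------------- speed-theta

def speed_theta_relation(lfp: LfpSeries, tracking: TrackingSeries,
                         bin_cm_s: float = 10.0, max_speed: float = 50.0):
    """Speed dependence of instantaneous theta power and frequency.

    Speed is binned in 10 cm/s bins over 0-50 cm/s; bin means of
    instantaneous power (squared amplitude envelope) and frequency are
    fitted with least-squares lines over bin centers. Returns
    (power_slope, power_r, freq_slope, freq_r).
    """
    if tracking.speed is None:
        raise ValueError("tracking kinematics not computed")
    _, freq, amp, _ = instantaneous_theta(lfp)
    # nearest LFP sample for each tracking sample
    idx = np.rint((tracking.t - lfp.t[0]) * lfp.fs).astype(int)
    idx = np.clip(idx, 0, len(lfp.t) - 1)
    power = amp[idx] ** 2
    f = freq[idx]
    speed = tracking.speed
    edges = np.arange(0.0, max_speed + bin_cm_s, bin_cm_s)
    centers, p_means, f_means = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (speed >= lo) & (speed < hi)
        if np.sum(sel) >= 10:
            centers.append((lo + hi) / 2)
            p_means.append(power[sel].mean())
            f_means.append(f[sel].mean())
    if len(centers) < 3:
        raise ValueError("fewer than 3 occupied speed bins")
    centers = np.asarray(centers)
    p_slope = np.polyfit(centers, p_means, 1)[0]
    f_slope = np.polyfit(centers, f_means, 1)[0]
    p_r = pearsonr(centers, p_means)[0]
    f_r = pearsonr(centers, f_means)[0]
    return float(p_slope), float(p_r), float(f_slope), float(f_r)
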