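"""Self-motion correlates: instantaneous rate, speed and AHV scores, and the
anticipatory time interval (ATI).

The instantaneous rate is the 20-ms binned spike count smoothed with a
250-ms-wide Gaussian kernel (total width read as +/- 2 sigma, so sigma =
62.5 ms) divided by 0.02 s. Speed and AHV scores are Pearson correlations
between binned speed (2 cm/s over 2-50 cm/s) or AHV (2 deg/s over the
signed and absolute 2-50 deg/s ranges) and the mean rate per bin.

The ATI is found by partitioning spikes into clockwise (AHV > 60 deg/s)
and counter-clockwise (AHV < -60 deg/s) sets, re-evaluating head direction
at shifted spike times (both sets shifted by the same delta, delta in
-160..160 ms by 20 ms: an anticipatory cell's firing matches the head
direction delta seconds later, whatever the turn direction), cross-
correlating the peak-normalized CW and CCW tuning curves in 6-degree
steps, and regressing the best rotation on the shift; the ATI is the
shift at which the fitted rotation crosses 0. Because CW and CCW turns
displace an anticipatory cell's tuning curve in opposite directions, the
CW-CCW rotation shrinks to zero as the shift undoes the anticipation.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import linregress, pearsonr

from ._circular import interp_angle_deg
from .maps import DIR_BIN_DEG, N_DIR_BINS, circular_crosscorr
from .session import TRACKING_DT, SpikeTrain, TrackingSeries

RATE_SMOOTH_SIGMA_S = 0.0625   # 250-ms-wide kernel, width = +/- 2 sigma
AHV_TURN_THRESHOLD = 60.0      # deg/s, defines CW/CCW spikes for the ATI
SCORE_THRESHOLD = 0.3          # |r| above which a cell counts as tuned


@dataclasses.dataclass
class RateSeries:
    t: np.ndarray      # 20-ms bin centers
    rate: np.ndarray   # Hz, Gaussian-smoothed


@dataclasses.dataclass
class AtiResult:
    ati_ms: Optional[float]
    difference_angle_deg: float
    max_crosscorr: float
    slope: float               # deg per ms of shift
    intercept: float
    shifts_ms: np.ndarray
    rotations_deg: np.ndarray
    reliable: bool             # max cross-correlation >= 0.7


def instantaneous_rate(spikes: SpikeTrain, tracking: TrackingSeries) -> RateSeries:
    """Smoothed instantaneous firing rate on the 50 Hz tracking time base."""
    t0 = float(tracking.t[0])
    n = len(tracking.t)
    idx = np.floor((np.asarray(spikes.times) - t0) / TRACKING_DT).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    counts = np.bincount(idx, minlength=n).astype(float)
    smoothed = gaussian_filter1d(counts, sigma=RATE_SMOOTH_SIGMA_S / TRACKING_DT,
                                 mode="reflect")
    return RateSeries(t=tracking.t + TRACKING_DT / 2, rate=smoothed / TRACKING_DT)


def _binned_means(values, rate, lo, hi, bin_width, min_samples=5):
    nb = int(round((hi - lo) / bin_width))
    idx = np.floor((values - lo) / bin_width).astype(int)
    ok = (idx >= 0) & (idx < nb)
    counts = np.bincount(idx[ok], minlength=nb)
    sums = np.bincount(idx[ok], weights=rate[ok], minlength=nb)
    keep = counts >= min_samples
    centers = lo + (np.arange(nb) + 0.5) * bin_width
    return centers[keep], sums[keep] / counts[keep]


def speed_score(rate: RateSeries, tracking: TrackingSeries,
                bin_cm_s: float = 2.0, lo: float = 2.0, hi: float = 50.0):
    """Pearson r between 2-cm/s speed-bin centers and mean rate per bin.

    Returns a dict with s_score, tuned (|s| > 0.3), slope, intercept and
    degenerate flag (constant rate across bins).
    """
    ok = ~np.isnan(tracking.speed)
    centers, means = _binned_means(tracking.speed[ok], rate.rate[ok], lo, hi, bin_cm_s)
    if centers.size < 3:
        raise ValueError("fewer than 3 occupied speed bins")
    if np.std(means) == 0:
        return {"s_score": 0.0, "tuned": False, "slope": 0.0,
                "intercept": float(means[0]), "degenerate": True}
    fit = linregress(centers, means)
    s = float(fit.rvalue)
    return {"s_score": s, "tuned": bool(abs(s) > SCORE_THRESHOLD),
            "slope": float(fit.slope), "intercept": float(fit.intercept),
            "degenerate": False}


def ahv_score(rate: RateSeries, tracking: TrackingSeries,
              bin_deg_s: float = 2.0, lo: float = 2.0, hi: float = 50.0):
    """Clockwise, counter-clockwise and absolute AHV scores.

    Regression lines are fitted to the signed half-ranges +/-(2-50) deg/s
    (values in (-2, 2) discarded as non-turning) and to |AHV| bins. The
    tuned flag uses |absolute score| > 0.3; the symmetric flag requires
    both half-slopes to mirror in sign with an absolute-slope ratio within
    [0.5, 2].
    """
    ok = ~np.isnan(tracking.ahv)
    ahv = tracking.ahv[ok]
    r = rate.rate[ok]
    out = {"cw_score": np.nan, "ccw_score": np.nan, "abs_score": np.nan,
           "cw_slope": np.nan, "ccw_slope": np.nan,
           "tuned": False, "symmetric": False,
           "cw_missing": False, "ccw_missing": False}
    c_cw, m_cw = _binned_means(ahv, r, lo, hi, bin_deg_s)
    c_ccw, m_ccw = _binned_means(ahv, r, -hi, -lo, bin_deg_s)
    if c_cw.size >= 3 and np.std(m_cw) > 0:
        fit = linregress(c_cw, m_cw)
        out["cw_score"], out["cw_slope"] = float(fit.rvalue), float(fit.slope)
    else:
        out["cw_missing"] = True
    if c_ccw.size >= 3 and np.std(m_ccw) > 0:
        fit = linregress(c_ccw, m_ccw)
        out["ccw_score"], out["ccw_slope"] = float(fit.rvalue), float(fit.slope)
    else:
        out["ccw_missing"] = True
    c_abs, m_abs = _binned_means(np.abs(ahv), r, lo, hi, bin_deg_s)
    if c_abs.size >= 3 and np.std(m_abs) > 0:
        out["abs_score"] = float(pearsonr(c_abs, m_abs)[0])
        out["tuned"] = bool(abs(out["abs_score"]) > SCORE_THRESHOLD)
    if not (out["cw_missing"] or out["ccw_missing"]):
        s1, s2 = out["cw_slope"], out["ccw_slope"]
        if s1 * s2 < 0 and min(abs(s1), abs(s2)) > 0:
            ratio = abs(s1) / abs(s2)
            out["symmetric"] = bool(0.5 <= ratio <= 2.0)
    return out


# --------------------------------------------------------------------- ATI

def _tuning_from_hd(hd_deg):
    counts = np.bincount(
        (np.floor(hd_deg / DIR_BIN_DEG).astype(int) % N_DIR_BINS),
        minlength=N_DIR_BINS).astype(float)
    return counts


def ati_estimate(spikes: SpikeTrain, tracking: TrackingSeries,
                 min_turn_spikes: int = 100, max_shift_ms: float = 160.0,
                 step_ms: float = 20.0) -> AtiResult:
    """Anticipatory time interval from CW/CCW tuning-curve cross-correlation.

    Positive ATI means the cell leads the head direction. The result is
    flagged unreliable (ati suppressed) when the zero-shift CW/CCW
    cross-correlation peak is below 0.7.
    """
    if tracking.ahv is None:
        raise ValueError("tracking kinematics not computed")
    st = np.asarray(spikes.times, dtype=float)
    idx = np.clip(np.rint((st - tracking.t[0]) / TRACKING_DT).astype(int),
                  1, len(tracking.t) - 2)
    # centered AHV at the spike sample: the forward-difference AHV series is
    # assigned to the earlier sample, so conditioning on it alone would judge
    # the turn half a sample (10 ms) in the future and bias the ATI by -10 ms
    from ._circular import circ_diff_deg
    ahv_at = circ_diff_deg(tracking.hd[idx + 1], tracking.hd[idx - 1]) / (2 * TRACKING_DT)
    cw = st[ahv_at > AHV_TURN_THRESHOLD]
    ccw = st[ahv_at < -AHV_TURN_THRESHOLD]
    if cw.size < min_turn_spikes or ccw.size < min_turn_spikes:
        raise ValueError("insufficient turns: too few CW/CCW spikes")
    good_hd = np.nan_to_num(tracking.hd)
    tmin, tmax = tracking.t[0], tracking.t[-1]
    shifts = np.arange(-max_shift_ms, max_shift_ms + step_ms, step_ms)
    rotations = np.empty(shifts.size)
    max_r = np.empty(shifts.size)
    # dwell-normalization cancels in the peak-normalized correlation of two
    # curves sharing the same occupancy, so raw count curves suffice
    for k, delta in enumerate(shifts / 1000.0):
        hd_cw = interp_angle_deg(np.clip(cw + delta, tmin, tmax), tracking.t, good_hd)
        hd_ccw = interp_angle_deg(np.clip(ccw + delta, tmin, tmax), tracking.t, good_hd)
        tc_cw = _tuning_from_hd(hd_cw)
        tc_ccw = _tuning_from_hd(hd_ccw)
        tc_cw = tc_cw / max(tc_cw.max(), 1e-12)
        tc_ccw = tc_ccw / max(tc_ccw.max(), 1e-12)
        # rotation = CCW curve relative to CW; positive for anticipatory
        # cells at zero shift (the CCW-CW difference-angle convention)
        lags, rs = circular_crosscorr(tc_ccw, tc_cw)
        best = int(np.argmax(rs))
        # parabolic sub-bin interpolation of the correlation peak: the 6-deg
        # lag grid alone quantizes the ATI by ~20 ms
        rm1, r0_, rp1 = rs[best - 1], rs[best], rs[(best + 1) % rs.size]
        denom = rm1 - 2 * r0_ + rp1
        frac = 0.5 * (rm1 - rp1) / denom if abs(denom) > 1e-12 else 0.0
        rot = lags[best] + np.clip(frac, -0.5, 0.5) * DIR_BIN_DEG
        rotations[k] = ((rot + 180.0) % 360.0) - 180.0
        max_r[k] = rs[best]
    i0 = int(np.argmin(np.abs(shifts)))
    difference_angle = float(rotations[i0])
    fit = linregress(shifts, rotations)
    ati = float(-fit.intercept / fit.slope) if fit.slope != 0 else None
    # second pass: refit locally around the crossing. Mean reversion of the
    # head's angular velocity makes rotation-vs-shift saturate asymmetrically
    # about the crossing, which pulls a single global line's zero outward;
    # a local line over the quasi-linear region is unbiased.
    if ati is not None:
        local = np.abs(shifts - np.clip(ati, shifts[0], shifts[-1])) <= 60.0
        if local.sum() >= 5:
            lfit = linregress(shifts[local], rotations[local])
            if lfit.slope != 0:
                ati = float(-lfit.intercept / lfit.slope)
                fit = lfit
    reliable = bool(max_r[i0] >= 0.7)
    return AtiResult(
        ati_ms=ati if reliable else None,
        difference_angle_deg=difference_angle,
        max_crosscorr=float(max_r[i0]),
        slope=float(fit.slope), intercept=float(fit.intercept),
        shifts_ms=shifts, rotations_deg=rotations, reliable=reliable)
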