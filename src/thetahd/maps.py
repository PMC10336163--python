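"""Locational ratemaps, directional tuning curves, information metrics,
place-field detection, position-by-direction (pxd) factorization and
cross-trial tuning stability.

Ratemaps use 2 x 2 cm bins; spike and dwell maps are smoothed separately
with a truncated Gaussian (sigma = 5 cm, zero weight beyond 10 cm) before
division. Tuning curves use 60 bins of 6 degrees with circular 5-bin
boxcar smoothing; summary statistics (R-vector, preferred firing
direction, width, concentration) are computed on the smoothed curve with
rate-weighted (occupancy-corrected) angular bins.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.stats import pearsonr

from ._circular import circ_sd_deg, kappa_from_R, mean_vector
from .session import TRACKING_DT, SpikeTrain, TrackingSeries, spike_sample_indices

BIN_CM = 2.0
SMOOTH_SIGMA_CM = 5.0
SMOOTH_CUTOFF_CM = 10.0
N_DIR_BINS = 60
DIR_BIN_DEG = 360.0 / N_DIR_BINS


@dataclasses.dataclass
class RateMap:
    rate: np.ndarray          # Hz; NaN where dwell smoothing is zero
    dwell: np.ndarray         # raw seconds per bin
    spikes: np.ndarray        # raw count per bin
    bin_size: float
    mean_rate: float          # total spikes / trial duration
    peak_rate: float
    peak_bin: tuple

    @property
    def occupancy(self) -> np.ndarray:
        """Dwell fraction per bin (sums to 1 over visited bins)."""
        return self.dwell / self.dwell.sum()


@dataclasses.dataclass
class TuningCurve:
    rates: np.ndarray         # Hz per 6-degree bin, smoothed; NaN = unvisited
    dwell: np.ndarray         # seconds per bin
    spikes: np.ndarray        # count per bin
    R: float
    pfd: float                # deg, center of the peak bin
    peak_rate: float
    width: float              # deg, 2 circular SD
    kappa: float
    dir_info: float           # bits/spike
    insufficient_sampling: bool

    @property
    def bin_centers(self) -> np.ndarray:
        return np.arange(N_DIR_BINS) * DIR_BIN_DEG + DIR_BIN_DEG / 2


@dataclasses.dataclass
class PlaceField:
    pixels: np.ndarray        # (n, 2) bin indices
    area: float               # cm^2
    peak_rate: float
    centroid: tuple           # cm


@dataclasses.dataclass
class PxdModel:
    p: np.ndarray             # positional rate factors, Hz scale
    d: np.ndarray             # directional factors, mean 1
    n: np.ndarray             # spike counts (pos x dir)
    t: np.ndarray             # dwell seconds (pos x dir)
    loglik_trace: np.ndarray
    converged: bool


# ---------------------------------------------------------------- ratemaps

def _truncated_gaussian_kernel(bin_cm=BIN_CM, sigma=SMOOTH_SIGMA_CM,
                               cutoff=SMOOTH_CUTOFF_CM):
    r = int(np.floor(cutoff / bin_cm))
    ax = np.arange(-r, r + 1) * bin_cm
    xx, yy = np.meshgrid(ax, ax)
    dist = np.hypot(xx, yy)
    k = np.exp(-dist**2 / (2 * sigma**2))
    k[dist > cutoff] = 0.0
    return k


def locational_ratemap(tracking: TrackingSeries, spikes: SpikeTrain,
                       arena_side: float = 90.0) -> RateMap:
    """2-cm binned, Gaussian-smoothed locational rate map.

    Spike and dwell maps are smoothed separately (sigma 5 cm, hard cutoff
    10 cm) and divided bin-wise; bins never smoothed onto stay missing.
    """
    nb = int(round(arena_side / BIN_CM))
    good = ~(np.isnan(tracking.x) | np.isnan(tracking.y))
    if not good.any():
        raise ValueError("empty trial: no valid position samples")
    ix = np.clip((tracking.x[good] / BIN_CM).astype(int), 0, nb - 1)
    iy = np.clip((tracking.y[good] / BIN_CM).astype(int), 0, nb - 1)
    dwell = np.zeros((nb, nb))
    np.add.at(dwell, (ix, iy), TRACKING_DT)
    if dwell.sum() <= 0:
        raise ValueError("empty trial: zero total dwell")
    sidx = spike_sample_indices(spikes.times, tracking)
    sgood = good[sidx]
    sx = np.clip((tracking.x[sidx[sgood]] / BIN_CM).astype(int), 0, nb - 1)
    sy = np.clip((tracking.y[sidx[sgood]] / BIN_CM).astype(int), 0, nb - 1)
    spk = np.zeros((nb, nb))
    np.add.at(spk, (sx, sy), 1.0)
    k = _truncated_gaussian_kernel()
    sm_dwell = ndimage.convolve(dwell, k, mode="constant")
    sm_spk = ndimage.convolve(spk, k, mode="constant")
    rate = np.full_like(dwell, np.nan)
    # rate defined on visited bins only; bins at the rim of the smoothing
    # kernel with no raw dwell would otherwise get unstable ratios
    vis = (sm_dwell > 0) & (dwell > 0)
    rate[vis] = sm_spk[vis] / sm_dwell[vis]
    duration = good.sum() * TRACKING_DT
    mean_rate = float(spikes.n_spikes / duration)
    if np.any(vis):
        flat = np.nanargmax(rate)
        peak_bin = np.unravel_index(flat, rate.shape)
        peak_rate = float(rate[peak_bin])
    else:
        peak_bin, peak_rate = (0, 0), np.nan
    return RateMap(rate=rate, dwell=dwell, spikes=spk, bin_size=BIN_CM,
                   mean_rate=mean_rate, peak_rate=peak_rate,
                   peak_bin=tuple(int(i) for i in peak_bin))


# ------------------------------------------------------------ tuning curve

def _circular_boxcar(values, size=5):
    n = values.size
    pad = size // 2
    ext = np.concatenate([values[-pad:], values, values[:pad]])
    out = np.convolve(ext, np.ones(size) / size, mode="valid")
    return out[:n]


def directional_tuning(tracking: TrackingSeries, spikes: SpikeTrain) -> TuningCurve:
    """60-bin head-direction tuning curve with circular summary statistics.

    Per-bin rate = spike count / dwell seconds, then circular 5-bin boxcar
    smoothing. R is the rate-weighted mean vector length of the smoothed
    curve; width = 2 circular SD; kappa by ML von Mises inversion;
    directional information by the Skaggs formula with dwell occupancy.
    """
    good = ~np.isnan(tracking.hd)
    bins = np.floor(tracking.hd[good] / DIR_BIN_DEG).astype(int) % N_DIR_BINS
    dwell = np.bincount(bins, minlength=N_DIR_BINS) * TRACKING_DT
    sidx = spike_sample_indices(spikes.times, tracking)
    shd = tracking.hd[sidx]
    sok = ~np.isnan(shd)
    sbins = np.floor(shd[sok] / DIR_BIN_DEG).astype(int) % N_DIR_BINS
    counts = np.bincount(sbins, minlength=N_DIR_BINS).astype(float)
    rate = np.full(N_DIR_BINS, np.nan)
    visited = dwell > 0
    rate[visited] = counts[visited] / dwell[visited]
    missing_frac = 1.0 - visited.mean()
    # smooth over visited bins (missing bins excluded from the kernel)
    filled = np.where(visited, rate, 0.0)
    weights = visited.astype(float)
    sm = _circular_boxcar(filled) / np.maximum(_circular_boxcar(weights), 1e-12)
    sm[~visited] = np.nan
    centers = np.arange(N_DIR_BINS) * DIR_BIN_DEG + DIR_BIN_DEG / 2
    w = np.where(np.isnan(sm), 0.0, sm)
    R, mean_dir = mean_vector(centers, weights=w)
    peak_idx = int(np.nanargmax(sm)) if np.any(visited) else 0
    occ = dwell / dwell.sum()
    info = skaggs_information(occ[visited], sm[visited])
    return TuningCurve(
        rates=sm, dwell=dwell, spikes=counts, R=float(R),
        pfd=float(centers[peak_idx]), peak_rate=float(np.nanmax(sm)),
        width=2.0 * circ_sd_deg(R), kappa=kappa_from_R(R), dir_info=info,
        insufficient_sampling=bool(missing_frac > 0.10))


# ----------------------------------------------------------------- metrics

def skaggs_information(occupancy, rates) -> float:
    """Information per spike: I = sum p_i (l_i/L) log2(l_i/L), L = sum p_i l_i."""
    p = np.asarray(occupancy, dtype=float)
    lam = np.asarray(rates, dtype=float)
    ok = ~np.isnan(lam)
    p, lam = p[ok], lam[ok]
    p = p / p.sum()
    mean = float(np.sum(p * lam))
    if mean <= 0:
        raise ValueError("silent cell: mean rate is zero")
    rel = lam / mean
    terms = np.where(lam > 0, p * rel * np.log2(np.where(rel > 0, rel, 1.0)), 0.0)
    return float(terms.sum())


def sparsity(occupancy, rates) -> float:
    """Skaggs sparsity (sum p l)^2 / sum p l^2, in (0, 1]."""
    p = np.asarray(occupancy, dtype=float)
    lam = np.asarray(rates, dtype=float)
    ok = ~np.isnan(lam)
    p, lam = p[ok], lam[ok]
    p = p / p.sum()
    denom = float(np.sum(p * lam**2))
    if denom <= 0:
        raise ValueError("silent cell: mean rate is zero")
    return float(np.sum(p * lam) ** 2 / denom)


def firing_area_fraction(ratemap: RateMap, threshold_hz: float = 0.1) -> float:
    """Fraction of visited bins with rate above threshold (diagnostic
    counterpart to sparsity: the share of the arena over which the cell fired)."""
    r = ratemap.rate
    vis = ~np.isnan(r)
    return float(np.mean(r[vis] > threshold_hz))


def selectivity(ratemap: RateMap) -> float:
    """Locational selectivity: peak rate / mean rate."""
    if ratemap.mean_rate <= 0:
        raise ValueError("silent cell: mean rate is zero")
    return float(ratemap.peak_rate / ratemap.mean_rate)


def detect_place_fields(ratemap: RateMap, rate_frac: float = 0.2,
                        min_pixels: int = 9, min_peak_hz: float = 1.0,
                        connectivity: int = 8):
    """Connected groups of >= 9 bins above 20% of the map peak (peak >= 1 Hz)."""
    r = ratemap.rate
    if not np.isfinite(ratemap.peak_rate) or ratemap.peak_rate < min_peak_hz:
        return []
    mask = np.nan_to_num(r) >= rate_frac * ratemap.peak_rate
    structure = (np.ones((3, 3), bool) if connectivity == 8
                 else ndimage.generate_binary_structure(2, 1))
    labels, nlab = ndimage.label(mask, structure=structure)
    fields = []
    for lab in range(1, nlab + 1):
        px = np.argwhere(labels == lab)
        if px.shape[0] < min_pixels:
            continue
        rates = r[px[:, 0], px[:, 1]]
        peak = float(np.nanmax(rates))
        wsum = np.nansum(rates)
        cx = float(np.sum((px[:, 0] + 0.5) * rates) / wsum * ratemap.bin_size)
        cy = float(np.sum((px[:, 1] + 0.5) * rates) / wsum * ratemap.bin_size)
        fields.append(PlaceField(pixels=px, area=px.shape[0] * ratemap.bin_size**2,
                                 peak_rate=peak, centroid=(cx, cy)))
    fields.sort(key=lambda f: -f.peak_rate)
    return fields


# --------------------------------------------------------------------- pxd

def pxd_counts(tracking: TrackingSeries, spikes: SpikeTrain,
               arena_side: float = 90.0, n_pos: int = 8, n_dir: int = N_DIR_BINS):
    """Unsmoothed joint (position x direction) dwell and spike-count matrices."""
    good = ~(np.isnan(tracking.x) | np.isnan(tracking.y) | np.isnan(tracking.hd))
    pb = np.clip((tracking.x / (arena_side / n_pos)).astype(int), 0, n_pos - 1) * n_pos \
        + np.clip((tracking.y / (arena_side / n_pos)).astype(int), 0, n_pos - 1)
    db = np.floor(tracking.hd / (360.0 / n_dir)).astype(int) % n_dir
    t = np.zeros((n_pos * n_pos, n_dir))
    np.add.at(t, (pb[good], db[good]), TRACKING_DT)
    sidx = spike_sample_indices(spikes.times, tracking)
    sgood = good[sidx]
    n = np.zeros_like(t)
    np.add.at(n, (pb[sidx[sgood]], db[sidx[sgood]]), 1.0)
    return n, t


def pxd_poisson_loglik(n, t, p, d):
    """Poisson log-likelihood of counts n given rate p_i d_j and dwell t (up
    to the n!-term, which is constant in the parameters)."""
    mu = np.outer(p, d) * t
    ok = t > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where((n > 0) & ok, n * np.log(np.where(mu > 0, mu, 1.0)), 0.0)
    return float(ll[ok].sum() - mu[ok].sum())


def pxd_factorize_counts(n, t, tol: float = 1e-8, max_iter: int = 500) -> PxdModel:
    """Alternating multiplicative ML updates for the factorized rate p_i d_j.

    p_i <- sum_j n_ij / sum_j d_j t_ij and d_j <- sum_i n_ij / sum_i p_i t_ij;
    after each sweep d is rescaled to mean 1 (the scale degeneracy). Iterates
    until the relative log-likelihood change is below `tol` or `max_iter`.
    Empty rows/columns of t are excluded (their factors are NaN on output).
    """
    n = np.asarray(n, dtype=float)
    t = np.asarray(t, dtype=float)
    row_ok = t.sum(axis=1) > 0
    col_ok = t.sum(axis=0) > 0
    nn, tt = n[np.ix_(row_ok, col_ok)], t[np.ix_(row_ok, col_ok)]
    total = nn.sum()
    if total == 0:
        raise ValueError("silent cell: no spikes in the pxd matrices")
    p = nn.sum(axis=1) / np.maximum(tt.sum(axis=1), 1e-300)
    d = np.ones(tt.shape[1])
    trace = [pxd_poisson_loglik(nn, tt, p, d)]
    converged = False
    for _ in range(max_iter):
        denom_p = tt @ d
        p = np.where(denom_p > 0, nn.sum(axis=1) / np.maximum(denom_p, 1e-300), 0.0)
        denom_d = tt.T @ p
        d = np.where(denom_d > 0, nn.sum(axis=0) / np.maximum(denom_d, 1e-300), 0.0)
        scale = d[d > 0].mean() if np.any(d > 0) else 1.0
        d = d / scale
        p = p * scale
        ll = pxd_poisson_loglik(nn, tt, p, d)
        trace.append(ll)
        if abs(ll - trace[-2]) <= tol * max(abs(trace[-2]), 1.0):
            converged = True
            break
    p_full = np.full(n.shape[0], np.nan)
    d_full = np.full(n.shape[1], np.nan)
    p_full[row_ok] = p
    d_full[col_ok] = d
    return PxdModel(p=p_full, d=d_full, n=n, t=t,
                    loglik_trace=np.asarray(trace), converged=converged)


def pxd_factorize(tracking: TrackingSeries, spikes: SpikeTrain,
                  arena_side: float = 90.0, **kw) -> PxdModel:
    """Position-by-direction ML factorization on 64 x 60 unsmoothed bins."""
    n, t = pxd_counts(tracking, spikes, arena_side=arena_side)
    return pxd_factorize_counts(n, t, **kw)


def pxd_corrected_information(model: PxdModel):
    """Locational/directional information and sparsity of the isolated factors.

    Uses the marginal dwell occupancies with the fitted p (locational) and
    d (directional) rate factors. Returns a dict with keys loc_info,
    dir_info, loc_sparsity, dir_sparsity.
    """
    t_pos = model.t.sum(axis=1)
    t_dir = model.t.sum(axis=0)
    ok_p = (t_pos > 0) & ~np.isnan(model.p)
    ok_d = (t_dir > 0) & ~np.isnan(model.d)
    occ_p = t_pos[ok_p] / t_pos[ok_p].sum()
    occ_d = t_dir[ok_d] / t_dir[ok_d].sum()
    return {
        "loc_info": skaggs_information(occ_p, model.p[ok_p]),
        "dir_info": skaggs_information(occ_d, model.d[ok_d]),
        "loc_sparsity": sparsity(occ_p, model.p[ok_p]),
        "dir_sparsity": sparsity(occ_d, model.d[ok_d]),
    }


def marginal_information(tracking: TrackingSeries, spikes: SpikeTrain,
                         arena_side: float = 90.0):
    """Uncorrected locational/directional information on the pxd bin grid."""
    n, t = pxd_counts(tracking, spikes, arena_side=arena_side)
    out = {}
    for axis, key in ((1, "loc_info"), (0, "dir_info")):
        cnt = n.sum(axis=axis)
        dw = t.sum(axis=axis)
        ok = dw > 0
        occ = dw[ok] / dw[ok].sum()
        out[key] = skaggs_information(occ, cnt[ok] / dw[ok])
    return out


# ------------------------------------------------------------- stability

def circular_crosscorr(a, b):
    """Pearson r between curve a and curve b rotated by each 6-degree lag.

    Returns (lags_deg, r) with positive lag meaning b rotated forward.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.nanstd(a) == 0 or np.nanstd(b) == 0:
        raise ValueError("degenerate curve: zero variance")
    nb = a.size
    rs = np.empty(nb)
    for k in range(nb):
        bb = np.roll(b, k)
        ok = ~(np.isnan(a) | np.isnan(bb))
        rs[k] = pearsonr(a[ok], bb[ok])[0]
    lags = np.arange(nb) * (360.0 / nb)
    lags = np.where(lags > 180.0, lags - 360.0, lags)
    return lags, rs


def cross_trial_stability(curve_a: TuningCurve, curve_b: TuningCurve,
                          tracking_b: Optional[TrackingSeries] = None,
                          spikes_b: Optional[SpikeTrain] = None,
                          n_shuffles: int = 0, seed: int = 0):
    """Cross-trial tuning stability: r at zero rotation plus a shuffle null.

    Returns a dict with r0, lags_deg, crosscorr, best_lag_deg and (when
    trial-b raw data and n_shuffles are given) null95, the 95th percentile
    of zero-lag correlations against time-shifted surrogates of trial b.
    """
    lags, rs = circular_crosscorr(curve_a.rates, curve_b.rates)
    out = {"r0": float(rs[0]), "lags_deg": lags, "crosscorr": rs,
           "best_lag_deg": float(lags[int(np.argmax(rs))]), "null95": None}
    if n_shuffles and tracking_b is not None and spikes_b is not None:
        rng = np.random.default_rng(seed)
        dur = tracking_b.duration
        r_null = np.empty(n_shuffles)
        for i in range(n_shuffles):
            shift = rng.uniform(20.0, dur - 20.0)
            shifted = SpikeTrain(cell_id=spikes_b.cell_id,
                                 times=np.sort(np.mod(spikes_b.times + shift, dur)))
            tc = directional_tuning(tracking_b, shifted)
            _, rr = circular_crosscorr(curve_a.rates, tc.rates)
            r_null[i] = rr[0]
        out["null95"] = float(np.percentile(r_null, 95))
    return out
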