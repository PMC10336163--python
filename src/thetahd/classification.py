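"""Shuffle-null construction, cell-type classification, ISI/burst metrics
and waveform-width population clustering.

Cell types follow conservative criteria: a theta-modulated cell is
phase-locked (IC at or above its 99th-percentile circular-shift null) with
autocorrelogram rhythmicity IR >= 0.001; an HD-modulated cell has a
tuning-curve R-vector at or above its 99th-percentile null and a smoothed
directional peak above 1 Hz; a place cell has 0.1 < mean rate < 10 Hz,
locational peak > 1 Hz, locational information > 0.8 bits/spike and
sparsity < 0.2. The composite label gives place precedence, then
Theta-by-HD, non-rhythmic HD, theta, else unclassified; the individual
flags are all preserved so conjunctions remain countable.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional

import numpy as np
from sklearn.mixture import GaussianMixture

from .maps import (detect_place_fields, directional_tuning, locational_ratemap,
                   skaggs_information, sparsity)
from .session import SpikeTrain, TrackingSeries, WAVEFORM_HZ
from .theta import (index_of_rhythmicity, phase_coupling, spike_autocorrelogram,
                    spike_phases)

DEFAULT_N_SHUFFLES = 10_000
SHUFFLE_MARGIN_S = 20.0


@dataclasses.dataclass
class ShuffleNull:
    metric_name: str
    values: np.ndarray
    p95: float
    p99: float
    n_shuffles: int
    seed: int


@dataclasses.dataclass
class CellReport:
    cell_id: str
    label: str
    theta_modulated: bool
    hd_modulated: bool
    place: bool
    bursting: bool
    speed_tuned: bool
    ahv_tuned: bool
    precessing: Optional[bool]
    metrics: dict
    thresholds: dict


@dataclasses.dataclass
class WaveformTypology:
    widths: np.ndarray
    means: np.ndarray          # mixture component means, sorted
    sds: np.ndarray
    weights: np.ndarray
    cutoff_narrow: float       # c1
    cutoff_broad: float        # c2
    classes: list              # per cell: narrow/intermediate/broad
    dip: float
    dip_p: float


# ------------------------------------------------------------ shuffle null

def circular_shift(times, duration: float, shift: float) -> np.ndarray:
    """Circularly time-shift a spike train, preserving count and ISI multiset
    up to the single wrap point."""
    return np.sort(np.mod(np.asarray(times, dtype=float) + shift, duration))


def shuffle_null(metric: Callable[[np.ndarray], float], spikes: SpikeTrain,
                 duration: float, n_shuffles: int = DEFAULT_N_SHUFFLES,
                 seed: int = 0, metric_name: str = "") -> ShuffleNull:
    """Empirical null for a spike-train metric under circular time shifts.

    Each replicate shifts the spike times by U(20 s, T - 20 s) relative to
    the (unshifted) behavior or LFP, recomputes `metric` on the shifted
    times, and the 95th/99th percentiles (linear interpolation) become the
    significance thresholds.
    """
    if duration <= 2 * SHUFFLE_MARGIN_S:
        raise ValueError("trial too short for circular shuffling (<= 40 s)")
    rng = np.random.default_rng(seed)
    shifts = rng.uniform(SHUFFLE_MARGIN_S, duration - SHUFFLE_MARGIN_S, n_shuffles)
    vals = np.empty(n_shuffles)
    times = np.asarray(spikes.times, dtype=float)
    for i, sh in enumerate(shifts):
        vals[i] = metric(circular_shift(times, duration, sh))
    # conservative (next-higher order statistic) percentiles: linear
    # interpolation would let a null cell beat its own 99th-percentile
    # threshold ~1.5x more often than nominal at small shuffle counts
    return ShuffleNull(metric_name=metric_name, values=vals,
                       p95=float(np.percentile(vals, 95, method="higher")),
                       p99=float(np.percentile(vals, 99, method="higher")),
                       n_shuffles=n_shuffles, seed=seed)


def tuning_r_metric(tracking: TrackingSeries):
    """Factory: spike-times -> tuning-curve R-vector, for shuffle nulls."""
    def metric(times):
        return directional_tuning(tracking, SpikeTrain("shuf", times)).R
    return metric


def ic_metric(lfp_t, unwrapped_phase_deg):
    """Factory: spike-times -> IC (phase-locking strength), for shuffle nulls."""
    def metric(times):
        ph, _ = spike_phases(SpikeTrain("shuf", times), lfp_t, unwrapped_phase_deg)
        if ph.size < 2:
            return 0.0
        return phase_coupling(ph, min_spikes=2, compute_kde=False)["ic"]
    return metric


# ---------------------------------------------------------- classification

def classify_cell(cell_id: str, *, ic: float, ic_null99: float, ir: float,
                  tuning_r: float, r_null99: float, dir_peak_rate: float,
                  mean_rate: float, loc_peak_rate: float, loc_info: float,
                  loc_sparsity: float, bursting: bool = False,
                  speed_tuned: bool = False, ahv_tuned: bool = False,
                  precessing: Optional[bool] = None,
                  metrics: Optional[dict] = None) -> CellReport:
    """Assemble flags and the composite label for one cell."""
    for name, v in (("ic", ic), ("ir", ir), ("tuning_r", tuning_r),
                    ("mean_rate", mean_rate)):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"incomplete inputs: {name} missing")
    theta_mod = bool(ic >= ic_null99 and ir >= 0.001)
    hd_mod = bool(tuning_r >= r_null99 and dir_peak_rate > 1.0)
    place = bool(0.1 < mean_rate < 10.0 and loc_peak_rate > 1.0
                 and loc_info > 0.8 and loc_sparsity < 0.2)
    if place:
        label = "place"
    elif theta_mod and hd_mod:
        label = "theta_hd"
    elif hd_mod:
        label = "hd"
    elif theta_mod:
        label = "theta"
    else:
        label = "unclassified"
    return CellReport(
        cell_id=cell_id, label=label, theta_modulated=theta_mod,
        hd_modulated=hd_mod, place=place, bursting=bursting,
        speed_tuned=speed_tuned, ahv_tuned=ahv_tuned, precessing=precessing,
        metrics=dict(metrics or {}, ic=ic, ir=ir, tuning_r=tuning_r,
                     dir_peak_rate=dir_peak_rate, mean_rate=mean_rate,
                     loc_peak_rate=loc_peak_rate, loc_info=loc_info,
                     loc_sparsity=loc_sparsity),
        thresholds={"ic_null99": ic_null99, "r_null99": r_null99})


def classify_session_cell(spikes: SpikeTrain, tracking: TrackingSeries,
                          lfp, n_shuffles: int = DEFAULT_N_SHUFFLES,
                          seed: int = 0) -> CellReport:
    """Full single-cell pipeline: metrics, shuffle nulls, flags, label."""
    from .motion import ahv_score, instantaneous_rate, speed_score
    from .theta import instantaneous_theta, intrinsic_frequency_fit, lfp_spectrum

    duration = tracking.duration
    tc = directional_tuning(tracking, spikes)
    rm = locational_ratemap(tracking, spikes)
    occ = rm.occupancy
    vis = ~np.isnan(rm.rate)
    loc_info = skaggs_information(occ[vis], rm.rate[vis])
    loc_sparsity = sparsity(occ[vis], rm.rate[vis])
    phase, _, _, unwrapped = instantaneous_theta(lfp)
    ph, _ = spike_phases(spikes, lfp.t, unwrapped)
    pc = phase_coupling(ph) if ph.size >= 2 else {"ic": 0.0}
    ac = spike_autocorrelogram(spikes)
    ir = index_of_rhythmicity(ac)
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    null_r = shuffle_null(tuning_r_metric(tracking), spikes, duration,
                          n_shuffles=n_shuffles, seed=s1, metric_name="tuning_r")
    null_ic = shuffle_null(ic_metric(lfp.t, unwrapped), spikes, duration,
                           n_shuffles=n_shuffles, seed=s2, metric_name="ic")
    bm = burst_metrics(spikes) if spikes.n_spikes >= 100 else {"bursting": False}
    rate = instantaneous_rate(spikes, tracking)
    try:
        sp = speed_score(rate, tracking)
    except ValueError:
        sp = {"s_score": np.nan, "tuned": False}
    av = ahv_score(rate, tracking)
    precessing = None
    if pc["ic"] >= null_ic.p99 and ir >= 0.001:
        fit = intrinsic_frequency_fit(ac)
        if fit is not None:
            _, _, _, lfp_freq, _ = lfp_spectrum(lfp)
            precessing = bool(fit.omega > lfp_freq)
    return classify_cell(
        spikes.cell_id, ic=pc["ic"], ic_null99=null_ic.p99, ir=ir,
        tuning_r=tc.R, r_null99=null_r.p99, dir_peak_rate=tc.peak_rate,
        mean_rate=rm.mean_rate, loc_peak_rate=rm.peak_rate, loc_info=loc_info,
        loc_sparsity=loc_sparsity, bursting=bool(bm["bursting"]),
        speed_tuned=bool(sp["tuned"]), ahv_tuned=bool(av["tuned"]),
        precessing=precessing,
        metrics={"s_score": sp.get("s_score"), "abs_ahv_score": av.get("abs_score"),
                 "n_fields": len(detect_place_fields(rm)),
                 "dir_info": tc.dir_info, "width": tc.width, "kappa": tc.kappa})


# ------------------------------------------------------------- ISI / burst

def burst_metrics(spikes: SpikeTrain, max_isi_ms: float = 250.0,
                  bin_ms: float = 2.0, burst_isi_ms: float = 6.0,
                  min_spikes: int = 100):
    """ISI histogram, modal (peak) ISI, bursting flag and burst index.

    A cell bursts when its modal ISI is below 6 ms; the burst index is the
    fraction of spikes that share an ISI < 6 ms with a neighbor.
    """
    t = np.asarray(spikes.times, dtype=float)
    low_n = t.size < min_spikes
    isi = np.diff(t) * 1000.0
    edges = np.arange(0.0, max_isi_ms + bin_ms, bin_ms)
    hist, _ = np.histogram(isi, bins=edges)
    peak_isi = float(edges[int(np.argmax(hist))] + bin_ms / 2)
    short = isi < burst_isi_ms
    in_burst = np.zeros(t.size, dtype=bool)
    in_burst[:-1] |= short
    in_burst[1:] |= short
    burst_index = float(in_burst.mean()) if t.size else 0.0
    return {"isi_hist": hist, "isi_edges": edges, "peak_isi_ms": peak_isi,
            "bursting": bool(peak_isi < burst_isi_ms), "burst_index": burst_index,
            "low_n": bool(low_n)}


# --------------------------------------------------------------- waveforms

def waveform_width(waveform) -> Optional[float]:
    """Peak-to-trough width (us) on the largest-amplitude channel.

    Returns None (discarded) when the global minimum precedes the global
    maximum (no repolarization) or the waveform is flat.
    """
    w = np.atleast_2d(np.asarray(waveform, dtype=float))
    ch = int(np.argmax(np.ptp(w, axis=1)))
    v = w[ch]
    if np.ptp(v) == 0:
        return None
    i_peak = int(np.argmax(v))
    i_trough = int(np.argmin(v))
    if i_trough <= i_peak:
        return None
    return float((i_trough - i_peak) / WAVEFORM_HZ * 1e6)


def _convex_flank_costs(x, y_lo, y_hi):
    """Per-prefix half max deviation of ECDF upper steps above the greatest
    convex minorant of the lower steps.

    For sorted x with lower/upper ECDF steps y_lo[i] = i/n, y_hi[i] =
    (i+1)/n, a convex CDF piece fits the prefix 0..k within a band of half
    width d iff the greatest convex minorant of the lower steps stays
    within 2d of every upper step; the returned A[k] is the smallest such
    d for each prefix. One left-to-right lower-convex-hull sweep; when a
    hull vertex is popped the deviations under the new chord are
    re-evaluated (they can only grow).
    """
    n = x.size
    hull = [0]                      # indices of hull vertices
    cummax = [y_hi[0] - y_lo[0]]    # running max deviation up to each vertex
    A = np.empty(n)
    A[0] = cummax[0] / 2.0
    for k in range(1, n):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # pop b when it lies on or above chord a->k
            if (y_lo[b] - y_lo[a]) * (x[k] - x[a]) >= (y_lo[k] - y_lo[a]) * (x[b] - x[a]):
                hull.pop()
                cummax.pop()
            else:
                break
        a = hull[-1]
        base = cummax[-1]
        if k - a > 1:
            xs = x[a + 1:k]
            chord = y_lo[a] + (y_lo[k] - y_lo[a]) * (xs - x[a]) / (x[k] - x[a])
            seg = float(np.max(y_hi[a + 1:k] - chord))
        else:
            seg = 0.0
        dev_k = y_hi[k] - y_lo[k]
        hull.append(k)
        cummax.append(max(base, seg, dev_k))
        A[k] = cummax[-1] / 2.0
    return A


def _dip_statistic(x):
    """Hartigan & Hartigan dip statistic of a 1-d sample.

    The dip is the smallest sup-distance between the empirical CDF and any
    unimodal CDF. Splitting at the mode, a unimodal CDF within sup-distance
    d exists iff some prefix admits a convex fit and the complementary
    suffix a concave fit, each within d; the per-flank minimal d values are
    computed by convex-hull sweeps and combined by minimizing over the
    split. Ties in x are separated by an infinitesimal (index-scaled)
    offset.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0
    if np.any(np.diff(x) == 0):
        span = x[-1] - x[0]
        x = x + np.arange(n) * (span * 1e-12 / n)
    i = np.arange(n)
    y_lo = i / n
    y_hi = (i + 1) / n
    A = _convex_flank_costs(x, y_lo, y_hi)                # prefix convex costs
    # suffix concave costs via the point reflection (x, y) -> (-x, 1 - y)
    B_rev = _convex_flank_costs(-x[::-1], y_lo, y_hi)
    B = B_rev[::-1]                                       # B[k]: suffix k..n-1
    # mode between k and k+1; k = -1 (pure concave) and n-1 (pure convex)
    best = min(A[-1], B[0])
    if n >= 2:
        best = min(best, float(np.min(np.maximum(A[:-1], B[1:]))))
    return float(best)


def dip_test(x, n_boot: int = 1000, seed: int = 0):
    """Calibrated dip test: bootstrap p-value under the best-fitting
    unimodal (maximum-likelihood Gaussian) null."""
    x = np.asarray(x, dtype=float)
    d = _dip_statistic(x)
    rng = np.random.default_rng(seed)
    mu, sd = x.mean(), x.std()
    boots = np.array([_dip_statistic(rng.normal(mu, sd, x.size))
                      for _ in range(n_boot)])
    p = float((np.sum(boots >= d) + 1) / (n_boot + 1))
    return float(d), p


def waveform_population_clustering(widths, seed: int = 0,
                                   n_boot: int = 200) -> WaveformTypology:
    """Two-Gaussian mixture over peak-to-trough widths with 10:1 odds cutoffs.

    A width below the narrow cutoff c1 has at least 10:1 posterior odds of
    belonging to the lower (narrow) component; above the broad cutoff c2,
    10:1 odds for the upper component. Widths in between fall in the dip of
    the bimodal distribution and are labelled intermediate. A calibrated
    Hartigan dip test quantifies the bimodality of the width distribution.
    """
    from scipy.stats import norm

    w = np.asarray(widths, dtype=float)
    if w.size < 50:
        raise ValueError("need at least 50 widths for population clustering")
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=5)
    gm.fit(w.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_.ravel()[order]
    dip, dip_p = dip_test(w, n_boot=n_boot, seed=seed)
    degenerate = abs(means[1] - means[0]) < 1e-6 or np.any(sds <= 0)
    if degenerate:
        classes = ["intermediate"] * w.size
        return WaveformTypology(widths=w, means=means, sds=sds, weights=weights,
                                cutoff_narrow=float(means[0]),
                                cutoff_broad=float(means[0]),
                                classes=classes, dip=dip, dip_p=dip_p)
    grid = np.linspace(w.min(), w.max(), 4000)
    log_odds = (np.log(weights[0]) + norm.logpdf(grid, means[0], sds[0])
                - np.log(weights[1]) - norm.logpdf(grid, means[1], sds[1]))
    thr = np.log(10.0)
    ok1 = log_odds >= thr
    c1 = float(grid[np.flatnonzero(ok1)[-1]]) if ok1.any() else float(grid[0])
    ok2 = log_odds <= -thr
    c2 = float(grid[np.flatnonzero(ok2)[0]]) if ok2.any() else float(grid[-1])
    if c2 < c1:
        c1 = c2 = float((c1 + c2) / 2)
    classes = ["narrow" if v < c1 else "broad" if v > c2 else "intermediate"
               for v in w]
    return WaveformTypology(widths=w, means=means, sds=sds, weights=weights,
                            cutoff_narrow=c1, cutoff_broad=c2, classes=classes,
                            dip=dip, dip_p=dip_p)
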