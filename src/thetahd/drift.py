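"""Intra-trial preferred-direction drift via per-sweep circular KDEs.

A "sweep" is one full pass of the head through a cell's preferred firing
direction: a contiguous epoch in which the smoothed instantaneous rate
exceeds 50% of the intra-trial peak, extended to the spikes emitted just
before and after while the head stays within +/- 50 degrees of the heading
at the threshold crossing. For each sweep with at least 5 spikes, the
circular kernel density estimate of the spike head directions (von Mises
kernel, Taylor plug-in bandwidth, 1-degree grid) yields a peak location
and a width at half height. Drifting cells show a large spread (circular
SEM) of peak locations across sweeps; inherently broad tuning shows as a
large mean peak width instead.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._circular import circ_diff_deg, mean_vector, vonmises_kde
from .motion import RateSeries, instantaneous_rate
from .session import TRACKING_DT, SpikeTrain, TrackingSeries, spike_sample_indices

MIN_SWEEP_SPIKES = 5
MERGE_GAP_S = 0.5   # adjacent supra-threshold epochs closer than this merge
HD_EXTENT_DEG = 50.0


@dataclasses.dataclass
class SweepEvent:
    spike_hd: np.ndarray       # deg
    t_start: float
    t_stop: float
    kde_grid: np.ndarray
    kde_density: np.ndarray
    peak_location: float       # deg
    peak_width: float          # deg, width at half height


def _half_height_width(grid, density):
    i_peak = int(np.argmax(density))
    half = density[i_peak] / 2.0
    above = density >= half
    # rotate so the peak is central, then measure the contiguous run
    shift = len(grid) // 2 - i_peak
    rolled = np.roll(above, shift)
    center = len(grid) // 2
    left = center
    while left > 0 and rolled[left - 1]:
        left -= 1
    right = center
    while right < len(grid) - 1 and rolled[right + 1]:
        right += 1
    step = grid[1] - grid[0]
    return float((right - left + 1) * step)


def detect_sweeps(spikes: SpikeTrain, tracking: TrackingSeries,
                  rate: RateSeries = None):
    """Segment the trial into full-sweep events through the preferred direction."""
    if rate is None:
        rate = instantaneous_rate(spikes, tracking)
    peak = float(np.max(rate.rate))
    if peak <= 0:
        return []
    supra = rate.rate > 0.5 * peak
    # contiguous supra-threshold epochs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], supra.view(np.int8), [0]))))
    epochs = [(tracking.t[a], tracking.t[b - 1] + TRACKING_DT)
              for a, b in zip(edges[::2], edges[1::2])]
    # merge epochs separated by less than MERGE_GAP_S
    merged = []
    for ep in epochs:
        if merged and ep[0] - merged[-1][1] < MERGE_GAP_S:
            merged[-1] = (merged[-1][0], ep[1])
        else:
            merged.append(ep)
    st = np.asarray(spikes.times, dtype=float)
    hd_at_spike = tracking.hd[spike_sample_indices(st, tracking)]
    events = []
    for t_on, t_off in merged:
        inside = np.flatnonzero((st >= t_on) & (st <= t_off))
        if inside.size == 0:
            continue
        i_cross = int(np.argmin(np.abs(tracking.t - t_on)))
        hd_cross = tracking.hd[i_cross]
        if np.isnan(hd_cross):
            continue
        sel = list(inside)
        # extend backward/forward over spikes within +/- 50 deg of the crossing
        j = inside[0] - 1
        while j >= 0 and not np.isnan(hd_at_spike[j]) \
                and abs(circ_diff_deg(hd_at_spike[j], hd_cross)) <= HD_EXTENT_DEG:
            sel.insert(0, j)
            j -= 1
        j = inside[-1] + 1
        while j < st.size and not np.isnan(hd_at_spike[j]) \
                and abs(circ_diff_deg(hd_at_spike[j], hd_cross)) <= HD_EXTENT_DEG:
            sel.append(j)
            j += 1
        hd_sel = hd_at_spike[sel]
        hd_sel = hd_sel[~np.isnan(hd_sel)]
        if hd_sel.size < MIN_SWEEP_SPIKES:
            continue
        grid, dens = vonmises_kde(hd_sel)
        peak_loc = float(grid[int(np.argmax(dens))])
        events.append(SweepEvent(
            spike_hd=hd_sel, t_start=float(st[sel[0]]), t_stop=float(st[sel[-1]]),
            kde_grid=grid, kde_density=dens, peak_location=peak_loc,
            peak_width=_half_height_width(grid, dens)))
    return events


def sweep_summary(events):
    """Mean KDE peak width, circular SEM of peak locations, SEM of widths.

    Raises when fewer than 2 events are available.
    """
    if len(events) < 2:
        raise ValueError("insufficient events: need at least 2 sweeps")
    locs = np.array([e.peak_location for e in events])
    widths = np.array([e.peak_width for e in events])
    _, mean_loc = mean_vector(locs)
    dev = circ_diff_deg(locs, mean_loc)
    sem_loc = dev.std(ddof=1) / np.sqrt(len(events))
    return {
        "n_sweeps": len(events),
        "mean_width_deg": float(widths.mean()),
        "sem_locations_deg": float(sem_loc),
        "sem_widths_deg": float(widths.std(ddof=1) / np.sqrt(len(widths))),
    }
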