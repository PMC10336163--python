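"""Synthetic foraging sessions with programmable firing correlates.

The generator emulates the statistical structure every downstream analysis
assumes: a foraging trajectory in a 90 x 90 cm arena, a speed-modulated
6-12 Hz theta LFP, and spike trains drawn from an inhomogeneous Poisson
process whose conditional intensity multiplies independent directional
(von Mises), locational (Gaussian field), theta-phase (von Mises), linear
speed, angular-head-velocity, theta-skipping and anticipation factors:

    lambda(t) = r0 * vm(hd(t + ati); mu_hd, k_hd)
                   * (1 + gain * G(x, y))
                   * vm(phi(t); mu_phi + 360 * f_off * t, k_phi)
                   * (1 + s_gain * speed) * (1 + a_gain * |ahv|)
                   * (1 - skip_depth * cycle_parity)

with each von Mises factor normalized by I0(kappa) so that kappa = 0 leaves
the rate untouched. Phase precession is a linearly advancing preferred
phase (an intrinsic oscillator f_off Hz faster than the LFP); theta
skipping attenuates alternate theta cycles; anticipation samples the head
direction ati seconds in the future. Bursting appends 2-4 extra spikes at
4-ms intervals after a fraction of accepted spikes.

Randomness uses numpy's default PCG64 generator; a fixed seed reproduces
sessions bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.special import i0

from ._circular import interp_angle_deg, wrap_deg
from .session import (LFP_HZ, TRACKING_DT, LfpSeries, SessionBundle, SpikeTrain,
                      TrackingSeries, Trial, compute_kinematics)
from .theta import instantaneous_theta

WAVEFORM_FS = 48000.0
# peak-to-trough width distributions (us) for the three template classes;
# the narrow/broad boundary in the field sits near 250 us
WAVEFORM_CLASS_US = {"narrow": (200.0, 15.0), "intermediate": (300.0, 20.0),
                     "broad": (400.0, 25.0)}


@dataclasses.dataclass
class TrajectoryParams:
    """Foraging-path model: mean-reverting speed, smoothed-random-walk heading."""

    mean_speed: float = 18.0      # cm/s
    speed_relaxation: float = 2.0  # 1/s: foraging speed bouts last ~0.5 s
    turn_sd: float = 60.0         # deg/sqrt(s): gives AHV SD ~70 deg/s, rat-like
    duration: float = 480.0       # s (one 8-min trial)
    arena_side: float = 90.0      # cm
    seed: int = 0
    hd_jitter_sd: float = 0.5     # deg, tracking noise added to heading
    turn_relaxation: float = 3.0  # 1/s, angular-velocity mean reversion

    def validate(self):
        if self.duration <= 0 or self.mean_speed <= 0:
            raise ValueError("duration and mean_speed must be positive")


@dataclasses.dataclass
class ThetaLfpParams:
    """Speed-modulated theta oscillator: f(t) = f0 + beta_f * speed."""

    # f0 is the zero-speed intercept; with the default speed modulation the
    # session-average theta frequency comes out near 8.9 Hz, inside the
    # 5-9 Hz band that the two-cosine autocorrelogram model can represent
    f0: float = 8.5               # Hz, baseline theta frequency
    beta_f: float = 0.02          # Hz per cm/s
    a0: float = 1.0               # baseline amplitude, arbitrary units
    beta_a: float = 0.02          # amplitude per cm/s
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self):
        if not (6.0 <= self.f0 <= 12.0):
            raise ValueError("f0 must lie in the 6-12 Hz theta band")


@dataclasses.dataclass
class CellSpec:
    """Ground-truth firing correlates of one simulated unit."""

    cell_id: str = "cell"
    r0: float = 5.0                               # Hz
    hd_pref: float = 0.0                          # deg
    hd_kappa: float = 0.0
    place_field: Optional[tuple] = None           # (cx, cy, sigma_cm, gain)
    phase_pref: float = 180.0                     # deg
    phase_kappa: float = 0.0
    speed_gain: float = 0.0                       # per cm/s
    ahv_gain: float = 0.0                         # per deg/s, on |AHV|
    ati: float = 0.0                              # s; positive = anticipatory
    burst_prob: float = 0.0
    skip_depth: float = 0.0                       # in [0, 1]
    intrinsic_freq_offset: float = 0.0            # Hz; > 0 = precessing
    pfd_drift_sd: float = 0.0                     # deg per sqrt(min): PFD random walk
    waveform_class: Optional[str] = None          # narrow/intermediate/broad
    archetype: Optional[str] = None               # manifest label, if any

    def validate(self):
        if self.r0 <= 0 or self.hd_kappa < 0 or self.phase_kappa < 0:
            raise ValueError("rates/concentrations must be non-negative, r0 > 0")
        if not (0 <= self.burst_prob <= 1 and 0 <= self.skip_depth <= 1):
            raise ValueError("burst_prob and skip_depth must lie in [0, 1]")
        if self.place_field is not None and self.place_field[2] <= 0:
            raise ValueError("place-field width must be positive")


# -------------------------------------------------------------- trajectory

def simulate_trajectory(p: TrajectoryParams) -> TrackingSeries:
    """Simulate a 50 Hz foraging path with wall reflection.

    Speed follows a mean-reverting positive process; heading integrates a
    mean-reverting angular velocity whose long-run diffusion matches a
    random walk of scale ``turn_sd`` deg/sqrt(s). Head direction equals the
    movement heading plus small tracking jitter.
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration / TRACKING_DT))
    dt = TRACKING_DT
    tau_w = 1.0 / p.turn_relaxation
    sd_w = p.turn_sd / np.sqrt(2.0 * tau_w) if p.turn_sd > 0 else 0.0
    theta_s = p.speed_relaxation
    sd_s = 0.6 * p.mean_speed

    speed = np.empty(n)
    heading = np.empty(n)
    x = np.empty(n)
    y = np.empty(n)
    s = p.mean_speed
    w = 0.0
    h = rng.uniform(0, 360.0) if p.turn_sd > 0 else 0.0
    cx = cy = p.arena_side / 2.0
    xi_s = rng.standard_normal(n)
    xi_w = rng.standard_normal(n)
    # walls reflect the heading, but the turn is executed continuously at a
    # bounded rate (the animal slides along the wall while turning): an
    # instantaneous heading flip would inject physically impossible
    # angular-velocity samples into every AHV-based analysis
    wall_turn_rate = 600.0  # deg/s
    target = None
    from ._circular import circ_diff_deg
    for i in range(n):
        speed[i] = s
        heading[i] = h
        x[i], y[i] = cx, cy
        # advance, clamping to the walls
        cx += s * np.cos(np.deg2rad(h)) * dt
        cy += s * np.sin(np.deg2rad(h)) * dt
        hit_x = cx < 0 or cx > p.arena_side
        hit_y = cy < 0 or cy > p.arena_side
        if (hit_x or hit_y) and target is None:
            tx = wrap_deg(180.0 - h) if hit_x else h
            target = wrap_deg(-tx) if hit_y else tx
        cx = min(max(cx, 0.0), p.arena_side)
        cy = min(max(cy, 0.0), p.arena_side)
        s += theta_s * (p.mean_speed - s) * dt + sd_s * np.sqrt(2 * theta_s * dt) * xi_s[i]
        s = abs(s)
        if sd_w > 0:
            w += -(w / tau_w) * dt + sd_w * np.sqrt(2 * dt / tau_w) * xi_w[i]
        if target is not None:
            d = float(circ_diff_deg(target, h))
            step = np.clip(d, -wall_turn_rate * dt, wall_turn_rate * dt)
            h = wrap_deg(h + step)
            if abs(d) <= wall_turn_rate * dt:
                target = None
        else:
            h = wrap_deg(h + w * dt)
    hd = heading
    if p.hd_jitter_sd > 0:
        hd = wrap_deg(heading + rng.normal(0, p.hd_jitter_sd, n))
    t = np.arange(n) * dt
    tr = TrackingSeries(t=t, x=x, y=y, hd=hd)
    return compute_kinematics(tr)


# --------------------------------------------------------------------- LFP

def simulate_lfp(tracking: TrackingSeries, p: ThetaLfpParams) -> LfpSeries:
    """Speed-modulated theta LFP at 250 Hz with continuous phase.

    v(t) = (a0 + beta_a * speed) * cos(2 pi integral f dt) + noise, with
    f(t) = f0 + beta_f * speed(t).
    """
    p.validate()
    if tracking.speed is None:
        raise ValueError("tracking kinematics not computed")
    rng = np.random.default_rng(p.seed)
    dt = 1.0 / LFP_HZ
    t = np.arange(tracking.t[0], tracking.t[-1] + TRACKING_DT - dt / 2, dt)
    speed = np.interp(t, tracking.t, np.nan_to_num(tracking.speed))
    f = p.f0 + p.beta_f * speed
    phase = 2 * np.pi * np.cumsum(f) * dt
    v = (p.a0 + p.beta_a * speed) * np.cos(phase)
    if p.noise_sd > 0:
        v = v + rng.normal(0, p.noise_sd, t.size)
    return LfpSeries(t=t, v=v)


# ------------------------------------------------------------------- cells

def _vm_factor(angle_deg, mu_deg, kappa):
    if kappa == 0:
        return np.ones_like(np.asarray(angle_deg, dtype=float))
    return np.exp(kappa * np.cos(np.deg2rad(angle_deg - mu_deg))) / i0(kappa)


def conditional_intensity(spec: CellSpec, tracking: TrackingSeries,
                          lfp: LfpSeries, dt_sim: float = 0.001,
                          hd_pref_series=None):
    """Evaluate lambda(t) on a fine grid; returns (t_grid, lam).

    `hd_pref_series`, when given, replaces the fixed preferred direction
    with a per-grid-sample series (used for programmed PFD drift).
    """
    spec.validate()
    if tracking.speed is None:
        raise ValueError("tracking kinematics not computed")
    tg = np.arange(tracking.t[0], tracking.t[-1], dt_sim)
    hd_at = interp_angle_deg(np.clip(tg + spec.ati, tracking.t[0], tracking.t[-1]),
                             tracking.t, np.nan_to_num(tracking.hd))
    mu_hd = spec.hd_pref if hd_pref_series is None else hd_pref_series
    lam = spec.r0 * _vm_factor(hd_at, mu_hd, spec.hd_kappa)
    if spec.place_field is not None:
        cx, cy, sig, gain = spec.place_field
        x = np.interp(tg, tracking.t, np.nan_to_num(tracking.x))
        y = np.interp(tg, tracking.t, np.nan_to_num(tracking.y))
        lam = lam * (1.0 + gain * np.exp(-((x - cx) ** 2 + (y - cy) ** 2)
                                         / (2 * sig**2)))
    needs_phase = spec.phase_kappa > 0 or spec.skip_depth > 0
    if needs_phase:
        _, _, _, unwrapped = instantaneous_theta(lfp)
        ph = np.interp(tg, lfp.t, unwrapped)
        # precession: the preferred phase regresses (spikes land progressively
        # earlier in the cycle), i.e. the cell's intrinsic oscillation runs
        # intrinsic_freq_offset Hz faster than the LFP
        mu_eff = spec.phase_pref - 360.0 * spec.intrinsic_freq_offset * (tg - tg[0])
        lam = lam * _vm_factor(np.mod(ph, 360.0), np.mod(mu_eff, 360.0),
                               spec.phase_kappa)
        if spec.skip_depth > 0:
            parity = np.floor(ph / 360.0).astype(int) % 2
            lam = lam * (1.0 - spec.skip_depth * parity)
    if spec.speed_gain != 0:
        sp = np.interp(tg, tracking.t, np.nan_to_num(tracking.speed))
        lam = lam * np.clip(1.0 + spec.speed_gain * sp, 0.0, None)
    if spec.ahv_gain != 0:
        av = np.abs(np.interp(tg, tracking.t, np.nan_to_num(tracking.ahv)))
        lam = lam * np.clip(1.0 + spec.ahv_gain * av, 0.0, None)
    return tg, lam


def simulate_cell(spec: CellSpec, tracking: TrackingSeries, lfp: LfpSeries,
                  seed: int = 0, dt_sim: float = 0.001) -> SpikeTrain:
    """Draw one spike train from the cell's conditional intensity.

    Spikes are sampled as a piecewise-constant inhomogeneous Poisson
    process on a 1-ms grid (bin counts Poisson(lambda dt), times jittered
    uniformly within bins), then bursts are appended.
    """
    rng = np.random.default_rng(seed)
    hd_pref_series = None
    if spec.pfd_drift_sd > 0:
        n_grid = np.arange(tracking.t[0], tracking.t[-1], dt_sim).size
        steps = rng.normal(0.0, spec.pfd_drift_sd * np.sqrt(dt_sim / 60.0), n_grid)
        hd_pref_series = spec.hd_pref + np.cumsum(steps)
    tg, lam = conditional_intensity(spec, tracking, lfp, dt_sim,
                                    hd_pref_series=hd_pref_series)
    # first-order compensation for refractory thinning (~lambda * 5 ms) so
    # r0 keeps its delivered-rate meaning
    lam = lam / max(1.0 - lam.mean() * 0.005, 0.5)
    counts = rng.poisson(lam * dt_sim)
    reps = counts[counts > 0]
    base = np.repeat(tg[counts > 0], reps)
    times = base + rng.uniform(0, dt_sim, base.size)
    # refractoriness: a 2-ms absolute dead time plus an exponential recovery
    # (tau ~ 3 ms). Without it the exponential ISI density is maximal at
    # zero lag and untuned Poisson cells read as "bursting" (modal ISI
    # < 6 ms) half the time.
    if times.size > 1:
        u = rng.random(times.size)
        keep = np.ones(times.size, dtype=bool)
        last = times[0]
        for i in range(1, times.size):
            gap = times[i] - last
            if gap < 0.002 or u[i] > 1.0 - np.exp(-(gap - 0.002) / 0.003):
                keep[i] = False
            else:
                last = times[i]
        times = times[keep]
    if spec.burst_prob > 0 and times.size:
        is_burst = rng.random(times.size) < spec.burst_prob
        extras = []
        n_extra = rng.integers(2, 5, size=int(is_burst.sum()))
        for t0, k in zip(times[is_burst], n_extra):
            extras.append(t0 + 0.004 * np.arange(1, k + 1))
        if extras:
            times = np.concatenate([times, np.concatenate(extras)])
    times = np.sort(times)
    times = times[(times >= tracking.t[0]) & (times <= tracking.t[-1] + TRACKING_DT)]
    waveform = None
    if spec.waveform_class is not None:
        waveform = waveform_template(spec.waveform_class, rng)
    return SpikeTrain(cell_id=spec.cell_id, times=times, waveform=waveform)


def waveform_template(wave_class: str, rng) -> np.ndarray:
    """Biphasic mean-waveform template (4 channels x 64 samples at 48 kHz).

    Peak-to-trough width is drawn from the class's Gaussian (narrow 200,
    intermediate 300, broad 400 us).
    """
    mu, sd = WAVEFORM_CLASS_US[wave_class]
    width_us = max(rng.normal(mu, sd), 90.0)
    n = 64
    ts = np.arange(n) / WAVEFORM_FS * 1e6  # us
    t_peak = 300.0
    t_trough = t_peak + width_us
    shape = (np.exp(-((ts - t_peak) ** 2) / (2 * 60.0**2))
             - 0.7 * np.exp(-((ts - t_trough) ** 2) / (2 * 110.0**2)))
    gains = np.array([1.0, 0.8, 0.5, 0.3]) * rng.uniform(0.8, 1.2)
    return gains[:, None] * shape[None, :] * 100.0


# ----------------------------------------------------------------- session

def simulate_session(specs, trajectory: TrajectoryParams = None,
                     lfp_params: ThetaLfpParams = None, n_trials: int = 2,
                     conditions=None, seed: int = 0):
    """Build a SessionBundle of `n_trials` trials plus a ground-truth manifest.

    Each trial gets an independent trajectory and LFP (seeded from `seed`);
    every cell keeps its CellSpec across trials, mirroring a real session
    where the same units are tracked over consecutive trials.
    """
    specs = list(specs)
    trajectory = trajectory or TrajectoryParams()
    lfp_params = lfp_params or ThetaLfpParams()
    conditions = conditions or ["light"] * n_trials
    ss = np.random.SeedSequence(seed)
    wf_rng = np.random.default_rng(ss.spawn(1)[0])
    # one mean waveform per unit, shared across trials of the session
    waveforms = {s.cell_id: (waveform_template(s.waveform_class, wf_rng)
                             if s.waveform_class else None) for s in specs}
    trial_seeds = ss.spawn(n_trials)
    trials = []
    for k in range(n_trials):
        sub = trial_seeds[k].spawn(2 + len(specs))
        tp = dataclasses.replace(trajectory,
                                 seed=int(sub[0].generate_state(1)[0] % (2**31)))
        lp = dataclasses.replace(lfp_params,
                                 seed=int(sub[1].generate_state(1)[0] % (2**31)))
        tr = simulate_trajectory(tp)
        lfp = simulate_lfp(tr, lp)
        spikes = []
        for i, s in enumerate(specs):
            train = simulate_cell(s, tr, lfp,
                                  seed=int(sub[2 + i].generate_state(1)[0] % (2**31)))
            train.waveform = waveforms[s.cell_id]
            spikes.append(train)
        trials.append(Trial(tracking=tr, lfp=lfp, spikes=spikes,
                            condition=conditions[k]))
    manifest = {s.cell_id: dataclasses.asdict(s) for s in specs}
    bundle = SessionBundle(trials=trials, arena_side=trajectory.arena_side,
                           metadata={"generator_seed": seed})
    return bundle, manifest


# ------------------------------------------------------- standard cohort

def archetype_spec(archetype: str, cell_id: str, rng) -> CellSpec:
    """One cell of a named archetype with mild parameter scatter.

    Archetypes mirror the four functional classes: ``place`` (compact
    Gaussian field, theta-locked, bursting), ``hd`` (sharply tuned,
    non-rhythmic, anticipatory), ``theta_hd`` (broadly tuned and
    theta-locked) and ``theta`` (phase-locked only).
    """
    mu_hd = float(rng.uniform(0, 360))
    mu_ph = float(rng.uniform(60, 180))
    if archetype == "place":
        cx, cy = rng.uniform(20, 70, size=2)
        return CellSpec(cell_id=cell_id, r0=float(rng.uniform(0.03, 0.05)),
                        place_field=(float(cx), float(cy),
                                     float(rng.uniform(6.5, 8.5)), 160.0),
                        phase_pref=mu_ph, phase_kappa=1.2,
                        burst_prob=0.35, speed_gain=0.02,
                        waveform_class="intermediate", archetype="place")
    if archetype == "hd":
        return CellSpec(cell_id=cell_id, r0=float(rng.uniform(3.5, 6.0)),
                        hd_pref=mu_hd, hd_kappa=float(rng.uniform(2.0, 3.5)),
                        ati=0.04, speed_gain=0.02,
                        waveform_class="narrow", archetype="hd")
    if archetype == "theta_hd":
        return CellSpec(cell_id=cell_id, r0=float(rng.uniform(2.0, 3.0)),
                        hd_pref=mu_hd, hd_kappa=float(rng.uniform(0.8, 1.2)),
                        phase_pref=mu_ph, phase_kappa=1.5,
                        burst_prob=0.25, speed_gain=0.02,
                        waveform_class="narrow", archetype="theta_hd")
    if archetype == "theta":
        return CellSpec(cell_id=cell_id, r0=float(rng.uniform(3.0, 5.0)),
                        phase_pref=mu_ph, phase_kappa=1.5,
                        burst_prob=0.2, speed_gain=0.02,
                        waveform_class="broad", archetype="theta")
    raise ValueError(f"unknown archetype {archetype!r}")


def standard_cohort(seed: int = 0, n_per_archetype: int = 10):
    """The 40-cell reference cohort: 10 cells per archetype."""
    rng = np.random.default_rng(seed)
    specs = []
    for arch in ("place", "hd", "theta_hd", "theta"):
        for i in range(n_per_archetype):
            specs.append(archetype_spec(arch, f"{arch}_{i:02d}", rng))
    return specs
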