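import numpy as np
import pytest
from scipy.optimize import minimize

from thetahd._circular import bessel_ratio
from thetahd.maps import (RateMap, circular_crosscorr, cross_trial_stability,
                          detect_place_fields, directional_tuning,
                          firing_area_fraction, locational_ratemap,
                          marginal_information, pxd_corrected_information,
                          pxd_factorize, pxd_factorize_counts, pxd_poisson_loglik,
                          selectivity, skaggs_information, sparsity)
from thetahd.session import TRACKING_DT, SpikeTrain, TrackingSeries, compute_kinematics
from thetahd.synthetic import CellSpec, simulate_cell


def _ratemap_from_surface(rate, dwell_s=1.0):
    dwell = np.full_like(rate, dwell_s)
    peak = np.unravel_index(np.nanargmax(rate), rate.shape)
    return RateMap(rate=rate, dwell=dwell, spikes=rate * dwell_s, bin_size=2.0,
                   mean_rate=float(np.nanmean(rate)), peak_rate=float(np.nanmax(rate)),
                   peak_bin=tuple(int(i) for i in peak))


def _gaussian_surface(nb=45, cx=45.0, cy=45.0, sigma=8.0, peak=10.0):
    ax = np.arange(nb) * 2.0 + 1.0
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    return peak * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


class TestRatemap:
    def test_homogeneous_cell_gives_flat_map(self, tracking, lfp, poisson_cell):
        _, s = poisson_cell
        rm = locational_ratemap(tracking, s)
        vis = ~np.isnan(rm.rate)
        # smoothing pools ~80 bins; allow a generous Poisson band around 5 Hz
        assert 4.0 < np.nanmean(rm.rate) < 6.0
        occ = rm.occupancy
        assert skaggs_information(occ[vis], rm.rate[vis]) < 0.1

    def test_point_mass_peak_bin(self, straight_tracking):
        # all spikes while the animal sits in one bin
        times = straight_tracking.t[100] + np.linspace(0, 0.015, 20)
        s = SpikeTrain("pt", times)
        rm = locational_ratemap(straight_tracking, s)
        expect = (int(straight_tracking.x[100] // 2), int(45.0 // 2))
        assert rm.peak_bin == expect

    def test_division_identity(self, tracking, place_cell):
        # rate * smoothed dwell == smoothed spikes wherever defined
        from scipy import ndimage
        from thetahd.maps import _truncated_gaussian_kernel
        _, s = place_cell
        rm = locational_ratemap(tracking, s)
        k = _truncated_gaussian_kernel()
        sm_dwell = ndimage.convolve(rm.dwell, k, mode="constant")
        sm_spk = ndimage.convolve(rm.spikes, k, mode="constant")
        vis = (sm_dwell > 0) & (rm.dwell > 0)
        np.testing.assert_allclose(rm.rate[vis] * sm_dwell[vis], sm_spk[vis],
                                   atol=1e-9)

    def test_place_cell_peak_near_programmed_center(self, tracking, place_cell):
        _, s = place_cell
        rm = locational_ratemap(tracking, s)
        px = rm.peak_bin[0] * 2 + 1.0
        py = rm.peak_bin[1] * 2 + 1.0
        # bin centers sit on a 2-cm grid, so 4 cm = two bins off
        assert np.hypot(px - 45.0, py - 45.0) <= 4.0

    def test_empty_trial_raises(self):
        n = 100
        tr = TrackingSeries(t=np.arange(n) * TRACKING_DT, x=np.full(n, np.nan),
                            y=np.full(n, np.nan), hd=np.zeros(n))
        with pytest.raises(ValueError, match="empty trial"):
            locational_ratemap(tr, SpikeTrain("x", np.array([0.5])))


class TestTuning:
    def test_uniform_firing_low_r(self, tracking, lfp, poisson_cell):
        _, s = poisson_cell
        tc = directional_tuning(tracking, s)
        assert tc.R < 0.05
        assert not tc.insufficient_sampling

    def test_point_mass_direction(self):
        # uniform dwell over hd, all spikes while facing 90 +/- 3 deg
        n = 18000
        t = np.arange(n) * TRACKING_DT
        hd = np.mod(np.linspace(0, 360 * 20, n), 360.0)
        tr = compute_kinematics(TrackingSeries(
            t=t, x=np.full(n, 45.0), y=np.full(n, 45.0), hd=hd))
        sel = np.abs((hd - 90 + 180) % 360 - 180) < 3.0
        s = SpikeTrain("pm", t[sel])
        tc = directional_tuning(tr, s)
        # the 5-bin boxcar caps R at ~0.989 even for a point mass and
        # spreads the peak over a plateau of up to 1.5 bins
        assert tc.R > 0.98
        assert abs(tc.pfd - 90.0) <= 9.0

    def test_r_matches_bessel_for_kappa4(self, tracking, lfp):
        s = simulate_cell(CellSpec(cell_id="k4", r0=5.0, hd_pref=30.0, hd_kappa=4.0),
                          tracking, lfp, seed=14)
        tc = directional_tuning(tracking, s)
        assert tc.R == pytest.approx(bessel_ratio(4.0), abs=0.05)

    def test_r_invariant_under_global_rotation(self, tracking, hd_cell):
        _, s = hd_cell
        tc1 = directional_tuning(tracking, s)
        rot = TrackingSeries(t=tracking.t, x=tracking.x, y=tracking.y,
                             hd=np.mod(tracking.hd + 120.0, 360.0),
                             speed=tracking.speed, ahv=tracking.ahv)
        tc2 = directional_tuning(rot, s)
        assert tc2.R == pytest.approx(tc1.R, abs=1e-6)
        assert tc2.width == pytest.approx(tc1.width, abs=1e-4)


class TestInformationMetrics:
    def test_skaggs_closed_forms(self):
        assert skaggs_information([0.25] * 4, [5.0] * 4) == pytest.approx(0.0)
        assert skaggs_information([0.5, 0.5], [2.0, 0.0]) == pytest.approx(1.0)
        assert skaggs_information([0.25] * 4, [4.0, 0, 0, 0]) == pytest.approx(2.0)

    def test_skaggs_nonnegative_random(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.dirichlet(np.ones(20))
            lam = rng.gamma(1.0, 2.0, 20)
            assert skaggs_information(p, lam) >= -1e-12

    def test_sparsity_closed_forms(self):
        assert sparsity([0.1] * 10, [3.0] * 10) == pytest.approx(1.0)
        lam = np.zeros(10)
        lam[0] = 7.0
        assert sparsity([0.1] * 10, lam) == pytest.approx(0.1)

    def test_sparsity_of_compact_field_surface(self):
        # Gaussian field whose 20%-of-peak contour covers ~15% of the arena:
        # pi sigma^2 2 ln5 / 8100 = 0.15 at sigma = 11 cm
        rate = _gaussian_surface(sigma=11.0)
        nb = rate.shape[0]
        sp = sparsity(np.full(nb * nb, 1 / nb**2), rate.ravel())
        assert 0.1 <= sp <= 0.25

    def test_selectivity(self):
        rm = _ratemap_from_surface(np.full((45, 45), 2.0))
        assert selectivity(rm) == pytest.approx(1.0)
        rm2 = _ratemap_from_surface(_gaussian_surface())
        assert selectivity(rm2) > 5.0

    def test_firing_area_fraction_diagnostic(self):
        rate = np.zeros((45, 45))
        rate[:9, :5] = 3.0
        rm = _ratemap_from_surface(rate)
        assert firing_area_fraction(rm) == pytest.approx(45 / 2025)

    def test_silent_cell_raises(self):
        with pytest.raises(ValueError, match="silent"):
            skaggs_information([0.5, 0.5], [0.0, 0.0])


class TestPlaceFields:
    def test_low_peak_map_has_no_fields(self):
        rm = _ratemap_from_surface(np.full((45, 45), 0.5))
        assert detect_place_fields(rm) == []

    def test_gaussian_bump_area_matches_analytic_contour(self):
        rm = _ratemap_from_surface(_gaussian_surface(sigma=8.0, peak=10.0))
        fields = detect_place_fields(rm)
        assert len(fields) == 1
        analytic = np.pi * (8.0 * np.sqrt(2 * np.log(5))) ** 2
        assert fields[0].area == pytest.approx(analytic, rel=0.25)

    def test_two_bumps_two_fields(self):
        surface = (_gaussian_surface(cx=25, cy=45, sigma=6, peak=10)
                   + _gaussian_surface(cx=65, cy=45, sigma=6, peak=10))
        fields = detect_place_fields(_ratemap_from_surface(surface))
        assert len(fields) == 2

    def test_small_blob_rejected(self):
        rate = np.zeros((45, 45))
        rate[20:22, 20:22] = 10.0  # 4 pixels < 9
        assert detect_place_fields(_ratemap_from_surface(rate)) == []


@pytest.fixture(scope="module")
def long_session():
    # the residual information after pxd correction is a Poisson noise floor
    # (~n_bins / 2 ln2 N bits), so isolating the sampling-bias artifact
    # needs a spike-rich session
    from thetahd.synthetic import (ThetaLfpParams, TrajectoryParams,
                                   simulate_lfp, simulate_trajectory)
    tr = simulate_trajectory(TrajectoryParams(seed=51, duration=960.0))
    return tr, simulate_lfp(tr, ThetaLfpParams(seed=52))


def _exhaustive_pxd_ml(n, t):
    """Direct numerical maximization of the Poisson likelihood (oracle)."""
    npos, ndir = n.shape
    p0 = np.full(npos, n.sum() / t.sum())
    d0 = np.ones(ndir)

    def negll(logpd):
        p = np.exp(logpd[:npos])
        d = np.exp(logpd[npos:])
        return -pxd_poisson_loglik(n, t, p, d)

    res = minimize(negll, np.log(np.concatenate([p0, d0]) + 1e-9),
                   method="L-BFGS-B", options={"maxiter": 5000, "ftol": 1e-14})
    p = np.exp(res.x[:npos])
    d = np.exp(res.x[npos:])
    scale = d.mean()
    return p * scale, d / scale


class TestPxd:
    def test_matches_exhaustive_ml_on_toy_grid(self):
        rng = np.random.default_rng(0)
        npos, ndir = 64, 12
        p_true = rng.gamma(2.0, 2.0, npos)
        d_true = rng.gamma(3.0, 0.4, ndir)
        d_true /= d_true.mean()
        t = rng.uniform(0.5, 2.0, (npos, ndir))
        n = rng.poisson(np.outer(p_true, d_true) * t)
        model = pxd_factorize_counts(n, t)
        p_ref, d_ref = _exhaustive_pxd_ml(n, t)
        np.testing.assert_allclose(np.outer(model.p, model.d),
                                   np.outer(p_ref, d_ref), rtol=2e-3)
        assert model.converged

    def test_loglik_nondecreasing_every_iteration(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0.2, 1.0, (16, 12))
        n = rng.poisson(2.0 * t)
        model = pxd_factorize_counts(n, t)
        assert np.all(np.diff(model.loglik_trace) >= -1e-9)

    def test_total_expected_spikes_matches(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(0.2, 1.0, (16, 12))
        n = rng.poisson(3.0 * t)
        model = pxd_factorize_counts(n, t)
        ok = ~np.isnan(model.p)
        okd = ~np.isnan(model.d)
        expected = np.outer(model.p[ok], model.d[okd]) * model.t[np.ix_(ok, okd)]
        assert expected.sum() == pytest.approx(model.n.sum(), rel=1e-3)

    def test_directional_cell_loses_locational_information(self, long_session):
        tr, lfp = long_session
        s = simulate_cell(CellSpec(cell_id="hd", r0=10.0, hd_pref=200.0,
                                   hd_kappa=3.0), tr, lfp, seed=21)
        model = pxd_factorize(tr, s)
        corrected = pxd_corrected_information(model)
        uncorrected = marginal_information(tr, s)
        assert corrected["loc_info"] < 0.15 * uncorrected["loc_info"]

    def test_locational_cell_loses_directional_information(self):
        # orbiting behavior: heading is tangential to position, so a purely
        # locational cell picks up large spurious directional information,
        # which the factorization removes
        from thetahd.session import compute_kinematics
        from thetahd.synthetic import ThetaLfpParams, simulate_lfp
        rng = np.random.default_rng(7)
        n = 48000
        t = np.arange(n) * TRACKING_DT
        theta = 0.4 * t + np.cumsum(rng.normal(0, 0.02, n))
        radius = 30 + 8 * np.sin(0.05 * t)
        x = 45 + radius * np.cos(theta)
        y = 45 + radius * np.sin(theta)
        hd = np.mod(np.rad2deg(theta) + 90 + rng.normal(0, 10, n), 360.0)
        tr = compute_kinematics(TrackingSeries(t=t, x=x, y=y, hd=hd))
        lfp = simulate_lfp(tr, ThetaLfpParams(seed=3))
        s = simulate_cell(CellSpec(cell_id="pl", r0=0.5,
                                   place_field=(75.0, 45.0, 8.0, 100.0)),
                          tr, lfp, seed=23)
        model = pxd_factorize(tr, s)
        corrected = pxd_corrected_information(model)
        uncorrected = marginal_information(tr, s)
        assert corrected["dir_info"] < 0.35 * uncorrected["dir_info"]
        # and the place field itself survives the correction
        assert corrected["loc_info"] > 0.5 * uncorrected["loc_info"]

    def test_conjunctive_cell_recovers_both_factors(self, tracking, lfp):
        spec = CellSpec(cell_id="conj", r0=0.6, hd_pref=140.0, hd_kappa=1.5,
                        place_field=(40.0, 50.0, 12.0, 20.0))
        s = simulate_cell(spec, tracking, lfp, seed=31)
        model = pxd_factorize(tracking, s)
        # generative factors on the same grids
        from thetahd.maps import pxd_counts
        _, t = pxd_counts(tracking, s)
        ax = np.arange(8) * (90 / 8) + 90 / 16
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        gen_p = (1 + 20.0 * np.exp(-((xx - 40) ** 2 + (yy - 50) ** 2)
                                   / (2 * 12.0**2))).ravel()
        centers = np.arange(60) * 6.0 + 3.0
        gen_d = np.exp(1.5 * np.cos(np.deg2rad(centers - 140.0)))
        okp = ~np.isnan(model.p)
        okd = ~np.isnan(model.d)
        assert np.corrcoef(model.p[okp], gen_p[okp])[0, 1] > 0.8
        assert np.corrcoef(model.d[okd], gen_d[okd])[0, 1] > 0.8


class TestStability:
    def test_identical_curves_r1(self, tracking, hd_cell):
        _, s = hd_cell
        tc = directional_tuning(tracking, s)
        out = cross_trial_stability(tc, tc)
        assert out["r0"] == pytest.approx(1.0)

    def test_rotation_recovered_at_lag(self, tracking, hd_cell):
        _, s = hd_cell
        tc = directional_tuning(tracking, s)
        rotated = np.roll(tc.rates, 15)  # 90 degrees
        lags, rs = circular_crosscorr(rotated, tc.rates)
        assert lags[int(np.argmax(rs))] == pytest.approx(90.0)

    def test_two_realizations_beat_shuffle_null(self, tracking, lfp):
        spec = CellSpec(cell_id="s", r0=5.0, hd_pref=250.0, hd_kappa=2.0)
        s1 = simulate_cell(spec, tracking, lfp, seed=41)
        s2 = simulate_cell(spec, tracking, lfp, seed=42)
        a = directional_tuning(tracking, s1)
        b = directional_tuning(tracking, s2)
        out = cross_trial_stability(a, b, tracking_b=tracking, spikes_b=s2,
                                    n_shuffles=100, seed=0)
        assert out["r0"] > out["null95"]

    def test_degenerate_curve_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            circular_crosscorr(np.ones(60), np.ones(60))
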