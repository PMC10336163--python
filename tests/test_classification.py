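import numpy as np
import pytest
from scipy.optimize import linprog

from thetahd.classification import (CellReport, _dip_statistic, burst_metrics,
                                    circular_shift, classify_cell,
                                    classify_session_cell, dip_test,
                                    ic_metric, shuffle_null, tuning_r_metric,
                                    waveform_population_clustering, waveform_width)
from thetahd.session import SpikeTrain
from thetahd.synthetic import (CellSpec, simulate_cell, standard_cohort,
                               waveform_template)
from thetahd.theta import instantaneous_theta


def _dip_lp_oracle(x):
    """Dip by definition: bisection on the band half-width d, feasibility of a
    convex-then-concave CDF through the ECDF band checked per mode split by
    linear programming. Independent of the hull-sweep implementation."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    lo_d, hi_d = 0.0, 0.5

    def feasible(d):
        L = (np.arange(n) + 1) / n - d
        U = np.arange(n) / n + d
        for k in range(-1, n):
            ok = True
            # convex prefix 0..k
            if k >= 2:
                A, b = [], []
                for i in range(1, k):
                    row = np.zeros(k + 1)
                    # convexity: second difference >= 0 (as -2nd diff <= 0)
                    row[i - 1] = -(x[i + 1] - x[i])
                    row[i] = (x[i + 1] - x[i - 1])
                    row[i + 1] = -(x[i] - x[i - 1])
                    A.append(row)
                    b.append(0.0)
                res = linprog(np.zeros(k + 1), A_ub=np.asarray(A), b_ub=b,
                              bounds=list(zip(L[:k + 1], U[:k + 1])),
                              method="highs")
                ok = ok and res.status == 0
            elif k >= 0:
                ok = ok and np.all(L[:k + 1] <= U[:k + 1])
            # concave suffix k+1..n-1
            m = n - (k + 1)
            if ok and m >= 3:
                A, b = [], []
                xs = x[k + 1:]
                for i in range(1, m - 1):
                    row = np.zeros(m)
                    row[i - 1] = (xs[i + 1] - xs[i])
                    row[i] = -(xs[i + 1] - xs[i - 1])
                    row[i + 1] = (xs[i] - xs[i - 1])
                    A.append(row)
                    b.append(0.0)
                res = linprog(np.zeros(m), A_ub=np.asarray(A), b_ub=b,
                              bounds=list(zip(L[k + 1:], U[k + 1:])),
                              method="highs")
                ok = ok and res.status == 0
            elif ok and m > 0:
                ok = ok and np.all(L[k + 1:] <= U[k + 1:])
            if ok:
                return True
        return False

    for _ in range(30):
        mid = (lo_d + hi_d) / 2
        if feasible(mid):
            hi_d = mid
        else:
            lo_d = mid
    return hi_d


class TestDipStatistic:
    def test_matches_lp_oracle_on_random_samples(self):
        rng = np.random.default_rng(0)
        for k in range(6):
            if k % 2 == 0:
                x = rng.normal(0, 1, 14)
            else:
                x = np.concatenate([rng.normal(0, 0.3, 7), rng.normal(4, 0.3, 7)])
            dip = _dip_statistic(x)
            oracle = _dip_lp_oracle(x)
            assert dip == pytest.approx(oracle, abs=2e-3)

    def test_known_values(self):
        n = 100
        grid = (np.arange(n) + 0.5) / n
        assert _dip_statistic(grid) == pytest.approx(1 / (2 * n), abs=1e-9)
        assert _dip_statistic([0.0, 1.0]) == pytest.approx(0.25)

    def test_invariant_to_affine_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200)
        assert _dip_statistic(3.5 * x - 7.0) == pytest.approx(
            _dip_statistic(x), abs=1e-12)

    def test_bimodal_exceeds_unimodal(self):
        rng = np.random.default_rng(2)
        uni = rng.normal(0, 1, 300)
        bim = np.concatenate([rng.normal(0, 1, 150), rng.normal(6, 1, 150)])
        assert _dip_statistic(bim) > 3 * _dip_statistic(uni)

    def test_calibrated_test_rejects_bimodal(self):
        rng = np.random.default_rng(3)
        bim = np.concatenate([rng.normal(200, 20, 150), rng.normal(400, 20, 150)])
        _, p = dip_test(bim, n_boot=200, seed=0)
        assert p < 0.01

    def test_calibrated_test_accepts_unimodal(self):
        rng = np.random.default_rng(4)
        rejected = 0
        for seed in range(10):
            x = rng.normal(300, 40, 300)
            _, p = dip_test(x, n_boot=200, seed=seed)
            rejected += p <= 0.05
        assert rejected <= 1


class TestShuffleNull:
    def test_circular_shift_preserves_counts_and_isis(self, poisson_cell):
        _, s = poisson_cell
        shifted = circular_shift(s.times, 480.0, 133.7)
        assert shifted.size == s.times.size
        assert np.all((shifted >= 0) & (shifted <= 480.0))
        isi_a = np.sort(np.diff(np.sort(s.times)))
        isi_b = np.sort(np.diff(shifted))
        # the multiset of ISIs matches except at the single wrap point
        matches = np.isin(np.round(isi_b, 9), np.round(isi_a, 9))
        assert matches.sum() >= isi_b.size - 2

    def test_strong_hd_cell_beats_null(self, tracking, lfp):
        s = simulate_cell(CellSpec(cell_id="k4", r0=5.0, hd_pref=10.0,
                                   hd_kappa=4.0), tracking, lfp, seed=17)
        metric = tuning_r_metric(tracking)
        null = shuffle_null(metric, s, tracking.duration, n_shuffles=200, seed=0)
        assert metric(s.times) > null.p99

    def test_poisson_cell_below_null(self, tracking, lfp, poisson_cell):
        _, s = poisson_cell
        metric = tuning_r_metric(tracking)
        null = shuffle_null(metric, s, tracking.duration, n_shuffles=200, seed=0)
        assert metric(s.times) < null.p99

    def test_thresholds_reproducible_and_seed_stable(self, tracking, poisson_cell):
        _, s = poisson_cell
        metric = tuning_r_metric(tracking)
        a = shuffle_null(metric, s, tracking.duration, n_shuffles=300, seed=5)
        b = shuffle_null(metric, s, tracking.duration, n_shuffles=300, seed=5)
        c = shuffle_null(metric, s, tracking.duration, n_shuffles=300, seed=6)
        assert a.p99 == b.p99
        assert c.p99 == pytest.approx(a.p99, rel=0.1)

    def test_short_trial_rejected(self, tracking, poisson_cell):
        _, s = poisson_cell
        with pytest.raises(ValueError):
            shuffle_null(tuning_r_metric(tracking), s, 30.0, n_shuffles=10, seed=0)


class TestClassifyCell:
    BASE = dict(ic=0.02, ic_null99=0.05, ir=0.0, tuning_r=0.05, r_null99=0.12,
                dir_peak_rate=5.0, mean_rate=4.0, loc_peak_rate=6.0,
                loc_info=0.2, loc_sparsity=0.6)

    def test_theta_only(self):
        rep = classify_cell("a", **{**self.BASE, "ic": 0.3, "ir": 0.02})
        assert rep.label == "theta" and rep.theta_modulated

    def test_nonrhythmic_hd(self):
        rep = classify_cell("b", **{**self.BASE, "tuning_r": 0.5,
                                    "dir_peak_rate": 20.0})
        assert rep.label == "hd" and not rep.theta_modulated

    def test_conjunctive(self):
        rep = classify_cell("c", **{**self.BASE, "ic": 0.3, "ir": 0.02,
                                    "tuning_r": 0.5})
        assert rep.label == "theta_hd"

    def test_place_takes_precedence_and_keeps_flags(self):
        rep = classify_cell("d", **{**self.BASE, "ic": 0.3, "ir": 0.02,
                                    "mean_rate": 1.0, "loc_info": 1.2,
                                    "loc_sparsity": 0.12})
        assert rep.label == "place"
        assert rep.theta_modulated  # conjunction preserved as a flag

    def test_theta_requires_rhythmicity(self):
        rep = classify_cell("e", **{**self.BASE, "ic": 0.3, "ir": -0.01})
        assert rep.label == "unclassified"

    def test_hd_requires_peak_rate(self):
        rep = classify_cell("f", **{**self.BASE, "tuning_r": 0.5,
                                    "dir_peak_rate": 0.5})
        assert rep.label == "unclassified"

    def test_missing_metric_rejected(self):
        with pytest.raises(ValueError, match="incomplete inputs"):
            classify_cell("g", **{**self.BASE, "ic": float("nan")})

    def test_deterministic(self):
        a = classify_cell("h", **self.BASE)
        b = classify_cell("h", **self.BASE)
        assert a == b


class TestBurstMetrics:
    def test_regular_train_not_bursting(self):
        s = SpikeTrain("r", np.arange(0, 48, 0.1))
        out = burst_metrics(s)
        assert out["peak_isi_ms"] == pytest.approx(101.0, abs=2.0)
        assert not out["bursting"]
        assert out["burst_index"] == 0.0

    def test_generator_bursts_detected(self, tracking, lfp):
        s = simulate_cell(CellSpec(cell_id="b", r0=5.0, burst_prob=0.6),
                          tracking, lfp, seed=26)
        out = burst_metrics(s)
        assert out["bursting"]
        assert out["burst_index"] > 0.3

    def test_poisson_rarely_bursting(self, tracking, lfp):
        hits = 0
        for seed in range(10):
            s = simulate_cell(CellSpec(cell_id="p", r0=5.0), tracking, lfp,
                              seed=4000 + seed)
            hits += burst_metrics(s)["bursting"]
        assert hits == 0

    def test_burst_index_monotone_in_burst_prob(self, tracking, lfp):
        vals = []
        for prob in (0.0, 0.2, 0.4, 0.6):
            s = simulate_cell(CellSpec(cell_id="m", r0=5.0, burst_prob=prob),
                              tracking, lfp, seed=27)
            vals.append(burst_metrics(s)["burst_index"])
        assert all(0 <= v <= 1 for v in vals)
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestWaveforms:
    def test_width_arithmetic(self):
        w = np.zeros((1, 64))
        w[0, 20] = 1.0
        w[0, 32] = -0.7
        assert waveform_width(w) == pytest.approx(250.0)  # 12 / 48 kHz in us

    def test_inverted_discarded(self):
        w = np.zeros((1, 64))
        w[0, 20] = -1.0
        w[0, 32] = 0.7
        assert waveform_width(w) is None

    def test_flat_discarded(self):
        assert waveform_width(np.zeros((4, 64))) is None

    def test_template_classes_ordered(self):
        rng = np.random.default_rng(5)
        widths = {c: [waveform_width(waveform_template(c, rng)) for _ in range(30)]
                  for c in ("narrow", "intermediate", "broad")}
        assert np.mean(widths["narrow"]) < 250.0
        assert np.mean(widths["narrow"]) < np.mean(widths["intermediate"])
        assert np.mean(widths["intermediate"]) < np.mean(widths["broad"])

    def test_population_clustering_recovers_mixture(self):
        rng = np.random.default_rng(6)
        w = np.concatenate([rng.normal(200, 20, 150), rng.normal(400, 20, 150)])
        out = waveform_population_clustering(w, seed=0, n_boot=200)
        assert out.dip_p < 0.01
        counts = {c: out.classes.count(c) for c in set(out.classes)}
        assert abs(counts.get("narrow", 0) - 150) <= 30
        assert abs(counts.get("broad", 0) - 150) <= 30
        assert out.cutoff_narrow < out.cutoff_broad
        # symmetric mixture: cutoffs bracket the midpoint
        assert out.cutoff_narrow < 300.0 < out.cutoff_broad

    def test_single_gaussian_rarely_rejected(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for seed in range(10):
            w = rng.normal(300, 40, 200)
            out = waveform_population_clustering(w, seed=seed, n_boot=100)
            rejections += out.dip_p <= 0.05
        assert rejections <= 1

    def test_too_few_widths_rejected(self):
        with pytest.raises(ValueError):
            waveform_population_clustering(np.arange(10.0))


def test_single_cell_pipeline_labels_each_archetype(tracking, lfp):
    rng = np.random.default_rng(99)
    from thetahd.synthetic import archetype_spec
    expected = {"place": "place", "hd": "hd", "theta_hd": "theta_hd",
                "theta": "theta"}
    for arch, label in expected.items():
        spec = archetype_spec(arch, arch, rng)
        s = simulate_cell(spec, tracking, lfp, seed=hash(arch) % 1000)
        rep = classify_session_cell(s, tracking, lfp, n_shuffles=200, seed=1)
        assert rep.label == label, f"{arch} mislabelled as {rep.label}"
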