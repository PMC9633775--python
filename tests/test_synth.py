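"""Generator tests: planted maps, arousal process, scans, pupil, tracing, expression."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import dyngrad as dg
from dyngrad.synth import modulation_weight


class TestSpatialMaps:
    def test_orthonormal_columns(self):
        maps, coords = dg.make_spatial_maps(50, 2, 0.3, seed=11)
        assert abs(maps[:, 0] @ maps[:, 1]) < 1e-10
        assert np.allclose(np.linalg.norm(maps, axis=0), 1.0)
        assert coords.shape == (50, 2)
        assert coords.min() >= 0 and coords.max() <= 1

    def test_no_smoothing_limit_is_white(self):
        # smoothness → 0: neighbours are uncorrelated
        maps, coords = dg.make_spatial_maps(400, 1, 1e-4, seed=3)
        x = maps[:, 0]
        order = np.argsort(coords[:, 0])
        lag1 = np.corrcoef(x[order][:-1], x[order][1:])[0, 1]
        assert abs(lag1) < 0.15

    def test_variogram_increases_with_distance(self):
        """Smooth maps: semivariance grows with lag (brute-force variogram)."""
        maps, coords = dg.make_spatial_maps(150, 1, 0.3, seed=5)
        x = maps[:, 0] * np.sqrt(150)
        d = squareform(pdist(coords))
        iu = np.triu_indices(150, 1)
        dist, sq = d[iu], 0.5 * (x[iu[0]] - x[iu[1]]) ** 2
        edges = np.quantile(dist, [0, 0.25, 0.5, 0.75, 1])
        gammas = [
            sq[(dist >= lo) & (dist <= hi)].mean() for lo, hi in zip(edges[:-1], edges[1:])
        ]
        assert gammas[0] < gammas[1] < gammas[3]

    def test_rank_error(self):
        with pytest.raises(ValueError, match="rank"):
            dg.make_spatial_maps(10, 10, 0.3, seed=0)


class TestArousalProcess:
    def test_bounds_and_determinism(self):
        a = dg.make_arousal_process(2000, 0.9, seed=4)
        assert a.min() >= 0 and a.max() <= 1
        assert np.array_equal(a, dg.make_arousal_process(2000, 0.9, seed=4))
        assert not np.array_equal(a, dg.make_arousal_process(2000, 0.9, seed=5))

    def test_zero_persistence_uncorrelated(self):
        a = dg.make_arousal_process(5000, 0.0, seed=1)
        assert abs(np.corrcoef(a[:-1], a[1:])[0, 1]) < 0.05

    def test_lag1_autocorrelation_matches_monte_carlo(self):
        """Transformed AR(1) lag-1 autocorr vs a direct Monte-Carlo oracle."""
        rng = np.random.default_rng(123)
        phi, n = 0.95, 5000
        # oracle: simulate the same law independently
        sd0 = 1 / np.sqrt(1 - phi**2)
        x = np.zeros(200_000)
        x[0] = rng.standard_normal() * sd0
        eps = rng.standard_normal(x.size)
        for t in range(1, x.size):
            x[t] = phi * x[t - 1] + eps[t]
        oracle = 1 / (1 + np.exp(-x / sd0))
        rho_oracle = np.corrcoef(oracle[:-1], oracle[1:])[0, 1]
        a = dg.make_arousal_process(n, phi, seed=2)
        rho = np.corrcoef(a[:-1], a[1:])[0, 1]
        assert abs(rho - rho_oracle) < 0.05

    def test_invalid_persistence(self):
        with pytest.raises(ValueError):
            dg.make_arousal_process(100, 1.0, seed=0)


class TestTimeseries:
    def test_static_fc_converges_to_target(self):
        """Law of large numbers: sample FC → planted static correlation."""
        truth = dg.make_ground_truth(n_regions=6, mod_amplitude=0.0, seed=9)
        dg.make_expression(truth, 8, 2, 0.5, seed=10)
        a = np.full(20000, 0.5)
        ts = dg.make_timeseries(truth, 20000, 2.0, 0.0, seed=11, arousal=a, template_gain=0.0)
        fc = dg.compute_fc(ts).values
        target = truth.sc_sim * truth.weights[1] + (1 - truth.weights[1]) * np.eye(6)
        assert np.linalg.norm(fc - target, "fro") < 0.05

    def test_constant_arousal_zero_mean(self):
        truth = dg.make_ground_truth(n_regions=15, seed=1)
        dg.make_expression(truth, 6, 2, 0.5, seed=2)
        a = np.full(3000, 0.5)
        ts = dg.make_timeseries(truth, 3000, 2.0, 0.0, seed=3, arousal=a)
        assert np.abs(ts.data.mean(axis=0)).max() < 0.1

    def test_seed_contract(self):
        truth = dg.make_ground_truth(n_regions=12, seed=5)
        dg.make_expression(truth, 6, 2, 0.5, seed=6)
        a = dg.make_arousal_process(50, 0.9, 7)
        t1 = dg.make_timeseries(truth, 50, 2.0, 0.2, seed=8, arousal=a)
        t2 = dg.make_timeseries(truth, 50, 2.0, 0.2, seed=8, arousal=a)
        t3 = dg.make_timeseries(truth, 50, 2.0, 0.2, seed=9, arousal=a)
        assert np.array_equal(t1.data, t2.data)
        assert not np.array_equal(t1.data, t3.data)

    def test_frame_correlations_are_valid(self, small_truth):
        """Every cached frame correlation target is PSD with unit diagonal."""
        w = small_truth.weights
        for wq in (0.0, 0.1, 0.3):
            r = w[1] * small_truth.sc_sim + wq * small_truth.ns_sim + (1 - w[1] - wq) * np.eye(30)
            assert np.allclose(np.diag(r), 1)
            assert np.linalg.eigvalsh(r).min() >= -1e-10


class TestPupil:
    def test_noiseless_median_recovers_arousal(self):
        a = np.array([0.2, 0.4, 0.6, 0.8])
        p = dg.make_pupil(a, tr=2.0, fps=6, noise_sd=0.0, blink_rate=0.0, seed=0)
        assert p.size == 4 * 12
        med = np.nanmedian(p.reshape(4, 12), axis=1)
        assert np.allclose(med, a)

    def test_blink_fraction_matches_counting_oracle(self):
        a = np.full(2000, 0.7)
        rate = 0.2
        p = dg.make_pupil(a, tr=2.0, fps=6, noise_sd=0.0, blink_rate=rate, seed=1)
        frac = np.mean(np.isnan(p))
        # oracle: expected missing ≈ rate × duration × mean gap / n_samples
        mean_gap = (1 + int(0.5 * 6)) / 2
        expected = min(1.0, rate * (p.size / 6) * mean_gap / p.size)
        assert abs(frac - expected) < 0.015

    def test_non_integer_samples_per_frame_rejected(self):
        with pytest.raises(ValueError):
            dg.make_pupil(np.ones(5), tr=0.7, fps=6, noise_sd=0, blink_rate=0, seed=0)


class TestTracing:
    def test_shape_and_positivity(self, small_truth):
        m = dg.make_tracing(30, 12, small_truth.coords, decay=1.0, seed=3)
        assert m.weights.shape == (30, 12)
        assert (m.weights > 0).all()

    def test_decay_strengthens_distance_coupling(self):
        """Monte-Carlo trend: larger decay → more negative corr(log w, distance)."""
        from scipy.spatial.distance import cdist

        cors = {0.0: [], 2.0: []}
        for seed in range(25):
            rng = np.random.default_rng(seed)
            coords = rng.uniform(0, 1, (40, 2))
            for decay in cors:
                m = dg.make_tracing(40, 20, coords, decay=decay, seed=seed + 100)
                tidx = [int(t[1:]) for t in m.target_labels]
                d = cdist(coords, coords[tidx])
                cors[decay].append(np.corrcoef(np.log(m.weights).ravel(), d.ravel())[0, 1])
        assert abs(np.mean(cors[0.0])) < 0.1
        assert np.mean(cors[2.0]) < np.mean(cors[0.0]) - 0.3


class TestExpression:
    def test_noiseless_loading_gives_perfect_correlation(self):
        truth = dg.make_ground_truth(n_regions=40, seed=2)
        loadings = np.zeros((4, truth.gradient_maps.shape[1]))
        loadings[0, 0] = 1.0
        e = dg.make_expression(truth, 4, 3, noise_sd=0.0, seed=3, loadings=loadings)
        r = np.corrcoef(e.values[0], truth.gradient_maps[:, 0])[0, 1]
        assert abs(r) > 1 - 1e-10

    def test_equal_loadings_give_equal_correlations(self):
        truth = dg.make_ground_truth(n_regions=40, seed=2)
        loadings = np.zeros((3, truth.gradient_maps.shape[1]))
        loadings[0, :2] = 1 / np.sqrt(2)
        e = dg.make_expression(truth, 3, 2, noise_sd=0.0, seed=3, loadings=loadings)
        r1 = abs(np.corrcoef(e.values[0], truth.gradient_maps[:, 0])[0, 1])
        r2 = abs(np.corrcoef(e.values[0], truth.gradient_maps[:, 1])[0, 1])
        assert abs(r1 - r2) < 0.05

    def test_null_receptors_decorrelated_from_maps(self):
        """Null receptors with unstructured noise: |corr with planted maps| < 0.2 in ≥95% of seeds."""
        hits = 0
        trials = 40
        for seed in range(trials):
            truth = dg.make_ground_truth(n_regions=200, seed=seed)
            e = dg.make_expression(
                truth, 6, 2, noise_sd=0.5, seed=seed + 1000, noise_smoothness=0.02
            )
            nulls = e.values[e.truth_groups == 4]
            ok = all(
                abs(np.corrcoef(row, truth.gradient_maps[:, k])[0, 1]) < 0.2
                for row in nulls
                for k in range(2)
            )
            hits += ok
        assert hits / trials >= 0.95

    def test_smooth_null_receptors_less_coupled_than_loaded(self, small_cohort):
        """With smooth expression noise, loaded receptors still out-correlate nulls."""
        e = small_cohort.expression
        maps = small_cohort.truth.gradient_maps
        best = lambda row: max(abs(np.corrcoef(row, maps[:, k])[0, 1]) for k in range(2))
        loaded = [best(r) for r, g in zip(e.values, e.truth_groups) if g != 4]
        nulls = [best(r) for r, g in zip(e.values, e.truth_groups) if g == 4]
        assert np.median(loaded) > np.median(nulls)

    def test_null_rows_have_exactly_zero_loading(self, small_cohort):
        groups = small_cohort.expression.truth_groups
        loads = small_cohort.truth.receptor_loadings
        assert np.all(loads[groups == 4] == 0)
        assert np.all(np.any(loads[groups != 4] != 0, axis=1))


class TestCohort:
    def test_cohort_determinism(self):
        c1 = dg.make_cohort(seed=3, n_regions=15, n_targets=8, n_scans=2, n_frames=60)
        c2 = dg.make_cohort(seed=3, n_regions=15, n_targets=8, n_scans=2, n_frames=60)
        assert np.array_equal(c1.scans[0].data, c2.scans[0].data)
        assert np.array_equal(
            np.nan_to_num(c1.pupil_traces[1]), np.nan_to_num(c2.pupil_traces[1])
        )
        assert np.array_equal(c1.tracing.weights, c2.tracing.weights)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(TypeError):
            dg.make_cohort(seed=0, bogus=1)

    def test_modulation_weight_shapes(self):
        a = np.linspace(0, 1, 11)
        u = modulation_weight(a, 1.0, "u")
        iu = modulation_weight(a, 1.0, "inverted_u")
        assert u[0] == pytest.approx(1.0) and u[5] == pytest.approx(0.0)
        assert iu[0] == pytest.approx(0.0) and iu[5] == pytest.approx(1.0)
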