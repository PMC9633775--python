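"""Dynamic connectivity (DCC), arousal-binned gradients, flow, entropy, trend fits."""

import numpy as np
import pytest

import dyngrad as dg
from dyngrad._utils import nearest_correlation
from dyngrad.containers import ConnectivityMatrix, GradientSet, RegionTimeSeries
from dyngrad.dynamics import (
    binned_mean_dfc,
    dcc_fit,
    dynamic_gradients,
    fc_entropy,
    flow_null,
    gradient_flow,
    quadratic_trend,
    simulate_garch_dcc,
)


class TestDCC:
    def test_iid_constant_correlation_recovered(self):
        """Time-mean conditional correlation ≈ static r for i.i.d. Gaussian data."""
        root = np.linalg.cholesky(np.array([[1.0, 0.5], [0.5, 1.0]]))
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = (root @ rng.standard_normal((2, 1500))).T
            _, dcc = dcc_fit(RegionTimeSeries(x, 2.0))
            errs.append(dcc.frames[:, 0, 1].mean() - 0.5)
        assert abs(np.mean(errs)) < 0.05

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((1200, 2))
        _, dcc = dcc_fit(RegionTimeSeries(x, 2.0))
        assert abs(dcc.frames[:, 0, 1].mean()) < 0.05

    def test_parameter_recovery_from_known_generator(self):
        garch = np.array([[0.05, 0.08, 0.88], [0.03, 0.05, 0.90]])
        s = np.array([[1.0, 0.5], [0.5, 1.0]])
        est = []
        for seed in range(6):
            x = simulate_garch_dcc(3000, garch, 0.06, 0.90, s, seed=seed)
            p, _ = dcc_fit(RegionTimeSeries(x, 2.0))
            est.append([p.a, p.b])
        bias = np.mean(est, axis=0) - [0.06, 0.90]
        assert np.abs(bias).max() < 0.05

    def test_step_change_tracked(self):
        ok = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            half = 400
            l1 = np.linalg.cholesky(np.array([[1, 0.2], [0.2, 1.0]]))
            l2 = np.linalg.cholesky(np.array([[1, 0.8], [0.8, 1.0]]))
            x = np.vstack(
                [(l1 @ rng.standard_normal((2, half))).T, (l2 @ rng.standard_normal((2, half))).T]
            )
            _, dcc = dcc_fit(RegionTimeSeries(x, 2.0))
            c = dcc.frames[:, 0, 1]
            ok += c[half:].mean() > c[:half].mean()
        assert ok >= 7

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            dcc_fit(RegionTimeSeries(rng.standard_normal((50, 3)), 2.0))

    def test_frames_are_valid_correlations(self, rng):
        x = rng.standard_normal((200, 4))
        _, dcc = dcc_fit(RegionTimeSeries(x, 2.0))
        assert np.allclose(dcc.frames.diagonal(axis1=1, axis2=2), 1.0)
        assert np.linalg.eigvalsh(dcc.frames).min() > -1e-8


class TestBinnedMeanDfc:
    def test_identical_frames(self, rng):
        m = nearest_correlation(np.corrcoef(rng.standard_normal((6, 40))))
        frames = np.repeat(m[None], 10, axis=0)
        out = binned_mean_dfc(frames, np.repeat([0, 1], 5))
        assert np.allclose(out[0].values, m, atol=1e-10)
        assert np.allclose(out[1].values, m, atol=1e-10)

    def test_partition_means_exact(self, rng):
        m1 = nearest_correlation(np.corrcoef(rng.standard_normal((5, 30))))
        m2 = nearest_correlation(np.corrcoef(rng.standard_normal((5, 30))))
        frames = np.array([m1, m2, m1, m2])
        out = binned_mean_dfc(frames, np.array([0, 1, 0, 1]))
        assert np.allclose(out[0].values, m1, atol=1e-10)
        assert np.allclose(out[1].values, m2, atol=1e-10)

    def test_random_frames_match_brute_force(self, rng):
        frames = np.array(
            [nearest_correlation(np.corrcoef(rng.standard_normal((6, 20)))) for _ in range(9)]
        )
        assign = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2])
        out = binned_mean_dfc(frames, assign)
        for b in range(3):
            brute = frames[assign == b].mean(axis=0)
            assert np.abs(out[b].values - nearest_correlation(brute)).max() < 1e-10

    def test_empty_bin_rejected(self, rng):
        frames = np.repeat(np.eye(3)[None], 4, axis=0)
        with pytest.raises(ValueError, match="empty"):
            binned_mean_dfc(frames, np.zeros(4, dtype=int), n_bins=2)


class TestDynamicGradients:
    def test_identical_bins_identical_gradients(self, small_cohort):
        fc = dg.compute_fc(small_cohort.scans[0])
        ref = dg.gradients_from_connectivity(fc, n_components=3)
        outs = dynamic_gradients([fc, fc, fc], ref)
        for g in outs[1:]:
            assert np.allclose(g.components, outs[0].components)
            assert np.allclose(g.explained_variance, outs[0].explained_variance)

    def test_reference_matrix_maps_to_reference(self, small_cohort):
        fc = dg.compute_fc(small_cohort.scans[0])
        ref = dg.gradients_from_connectivity(fc, n_components=3)
        out = dynamic_gradients([fc], ref)[0]
        assert np.abs(out.components - ref.components).max() < 1e-8

    def test_planted_eigenweight_trend_detected(self):
        """Per-bin EV of gradient 1 follows a planted inverted-U eigenweight course."""
        maps, _ = dg.make_spatial_maps(40, 2, 0.3, seed=21)
        z = maps * np.sqrt(40)
        xs = np.linspace(0, 1, 10)
        w1 = 0.30 + 0.25 * (1 - 4 * (xs - 0.5) ** 2)  # inverted-U course
        mats = []
        for w in w1:
            m = w * np.outer(z[:, 0], z[:, 0]) + 0.18 * np.outer(z[:, 1], z[:, 1])
            mats.append(ConnectivityMatrix(nearest_correlation(m + (1 - w - 0.18) * np.eye(40))))
        ref = dg.gradients_from_connectivity(mats[5], n_components=3)
        grads = dynamic_gradients(mats, ref)
        ev1 = np.array([g.explained_variance[0] for g in grads])
        fit = quadratic_trend(xs, ev1)
        assert fit.coefficients[0] < 0
        assert ev1[4] > ev1[0] and ev1[5] > ev1[9]


class TestGradientFlow:
    def _gsets(self, trajs):
        # trajs: (B, N, 2) component values per bin
        return [
            GradientSet(np.array(t), np.ones(2), np.full(2, 0.5)) for t in trajs
        ]

    def test_identical_bins_zero_flow(self, rng):
        comp = rng.standard_normal((12, 2))
        flows = gradient_flow(self._gsets([comp] * 5), np.repeat([0, 1, 2], 4))
        assert all(v["magnitude"] == pytest.approx(0, abs=1e-12) for v in flows.values())

    def test_linear_translation_exact_magnitude(self, rng):
        comp = rng.standard_normal((8, 2))
        delta = 0.37
        trajs = [comp + [b * delta, 0.0] for b in range(6)]
        flows = gradient_flow(self._gsets(trajs), np.repeat([0, 1], 4))
        for v in flows.values():
            assert v["magnitude"] == pytest.approx(delta, abs=1e-10)
            assert v["drift"][0] == pytest.approx(delta)

    def test_singleton_network_allowed(self, rng):
        comp = rng.standard_normal((3, 2))
        flows = gradient_flow(self._gsets([comp, comp + 0.1]), np.array([0, 1, 1]))
        assert "0" in flows


class TestFlowNull:
    def test_preconditions(self, rng):
        frames = np.repeat(np.eye(4)[None], 20, axis=0)
        ref = GradientSet(rng.standard_normal((4, 2)), np.ones(2), np.full(2, 0.5))
        with pytest.raises(ValueError):
            flow_null([frames], [np.arange(20.0)], ref, np.zeros(4), n_perm=10)
        with pytest.raises(ValueError):
            flow_null(
                [frames, frames], [np.arange(20.0), np.arange(20.0)], ref, np.zeros(4), n_perm=0
            )

    def test_planted_arousal_coupled_shift_significant(self):
        """Scan-shuffle null: arousal-locked connectivity drift yields small p."""
        rng = np.random.default_rng(5)
        maps, _ = dg.make_spatial_maps(20, 2, 0.3, seed=31)
        z = maps * np.sqrt(20)
        n_scans, t_len = 4, 120
        dfcs, ars = [], []
        for s in range(n_scans):
            a = dg.make_arousal_process(t_len, 0.9, seed=50 + s)
            frames = np.empty((t_len, 20, 20))
            for t in range(t_len):
                w1 = 0.25 + 0.3 * a[t]
                m = w1 * np.outer(z[:, 0], z[:, 0]) + 0.15 * np.outer(z[:, 1], z[:, 1])
                frames[t] = nearest_correlation(m + (1 - w1 - 0.15) * np.eye(20))
            dfcs.append(frames)
            ars.append(a)
        ref = dg.gradients_from_connectivity(
            ConnectivityMatrix(nearest_correlation(np.concatenate(dfcs).mean(0))), n_components=2
        )
        res = flow_null(dfcs, ars, ref, np.repeat([0, 1], 10), n_bins=5, n_perm=120, seed=3)
        assert min(res["p"].values()) < 0.05


class TestEntropy:
    def test_single_value_zero_bits(self):
        v = np.full((5, 5), 0.3)
        np.fill_diagonal(v, 1.0)
        assert fc_entropy(ConnectivityMatrix(v)) == 0.0

    def test_uniform_64_bins_is_six_bits(self):
        # one pair value centered in each histogram bin
        vals = -1 + (np.arange(64) + 0.5) * (2 / 64)
        n = 12  # 66 pairs; use first 64
        v = np.eye(n)
        iu = np.triu_indices(n, 1)
        fill = np.concatenate([vals, [vals[0], vals[-1]]])  # 66 values, 64 distinct bins
        v[iu] = fill
        v[(iu[1], iu[0])] = fill
        h = fc_entropy(v)
        assert h == pytest.approx(np.log2(64), abs=0.05)

    def test_matches_brute_force(self, rng):
        v = dg._utils.pearson_rows(rng.standard_normal((10, 30)))
        iu = np.triu_indices(10, 1)
        counts, _ = np.histogram(v[iu], bins=64, range=(-1, 1))
        p = counts[counts > 0] / counts.sum()
        assert fc_entropy(ConnectivityMatrix(v)) == pytest.approx(-(p * np.log2(p)).sum())


class TestQuadraticTrend:
    def test_exact_inverted_u(self):
        x = np.linspace(0, 1, 10)
        fit = quadratic_trend(x, -((x - 0.5) ** 2))
        assert fit.coefficients[0] == pytest.approx(-1.0, abs=1e-10)
        assert fit.shape == "inverted-U"
        fit_u = quadratic_trend(x, (x - 0.5) ** 2)
        assert fit_u.coefficients[0] == pytest.approx(1.0, abs=1e-10)
        assert fit_u.shape == "U"

    def test_linear_data_classified_monotone(self, rng):
        x = np.linspace(0, 1, 30)
        y = 2 * x + 0.01 * rng.standard_normal(30)
        fit = quadratic_trend(x, y)
        assert fit.shape == "monotone"

    def test_flat_noise_classified_flat(self, rng):
        x = np.linspace(0, 1, 30)
        fit = quadratic_trend(x, 0.01 * rng.standard_normal(30))
        assert fit.shape == "flat"

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            quadratic_trend(np.arange(3.0), np.arange(3.0))
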