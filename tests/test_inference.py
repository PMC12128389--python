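"""Variational machinery: inducing points, chunking, ELBO, gradients, training."""

import numpy as np
import pytest

from mnsf.core_model import SampleData
from mnsf.gp_prior import InducingSet
from mnsf.inference import (
    FitConfig,
    _Adam,
    _Unit,
    _unit_value_grad,
    chunk_data,
    chunk_partition,
    elbo,
    elbo_dataset,
    fit,
    fit_pnmf,
    init_params,
    predict_factors,
    select_inducing_points,
)


class TestSelectInducingPoints:
    def test_fraction_one_returns_all_in_order(self):
        coords = np.random.default_rng(0).normal(0, 1, (20, 2))
        ind = select_inducing_points(coords, 1.0, seed=3)
        assert np.array_equal(ind.indices, np.arange(20))
        assert np.array_equal(ind.Z, coords)

    def test_35_percent_of_100(self):
        coords = np.random.default_rng(1).normal(0, 1, (100, 2))
        ind = select_inducing_points(coords, 0.35, seed=0)
        assert len(np.unique(ind.indices)) == 35

    def test_deterministic(self):
        coords = np.random.default_rng(2).normal(0, 1, (50, 2))
        a = select_inducing_points(coords, 0.4, seed=9)
        b = select_inducing_points(coords, 0.4, seed=9)
        assert np.array_equal(a.indices, b.indices)

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            select_inducing_points(np.zeros((5, 2)), 0.0, seed=0)


class TestChunking:
    def test_single_chunk_is_identity(self, single_sample):
        out = chunk_data(single_sample, 1, seed=0)
        assert len(out) == 1
        assert out[0] is single_sample

    def test_partition_sizes_and_union(self):
        parts = chunk_partition(10, 3, seed=4)
        sizes = sorted(len(p) for p in parts)
        assert sizes == [3, 3, 4]
        assert np.array_equal(np.sort(np.concatenate(parts)), np.arange(10))

    def test_deterministic(self):
        a = chunk_partition(30, 4, seed=5)
        b = chunk_partition(30, 4, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_chunks_carry_aligned_slices(self, single_sample):
        out = chunk_data(single_sample, 2, seed=1)
        n = sum(c.n_spots for c in out)
        assert n == single_sample.n_spots
        ids = np.concatenate([c.spot_ids for c in out])
        assert set(ids) == set(single_sample.spot_ids)

    def test_too_many_chunks(self, single_sample):
        with pytest.raises(ValueError):
            chunk_data(single_sample, 26, seed=0)


class TestInitParams:
    def test_nonnegative_and_deterministic(self, tiny_dataset):
        samples, _ = tiny_dataset
        a = init_params(samples, L=4, seed=2)
        b = init_params(samples, L=4, seed=2)
        assert np.all(a.params.W >= 0)
        assert np.array_equal(a.params.W, b.params.W)
        assert np.array_equal(a.vstates[0].q_mean, b.vstates[0].q_mean)

    def test_rank_recovery_on_clean_data(self):
        # exact low-rank counts: NMF init must reconstruct well
        rng = np.random.default_rng(3)
        scores = rng.uniform(0.5, 2, (40, 2))
        loadings = rng.uniform(0.5, 2, (15, 2))
        Y = np.round(50 * scores @ loadings.T).astype(int)
        s = SampleData(
            counts=Y, coords=rng.normal(0, 1, (40, 2)), sample_id="lowrank"
        )
        init = init_params([s], L=2, seed=0, nmf_iter=500)
        recon = init.scores[0] @ init.params.W.T
        rel = np.linalg.norm(recon - Y) / np.linalg.norm(Y)
        assert rel < 0.1

    def test_vstate_shapes_follow_inducing_fraction(self, tiny_dataset):
        samples, _ = tiny_dataset
        init = init_params(samples, L=3, seed=1, inducing_fraction=0.5)
        n = init.inducing[0].n_points
        assert n == int(np.ceil(0.5 * samples[0].n_spots))
        assert init.vstates[0].q_mean.shape == (3, n)


class TestGradients:
    """Analytic gradients against central finite differences."""

    def _make_unit(self, seed=0, N=6, n=3, L=2, G=4):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, (N, 2))
        Z = X[rng.choice(N, n, replace=False)]
        theta = {
            "la": rng.normal(0, 0.3, L),
            "lb": rng.normal(-1, 0.3, L),
            "b0": rng.normal(0, 0.5, L),
            "b1": rng.normal(0, 0.3, (L, 2)),
            "qm": rng.normal(0, 0.5, (L, n)),
            "Craw": np.tril(rng.normal(0, 0.3, (L, n, n))),
        }
        unit = _Unit(
            0, np.arange(N), rng.poisson(3.0, (N, G)), X,
            rng.uniform(0.5, 1.5, N), InducingSet(Z=Z), theta,
            np.log(5.0), 1e-6,
        )
        W = rng.uniform(0.1, 2.0, (G, L))
        return unit, W

    @pytest.mark.parametrize("mode", ["delta", "mc"])
    def test_theta_and_w_gradients(self, mode):
        unit, W = self._make_unit()
        eps = (
            np.random.default_rng(9).standard_normal((2, unit.n_spots, 2))
            if mode == "mc"
            else None
        )
        _, grad, gW, g_lphi, _, _ = _unit_value_grad(
            unit, W, want_grad=True, optimize_phi=True, mc_eps=eps
        )
        h = 1e-6

        def f():
            return _unit_value_grad(unit, W, want_grad=False, mc_eps=eps)[0]

        for k in unit.theta:
            it = np.nditer(unit.theta[k], flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                if k == "Craw" and idx[-1] > idx[-2]:
                    continue
                o = unit.theta[k][idx]
                unit.theta[k][idx] = o + h
                fp = f()
                unit.theta[k][idx] = o - h
                fm = f()
                unit.theta[k][idx] = o
                fd = (fp - fm) / (2 * h)
                assert abs(fd - grad[k][idx]) / (abs(fd) + 1e-4) < 1e-4, k
        # spot-check W and dispersion gradients
        for (i, j) in [(0, 0), (2, 1)]:
            o = W[i, j]
            W[i, j] = o + h
            fp = f()
            W[i, j] = o - h
            fm = f()
            W[i, j] = o
            fd = (fp - fm) / (2 * h)
            assert abs(fd - gW[i, j]) / (abs(fd) + 1e-4) < 1e-4
        o = unit.log_phi
        unit.log_phi = o + h
        fp = f()
        unit.log_phi = o - h
        fm = f()
        unit.log_phi = o
        fd = (fp - fm) / (2 * h)
        assert abs(fd - g_lphi) / (abs(fd) + 1e-4) < 1e-4


class TestElbo:
    def test_rejects_all_zero_loadings(self, tiny_dataset):
        samples, _ = tiny_dataset
        init = init_params(samples, L=2, seed=0)
        init.params.W[:] = 0.0
        with pytest.raises(ValueError, match="positive column"):
            elbo(samples[0], init.params, init.vstates[0], init.inducing[0])

    def test_two_sample_additivity(self, tiny_dataset):
        samples, _ = tiny_dataset
        init = init_params(samples, L=2, seed=0)
        sub = np.random.SeedSequence(5).generate_state(2) % (2**31)
        per_sample = [
            elbo(samples[m], init.params, init.vstates[m], init.inducing[m],
                 mc_samples=20, seed=int(sub[m]), sample_index=m)
            for m in range(2)
        ]
        total = elbo_dataset(samples, init.params, init.vstates, init.inducing,
                             mc_samples=20, seed=5)
        assert abs(total - sum(per_sample)) <= 1e-8 * abs(total)

    def test_identical_single_spot_samples_double(self):
        from mnsf.core_model import ModelParams
        from mnsf.inference import VariationalState

        counts = np.array([[3, 1, 4, 2]])
        coords = np.array([[0.0, 0.0]])
        a = SampleData(counts=counts, coords=coords, sample_id="a")
        b = SampleData(counts=counts.copy(), coords=coords.copy(), sample_id="b")
        params = ModelParams(
            W=np.full((4, 1), 0.5),
            dispersion=np.array([5.0, 5.0]),
            kernel_amplitude=np.ones((2, 1)),
            kernel_lengthscale=np.ones((2, 1)),
            mean_intercept=np.zeros((2, 1)),
            mean_slope=np.zeros((2, 1, 2)),
        )
        vs = VariationalState(
            q_mean=np.array([[0.3]]), q_cov_factor=np.array([[[0.2]]])
        )
        ind = InducingSet(Z=coords)
        e0 = elbo(a, params, vs, ind, mc_samples=500, seed=1, sample_index=0)
        e1 = elbo(b, params, vs, ind, mc_samples=500, seed=1, sample_index=1)
        assert e1 == pytest.approx(e0, rel=1e-12)

    def test_mc_estimates_agree_within_error(self, tiny_dataset):
        samples, _ = tiny_dataset
        init = init_params(samples, L=1, seed=0)
        runs = [
            elbo(samples[0], init.params, init.vstates[0], init.inducing[0],
                 mc_samples=400, seed=s)
            for s in (1, 2, 3, 4)
        ]
        spread = np.std(runs)
        assert spread / abs(np.mean(runs)) < 0.01


class TestAdam:
    def test_quadratic_descent(self):
        opt = _Adam(lr=0.1)
        p = {"x": np.array([5.0])}
        for _ in range(500):
            p = opt.step(p, {"x": 2 * p["x"]})
        assert abs(p["x"][0]) < 1e-3


@pytest.fixture(scope="module")
def small_fit(tiny_dataset):
    samples, _ = tiny_dataset
    cfg = FitConfig(L=2, max_iter=60, seed=3, inducing_fraction=0.5)
    return fit(samples, cfg), samples, cfg


class TestFit:
    def test_w_nonnegative_and_shapes(self, small_fit):
        res, samples, cfg = small_fit
        assert np.min(res.params.W) >= 0
        for m, s in enumerate(samples):
            assert res.factors[m].values.shape == (s.n_spots, cfg.L)
        assert np.all(np.isfinite(res.loss_trajectory))

    def test_loss_decreases_overall(self, small_fit):
        res, _, _ = small_fit
        assert np.mean(res.loss_trajectory[-10:]) < np.mean(res.loss_trajectory[:10])

    def test_total_loss_is_sum_of_unit_losses(self, small_fit):
        res, _, _ = small_fit
        assert np.allclose(
            res.loss_trajectory, res.loss_per_unit.sum(axis=1), rtol=1e-12
        )

    def test_deterministic_given_seed(self, tiny_dataset):
        samples, _ = tiny_dataset
        cfg = FitConfig(L=2, max_iter=25, seed=7)
        a = fit(samples, cfg)
        b = fit(samples, cfg)
        assert np.array_equal(a.params.W, b.params.W)
        assert np.array_equal(a.factors[0].values, b.factors[0].values)

    def test_single_sample_reduction_matches_manual_loop(self, tiny_dataset):
        """With M=1 the multi-sample loop must equal a plain one-sample fit:
        the W average is over one element and projection is the only coupling."""
        samples, _ = tiny_dataset
        one = [samples[0]]
        cfg = FitConfig(L=2, max_iter=15, seed=5, inducing_fraction=1.0)
        res = fit(one, cfg)

        from mnsf.inference import _build_units

        units, _, W = _build_units(one, cfg)
        opt_t, opt_w = _Adam(cfg.learning_rate), _Adam(cfg.learning_rate)
        rng = np.random.default_rng(
            int(np.random.SeedSequence([cfg.seed, 7]).generate_state(1)[0]) % (2**31)
        )
        manual_losses = []
        for _ in range(cfg.max_iter):
            eps = rng.standard_normal((cfg.mc_samples, units[0].n_spots, cfg.L))
            value, grad, gW, _, _, _ = _unit_value_grad(
                units[0], W, want_grad=True, mc_eps=eps
            )
            manual_losses.append(value)
            units[0].theta = opt_t.step(units[0].theta, grad)
            W = opt_w.step({"W": W.copy()}, {"W": gW})["W"]
            W[W < 0] = 0.0
        assert np.allclose(res.loss_trajectory, manual_losses, rtol=1e-12)
        assert np.allclose(res.params.W, W, rtol=1e-12)

    def test_chunked_fit_runs_and_covers_all_spots(self, tiny_dataset):
        samples, _ = tiny_dataset
        cfg = FitConfig(L=2, max_iter=20, seed=2, n_chunks=2)
        res = fit(samples, cfg)
        for m, s in enumerate(samples):
            assert res.factors[m].values.shape[0] == s.n_spots
            assert np.all(np.isfinite(res.factors[m].values))

    def test_predict_at_observed_spots_matches_factors(self, tiny_dataset):
        samples, _ = tiny_dataset
        cfg = FitConfig(L=2, max_iter=20, seed=4, inducing_fraction=0.5)
        res = fit(samples, cfg)
        pred = predict_factors(res, 0, samples[0].coords)
        assert np.allclose(pred.values, res.factors[0].values, atol=1e-8)

    def test_predict_at_inducing_points_returns_q_mean(self, tiny_dataset):
        samples, _ = tiny_dataset
        cfg = FitConfig(L=2, max_iter=10, seed=4, inducing_fraction=0.5)
        res = fit(samples, cfg)
        unit = res._units[0]
        Z_orig = res.transforms[0].invert(unit.inducing.Z)
        pred = predict_factors(res, 0, Z_orig)
        # at inducing locations the conditional mean passes through q_mean
        assert np.allclose(pred.values.T, unit.theta["qm"], atol=1e-4)

    def test_unknown_sample_index(self, tiny_dataset):
        samples, _ = tiny_dataset
        res = fit(samples, FitConfig(L=2, max_iter=5, seed=0))
        with pytest.raises(ValueError, match="sample index"):
            predict_factors(res, 5, samples[0].coords)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            fit([], FitConfig(L=2))


class TestFitPnmf:
    def test_runs_and_w_nonnegative(self, tiny_dataset):
        samples, truth = tiny_dataset
        res = fit_pnmf(samples, FitConfig(L=4, max_iter=80, seed=0))
        assert np.min(res.params.W) >= 0
        assert np.mean(res.loss_trajectory[-10:]) < np.mean(res.loss_trajectory[:10])

    def test_recovers_factors_without_spatial_prior(self, tiny_dataset):
        from mnsf.evaluate import match_factors

        samples, truth = tiny_dataset
        res = fit_pnmf(samples, FitConfig(L=4, max_iter=300, seed=0))
        est = [np.exp(f.values) for f in res.factors]
        m = match_factors(est, truth.true_factors)
        assert m.correlations.min() > 0.6
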