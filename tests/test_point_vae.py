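"""Tests of the multi-class point-cloud VAE: encoding, decoding, losses,
training behaviour and persistence."""

import numpy as np
import pytest

from cardiovae import point_vae as pv, shape_metrics as sm, synthetic_anatomy as sa
from conftest import tiny_config


class TestEncode:
    def test_latent_dimension_is_16(self, untrained_model, one_sample):
        code = pv.encode(one_sample, untrained_model)
        assert code.mu.shape == (16,)
        assert code.sigma.shape == (16,)
        assert np.all(code.sigma > 0)

    def test_permutation_invariance(self, untrained_model, one_sample):
        code1 = pv.encode(one_sample, untrained_model)
        rng = np.random.default_rng(0)
        shuf = sa.AnatomySample(
            subject_id="shuffled",
            ed=_shuffle(one_sample.ed, rng), es=_shuffle(one_sample.es, rng))
        code2 = pv.encode(shuf, untrained_model)
        np.testing.assert_allclose(code1.mu, code2.mu, rtol=1e-4, atol=1e-6)

    def test_distinct_inputs_distinct_codes(self, untrained_model,
                                            small_cohort):
        c1 = pv.encode(small_cohort[0], untrained_model)
        c2 = pv.encode(small_cohort[1], untrained_model)
        assert np.all(np.isfinite(c1.mu)) and np.all(np.isfinite(c2.mu))
        assert not np.allclose(c1.mu, c2.mu)

    def test_wrong_point_count_names_field(self, untrained_model, one_sample):
        bad_ed = sa.MultiClassPointCloud(
            points=one_sample.ed.points[:-3],
            labels=one_sample.ed.labels[:-3], phase="ED")
        bad = sa.AnatomySample(subject_id="bad", ed=bad_ed, es=one_sample.es)
        with pytest.raises(ValueError, match="n_input_points"):
            pv.encode(bad, untrained_model)


def _shuffle(cloud, rng):
    order = rng.permutation(len(cloud.points))
    return sa.MultiClassPointCloud(points=cloud.points[order],
                                   labels=cloud.labels[order],
                                   phase=cloud.phase)


class TestReparameterize:
    def test_zero_noise_returns_mean(self):
        code = pv.LatentCode(mu=np.arange(16.0), sigma=np.full(16, 1e-12))
        z = pv.reparameterize(code, seed=0)
        np.testing.assert_allclose(z, code.mu, atol=1e-9)

    def test_moments_match_standard_normal(self):
        code = pv.LatentCode(mu=np.zeros(4), sigma=np.ones(4))
        zs = np.array([pv.reparameterize(code, seed=s) for s in range(10000)])
        assert abs(zs.mean()) < 0.05
        assert 0.9 < zs.var() < 1.1

    def test_seeded_determinism(self):
        code = pv.LatentCode(mu=np.zeros(16), sigma=np.ones(16))
        np.testing.assert_array_equal(pv.reparameterize(code, 5),
                                      pv.reparameterize(code, 5))


class TestDecode:
    def test_dense_is_grid_squared_times_coarse(self, untrained_model):
        dec = pv.decode(np.zeros(16), untrained_model)
        cfg = untrained_model.config
        assert dec.coarse.shape == (cfg.m_coarse, 3, 6)
        assert dec.dense.shape == (cfg.grid_side**2 * cfg.m_coarse, 3, 6)

    def test_default_grid_gives_16x(self):
        cfg = pv.PointVAEConfig(m_coarse=256)
        assert cfg.p_dense == 4096

    def test_deterministic(self, untrained_model):
        z = np.random.default_rng(0).normal(size=16)
        a = pv.decode(z, untrained_model)
        b = pv.decode(z, untrained_model)
        np.testing.assert_array_equal(a.dense, b.dense)

    def test_nan_rejected(self, untrained_model):
        z = np.zeros(16)
        z[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            pv.decode(z, untrained_model)

    def test_trained_decoder_responds_to_latent(self, trained_tiny):
        model, _, _ = trained_tiny
        z = np.zeros(16)
        a = pv.decode(z, model)
        z2 = z.copy()
        z2[0] = 2.0
        b = pv.decode(z2, model)
        assert not np.allclose(a.dense, b.dense)


class TestKL:
    def test_standard_normal_is_zero(self):
        code = pv.LatentCode(mu=np.zeros(16), sigma=np.ones(16))
        assert pv.kl_loss(code) == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_closed_form(self):
        code = pv.LatentCode(mu=np.array([1.0]), sigma=np.array([1.0]))
        assert pv.kl_loss(code) == pytest.approx(0.5)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(size=3)
        sigma = np.abs(rng.normal(size=3)) + 0.3
        code = pv.LatentCode(mu=mu, sigma=sigma)
        n = 10**6
        z = mu + sigma * rng.standard_normal((n, 3))
        log_q = -0.5 * (((z - mu) / sigma) ** 2 + np.log(2 * np.pi)
                        + 2 * np.log(sigma)).sum(axis=1)
        log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(axis=1)
        mc = (log_q - log_p).mean()
        assert pv.kl_loss(code) == pytest.approx(mc, rel=0.01)


class TestReconstructionLoss:
    def test_perfect_output_is_zero(self, one_sample):
        # m_coarse equal to the target count so channel sets can coincide;
        # dense channels tile the target points (equal as point sets)
        cfg = pv.PointVAEConfig(n_input_points=256, m_coarse=256,
                                total_steps=10)
        _, targets, _ = pv.prepare_sample(one_sample, cfg)
        coarse = np.stack(targets, axis=-1)
        dense = np.stack([np.resize(t, (cfg.p_dense, 3)) for t in targets],
                         axis=-1)
        out = pv.DecodedAnatomy(coarse=coarse, dense=dense)
        lb = pv.reconstruction_loss(out, one_sample, alpha=1.0, config=cfg)
        assert lb.total == pytest.approx(0.0, abs=1e-9)

    def test_alpha_zero_keeps_coarse_only(self, untrained_model, one_sample):
        dec = pv.decode(np.zeros(16), untrained_model)
        lb0 = pv.reconstruction_loss(dec, one_sample, alpha=0.0,
                                     config=untrained_model.config)
        assert lb0.total == pytest.approx(sum(lb0.coarse.values()), rel=1e-9)

    def test_composes_with_chamfer_oracle(self, one_sample):
        cfg = tiny_config()
        _, targets, _ = pv.prepare_sample(one_sample, cfg)
        rng = np.random.default_rng(0)
        coarse = rng.normal(scale=30, size=(cfg.m_coarse, 3, 6))
        dense = rng.normal(scale=30, size=(cfg.p_dense, 3, 6))
        out = pv.DecodedAnatomy(coarse=coarse, dense=dense)
        alpha = 0.37
        lb = pv.reconstruction_loss(out, one_sample, alpha=alpha, config=cfg)
        expect = sum(
            sm.chamfer_distance(coarse[:, :, k], targets[k], squared=True)
            + alpha * sm.chamfer_distance(dense[:, :, k], targets[k],
                                          squared=True)
            for k in range(6))
        assert lb.total == pytest.approx(expect, rel=1e-6)


class TestAlphaSchedule:
    def test_endpoints(self):
        cfg = pv.PointVAEConfig(total_steps=1000)
        assert pv.alpha_schedule(0, cfg) == cfg.alpha_start
        assert pv.alpha_schedule(1000, cfg) == cfg.alpha_end

    def test_monotone_nondecreasing(self):
        cfg = pv.PointVAEConfig(total_steps=777)
        vals = [pv.alpha_schedule(s, cfg) for s in range(0, 778, 7)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        cfg = pv.PointVAEConfig(total_steps=10)
        with pytest.raises(ValueError):
            pv.alpha_schedule(11, cfg)


class TestTraining:
    def test_overfits_single_sample(self, one_sample):
        cfg = tiny_config(seed=1, steps=500)
        model, hist = pv.train([one_sample], pv.PointVAEConfig(
            **{**cfg.__dict__, "batch_size": 1}))
        start = hist.reconstruction.iloc[:10].mean()
        end = hist.reconstruction.iloc[-10:].mean()
        assert end < 0.10 * start

    def test_beta_zero_reaches_lower_reconstruction(self, small_cohort):
        subset = small_cohort[:6]
        runs = {}
        for beta in (0.0, 0.2):
            cfg = pv.PointVAEConfig(
                **{**tiny_config(seed=2, steps=300).__dict__, "beta": beta})
            _, hist = pv.train(subset, cfg)
            runs[beta] = hist.reconstruction.iloc[-50:].mean()
        assert runs[0.0] < runs[0.2]

    def test_seeded_runs_identical(self, small_cohort):
        subset = small_cohort[:4]
        cfg = tiny_config(seed=5, steps=15)
        _, h1 = pv.train(subset, cfg)
        _, h2 = pv.train(subset, cfg)
        np.testing.assert_array_equal(h1.total.to_numpy(), h2.total.to_numpy())

    def test_loss_identity_every_step(self, trained_tiny):
        _, hist, _ = trained_tiny
        recon = hist.reconstruction.to_numpy()
        total = hist.total.to_numpy()
        kl = hist.kl.to_numpy()
        np.testing.assert_allclose(total, recon + 0.2 * kl, rtol=1e-5)

    def test_validation_loss_decreases(self, trained_tiny):
        _, hist, _ = trained_tiny
        # smoothed training total as convergence proxy over 100-step windows
        smoothed = hist.total.rolling(100).mean().dropna()
        assert smoothed.iloc[-1] < smoothed.iloc[0]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pv.train([], tiny_config())


class TestReconstruct:
    def test_layout_and_determinism(self, trained_tiny):
        model, _, cohort = trained_tiny
        rec1 = pv.reconstruct(model, cohort[0])
        rec2 = pv.reconstruct(model, cohort[0])
        # inference samples the folding patches at eval_grid_side
        p = model.config.eval_grid_side**2 * model.config.m_coarse
        for cloud in (rec1.ed, rec1.es):
            assert sorted(set(cloud.labels)) == [1, 2, 3]
            for c in (1, 2, 3):
                assert (cloud.labels == c).sum() == p
        np.testing.assert_array_equal(rec1.ed.points, rec2.ed.points)

    def test_reconstruction_tracks_input(self, trained_tiny):
        """A briefly trained model reconstructs its own training samples
        much better than it reconstructs a differently-sized heart."""
        model, _, cohort = trained_tiny
        s = cohort[0]
        rec = pv.reconstruct(model, s)
        cd_same = sm.chamfer_distance(rec.ed.points, s.ed.points)
        assert np.isfinite(cd_same) and cd_same < 15.0


class TestPersistence:
    def test_save_load_bit_identical(self, trained_tiny, tmp_path):
        model, _, cohort = trained_tiny
        path = tmp_path / "model.npz"
        pv.save_model(model, path)
        back = pv.load_model(path)
        rec1 = pv.reconstruct(model, cohort[0])
        rec2 = pv.reconstruct(back, cohort[0])
        np.testing.assert_array_equal(rec1.ed.points, rec2.ed.points)
        np.testing.assert_array_equal(rec1.es.points, rec2.es.points)

    def test_config_json_roundtrip(self):
        cfg = pv.PointVAEConfig(latent_dim=8, beta=0.3, dec_widths=(64, 96))
        assert pv.PointVAEConfig.from_json(cfg.to_json()) == cfg

    def test_config_yaml_file(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("latent_dim: 8\nbeta: 0.1\ntotal_steps: 50\n")
        cfg = pv.PointVAEConfig.from_file(path)
        assert cfg.latent_dim == 8 and cfg.beta == 0.1
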