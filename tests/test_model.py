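import numpy as np
import pytest

import perturbsig as ps
from conftest import tiny_model_config
from oracles import mc_kl_divergence
from perturbsig.model import GaussianLatent, kl_gaussians, kl_standard


# ---------------------------------------------------------------- KL terms

class TestKLClosedForms:
    def test_standard_prior_is_zero(self):
        assert kl_standard(GaussianLatent([0.0], [0.0])) == 0.0

    def test_unit_mean_shift(self):
        # closed form mu^2 / 2
        assert kl_standard(GaussianLatent([1.0], [0.0])) == pytest.approx(0.5)
        est = mc_kl_divergence([1.0], [0.0], [0.0], [0.0], 10**6)
        assert abs(est - 0.5) < 0.01

    def test_variance_four(self):
        expected = -0.5 * (1 + np.log(4) - 4)
        got = kl_standard(GaussianLatent([0.0], [np.log(4.0)]))
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.8069, abs=1e-4)
        est = mc_kl_divergence([0.0], [np.log(4.0)], [0.0], [0.0], 10**6)
        assert abs(est - got) < 0.01

    def test_identical_gaussians_zero(self):
        q = GaussianLatent([0.3, -1.0], [0.2, -0.5])
        assert kl_gaussians(q, q) == pytest.approx(0.0, abs=1e-12)

    def test_mean_shift_between_gaussians(self):
        q = GaussianLatent([1.0], [0.0])
        p = GaussianLatent([0.0], [0.0])
        assert kl_gaussians(q, p) == pytest.approx(0.5)

    def test_random_pair_matches_monte_carlo(self):
        rng = np.random.default_rng(42)
        mu_q, mu_p = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        lv_q, lv_p = rng.normal(0, 0.5, 8), rng.normal(0, 0.5, 8)
        closed = kl_gaussians(GaussianLatent(mu_q, lv_q),
                              GaussianLatent(mu_p, lv_p))
        est = mc_kl_divergence(mu_q, lv_q, mu_p, lv_p, 10**6)
        assert abs(closed - est) < 0.01

    def test_reduces_to_standard_form(self):
        rng = np.random.default_rng(7)
        q = GaussianLatent(rng.normal(0, 1, 6), rng.normal(0, 0.3, 6))
        p = GaussianLatent(np.zeros(6), np.zeros(6))
        assert abs(kl_gaussians(q, p) - kl_standard(q)) < 1e-9

    def test_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            q = GaussianLatent(rng.normal(0, 2, 4), rng.normal(0, 1, 4))
            p = GaussianLatent(rng.normal(0, 2, 4), rng.normal(0, 1, 4))
            assert kl_gaussians(q, p) >= 0
            assert kl_standard(q) >= 0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kl_gaussians(GaussianLatent([0.0], [0.0]),
                         GaussianLatent([0.0, 0.0], [0.0, 0.0]))


# ---------------------------------------------------------------- forward

class TestForward:
    def _inputs(self, model):
        rng = np.random.default_rng(0)
        c = model.config
        return (rng.standard_normal(c.input_dim),
                rng.standard_normal(c.input_dim),
                rng.standard_normal(c.feature_dim))

    def test_total_is_sum_of_components(self, tiny_model):
        x1, x2, cm = self._inputs(tiny_model)
        *_, report = tiny_model.forward(x1, x2, cm,
                                        np.random.default_rng(1))
        parts = (report.mse_x1 + report.mse_x2 + report.mse_dx
                 + report.kl_z1 + report.kl_z2 + report.kl_fuse)
        assert report.total == pytest.approx(parts, abs=1e-6)

    def test_seeded_determinism(self, tiny_model):
        x1, x2, cm = self._inputs(tiny_model)
        r1 = tiny_model.forward(x1, x2, cm, np.random.default_rng(9))[-1]
        r2 = tiny_model.forward(x1, x2, cm, np.random.default_rng(9))[-1]
        assert r1 == r2

    def test_kl_fuse_matches_direct_call(self, tiny_model):
        """The fusion KL term equals kl_gaussians on the two latents."""
        x1, x2, cm = self._inputs(tiny_model)
        *_, report = tiny_model.forward(x1, x2, cm,
                                        np.random.default_rng(2))
        fused = tiny_model.fuse(x1, cm)
        z2 = tiny_model.encode_perturbed(x2)
        assert report.kl_fuse == pytest.approx(kl_gaussians(fused, z2),
                                               rel=1e-9)

    def test_dimension_mismatch(self, tiny_model):
        with pytest.raises(ValueError, match="cmol"):
            tiny_model.forward(np.zeros(40), np.zeros(40), np.zeros(7),
                               np.random.default_rng(0))


# ---------------------------------------------------------------- training

class TestTraining:
    def test_loss_improves_over_epochs(self, tiny_pairs, tiny_dataset):
        _, compounds, _ = tiny_dataset
        net = ps.DualVAE(tiny_model_config())
        _, hist = ps.train(net, tiny_pairs, compounds, epochs=30)
        assert hist[-1].total < hist[0].total

    def test_identical_trajectories_same_seed(self, tiny_pairs, tiny_dataset):
        _, compounds, _ = tiny_dataset
        hists = []
        for _ in range(2):
            net = ps.DualVAE(tiny_model_config())
            _, hist = ps.train(net, tiny_pairs, compounds, epochs=3)
            hists.append([h.total for h in hist])
        assert hists[0] == hists[1]

    def test_empty_dataset_rejected(self, tiny_dataset):
        _, compounds, _ = tiny_dataset
        with pytest.raises(ValueError):
            ps.train(ps.DualVAE(tiny_model_config()), [], compounds)

    def test_missing_features_listed(self, tiny_pairs):
        table = ps.CompoundTable(smiles={}, features={"nope": np.zeros(16)})
        with pytest.raises(ValueError, match="CPD"):
            ps.train(ps.DualVAE(tiny_model_config()), tiny_pairs, table,
                     epochs=1)


@pytest.fixture(scope="module")
def knockdown(tiny_config):
    import dataclasses
    cfg = dataclasses.replace(tiny_config, seed=99)
    matrix = ps.generate_knockdown(cfg)
    pairs = ps.prepare_pairs(matrix, time_h=24.0, dose_um=None)
    return pairs[:40], pairs[40:]


class TestPretraining:
    def test_improves_heldout_reconstruction(self, knockdown):
        train_kd, held_kd = knockdown
        feats = ps.CompoundTable(smiles={}, features={
            p.compound_id: np.zeros(16) for p in train_kd + held_kd})
        fresh = ps.DualVAE(tiny_model_config())
        fresh.fit_scaler(train_kd)
        base = fresh.evaluate_loss(held_kd, feats, np.random.default_rng(0))
        pre = ps.pretrain_init(ps.DualVAE(tiny_model_config()), train_kd,
                               epochs=30)
        after = pre.evaluate_loss(held_kd, feats, np.random.default_rng(0))
        assert (after.mse_x1 + after.mse_x2) < (base.mse_x1 + base.mse_x2)

    def test_fusion_and_mol_encoder_untouched(self, knockdown):
        train_kd, _ = knockdown
        net = ps.DualVAE(tiny_model_config())
        before = [p.data.copy()
                  for p in net.mol_encoder.params + net.fusion.params]
        vae_before = [p.data.copy() for p in net.vae_params]
        ps.pretrain_init(net, train_kd, epochs=2)
        after = [p.data for p in net.mol_encoder.params + net.fusion.params]
        assert all(np.array_equal(a, b) for a, b in zip(before, after))
        assert any(not np.array_equal(a, b) for a, b in
                   zip(vae_before, [p.data for p in net.vae_params]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ps.pretrain_init(ps.DualVAE(tiny_model_config()), [])


# ---------------------------------------------------------------- inference

class TestPredict:
    def test_delta_identity_and_determinism(self, tiny_model):
        rng = np.random.default_rng(4)
        x1 = rng.standard_normal(40)
        cm = rng.standard_normal(16)
        x2p, dx = tiny_model.predict(x1, cm)
        assert np.allclose(dx + x1, x2p, atol=1e-6)
        x2p2, dx2 = tiny_model.predict(x1, cm)
        assert np.array_equal(x2p, x2p2) and np.array_equal(dx, dx2)

    def test_recovery_on_noiseless_data(self):
        """On zero-noise synthetic pairs the predicted signatures recover
        the planted compound effects almost exactly (held-in)."""
        cfg = ps.SyntheticConfig(
            n_genes=40, n_cells=2, n_compounds=40, n_replicates=1,
            feature_dim=16, effect_rank=4, noise_sd_basal=0.0,
            noise_sd_pert=0.0, seed=5)
        matrix, compounds, gt = ps.generate(cfg)
        pairs = ps.prepare_pairs(matrix)
        net = ps.DualVAE(tiny_model_config(batch_size=32))
        ps.train(net, pairs, compounds, epochs=500)
        pccs = []
        for p in pairs:
            f = compounds.feature_matrix([p.compound_id])[0]
            _, dx = net.predict(p.x1, f)
            pccs.append(ps.pearson(dx, gt.effect(p.compound_id)))
        assert np.mean(pccs) >= 0.9

    def test_dimension_mismatch(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.predict(np.zeros(12), np.zeros(16))


# ---------------------------------------------------------------- persistence

def test_save_load_round_trip(tmp_path, tiny_pairs, tiny_dataset):
    _, compounds, _ = tiny_dataset
    net = ps.DualVAE(tiny_model_config())
    ps.train(net, tiny_pairs, compounds, epochs=2)
    path = tmp_path / "model.npz"
    ps.save_model(net, path)
    back = ps.load_model(path)
    for a, b in zip(net.params, back.params):
        assert np.array_equal(a.data, b.data)
    assert np.array_equal(net.scale_mean, back.scale_mean)
    assert back.config == net.config
    x1 = tiny_pairs[0].x1
    cm = compounds.feature_matrix([tiny_pairs[0].compound_id])[0]
    assert np.array_equal(net.predict(x1, cm)[1], back.predict(x1, cm)[1])
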