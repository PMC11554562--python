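"""Core model behavior: weight sharing, noise law, training effects,
determinism, single-cell latent refitting and serialization."""

import numpy as np
import pytest

from discell import DisentanglementModel, LatentSpec

from conftest import small_config, small_spec
from discell.synthetic import generate


class TestEmbeddings:
    def test_categorical_embedding_shared_and_distinct(self, small_results):
        a = small_results.embed_categorical("status", "control")
        b = small_results.embed_categorical("status", "control")
        np.testing.assert_array_equal(a, b)
        other = small_results.embed_categorical("status", "perturbed")
        assert not np.array_equal(a, other)

    def test_unseen_label_errors_with_names(self, small_results):
        with pytest.raises(KeyError, match="status.*unknown-state"):
            small_results.embed_categorical("status", "unknown-state")

    def test_ordered_encoder_deterministic_and_rejects_nan(self, small_results):
        z1 = small_results.embed_ordered("dose", np.array([0.5]))
        z2 = small_results.embed_ordered("dose", np.array([0.5]))
        np.testing.assert_array_equal(z1, z2)
        assert z1.shape == (small_results.spec.n_latent_attr,)
        with pytest.raises(ValueError, match="non-finite"):
            small_results.embed_ordered("dose", np.array([np.nan]))

    def test_unknown_code_noise_law(self, small_results):
        """Training-mode noise is N(0, sigma^2 I) around the stored row;
        evaluation mode returns the row exactly."""
        cid = small_results.dataset.cell_ids[0]
        row = small_results.embed_unknown(cid)
        np.testing.assert_array_equal(row, small_results.embed_unknown(cid,
                                                                       training_mode=False))
        rng = np.random.default_rng(123)
        draws = np.stack([small_results.embed_unknown(cid, training_mode=True, rng=rng)
                          for _ in range(10_000)])
        sigma = small_results.spec.sigma
        assert np.abs(draws.mean(axis=0) - row).max() < 3 * sigma / np.sqrt(10_000) * 3
        assert np.abs(draws.std(axis=0) / sigma - 1).max() < 0.05

    def test_unseen_cell_directs_to_refit(self, small_results):
        with pytest.raises(KeyError, match="fit_new_cell_embedding"):
            small_results.embed_unknown("not-a-cell")


class TestGeneration:
    def test_generate_deterministic_and_positive_means(self, small_results):
        latent = small_results.decompose(small_results.dataset.cell_ids[:10])
        d1 = small_results.generate(latent, library_size=np.full(10, 1000.0))
        d2 = small_results.generate(latent, library_size=np.full(10, 1000.0))
        np.testing.assert_array_equal(d1.mean, d2.mean)
        assert (d1.mean > 0).all()

    def test_output_depends_on_unknown_code(self, small_results):
        ids = small_results.dataset.cell_ids[:2]
        latent = small_results.decompose(ids)
        swapped = small_results.decompose(ids)
        swapped.z_u = swapped.z_u[::-1].copy()
        same_labels = all(
            np.array_equal(latent.z_y[k], swapped.z_y[k]) for k in latent.z_y)
        d1 = small_results.generate(latent, library_size=np.full(2, 1e3))
        d2 = small_results.generate(swapped, library_size=np.full(2, 1e3))
        changed = not np.allclose(d1.mean, d2.mean)
        assert changed == (not np.allclose(latent.z_u, swapped.z_u)) or not same_labels

    def test_missing_attribute_code_listed(self, small_results):
        latent = small_results.decompose(small_results.dataset.cell_ids[:1])
        del latent.z_y["dose"]
        with pytest.raises(ValueError, match="dose"):
            small_results.generate(latent)


class TestTraining:
    def test_loss_decreases_on_synthetic_data(self, small_results):
        log = small_results.training_log
        assert log["total"].iloc[-1] < log["total"].iloc[0]

    def test_same_seed_bitwise_reproducible(self, small_data):
        ds, _ = small_data
        r1 = DisentanglementModel(ds, small_spec()).fit(epochs=8, seed=11)
        r2 = DisentanglementModel(ds, small_spec()).fit(epochs=8, seed=11)
        np.testing.assert_array_equal(r1._params["u_table"].data,
                                      r2._params["u_table"].data)
        np.testing.assert_array_equal(r1.predict().mean, r2.predict().mean)
        assert r1.training_log.equals(r2.training_log)

    def test_penalty_shrinks_unknown_codes(self, small_data):
        ds, _ = small_data
        norms = {}
        for lam in (0.0, 10.0):
            res = DisentanglementModel(ds, small_spec(lambda_=lam)).fit(
                epochs=25, seed=0)
            norms[lam] = np.median(res.unknown_norms())
        assert norms[10.0] < norms[0.0]

    def test_missing_labels_rejected_by_supervised_model(self, small_data):
        ds, _ = small_data
        masked = ds.copy()
        masked.attribute_values["status"][0] = None
        with pytest.raises(ValueError, match="SemiSupervised"):
            DisentanglementModel(masked, small_spec())


class TestNewCellRefit:
    def test_refit_no_worse_than_stored_embedding(self, small_results):
        ds = small_results.dataset
        i = 3
        attrs = {"status": ds.attribute_values["status"][i],
                 "dose": ds.attribute_values["dose"][i]}
        z = small_results.fit_new_cell_embedding(ds.x[i], attrs, steps=400)
        loss_refit = small_results.cell_loss(ds.x[i], attrs, z)
        loss_stored = small_results.cell_loss(
            ds.x[i], attrs, small_results.embed_unknown(ds.cell_ids[i]))
        assert loss_refit <= loss_stored + 1e-3

    def test_huge_penalty_forces_near_zero_code(self, small_data):
        ds, _ = small_data
        res = DisentanglementModel(ds, small_spec(lambda_=1e6)).fit(epochs=5, seed=0)
        z = res.fit_new_cell_embedding(
            ds.x[0], {"status": ds.attribute_values["status"][0],
                      "dose": ds.attribute_values["dose"][0]}, steps=300)
        assert np.linalg.norm(z) < 1e-2

    def test_self_consistency_on_model_generated_counts(self, small_results):
        """Counts sampled from the model's own distribution at a known z_u*:
        refitting from zero reaches a loss no worse than at z_u*."""
        rng = np.random.default_rng(0)
        ds = small_results.dataset
        attrs = {"status": "control", "dose": np.array([0.5])}
        z_star = rng.normal(0, 0.5, size=small_results.spec.n_latent_u)
        from discell.model import DecomposedLatent

        latent = DecomposedLatent(
            z_y={"status": small_results.embed_categorical("status", "control"),
                 "dose": small_results.embed_ordered("dose", np.array([0.5]))},
            z_u=z_star.reshape(1, -1))
        dist = small_results.generate(latent, library_size=np.array([2000.0]))
        x = rng.poisson(dist.mean[0]).astype(float)
        z_hat = small_results.fit_new_cell_embedding(x, attrs, steps=600)
        assert small_results.cell_loss(x, attrs, z_hat) <= \
            small_results.cell_loss(x, attrs, z_star) + 1e-3


class TestSerialization:
    def test_save_load_restores_bit_identical_inference(self, small_results, tmp_path):
        path = tmp_path / "model.npz"
        small_results.save(path)
        from discell import DisentanglementResults

        back = DisentanglementResults.load(path)
        np.testing.assert_array_equal(back.predict().mean,
                                      small_results.predict().mean)
        np.testing.assert_array_equal(
            back.embed_categorical("status", "control"),
            small_results.embed_categorical("status", "control"))
        assert back.seed == small_results.seed
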