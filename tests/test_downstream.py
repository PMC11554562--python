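"""Downstream analyses: counterfactuals, the evaluation harness, the paired
association test, k-NN uncertainty, and latent export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from discell import (
    CellDataset,
    ExpressionDistribution,
    associate_features,
    counterfactual_predict,
    evaluate_counterfactuals,
    export_latent,
    uncertainty,
)
from discell.downstream import CounterfactualResult


def _fake_counterfactual(mean, family="gaussian", cell_ids=None, features=None):
    n, m = mean.shape
    cell_ids = cell_ids or [f"c{i}" for i in range(n)]
    features = features or [f"g{j}" for j in range(m)]
    disp = np.ones(m)
    dist = ExpressionDistribution(family, mean, dispersion=disp)
    return CounterfactualResult(cell_ids=cell_ids, original={}, target={"a": "b"},
                                mean=mean, dist=dist, feature_names=features)


class TestCounterfactual:
    def test_identity_manipulation_is_reconstruction_bit_exact(self, small_results):
        ids = small_results.dataset.cell_ids[:20]
        recon = small_results.predict(ids).mean
        cf = counterfactual_predict(small_results, {}, reference=ids)
        np.testing.assert_array_equal(cf.mean, recon)
        assert cf.noise_applied is False

    def test_planted_effect_sign_recovered(self, small_results, small_data):
        ds, gt = small_data
        ctrl = [c for c, v in zip(ds.cell_ids, ds.attribute_values["status"])
                if v == "control"]
        cf = counterfactual_predict(small_results, {"status": "perturbed"},
                                    reference=ctrl)
        base = small_results.predict(ctrl).mean
        shift = np.log1p(cf.mean).mean(axis=0) - np.log1p(base).mean(axis=0)
        delta = gt.effects["status"]["perturbed"]
        targets = gt.target_features("status")
        agree = np.sign(shift[targets]) == np.sign(delta[targets])
        assert agree.mean() > 0.9

    def test_cell_specificity_under_shared_manipulation(self, small_results):
        ids = small_results.dataset.cell_ids[:2]
        cf = counterfactual_predict(small_results, {"status": "perturbed"},
                                    reference=ids)
        assert not np.allclose(cf.mean[0], cf.mean[1])

    def test_unseen_target_category_rejected(self, small_results):
        with pytest.raises(KeyError, match="never-seen"):
            counterfactual_predict(small_results, {"status": "never-seen"})

    def test_additive_composite_of_single_vector_matches_plain(self, small_results):
        ids = small_results.dataset.cell_ids[:5]
        plain = counterfactual_predict(small_results, {"dose": np.array([1.0])},
                                       reference=ids)
        add = counterfactual_predict(small_results,
                                     {"dose": [np.array([1.0])]},
                                     reference=ids, additive=True)
        np.testing.assert_allclose(add.mean, plain.mean, atol=1e-12)


class TestEvaluationHarness:
    def test_perfect_prediction_scores_r2_one_nmse_zero(self, tiny_schema):
        truth = CellDataset(x=np.array([[1.0, 4.0, 8.0], [3.0, 0.0, 2.0]]),
                            schema=tiny_schema)
        pred = _fake_counterfactual(np.tile(truth.x.mean(axis=0), (2, 1)))
        control = CellDataset(x=truth.x + 5.0, schema=tiny_schema)
        out = evaluate_counterfactuals(pred, truth, control=control)
        assert out["r2"] == pytest.approx(1.0)
        assert out["nmse"] == pytest.approx(0.0)

    def test_no_perturb_prediction_anchors_nmse_at_one(self, tiny_schema):
        rng = np.random.default_rng(0)
        truth = CellDataset(x=rng.poisson(10, (6, 3)).astype(float),
                            schema=tiny_schema)
        control = CellDataset(x=rng.poisson(20, (6, 3)).astype(float),
                              schema=tiny_schema)
        pred = _fake_counterfactual(np.tile(control.x.mean(axis=0), (6, 1)))
        out = evaluate_counterfactuals(pred, truth, control=control, log1p=False)
        assert out["nmse"] == pytest.approx(1.0)

    def test_r2_matches_hand_worked_sums_of_squares(self, tiny_schema):
        truth_prof = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        pred_prof = np.array([1.0, 5.0, 6.0, 7.0, 11.0])
        ss_res = np.sum((truth_prof - pred_prof) ** 2)
        ss_tot = np.sum((truth_prof - truth_prof.mean()) ** 2)
        expected = 1.0 - ss_res / ss_tot
        schema = tiny_schema
        truth = CellDataset(x=np.tile(truth_prof, (2, 1)), schema=schema,
                            layer_kind="log_normalized")
        pred = _fake_counterfactual(np.tile(pred_prof, (2, 1)))
        out = evaluate_counterfactuals(pred, truth, log1p=False)
        assert out["r2"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_truth_reported_undefined(self, tiny_schema):
        truth = CellDataset(x=np.ones((3, 3)), schema=tiny_schema)
        pred = _fake_counterfactual(np.ones((3, 3)))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = evaluate_counterfactuals(pred, truth, log1p=False)
        assert np.isnan(out["r2"])


class TestAssociation:
    def test_three_pair_t_statistic_closed_form(self, tiny_schema):
        obs = np.zeros((3, 2))
        cf_mean = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        original = CellDataset(x=obs, schema=tiny_schema,
                               layer_kind="log_normalized",
                               cell_ids=["c0", "c1", "c2"],
                               feature_names=["g0", "g1"])
        pred = _fake_counterfactual(cf_mean, cell_ids=["c0", "c1", "c2"],
                                    features=["g0", "g1"])
        table = associate_features(original, pred)
        # differences (1,2,3): t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        assert table.statistic[0] == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        expected_p = 2 * stats.t.sf(2 * np.sqrt(3), df=2)
        assert table.p_value[0] == pytest.approx(expected_p, abs=1e-9)
        assert expected_p == pytest.approx(0.0742, abs=5e-4)
        # second feature identical in both -> degenerate, p = 1
        assert table.degenerate[1] and table.p_adjusted[1] == 1.0
        assert table.direction[1] == "none"

    def test_bh_adjustment_is_valid(self, tiny_schema):
        rng = np.random.default_rng(7)
        obs = rng.normal(size=(20, 50))
        pred = _fake_counterfactual(obs + rng.normal(size=(20, 50)))
        original = CellDataset(x=obs, schema=tiny_schema,
                               layer_kind="log_normalized",
                               cell_ids=[f"c{i}" for i in range(20)],
                               feature_names=[f"g{j}" for j in range(50)])
        table = associate_features(original, pred)
        assert (table.p_adjusted >= table.p_value - 1e-15).all()
        srt = table.sort_values("p_value")
        assert (np.diff(srt.p_adjusted.to_numpy()) >= -1e-12).all()

    def test_null_simulation_controls_false_discoveries(self, tiny_schema):
        """Global-null paired data: BH at 0.05 discovers (almost) nothing."""
        rng = np.random.default_rng(11)
        props = []
        for _ in range(20):
            obs = rng.normal(size=(30, 500))
            pred = _fake_counterfactual(obs + rng.normal(size=(30, 500)))
            original = CellDataset(x=obs, schema=tiny_schema,
                                   layer_kind="log_normalized",
                                   cell_ids=[f"c{i}" for i in range(30)],
                                   feature_names=[f"g{j}" for j in range(500)])
            table = associate_features(original, pred, alpha=0.05)
            props.append((table.p_adjusted <= 0.05).mean())
        mc_se = np.std(props, ddof=1) / np.sqrt(len(props))
        assert np.mean(props) <= 0.05 + 3 * mc_se + 1e-12

    def test_fewer_than_two_pairs_rejected(self, tiny_schema):
        original = CellDataset(x=np.ones((1, 2)), schema=tiny_schema,
                               cell_ids=["c0"], feature_names=["g0", "g1"])
        pred = _fake_counterfactual(np.ones((1, 2)), cell_ids=["c0"],
                                    features=["g0", "g1"])
        with pytest.raises(ValueError, match="at least 2"):
            associate_features(original, pred)


class TestUncertainty:
    def test_homogeneous_neighborhood_has_zero_uncertainty(self):
        emb = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        cov = np.array(["a", "a", "a", "b", "b", "b"])
        res = uncertainty(emb, cov, k=2, standardize=False)
        np.testing.assert_allclose(res.u, 0.0)

    def test_hand_computed_split_neighborhood(self):
        """k=2, both neighbors at distance e^2, labels split 1/1:
        u = (1/2 + 1/2) * ln 2 = ln 2."""
        e2 = np.exp(2.0)
        emb = np.array([[0.0], [e2], [-e2]])
        cov = np.array(["x", "y", "z"])  # neighbor labels of item 0 differ
        res = uncertainty(emb, cov, k=2, standardize=False)
        assert res.u[0] == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            n = rng.integers(5, 11)
            emb = rng.normal(size=(n, 3))
            cov = rng.choice(["p", "q", "r"], size=n)
            k = int(rng.integers(2, n - 1))
            res = uncertainty(emb, cov, k=k, standardize=False)
            # brute force: exhaustive distances, argsort, factored entropy
            for i in range(n):
                d = np.linalg.norm(emb - emb[i], axis=1)
                order = [j for j in np.argsort(d, kind="stable") if j != i][:k]
                dd = np.maximum(d[order], 1 + 1e-6)
                labels, counts = np.unique(cov[order], return_counts=True)
                p = counts / counts.sum()
                expected = -(p * np.log(p)).sum() * (1 / np.log(dd)).sum()
                assert res.u[i] == pytest.approx(expected, abs=1e-12)

    def test_k_bounds_enforced_and_duplicates_warn(self):
        emb = np.array([[0.0], [0.0], [1.0]])
        with pytest.raises(ValueError, match="k must"):
            uncertainty(emb, ["a", "b", "c"], k=3)
        with pytest.warns(UserWarning, match="clamped"):
            uncertainty(emb, ["a", "b", "c"], k=1, standardize=False)


class TestExportLatent:
    def test_categorical_export_shape_and_determinism(self, small_results):
        df1 = export_latent(small_results, "status")
        df2 = export_latent(small_results, "status")
        assert df1.shape == (2, small_results.spec.n_latent_attr)
        assert list(df1.index) == ["control", "perturbed"]
        pd.testing.assert_frame_equal(df1, df2)

    def test_ordered_export_requires_features(self, small_results):
        with pytest.raises(ValueError, match="feature set"):
            export_latent(small_results, "dose")
        df = export_latent(small_results, "dose", features=np.array([[0.0], [1.0]]))
        assert df.shape == (2, small_results.spec.n_latent_attr)

    def test_unknown_export_keyed_by_cell(self, small_results):
        df = export_latent(small_results, "unknown")
        assert list(df.index) == small_results.dataset.cell_ids
        assert df.shape == (small_results.dataset.n, small_results.spec.n_latent_u)

    def test_unknown_attribute_name_rejected(self, small_results):
        with pytest.raises(KeyError):
            export_latent(small_results, "no-such-attribute")

    def test_similar_class_effects_stay_close_in_latent(self):
        """Two classes planted with nearly identical effect vectors embed
        closer to each other than to a class with an unrelated effect."""
        from discell import DisentanglementModel, LatentSpec

        rng = np.random.default_rng(21)
        n, m = 450, 60
        base = rng.normal(0, 1, size=m)
        delta = np.zeros(m)
        delta[:15] = 1.2
        effects = {"grpA": np.zeros(m), "grpB": delta, "grpC": 0.9 * delta}
        labels = rng.choice(["grpA", "grpB", "grpC"], size=n)
        logit = base + np.stack([effects[l] for l in labels])
        prop = np.exp(logit - logit.max(axis=1, keepdims=True))
        prop /= prop.sum(axis=1, keepdims=True)
        x = rng.poisson(1500 * prop).astype(float)
        from discell import Attribute, AttributeSchema

        schema = AttributeSchema((Attribute("group", "categorical",
                                            categories=("grpA", "grpB", "grpC")),))
        ds = CellDataset(x=x, schema=schema,
                         attribute_values={"group": labels.astype(object)})
        res = DisentanglementModel(ds, LatentSpec(
            n_latent_attr=8, n_latent_u=8, decoder_width=64,
            family="poisson")).fit(epochs=50, batch_size=128, seed=0)
        df = export_latent(res, "group")
        d = lambda a, b: np.linalg.norm(df.loc[a] - df.loc[b])
        assert d("grpB", "grpC") < d("grpA", "grpB")
        assert d("grpB", "grpC") < d("grpA", "grpC")
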