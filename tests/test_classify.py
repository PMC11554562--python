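"""Semi-supervised training: classification loss, loss additivity,
label imputation and its contracts."""

import numpy as np
import pytest

from discell import (
    AttributePlan,
    LatentSpec,
    SemiSupervisedDisentanglementModel,
    SyntheticConfig,
    classification_loss,
    generate,
    mask_labels,
)


@pytest.fixture(scope="module")
def masked_run():
    cfg = SyntheticConfig(
        n=400, m=60, seed=9,
        attributes=[
            AttributePlan("outcome", "categorical", range(0, 20), 1.0,
                          categories=("abortive", "productive")),
            AttributePlan("zone", "categorical", range(20, 32), 0.7,
                          categories=("periportal", "pericentral")),
        ])
    ds, gt = generate(cfg)
    masked, idx = mask_labels(ds, "outcome", 0.5, seed=4)
    spec = LatentSpec(n_latent_attr=8, n_latent_u=8, decoder_width=64,
                      family="zinb")
    res = SemiSupervisedDisentanglementModel(masked, spec=spec,
                                             classifier_width=64).fit(
        epochs=40, batch_size=128, seed=0)
    return ds, gt, masked, idx, res


class TestClassificationLoss:
    def test_uniform_classifier_scores_ln_k(self, masked_run):
        """A classifier putting (0.5, 0.5) on every cell scores exactly ln 2
        per labeled cell on a 2-class attribute."""
        from discell.classify import ClassifierBank

        _, _, masked, _, _ = masked_run
        bank = ClassifierBank(masked.schema, masked.m, ["outcome"], depth=1,
                              width=8, rng=np.random.default_rng(0),
                              log1p_input=True)
        bank.heads["outcome"].layers[-1].W.data[:] = 0.0
        bank.heads["outcome"].layers[-1].b.data[:] = 0.0
        assert classification_loss(bank, masked) == pytest.approx(np.log(2),
                                                                  abs=1e-12)

    def test_zero_labeled_cells_rejected_at_setup(self, masked_run):
        ds, _, _, _, _ = masked_run
        allgone = ds.copy()
        allgone.attribute_values["outcome"][:] = None
        with pytest.raises(ValueError, match="zero labeled"):
            SemiSupervisedDisentanglementModel(allgone)

    def test_class_without_labeled_support_warns(self, masked_run):
        ds, _, _, _, _ = masked_run
        onesided = ds.copy()
        for i, v in enumerate(onesided.attribute_values["outcome"]):
            if v == "abortive":
                onesided.attribute_values["outcome"][i] = None
        with pytest.warns(UserWarning, match="abortive"):
            SemiSupervisedDisentanglementModel(onesided)


class TestLossAdditivity:
    def test_total_minus_generative_equals_classification(self, masked_run):
        """L_total - (L_cmp + L_min) == L_cls exactly, on the same parameters."""
        _, _, _, _, res = masked_run
        comps = res.loss_components()
        assert comps["total"] - (comps["completeness"] + comps["minimality"]) \
            == pytest.approx(comps["classification"], abs=1e-12)
        assert comps["classification"] == pytest.approx(
            classification_loss(res.bank, res.dataset), abs=1e-12)


class TestImputation:
    def test_masked_recovery_and_confidence(self, masked_run):
        ds, gt, masked, idx, res = masked_run
        completed, table = res.impute_labels()
        true = gt.labels["outcome"][idx]
        imputed = completed.attribute_values["outcome"][idx]
        acc = np.mean([a == b for a, b in zip(true, imputed)])
        assert acc >= 0.9
        imput_rows = table[(table.attribute == "outcome") & (table.flag == "imputed")]
        assert len(imput_rows) == len(idx)
        assert ((imput_rows.confidence > 0.5 - 1e-12) &
                (imput_rows.confidence <= 1.0)).all()

    def test_observed_labels_never_overwritten(self, masked_run):
        _, _, masked, idx, res = masked_run
        completed, table = res.impute_labels()
        observed = np.setdiff1d(np.arange(masked.n), idx)
        before = masked.attribute_values["outcome"][observed]
        after = completed.attribute_values["outcome"][observed]
        assert list(before) == list(after)
        obs_rows = table[(table.attribute == "outcome") & (table.flag == "observed")]
        assert (obs_rows.confidence == 1.0).all()

    def test_classifier_argmax_beats_majority_on_observed(self, masked_run):
        _, gt, masked, idx, res = masked_run
        observed = np.setdiff1d(np.arange(masked.n), idx)
        probs = res.bank.predict_proba("outcome", masked.x[observed])
        attr = masked.schema["outcome"]
        pred = [attr.categories[j] for j in probs.argmax(axis=1)]
        truth = masked.attribute_values["outcome"][observed]
        acc = np.mean([a == b for a, b in zip(pred, truth)])
        _, counts = np.unique(list(truth), return_counts=True)
        majority = counts.max() / counts.sum()
        assert acc > majority

    def test_fully_labeled_data_trains_with_auxiliary_head(self, small_data):
        ds, _ = small_data
        res = SemiSupervisedDisentanglementModel(
            ds, spec=LatentSpec(n_latent_attr=8, n_latent_u=8, decoder_width=64),
            supervised=["status"], classifier_width=32).fit(epochs=5, seed=0)
        comps = res.loss_components()
        assert comps["classification"] > 0
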