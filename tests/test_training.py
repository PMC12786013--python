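"""Splits, the training loop, and the missing-modality harness."""

import numpy as np
import pytest

from idfnet.fusion import ModelConfig
from idfnet.optim import cosine_lr
from idfnet.synthdata import MODALITIES, SyntheticSpec, generate_dataset
from idfnet.training import (
    TrainConfig,
    evaluate_missing_modality,
    modality_probe_auc,
    simulate_missing,
    stratified_group_kfold,
    train,
    train_val_test_split,
)


class TestSplits:
    def test_kfold_sizes_and_patient_integrity(self, small_dataset):
        fa = stratified_group_kfold(small_dataset.manifest, k=5, seed=0)
        assert fa.k == 5
        assert sorted(np.unique(fa.fold)) == [0, 1, 2, 3, 4]
        m = small_dataset.manifest
        for pid in m["patient_id"].unique():
            folds = fa.fold[(m["patient_id"] == pid).to_numpy()]
            assert len(np.unique(folds)) == 1

    def test_kfold_class_balance(self):
        ds = generate_dataset(SyntheticSpec(n_cases=200, class_balance=0.6, image_size=32,
                                            cases_per_patient=2, seed=11))
        fa = stratified_group_kfold(ds.manifest, k=5, seed=0)
        labels = ds.labels()
        global_frac = labels.mean()
        for f in range(5):
            frac = labels[fa.fold == f].mean()
            assert abs(frac - global_frac) <= 0.1

    def test_kfold_needs_enough_patients(self, small_dataset):
        with pytest.raises(ValueError):
            stratified_group_kfold(small_dataset.manifest.iloc[:4], k=5, seed=0)

    def test_holdout_split_grouped_and_stratified(self, small_dataset):
        tr, va, te = train_val_test_split(small_dataset, (0.7, 0.15, 0.15), seed=0)
        assert sorted(tr + va + te) == list(range(len(small_dataset)))
        m = small_dataset.manifest
        sets = [set(m.iloc[list(ix)]["patient_id"]) for ix in (tr, va, te)]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])


class TestConfigAndSchedule:
    def test_cosine_endpoints(self):
        assert cosine_lr(0, 50, 1e-3, 1e-6) == 1e-3
        assert np.isclose(cosine_lr(49, 50, 1e-3, 1e-6), 1e-6)
        lrs = [cosine_lr(e, 50, 1e-3, 1e-6) for e in range(50)]
        assert min(lrs) >= 1e-6 and np.all(np.diff(lrs) < 0)

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=1e-7, min_lr=1e-6)
        with pytest.raises(ValueError):
            TrainConfig(patience=0)
        with pytest.raises(ValueError):
            TrainConfig(modality_dropout=1.5)


class TestSimulateMissing:
    def test_only_named_modality_zeroed(self, small_dataset):
        case = small_dataset.cases[0]
        out = simulate_missing(case, "endoscopy")
        assert not out.endoscopy.any()
        assert np.array_equal(out.ct, case.ct)
        assert np.array_equal(out.histology, case.histology)
        assert out.present["endoscopy"] is False
        assert case.present["endoscopy"] is True  # original untouched

    def test_idempotent(self, small_dataset):
        once = simulate_missing(small_dataset.cases[0], "ct")
        twice = simulate_missing(once, "ct")
        assert np.array_equal(once.ct, twice.ct)

    def test_unknown_modality_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            simulate_missing(small_dataset.cases[0], "mri")

    def test_all_three_zeroed_gives_constant_output(self, untrained_model, small_dataset):
        blanked = []
        for c in small_dataset.cases[:6]:
            for m in MODALITIES:
                c = simulate_missing(c, m)
            blanked.append(c)
        probs = untrained_model.predict(blanked).probability
        assert np.allclose(probs, probs[0])


class TestTrainLoop:
    @pytest.fixture(scope="class")
    def short_run(self):
        ds = generate_dataset(SyntheticSpec(n_cases=80, image_size=32,
                                            cases_per_patient=2, seed=21))
        tr, va, _ = train_val_test_split(ds, seed=21)
        mc = ModelConfig(image_size=32, d_latent=16, d_fused=32, n_heads=4, seed=21)
        cfg = TrainConfig.desk(max_epochs=6, patience=6, seed=21)
        result = train([ds.cases[i] for i in tr], [ds.cases[i] for i in va],
                       model_config=mc, config=cfg)
        return ds, tr, va, result

    def test_loss_decreases(self, short_run):
        _, _, _, result = short_run
        h = result.history
        assert h.loss_bce.iloc[-1] < h.loss_bce.iloc[0]

    def test_history_schema_and_lr(self, short_run):
        _, _, _, result = short_run
        h = result.history
        assert {"epoch", "lr", "loss_total", "loss_bce", "loss_entropy", "loss_l2",
                "val_auc", "val_routing_entropy"} <= set(h.columns)
        assert np.isclose(h.lr.iloc[0], 2e-3)

    def test_best_checkpoint_matches_best_val_auc(self, short_run):
        _, _, _, result = short_run
        assert np.isclose(result.best_val_auc, result.history.val_auc.max())

    def test_same_seed_identical_first_epoch_loss(self, short_run):
        ds, tr, va, result = short_run
        mc = ModelConfig(image_size=32, d_latent=16, d_fused=32, n_heads=4, seed=21)
        cfg = TrainConfig.desk(max_epochs=1, patience=1, seed=21)
        rerun = train([ds.cases[i] for i in tr], [ds.cases[i] for i in va],
                      model_config=mc, config=cfg)
        assert round(rerun.history.loss_total.iloc[0], 6) == round(
            result.history.loss_total.iloc[0], 6
        )

    def test_empty_split_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            train([], small_dataset.cases[:2])


def test_rws_sampling_used_for_imbalanced_data():
    """An imbalanced dataset still trains (reweighted sampling path)."""
    ds = generate_dataset(SyntheticSpec(n_cases=80, class_balance=0.25, image_size=32,
                                        cases_per_patient=2, seed=31))
    tr, va, _ = train_val_test_split(ds, seed=31)
    mc = ModelConfig(image_size=32, d_latent=16, d_fused=32, n_heads=4, seed=31)
    result = train([ds.cases[i] for i in tr], [ds.cases[i] for i in va],
                   model_config=mc, config=TrainConfig.desk(max_epochs=4, patience=4, seed=31))
    assert np.isfinite(result.history.loss_total).all()


def test_evaluate_missing_modality_rows_and_determinism(untrained_model, small_dataset):
    cases = small_dataset.cases[:20]
    a = evaluate_missing_modality(untrained_model, cases)
    b = evaluate_missing_modality(untrained_model, cases)
    assert list(a.scenario) == ["all", "missing_endoscopy", "missing_ct", "missing_histology"]
    assert a.equals(b)
    assert ((a.accuracy >= 0) & (a.accuracy <= 1)).all()


def test_all_noise_dataset_trains_to_chance():
    """With reliability 0 everywhere there is no signal: val AUC near 0.5."""
    ds = generate_dataset(SyntheticSpec(n_cases=120, image_size=32, reliability=0.0,
                                        cases_per_patient=2, seed=41))
    tr, va, _ = train_val_test_split(ds, seed=41)
    mc = ModelConfig(image_size=32, d_latent=16, d_fused=32, n_heads=4, seed=41)
    result = train([ds.cases[i] for i in tr], [ds.cases[i] for i in va],
                   model_config=mc, config=TrainConfig.desk(max_epochs=8, patience=8, seed=41))
    # best-of-epochs selection biases upward on a small validation set
    assert result.best_val_auc <= 0.75
    assert result.history.val_auc.iloc[-1] <= 0.7
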