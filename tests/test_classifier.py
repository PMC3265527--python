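import numpy as np
import pytest

from mirevo.classifier import (
    SVMParams,
    TrainedModel,
    TrainingRecord,
    expand_negatives,
    fit_scaler,
    mirna_disjoint_split,
    predict,
    train_svm,
)
from mirevo.core_seq import MiRNA, UTRSequence, reverse_complement
from mirevo.features import FEATURE_NAMES, FeatureVector
from mirevo.ga import GAConfig


def fv_from_array(arr):
    return FeatureVector(*arr)


def gaussian_records(rng, n_per_class, sep=2.0, sigma=0.1):
    records = []
    for label, center in ((0, 0.0), (1, sep)):
        X = rng.normal(center, sigma, size=(n_per_class, 25))
        for k, row in enumerate(X):
            records.append(
                TrainingRecord(fv_from_array(row), label,
                               mirna_id=f"mir-{k % 10}", gene_id=f"g{k}")
            )
    return records


class TestScaler:
    def test_affine_map_to_unit_interval(self):
        s = fit_scaler(np.array([[2.0], [4.0]]))
        out = s.transform(np.array([[2.0], [4.0], [3.0]]))
        assert out.ravel().tolist() == [-1.0, 1.0, 0.0]

    def test_degenerate_feature_maps_to_zero(self):
        s = fit_scaler(np.array([[5.0, 1.0], [5.0, 3.0]]))
        out = s.transform(np.array([[5.0, 2.0], [7.0, 2.0]]))
        assert out[:, 0].tolist() == [0.0, 0.0]

    def test_extrapolation_unclipped(self):
        s = fit_scaler(np.array([[2.0], [4.0]]))
        assert s.transform(np.array([[5.0]])).item() == pytest.approx(2.0)

    def test_needs_two_records(self):
        with pytest.raises(ValueError):
            fit_scaler(np.array([[1.0, 2.0]]))


class TestTrainPredict:
    def test_separable_classes_high_heldout_accuracy(self, rng):
        records = gaussian_records(rng, 100)
        train = records[:80] + records[100:180]
        test = records[80:100] + records[180:]
        model = train_svm(train, SVMParams())
        labels, _ = predict(model, [r.features for r in test])
        truth = np.array([r.label for r in test])
        assert (labels == truth).mean() >= 0.95

    def test_hard_margin_fits_training_set(self, rng):
        records = gaussian_records(rng, 40, sep=4.0)
        model = train_svm(records, SVMParams(kernel="linear", C=1000.0))
        labels, _ = predict(model, [r.features for r in records])
        assert (labels == np.array([r.label for r in records])).all()

    def test_retrain_same_seed_identical_predictions(self, rng):
        records = gaussian_records(rng, 50)
        m1 = train_svm(records, rng_seed=5)
        m2 = train_svm(records, rng_seed=5)
        _, d1 = predict(m1, [r.features for r in records])
        _, d2 = predict(m2, [r.features for r in records])
        assert np.array_equal(d1, d2)

    def test_single_class_rejected(self, rng):
        records = [r for r in gaussian_records(rng, 20) if r.label == 1]
        with pytest.raises(ValueError):
            train_svm(records)

    def test_empty_candidates_give_empty_output(self, rng):
        model = train_svm(gaussian_records(rng, 20))
        labels, dec = predict(model, [])
        assert len(labels) == 0 and len(dec) == 0

    def test_feature_order_mismatch_rejected(self, rng):
        model = train_svm(gaussian_records(rng, 20))
        with pytest.raises(ValueError):
            predict(model, [], feature_order=tuple(reversed(FEATURE_NAMES)))

    def test_decision_threshold_sweep_monotone(self, rng):
        records = gaussian_records(rng, 100, sep=1.0, sigma=0.5)
        model = train_svm(records[:120])
        test = records[120:]
        _, dec = predict(model, [r.features for r in test])
        truth = np.array([r.label for r in test])
        sens, npos = [], []
        for thr in np.linspace(dec.min() - 0.1, dec.max() + 0.1, 15):
            called = dec > thr
            npos.append(called.sum())
            sens.append((called & (truth == 1)).sum() / max(1, (truth == 1).sum()))
        # lowering the operating point can only add predictions
        assert all(a >= b for a, b in zip(npos, npos[1:]))
        assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SVMParams(kernel="sigmoid")
        with pytest.raises(ValueError):
            SVMParams(C=-1.0)

    def test_model_persistence_roundtrip(self, rng, tmp_path):
        records = gaussian_records(rng, 30)
        model = train_svm(records)
        path = tmp_path / "model.bin"
        model.save(path)
        loaded = TrainedModel.load(path)
        _, d1 = predict(model, [r.features for r in records])
        _, d2 = predict(loaded, [r.features for r in records])
        assert np.allclose(d1, d2)


class TestExpandNegatives:
    MIRNA = MiRNA("mir-x", "UGAGGUAGUAGGUUGUAUAGUU")

    def test_unmappable_utr_contributes_nothing(self):
        utr = UTRSequence("gc-desert", "G" * 300)
        records = expand_negatives(
            [self.MIRNA], [utr], ga_cfg=GAConfig(rng_seed=2, offspring_per_generation=40)
        )
        assert records == []

    def test_implanted_decoy_recovered_as_negative(self, rng):
        from conftest import random_rna

        rc = reverse_complement(self.MIRNA.sequence)
        seq = random_rna(rng, 120) + rc + random_rna(rng, 120)
        utr = UTRSequence("decoy-utr", seq)
        records = expand_negatives(
            [self.MIRNA], [utr], ga_cfg=GAConfig(rng_seed=2, offspring_per_generation=40)
        )
        assert any(r.gene_id == "decoy-utr" for r in records)
        assert all(r.label == 0 and r.provenance == "expanded_negative" for r in records)

    def test_max_per_pair_caps_output(self, rng):
        from conftest import random_rna

        rc = reverse_complement(self.MIRNA.sequence)
        seq = random_rna(rng, 60) + rc + random_rna(rng, 60) + rc + random_rna(rng, 60)
        utr = UTRSequence("double", seq)
        cfg = GAConfig(rng_seed=2, offspring_per_generation=40)
        all_recs = expand_negatives([self.MIRNA], [utr], ga_cfg=cfg)
        capped = expand_negatives([self.MIRNA], [utr], ga_cfg=cfg, max_per_pair=1)
        assert len(all_recs) > 1
        assert len(capped) == 1


class TestSplit:
    def test_split_shares_no_mirna(self, rng):
        records = gaussian_records(rng, 50)
        train, test = mirna_disjoint_split(records, 0.3, rng_seed=1)
        assert {r.mirna_id for r in train}.isdisjoint({r.mirna_id for r in test})
        assert len(train) + len(test) == len(records)
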