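import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from oracles import nearest_centroid_oracle
from ucrna.classify import (
    NearestShrunkenCentroid,
    cross_validate_nsc,
    extract_signature,
    predict_nsc,
    train_nsc,
)


def _separable(rng, n_per_class=15, n_features=30, n_informative=8, effect=3.0, sigma=0.3):
    X = rng.normal(0, sigma, size=(2 * n_per_class, n_features))
    X[n_per_class:, :n_informative] += effect
    y = np.array(["nontumor"] * n_per_class + ["tumor"] * n_per_class)
    return X, y


class TestFitAndShrinkage:
    def test_delta_zero_keeps_raw_differences(self, rng):
        X, y = _separable(rng)
        mdl = NearestShrunkenCentroid(delta=0.0).fit(X, y)
        assert np.allclose(mdl.shrunken_dik_, mdl.dik_)

    def test_full_shrinkage_leaves_priors_only(self, rng):
        X = rng.normal(size=(12, 10))
        y = np.array(["a"] * 4 + ["b"] * 8)
        mdl = NearestShrunkenCentroid(delta=0.0).fit(X, y)
        big = np.abs(mdl.dik_).max() + 1.0
        shrunk = mdl.with_delta(big)
        assert (shrunk.shrunken_dik_ == 0).all()
        # with all differences gone the majority class wins everywhere
        preds = shrunk.predict(rng.normal(size=(20, 10)))
        assert (preds == "b").all()

    def test_two_probe_toy_shrinks_constant_probe_only(self):
        # probe 1 separates the classes, probe 2 is constant
        X = np.array([[0.0, 5.0], [0.2, 5.0], [2.0, 5.0], [2.2, 5.0]])
        y = np.array(["a", "a", "b", "b"])
        mdl = NearestShrunkenCentroid(delta=0.5).fit(X, y)
        assert (mdl.shrunken_dik_[:, 1] == 0).all()
        assert (mdl.shrunken_dik_[:, 0] != 0).any()

    def test_class_with_one_sample_rejected(self):
        X = np.zeros((3, 4))
        with pytest.raises(ValueError, match="fewer than 2"):
            NearestShrunkenCentroid().fit(X, np.array(["a", "a", "b"]))

    def test_mk_definition(self, rng):
        X, y = _separable(rng, n_per_class=10)
        mdl = NearestShrunkenCentroid().fit(X, y)
        n = len(y)
        assert np.allclose(mdl.mk_**2, 1.0 / np.array([10, 10]) - 1.0 / n)


class TestPredict:
    def test_sample_at_centroid_classified_there(self, rng):
        X, y = _separable(rng)
        mdl = NearestShrunkenCentroid(delta=0.0, priors=[0.5, 0.5]).fit(X, y)
        preds = mdl.predict(mdl.shrunken_centroids_)
        assert list(preds) == list(mdl.classes_)

    def test_delta_zero_equals_nearest_centroid_oracle(self, rng):
        X, y = _separable(rng, effect=1.0, sigma=1.0)
        X_test = rng.normal(0.5, 1.0, size=(40, X.shape[1]))
        mdl = NearestShrunkenCentroid(delta=0.0).fit(X, y)
        expected = nearest_centroid_oracle(X, y, X_test, mdl.s0_)
        assert (mdl.predict(X_test) == expected).all()

    def test_tie_flag_lexicographic(self):
        X = np.array([[0.0], [0.2], [1.0], [1.2]])
        y = np.array(["a", "a", "b", "b"])
        mdl = NearestShrunkenCentroid(delta=0.0, priors=[0.5, 0.5]).fit(X, y)
        labels, _, ties = mdl.predict_with_scores(np.array([[0.6]]))  # midpoint
        assert ties[0]
        assert labels[0] == "a"

    def test_feature_mismatch_rejected(self, rng):
        X, y = _separable(rng)
        mdl = NearestShrunkenCentroid().fit(X, y)
        with pytest.raises(ValueError, match="features"):
            mdl.predict(np.zeros((2, X.shape[1] + 1)))


class TestSignature:
    def test_nonincreasing_in_delta(self, rng):
        X, y = _separable(rng, effect=1.5, sigma=1.0)
        mdl = NearestShrunkenCentroid(delta=0.0).fit(X, y)
        sizes = [
            int(mdl.with_delta(d).signature_mask_.sum())
            for d in np.arange(0.0, 4.01, 0.25)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_full_shrinkage_empty_signature(self, rng):
        X, y = _separable(rng)
        mdl = NearestShrunkenCentroid(delta=0.0).fit(X, y)
        shrunk = mdl.with_delta(np.abs(mdl.dik_).max() + 1)
        m = make_matrix(X.T)
        assert len(extract_signature(shrunk, m.probe_ids)) == 0

    def test_planted_probes_recovered_at_tuned_delta(self, rng):
        X, y = _separable(rng, n_informative=6, effect=3.0, sigma=0.2)
        m = make_matrix(X.T)
        labels = pd.Series(y, index=m.sample_ids)
        mdl = train_nsc(m, labels, delta=0.0)
        # pick the delta that exactly separates planted from background
        cut = np.abs(mdl.dik_[:, 6:]).max() + 1e-9
        sig = extract_signature(mdl.with_delta(cut), m.probe_ids)
        assert set(sig.index) == set(m.probe_ids[:6])


class TestCrossValidation:
    def test_separable_data_reaches_zero_error(self, rng):
        X, y = _separable(rng, effect=3.0, sigma=0.1)
        m = make_matrix(X.T)
        labels = pd.Series(y, index=m.sample_ids)
        report = cross_validate_nsc(m, labels, k_folds=5, seed=0)
        assert report.cv_errors["overall_error"].min() == 0.0
        assert (report.predictions["predicted"] == report.predictions["true"]).all()

    def test_permuted_labels_error_near_majority_rate(self, rng):
        X, y = _separable(rng, n_per_class=20, effect=2.0, sigma=0.5)
        y_perm = rng.permutation(y)
        m = make_matrix(X.T)
        labels = pd.Series(y_perm, index=m.sample_ids)
        report = cross_validate_nsc(m, labels, k_folds=5, seed=0)
        chosen = report.cv_errors.loc[
            report.cv_errors["delta"] == report.chosen_delta, "overall_error"
        ].iloc[0]
        assert chosen >= 0.3  # majority rate is 0.5; allow sampling slack

    def test_single_delta_grid(self, rng):
        X, y = _separable(rng)
        m = make_matrix(X.T)
        labels = pd.Series(y, index=m.sample_ids)
        report = cross_validate_nsc(m, labels, delta_grid=[0.7], k_folds=3, seed=0)
        assert report.chosen_delta == 0.7

    def test_k_folds_above_min_class_size(self, rng):
        X, y = _separable(rng, n_per_class=4)
        m = make_matrix(X.T)
        labels = pd.Series(y, index=m.sample_ids)
        with pytest.raises(ValueError, match="leave-one-out"):
            cross_validate_nsc(m, labels, k_folds=5, seed=0)

    def test_folds_partition_samples(self, rng):
        from sklearn.model_selection import StratifiedKFold

        X, y = _separable(rng, n_per_class=10)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
        seen = np.concatenate([te for _, te in skf.split(X, y)])
        assert sorted(seen) == list(range(len(y)))


class TestMatrixFrontend:
    def test_train_predict_roundtrip(self, rng):
        X, y = _separable(rng)
        m = make_matrix(X.T)
        labels = pd.Series(y, index=m.sample_ids)
        mdl = train_nsc(m, labels, delta=0.0)
        out = predict_nsc(mdl, m)
        assert (out["predicted"].to_numpy() == y).mean() > 0.9
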