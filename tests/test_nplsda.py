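"""NPLS-DA: two-way PLS oracle equivalence, score/weight invariants,
cross-validation behaviour and null calibration."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from triomics.nplsda import (
    _fold_indices,
    cross_validate,
    fit_nplsda,
    predict,
)

from conftest import prepared_tensor


def pls2_reference(X, Y, H):
    """Independent matrix-space PLS2 with response-only deflation.

    Weights from the SVD of X_c' Y_res per component, scores t = X_c w,
    response deflated by regression on the accumulated scores.  Written
    directly against matrices — no tensors, no shared code paths.
    """
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    W, T = [], []
    Yres = Yc.copy()
    for _ in range(H):
        u, _, _ = np.linalg.svd(Xc.T @ Yres, full_matrices=False)
        w = u[:, 0]
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        W.append(w)
        T.append(Xc @ w)
        Tm = np.column_stack(T)
        coef, *_ = np.linalg.lstsq(Tm, Yc, rcond=None)
        Yres = Yc - Tm @ coef
    return np.column_stack(W), np.column_stack(T)


@pytest.fixture(scope="module")
def matrix_problem():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(30, 12))
    beta = rng.normal(size=12)
    labels = np.where(X @ beta + rng.normal(size=30) > 0, "case", "control")
    return X, labels


class TestOracleEquivalence:
    def test_single_timepoint_matches_two_way_pls(self, matrix_problem):
        """An N-way fit on a K=1 tensor is exactly two-way PLS."""
        X, labels = matrix_problem
        model = fit_nplsda(X[:, :, None], labels, 3)
        Y = np.column_stack(
            [(labels == "case").astype(float), (labels == "control").astype(float)]
        )
        W_ref, T_ref = pls2_reference(X, Y, 3)
        assert np.max(np.abs(model.mode2_weights - W_ref)) < 1e-8
        assert np.max(np.abs(model.mode1_scores - T_ref)) < 1e-8
        # the timepoint weight of a K=1 tensor is a sign
        np.testing.assert_allclose(np.abs(model.mode3_weights), 1.0, atol=1e-12)

    def test_first_component_matches_sklearn(self, matrix_problem):
        """Cross-check the leading weight vector against an external
        implementation (identical for every PLS variant)."""
        X, labels = matrix_problem
        model = fit_nplsda(X[:, :, None], labels, 1)
        sk = PLSRegression(n_components=1, scale=False).fit(
            X, (labels == "case").astype(float)
        )
        w_sk, w = sk.x_weights_[:, 0], model.mode2_weights[:, 0]
        dev = min(np.max(np.abs(w - w_sk)), np.max(np.abs(w + w_sk)))
        assert dev < 1e-8


class TestModelInvariants:
    def test_scores_are_tensor_contractions_with_weights(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 8, 5))
        labels = np.array(["case", "control"] * 10)
        m = fit_nplsda(x, labels, 3)
        xc = (x - x.mean(axis=0)).reshape(20, -1)
        for h in range(3):
            t_direct = xc @ np.kron(m.mode2_weights[:, h], m.mode3_weights[:, h])
            np.testing.assert_allclose(m.mode1_scores[:, h], t_direct, atol=1e-10)

    def test_weight_columns_unit_norm_and_sign_convention(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(16, 6, 5))
        labels = np.array(["case"] * 8 + ["control"] * 8)
        m = fit_nplsda(x, labels, 2)
        np.testing.assert_allclose(np.linalg.norm(m.mode2_weights, axis=0), 1.0, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(m.mode3_weights, axis=0), 1.0, atol=1e-10)
        for h in range(2):
            w = m.mode2_weights[:, h]
            assert w[np.argmax(np.abs(w))] > 0

    def test_r2y_non_decreasing_in_components(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(24, 10, 5))
        labels = np.array(["case", "control"] * 12)
        r2 = [fit_nplsda(x, labels, h).r2y for h in (1, 2, 3, 4)]
        assert all(b >= a - 1e-10 for a, b in zip(r2, r2[1:]))

    def test_single_class_labels_error(self):
        x = np.zeros((6, 4, 5)) + np.random.default_rng(0).normal(size=(6, 4, 5))
        with pytest.raises(ValueError, match="single class"):
            fit_nplsda(x, np.array(["case"] * 6), 1)

    def test_too_many_components_error(self):
        x = np.random.default_rng(0).normal(size=(6, 4, 5))
        labels = np.array(["case", "control"] * 3)
        with pytest.raises(ValueError):
            fit_nplsda(x, labels, 10)


class TestPredict:
    def test_training_set_self_consistency(self, signal_tensor):
        norm, labels, _, _ = signal_tensor
        m = fit_nplsda(norm.values, labels, 2)
        yhat, scores, proba = predict(m, norm.values)
        np.testing.assert_allclose(scores, m.mode1_scores, atol=1e-10)
        assert np.mean(yhat == labels) == 1.0

    def test_held_out_subjects_with_strong_signal(self):
        norm, labels, _, _ = prepared_tensor(
            21, 2.0, n_pairs=30, n_features=60, n_informative=5
        )
        train = np.arange(0, 40)
        test = np.arange(40, len(labels))
        m = fit_nplsda(norm.values[train], labels[train], 2)
        yhat, _, _ = predict(m, norm.values[test])
        assert np.mean(yhat == labels[test]) >= 0.9

    def test_mode_mismatch_error_names_the_mode(self):
        x = np.random.default_rng(0).normal(size=(10, 6, 5))
        labels = np.array(["case", "control"] * 5)
        m = fit_nplsda(x, labels, 1)
        with pytest.raises(ValueError, match="feature mode"):
            predict(m, x[:, :4, :])
        with pytest.raises(ValueError, match="timepoint mode"):
            predict(m, x[:, :, :3])

    def test_all_zero_subject_slice_is_deterministic(self):
        x = np.random.default_rng(1).normal(size=(10, 6, 5))
        labels = np.array(["case", "control"] * 5)
        m = fit_nplsda(x, labels, 1)
        y1, _, _ = predict(m, np.zeros((1, 6, 5)))
        y2, _, _ = predict(m, np.zeros((1, 6, 5)))
        assert y1[0] == y2[0]
        assert y1[0] in ("case", "control")


class TestCrossValidation:
    def test_loo_performs_one_fit_per_subject(self):
        labels = np.array(["case", "control"] * 6)
        folds = _fold_indices("loo", labels, np.random.default_rng(0))
        assert len(folds) == 12
        covered = np.sort(np.concatenate([t for t, _ in folds]))
        np.testing.assert_array_equal(covered, np.arange(12))

    def test_kfold_predictions_cover_every_sample_once(self, signal_tensor):
        norm, labels, pairs, _ = signal_tensor
        res = cross_validate(
            norm.values, labels, 2, "5fold", n_repeats=2, seed=3, pair_ids=pairs
        )
        assert res.predictions.shape == (2, len(labels))

    def test_null_labels_give_low_q2(self):
        """Labels independent of the data: pair-grouped CV Q2 near or below 0."""
        q2s = []
        for seed in range(5):
            norm, labels, pairs, _ = prepared_tensor(
                300 + seed, 0.0, n_pairs=15, n_features=40
            )
            cv = cross_validate(
                norm.values, labels, 2, "5fold", seed=seed, pair_ids=pairs
            )
            q2s.append(cv.q2_mean)
        assert np.mean(q2s) <= 0.1

    def test_null_training_r2y_low_when_samples_dominate(self):
        """With many more subjects than unfolded variables, pure-noise
        training R2Y for a 2-component model stays small."""
        rng = np.random.default_rng(17)
        r2s = []
        for _ in range(10):
            x = rng.normal(size=(120, 3, 5))
            labels = np.where(rng.random(120) > 0.5, "case", "control")
            r2s.append(fit_nplsda(x, labels, 2).r2y)
        assert np.mean(r2s) < 0.3

    def test_q2_at_most_r2_on_signal(self, signal_tensor):
        norm, labels, pairs, _ = signal_tensor
        m = fit_nplsda(norm.values, labels, 2)
        cv = cross_validate(norm.values, labels, 2, "5fold", seed=1, pair_ids=pairs)
        assert cv.q2_mean <= m.r2y + 0.02

    def test_schemes_agree_on_strong_signal(self, signal_tensor):
        norm, labels, pairs, _ = signal_tensor
        q2 = {
            s: cross_validate(
                norm.values, labels, 2, s, seed=5, pair_ids=pairs
            ).q2_mean
            for s in ("loo", "5fold", "10fold")
        }
        assert abs(q2["5fold"] - q2["10fold"]) < 0.1
        assert abs(q2["5fold"] - q2["loo"]) < 0.1

    def test_fold_count_exceeding_class_size_errors(self):
        x = np.random.default_rng(0).normal(size=(6, 4, 5))
        labels = np.array(["case", "control"] * 3)
        with pytest.raises(ValueError):
            cross_validate(x, labels, 1, "10fold")
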