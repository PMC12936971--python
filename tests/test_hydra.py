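"""HYDRA polytope clustering: recovery, stability, transfer scoring."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.svm import SVC

from msnbiotype.hydra import (
    HydraModel,
    cv_select_k,
    expression_scores,
    fit_hydra,
    permutation_validate,
    split_half_validate,
    stability_ari,
)


def planted_clusters(n_ctrl=150, n_case=150, p=40, sep=3.0, k=3, seed=0):
    """Controls at the origin; case clusters displaced in distinct directions."""
    rng = np.random.default_rng(seed)
    X_ctrl = rng.normal(0, 1, (n_ctrl, p))
    dirs = np.zeros((k, p))
    for j in range(k):
        sign = -1 if j % 2 else 1
        dirs[j, j * 5 : (j + 1) * 5] = sign * sep
    bt = rng.integers(0, k, n_case)
    X_case = rng.normal(0, 1, (n_case, p)) + dirs[bt]
    X = np.vstack([X_ctrl, X_case])
    y = np.concatenate([np.zeros(n_ctrl, bool), np.ones(n_case, bool)])
    return X, y, bt


class TestFit:
    def test_k1_reduces_to_plain_linear_svm(self):
        X, y, _ = planted_clusters(n_ctrl=60, n_case=60, p=10, k=1, seed=1)
        model = fit_hydra(X, y, k=1, seed=0, C=1.0)
        Xs = (X - model.scaler_mean) / model.scaler_scale
        svm = SVC(kernel="linear", C=1.0)
        sw = np.concatenate([np.ones(60), np.full(60, 1.0)])  # case_weight = k*nc/nk = 1
        svm.fit(Xs, np.where(y, 1, -1), sample_weight=sw)
        mine = Xs @ model.weights[0] + model.biases[0]
        ref = svm.decision_function(Xs)
        assert np.allclose(mine, ref, atol=1e-6)

    def test_two_flanking_clusters_recovered(self):
        X, y, bt = planted_clusters(n_ctrl=150, n_case=150, k=2, sep=3.0, seed=2)
        model = fit_hydra(X, y, k=2, n_restarts=5, seed=0)
        assert adjusted_rand_score(bt, model.case_labels) >= 0.95

    def test_three_clusters_recovered(self):
        X, y, bt = planted_clusters(k=3, sep=3.0, seed=3)
        model = fit_hydra(X, y, k=3, n_restarts=5, seed=0)
        assert adjusted_rand_score(bt, model.case_labels) >= 0.95

    def test_duplicating_subjects_leaves_labels_unchanged(self):
        X, y, bt = planted_clusters(n_ctrl=60, n_case=45, p=20, k=2, seed=4)
        m1 = fit_hydra(X, y, k=2, n_restarts=3, seed=0)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        m2 = fit_hydra(X2, y2, k=2, n_restarts=3, seed=0)
        n_case = int(y.sum())
        assert adjusted_rand_score(m1.case_labels, m2.case_labels[:n_case]) == pytest.approx(1.0)
        assert np.array_equal(m2.case_labels[:n_case], m2.case_labels[n_case:])

    def test_objective_monotone_along_trajectory(self):
        X, y, _ = planted_clusters(seed=5)
        model = fit_hydra(X, y, k=3, n_restarts=3, seed=1)
        traj = np.array(model.objective_trajectory)
        assert np.all(np.diff(traj) <= np.abs(traj[:-1]) * 1e-6 + 1e-6)

    def test_errors(self):
        X, y, _ = planted_clusters(n_ctrl=20, n_case=10, p=5, k=1, seed=6)
        with pytest.raises(ValueError, match="exceeds"):
            fit_hydra(X, y, k=50)
        with pytest.raises(ValueError, match="both classes"):
            fit_hydra(X[y], y[y], k=2)

    def test_deterministic_given_seed(self):
        X, y, _ = planted_clusters(n_ctrl=50, n_case=40, p=12, k=2, seed=7)
        m1 = fit_hydra(X, y, k=2, n_restarts=3, seed=9)
        m2 = fit_hydra(X, y, k=2, n_restarts=3, seed=9)
        assert np.array_equal(m1.case_labels, m2.case_labels)
        assert np.allclose(m1.weights, m2.weights)


class TestExpressionScores:
    def test_self_consistency(self):
        X, y, _ = planted_clusters(seed=8)
        model = fit_hydra(X, y, k=3, n_restarts=3, seed=0)
        scores = expression_scores(model, X[y])
        agreement = np.mean(scores.assignment == model.case_labels)
        assert agreement >= 0.95

    def test_affine_in_x(self):
        X, y, _ = planted_clusters(n_ctrl=40, n_case=30, p=8, k=2, seed=9)
        model = fit_hydra(X, y, k=2, n_restarts=3, seed=0)
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, (2, 8))
        for lam in (0.0, 0.3, 0.7, 1.0):
            x = lam * a + (1 - lam) * b
            s = expression_scores(model, x[None]).scores[0]
            sa = expression_scores(model, a[None]).scores[0]
            sb = expression_scores(model, b[None]).scores[0]
            assert np.allclose(s, lam * sa + (1 - lam) * sb, atol=1e-10)

    def test_feature_name_mismatch_raises(self):
        X, y, _ = planted_clusters(n_ctrl=30, n_case=20, p=4, k=1, seed=10)
        model = fit_hydra(X, y, k=1, feature_names=["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="feature mismatch"):
            expression_scores(model, X, feature_names=["a", "b", "c", "x"])

    def test_serialization_round_trip(self):
        X, y, _ = planted_clusters(n_ctrl=30, n_case=24, p=6, k=2, seed=11)
        model = fit_hydra(X, y, k=2, n_restarts=3, seed=0, feature_names=list("abcdef"))
        restored = HydraModel.from_dict(model.to_dict())
        s1 = expression_scores(model, X).scores
        s2 = expression_scores(restored, X).scores
        assert np.allclose(s1, s2)


class TestModelSelection:
    def test_planted_k_chosen(self):
        X, y, bt = planted_clusters(n_ctrl=120, n_case=120, k=3, sep=3.0, seed=12)
        table, chosen = cv_select_k(X, y, k_grid=(2, 3, 4), n_folds=5, seed=0, n_restarts=3)
        assert chosen == 3
        assert table.loc[table["k"] == 3, "ari"].iloc[0] >= 0.8

    def test_noise_cases_low_ari(self):
        rng = np.random.default_rng(13)
        X = rng.normal(0, 1, (160, 20))
        y = np.zeros(160, bool)
        y[80:] = True
        table, _ = cv_select_k(X, y, k_grid=(2, 3), n_folds=4, seed=0, n_restarts=2)
        assert (table["ari"] < 0.35).all()

    def test_split_half_peaks_at_planted_k(self):
        X, y, _ = planted_clusters(n_ctrl=100, n_case=100, k=3, sep=3.0, seed=14)
        table = split_half_validate(X, y, k_grid=(2, 3, 4), n_splits=3, seed=0, n_restarts=3)
        best = int(table.loc[table["ari"].idxmax(), "k"])
        assert best == 3
        assert table["ari"].between(-1, 1).all()

    def test_split_half_deterministic(self):
        X, y, _ = planted_clusters(n_ctrl=60, n_case=60, p=15, k=2, seed=15)
        t1 = split_half_validate(X, y, k_grid=(2,), n_splits=2, seed=4, n_restarts=2)
        t2 = split_half_validate(X, y, k_grid=(2,), n_splits=2, seed=4, n_restarts=2)
        assert t1.equals(t2)


class TestPermutationValidation:
    def test_structured_data_significant(self):
        X, y, _ = planted_clusters(n_ctrl=80, n_case=80, p=30, k=2, sep=3.0, seed=16)
        obs, null, p = permutation_validate(X, y, k=2, n_perm=19, seed=0, n_splits=2, n_restarts=2)
        assert obs > np.percentile(null, 95)
        assert p == pytest.approx(1 / 20)

    def test_p_lower_bound(self):
        X, y, _ = planted_clusters(n_ctrl=40, n_case=30, p=10, k=2, seed=17)
        _, _, p = permutation_validate(X, y, k=2, n_perm=9, seed=0, n_splits=2, n_restarts=2)
        assert p >= 1 / 10


class TestTransferFidelity:
    def test_transfer_matches_fresh_model_on_shared_process(self):
        """Mirrors cross-cohort replication: a pretrained polytope applied
        to a second cohort from the same generative process agrees with a
        freshly trained one."""
        X1, y1, _ = planted_clusters(seed=18)
        X2, y2, bt2 = planted_clusters(seed=19)
        pretrained = fit_hydra(X1, y1, k=3, n_restarts=5, seed=0)
        transferred = expression_scores(pretrained, X2[y2]).assignment
        fresh = fit_hydra(X2, y2, k=3, n_restarts=5, seed=1)
        assert adjusted_rand_score(transferred, fresh.case_labels) >= 0.6
        assert adjusted_rand_score(transferred, bt2) >= 0.6
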