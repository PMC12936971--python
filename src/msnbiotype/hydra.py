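"""HYDRA: semi-supervised max-margin polytope clustering of case deviations.

K linear max-margin classifiers (faces) are fitted so that every face
separates the full control group (negative side) from its assigned subset
of cases (positive side); jointly the faces form a convex polytope that
encloses the control distribution, and each case's face defines its
biotype.  Fitting alternates between (i) per-face weighted linear SVM
fits given the current case-to-face assignment and (ii) reassignment of
each case to the face with the largest decision value, from several
seeded random balanced initializations; the restart ensemble is reduced
by spectral consensus over the case co-assignment matrix, followed by a
final alternating refit from the consensus labels so the returned
polytope is consistent with the returned labels.

Expression scores E_ij = (w_j . x_i + b_j) (optionally normalized by
||w_j||) evaluate any subject against each face; row argmax transfers the
biotype assignment to new cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC
from sklearn.cluster import KMeans, SpectralClustering
from sklearn.metrics import adjusted_rand_score
from sklearn.model_selection import KFold

__all__ = [
    "HydraModel",
    "ExpressionScores",
    "fit_hydra",
    "expression_scores",
    "cv_select_k",
    "permutation_validate",
    "split_half_validate",
    "stability_ari",
]


@dataclass
class HydraModel:
    k: int
    weights: np.ndarray = field(repr=False)  # k x features
    biases: np.ndarray = field(repr=False)  # k
    case_labels: np.ndarray = field(repr=False)  # biotype index 0..k-1 per training case
    consensus_matrix: np.ndarray | None = field(default=None, repr=False)
    feature_names: list[str] | None = None
    scaler_mean: np.ndarray | None = field(default=None, repr=False)
    scaler_scale: np.ndarray | None = field(default=None, repr=False)
    regularization: float = 1.0
    seed: int = 0
    objective_trajectory: list[float] = field(default_factory=list, repr=False)
    ari_cv: float | None = None
    normalize_scores: bool = True

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "weights": self.weights.tolist(),
            "biases": self.biases.tolist(),
            "case_labels": self.case_labels.tolist(),
            "feature_names": self.feature_names,
            "scaler_mean": None if self.scaler_mean is None else self.scaler_mean.tolist(),
            "scaler_scale": None if self.scaler_scale is None else self.scaler_scale.tolist(),
            "regularization": float(self.regularization),
            "seed": int(self.seed),
            "normalize_scores": bool(self.normalize_scores),
            "ari_cv": None if self.ari_cv is None else float(self.ari_cv),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HydraModel":
        d = dict(d)
        for k in ("weights", "biases", "case_labels"):
            d[k] = np.asarray(d[k])
        for k in ("scaler_mean", "scaler_scale"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


@dataclass
class ExpressionScores:
    scores: np.ndarray = field(repr=False)  # subjects x k
    assignment: np.ndarray = field(repr=False)  # row argmax, ties -> lowest face


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def _fit_face(
    X_ctrl: np.ndarray, X_cases: np.ndarray, C: float, case_weight: float
) -> tuple[np.ndarray, float]:
    X = np.vstack([X_ctrl, X_cases])
    y = np.concatenate([-np.ones(X_ctrl.shape[0]), np.ones(X_cases.shape[0])])
    sw = np.concatenate([np.ones(X_ctrl.shape[0]), np.full(X_cases.shape[0], case_weight)])
    svm = SVC(kernel="linear", C=C)
    svm.fit(X, y, sample_weight=sw)
    return svm.coef_.ravel().copy(), float(svm.intercept_[0])


def _objective(
    W: np.ndarray,
    b: np.ndarray,
    X_ctrl: np.ndarray,
    X_case: np.ndarray,
    assign: np.ndarray,
    C: float,
    case_weight: float,
) -> float:
    """Global regularized-margin objective (non-increasing across steps)."""
    margin = 0.5 * np.sum(W**2)
    d_ctrl = X_ctrl @ W.T + b  # controls x k, should be <= -1
    hinge_ctrl = np.maximum(0.0, 1.0 + d_ctrl).sum()
    d_case = np.take_along_axis(X_case @ W.T + b, assign[:, None], axis=1).ravel()
    hinge_case = np.maximum(0.0, 1.0 - d_case).sum()
    return margin + C * (hinge_ctrl + case_weight * hinge_case)


def _alternate(
    X_ctrl: np.ndarray,
    X_case: np.ndarray,
    assign0: np.ndarray,
    k: int,
    C: float,
    case_weight: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    assign = assign0.copy()
    p = X_ctrl.shape[1]
    W = np.zeros((k, p))
    b = np.zeros(k)
    trajectory: list[float] = []
    for _ in range(max_iter):
        # repair empty faces: seed with the case deepest inside the polytope
        for j in range(k):
            if not np.any(assign == j):
                depth = np.max(X_case @ W.T + b, axis=1) if trajectory else np.zeros(len(assign))
                movable = np.array(
                    [i for i in range(len(assign)) if np.sum(assign == assign[i]) > 1]
                )
                pick = movable[np.argmin(depth[movable])]
                assign[pick] = j
        for j in range(k):
            W[j], b[j] = _fit_face(X_ctrl, X_case[assign == j], C, case_weight)
        trajectory.append(_objective(W, b, X_ctrl, X_case, assign, C, case_weight))
        new_assign = np.argmax(X_case @ W.T + b, axis=1)
        obj_after = _objective(W, b, X_ctrl, X_case, new_assign, C, case_weight)
        trajectory.append(obj_after)
        if np.array_equal(new_assign, assign):
            break
        if len(trajectory) > 2 and obj_after > trajectory[-3] * (1 + 1e-9) + 1e-9:
            break  # numerical stall; keep the better previous state
        assign = new_assign
    return W, b, assign, trajectory


def fit_hydra(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    C: float = 1.0,
    max_iter: int = 100,
    feature_names: list[str] | None = None,
    standardize: bool = True,
    normalize_scores: bool = True,
    init: str = "directions",
) -> HydraModel:
    """Fit the HYDRA polytope.

    Parameters
    ----------
    X, y
        Feature matrix (subjects x features) and case indicator
        (boolean or {0, 1}; 1 = case).
    k
        Number of faces (biotypes); ``k = 1`` reduces to a plain linear
        SVM.
    n_restarts
        Seeded random balanced initializations feeding the spectral
        consensus.
    C
        Margin-tradeoff constant shared by all faces.

    Case sample weights are fixed at ``k * n_controls / n_cases`` so the
    aggregate case weight per face roughly balances the control weight
    regardless of face occupancy (and the alternating objective stays
    monotone).
    """
    y = np.asarray(y).astype(bool)
    if not (y.any() and (~y).any()):
        raise ValueError("both classes must be present")
    n_cases = int(y.sum())
    if k > n_cases:
        raise ValueError(f"k={k} exceeds the number of cases ({n_cases})")
    X = np.asarray(X, dtype=float)
    if standardize:
        mean, scale = _standardize_fit(X)
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - mean) / scale
    X_ctrl, X_case = Xs[~y], Xs[y]
    case_weight = k * X_ctrl.shape[0] / n_cases

    rng = np.random.default_rng(seed)

    def make_init() -> np.ndarray:
        if init == "random":
            a = np.arange(n_cases) % k
            return a[rng.permutation(n_cases)]
        # direction clustering: k-means on unit displacement directions of
        # cases from the control centroid.  Alternating SVM fits from
        # purely random assignments converge to near-arbitrary fixed
        # points (each face can separate any case subset from controls),
        # whereas case *directions* carry exactly the polytope geometry.
        disp = X_case - X_ctrl.mean(axis=0)
        norms = np.linalg.norm(disp, axis=1, keepdims=True)
        d = disp / np.where(norms > 0, norms, 1.0)
        km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31 - 1)))
        return km.fit_predict(d)

    if k == 1:
        W, b, assign, traj = _alternate(
            X_ctrl, X_case, np.zeros(n_cases, dtype=int), 1, C, case_weight, 1
        )
        consensus = np.ones((n_cases, n_cases))
    else:
        runs = np.empty((n_restarts, n_cases), dtype=int)
        for r in range(n_restarts):
            *_, assign_r, _ = _alternate(
                X_ctrl, X_case, make_init(), k, C, case_weight, max_iter
            )
            runs[r] = assign_r
        consensus = np.mean(runs[:, :, None] == runs[:, None, :], axis=0)
        sc = SpectralClustering(
            n_clusters=k,
            affinity="precomputed",
            random_state=int(rng.integers(2**31 - 1)),
            assign_labels="kmeans",
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            # consensus matrices from unanimous restarts are block-diagonal;
            # the disconnected-graph warning is expected there
            _warnings.filterwarnings("ignore", message="Graph is not fully connected")
            labels0 = sc.fit_predict(consensus)
        # guarantee no empty face entering the final refit
        for j in range(k):
            if not np.any(labels0 == j):
                labels0[int(rng.integers(n_cases))] = j
        W, b, assign, traj = _alternate(X_ctrl, X_case, labels0, k, C, case_weight, max_iter)

    return HydraModel(
        k=k,
        weights=W,
        biases=b,
        case_labels=assign,
        consensus_matrix=consensus,
        feature_names=feature_names,
        scaler_mean=mean,
        scaler_scale=scale,
        regularization=C,
        seed=seed,
        objective_trajectory=traj,
        normalize_scores=normalize_scores,
    )


def expression_scores(
    model: HydraModel,
    X_new: np.ndarray,
    feature_names: list[str] | None = None,
    normalize: bool | None = None,
) -> ExpressionScores:
    """Evaluate subjects against every polytope face; argmax assigns biotype.

    Ties break toward the lowest face index (numpy argmax convention).
    Feature columns must align with the training features; pass
    ``feature_names`` to have the alignment checked.
    """
    if feature_names is not None and model.feature_names is not None:
        if list(feature_names) != list(model.feature_names):
            missing = sorted(set(model.feature_names) - set(feature_names))
            extra = sorted(set(feature_names) - set(model.feature_names))
            raise ValueError(f"feature mismatch; missing={missing[:5]}, extra={extra[:5]}")
    X = np.asarray(X_new, dtype=float)
    Xs = (X - model.scaler_mean) / model.scaler_scale
    E = Xs @ model.weights.T + model.biases
    if normalize is None:
        normalize = model.normalize_scores
    if normalize:
        norms = np.linalg.norm(model.weights, axis=1)
        E = E / np.where(norms > 0, norms, 1.0)
    return ExpressionScores(scores=E, assignment=np.argmax(E, axis=1))


def cv_select_k(
    X: np.ndarray,
    y: np.ndarray,
    k_grid: tuple[int, ...] = (2, 3, 4),
    n_folds: int = 10,
    seed: int = 0,
    n_restarts: int = 5,
    C: float = 1.0,
) -> tuple[pd.DataFrame, int]:
    """Cross-validated clustering-stability ARI per k; argmax selects k.

    For each k the full-sample consensus model provides reference labels;
    in each of ``n_folds`` folds (over cases; all controls train every
    fold) a model fitted without the held-out cases assigns them via
    expression scores, and the ARI between held-out assignments and the
    reference labels is recorded.  Returned table columns: k, ari.

    Selection uses a one-SE plateau rule toward the *largest* k: the
    chosen k is the largest whose mean ARI lies within one of its own
    fold-level standard errors of the best mean.  When the data supports a stable
    k-cluster solution, every coarser model merges the same clusters
    deterministically and is spuriously just as stable, so among
    statistically indistinguishable stabilities the finest partition is
    the informative one.
    """
    y = np.asarray(y).astype(bool)
    X = np.asarray(X, dtype=float)
    case_idx = np.where(y)[0]
    rows = []
    for ki, k in enumerate(k_grid):
        full = fit_hydra(X, y, k, n_restarts=n_restarts, seed=seed + 7919 * ki, C=C)
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed + 17 * ki)
        aris = []
        for fold, (tr, te) in enumerate(kf.split(case_idx)):
            keep = np.concatenate([np.where(~y)[0], case_idx[tr]])
            sub = fit_hydra(
                X[keep], y[keep], k, n_restarts=n_restarts, seed=seed + 101 * ki + fold, C=C
            )
            held = expression_scores(sub, X[case_idx[te]]).assignment
            aris.append(adjusted_rand_score(full.case_labels[te], held))
        rows.append(
            {
                "k": k,
                "ari": float(np.mean(aris)),
                "ari_se": float(np.std(aris, ddof=1) / np.sqrt(len(aris))),
            }
        )
    table = pd.DataFrame(rows)
    best_ari = table["ari"].max()
    plateau = table["ari"] + table["ari_se"] >= best_ari - 1e-12
    chosen = int(table.loc[plateau, "k"].max())
    return table, chosen


def stability_ari(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    n_splits: int = 5,
    seed: int = 0,
    n_restarts: int = 5,
    C: float = 1.0,
) -> float:
    """Mean split-half assignment agreement (ARI) at a given k.

    Cases are randomly halved; each half (plus all controls) trains a
    model; both models assign *all* cases via expression scores and the
    two assignments are compared.
    """
    y = np.asarray(y).astype(bool)
    X = np.asarray(X, dtype=float)
    case_idx = np.where(y)[0]
    ctrl_idx = np.where(~y)[0]
    rng = np.random.default_rng(seed)
    aris = []
    for s in range(n_splits):
        perm = rng.permutation(case_idx)
        halves = (perm[: len(perm) // 2], perm[len(perm) // 2 :])
        assigns = []
        for h, half in enumerate(halves):
            keep = np.concatenate([ctrl_idx, half])
            m = fit_hydra(X[keep], y[keep], k, n_restarts=n_restarts, seed=seed + 31 * s + h, C=C)
            assigns.append(expression_scores(m, X[case_idx]).assignment)
        aris.append(adjusted_rand_score(assigns[0], assigns[1]))
    return float(np.mean(aris))


def permutation_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    n_perm: int = 100,
    seed: int = 0,
    n_splits: int = 3,
    n_restarts: int = 3,
    C: float = 1.0,
) -> tuple[float, np.ndarray, float]:
    """Permutation p-value for the observed clustering stability.

    The null destroys nodal structure while preserving each case's value
    margins: every case row's features are independently permuted.
    Returns (observed stability ARI, null ARIs, add-one p).
    """
    y = np.asarray(y).astype(bool)
    X = np.asarray(X, dtype=float)
    observed = stability_ari(X, y, k, n_splits=n_splits, seed=seed, n_restarts=n_restarts, C=C)
    rng = np.random.default_rng(seed + 1)
    null = np.empty(n_perm)
    for b in range(n_perm):
        Xp = X.copy()
        for i in np.where(y)[0]:
            Xp[i] = Xp[i][rng.permutation(X.shape[1])]
        null[b] = stability_ari(
            Xp, y, k, n_splits=n_splits, seed=seed + 977 * (b + 1), n_restarts=n_restarts, C=C
        )
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (n_perm + 1.0)
    return observed, null, float(p)


def split_half_validate(
    X: np.ndarray,
    y: np.ndarray,
    k_grid: tuple[int, ...] = (2, 3, 4),
    n_splits: int = 5,
    seed: int = 0,
    n_restarts: int = 5,
    C: float = 1.0,
) -> pd.DataFrame:
    """Split-half agreement (ARI) for each candidate k."""
    rows = [
        {
            "k": k,
            "ari": stability_ari(
                X, y, k, n_splits=n_splits, seed=seed + 13 * i, n_restarts=n_restarts, C=C
            ),
        }
        for i, k in enumerate(k_grid)
    ]
    return pd.DataFrame(rows)
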