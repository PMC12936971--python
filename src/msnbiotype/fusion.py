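"""Multimodal fusion of metric-wise deviation matrices (mCCA + jICA).

Multiset canonical correlation analysis links the K modalities (here the
three topology metrics' subjects x nodes deviation matrices) by finding,
per modality, orthonormal subject-space profiles D_k whose variates
maximize the sum of squared pairwise correlations (SSQCOR criterion,
solved deflationarily).  Associated maps C_k are the least-squares
back-projections of each modality onto its profiles.  Joint ICA then
unmixes the node-wise concatenation [C_1 .. C_K] into maximally
independent spatial sources S_k with unmixing matrix W, and subject-wise
mixing coefficients follow as A_k = D_k @ pinv(W).

A "joint group-differentiating component" is a component whose mixing
coefficients differ between groups (two-sample t, p < alpha) in *every*
modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA

__all__ = [
    "FusionResult",
    "mcca",
    "jica",
    "mcca_jica",
    "component_group_test",
    "select_component_count",
]

# E[log cosh nu] for standard normal nu (Gauss-Hermite, frozen)
_LOGCOSH_GAUSS = 0.3745672962676661


@dataclass
class FusionResult:
    modality_names: list[str]
    D: list[np.ndarray] = field(repr=False)  # per modality, subjects x c
    C: list[np.ndarray] = field(repr=False)  # per modality, c x nodes
    S: list[np.ndarray] = field(repr=False)  # per modality, c x nodes (sources)
    W: np.ndarray = field(default=None, repr=False)  # ICA unmixing, c x c
    A: list[np.ndarray] = field(default=None, repr=False)  # subjects x c per modality
    explained_variance: np.ndarray = None  # per modality, at full component count
    canonical_ssq: np.ndarray = None  # per component, sum of squared pairwise corrs
    negentropy: np.ndarray = None  # per source
    low_nongaussianity: bool = False


def _center(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=0, keepdims=True)


def _whiten_basis(X: np.ndarray, rank: int) -> np.ndarray:
    """Orthonormal subject-space basis of the column space (left SVs)."""
    U, s, _ = np.linalg.svd(_center(X), full_matrices=False)
    keep = s > s[0] * 1e-10 if s.size else np.zeros(0, bool)
    r = min(rank, int(keep.sum()))
    return U[:, :r]


def mcca(
    X_list: list[np.ndarray],
    n_components: int,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Deflationary SSQCOR multiset CCA.

    Returns (D_list, C_list, ssqcor_per_component) where D_k is the
    subjects x n_components orthonormal profile matrix of modality k and
    C_k = D_k' X_k its associated maps.
    """
    if len({X.shape[0] for X in X_list}) != 1:
        raise ValueError("all modalities must share the same subject set")
    n = X_list[0].shape[0]
    max_rank = min(n - 1, *[X.shape[1] for X in X_list])
    K = len(X_list)
    Y = [_whiten_basis(X, max_rank) for X in X_list]
    numerical_rank = min(Yk.shape[1] for Yk in Y)
    if n_components > numerical_rank:
        warnings.warn(
            f"rank-deficient input: reducing components {n_components} -> {numerical_rank}",
            stacklevel=2,
        )
        n_components = numerical_rank
    D = [np.zeros((n, n_components)) for _ in range(K)]
    ssq = np.zeros(n_components)

    for c in range(n_components):
        if any(Yk.shape[1] == 0 for Yk in Y):  # deflation exhausted a modality
            D = [Dk[:, :c] for Dk in D]
            ssq = ssq[:c]
            n_components = c
            break
        # init from the dominant shared direction of the concatenated bases
        concat = np.hstack(Y)
        u = np.linalg.svd(concat, full_matrices=False)[0][:, 0]
        a = [Yk.T @ u for Yk in Y]
        a = [ak / max(np.linalg.norm(ak), 1e-300) for ak in a]
        obj_prev = -np.inf
        for _ in range(max_iter):
            d = [Y[k] @ a[k] for k in range(K)]
            obj = sum(
                (d[k] @ d[l]) ** 2 for k in range(K) for l in range(K) if k != l
            )
            if obj - obj_prev < tol * max(abs(obj), 1.0):
                break
            obj_prev = obj
            for k in range(K):
                M = np.zeros((Y[k].shape[1], Y[k].shape[1]))
                for l in range(K):
                    if l == k:
                        continue
                    v = Y[k].T @ d[l]
                    M += np.outer(v, v)
                evals, evecs = np.linalg.eigh(M)
                a[k] = evecs[:, -1]
                d[k] = Y[k] @ a[k]
        for k in range(K):
            dk = Y[k] @ a[k]
            D[k][:, c] = dk / max(np.linalg.norm(dk), 1e-300)
        ssq[c] = sum(
            (D[k][:, c] @ D[l][:, c]) ** 2 for k in range(K) for l in range(K) if k < l
        )
        # deflate: remove each found variate from its modality's basis
        newY = []
        for k in range(K):
            dk = D[k][:, c : c + 1]
            Z = Y[k] - dk @ (dk.T @ Y[k])
            Q, Rq = np.linalg.qr(Z)
            keep = np.abs(np.diag(Rq)) > 1e-10
            newY.append(Q[:, keep])
        Y = newY

    C = [D[k].T @ _center(X_list[k]) for k in range(K)]
    # sign convention: largest-|element| of each concatenated map row positive
    for c in range(n_components):
        row = np.concatenate([Ck[c] for Ck in C])
        if row[np.argmax(np.abs(row))] < 0:
            for k in range(K):
                C[k][c] *= -1
                D[k][:, c] *= -1
    return D, C, ssq


def _negentropy(S: np.ndarray) -> np.ndarray:
    """Logcosh negentropy approximation per source row (unit-variance rows)."""
    Sn = S / S.std(axis=1, keepdims=True)
    return (np.mean(np.log(np.cosh(Sn)), axis=1) - _LOGCOSH_GAUSS) ** 2


def jica(
    C_list: list[np.ndarray],
    seed: int = 0,
    n_restarts: int = 20,
    low_ng_threshold: float = 1e-4,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, bool]:
    """Joint ICA on node-concatenated associated maps.

    Runs FastICA (logcosh contrast, symmetric decorrelation) from
    ``n_restarts`` derived seeds and keeps the run with the best total
    negentropy.  Sources are scaled/flipped so each row's
    largest-magnitude element is positive.

    Returns (S_list split back per modality, W unmixing, negentropy per
    source, low_nongaussianity flag).
    """
    blocks = np.cumsum([C.shape[1] for C in C_list])[:-1]
    X = np.hstack(C_list)  # components x total nodes
    c = X.shape[0]
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        sub = int(rng.integers(2**31 - 1))
        ica = FastICA(
            n_components=c,
            algorithm="parallel",
            fun="logcosh",
            whiten="unit-variance",
            random_state=sub,
            max_iter=1000,
            tol=1e-7,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S_nodes = ica.fit_transform(X.T)  # total_nodes x c
        ng = _negentropy(S_nodes.T)
        if best is None or ng.sum() > best[0]:
            best = (ng.sum(), S_nodes, ica, ng)
    _, S_nodes, ica, ng = best
    S = S_nodes.T  # c x total_nodes
    W = ica.components_  # unmixing: S' = (X' - mean) W'
    for i in range(c):
        j = np.argmax(np.abs(S[i]))
        if S[i, j] < 0:
            S[i] *= -1
            W[i] *= -1
    low = bool(np.all(ng < low_ng_threshold))
    S_split = np.split(S, blocks, axis=1)
    return S_split, W, ng, low


def mcca_jica(
    X_list: list[np.ndarray],
    n_components: int,
    modality_names: list[str] | None = None,
    seed: int = 0,
    n_restarts: int = 20,
) -> FusionResult:
    """Full fusion: mCCA profiles + jICA sources + mixing coefficients A_k."""
    names = modality_names or [f"modality-{k}" for k in range(len(X_list))]
    D, C, ssq = mcca(X_list, n_components)
    S, W, ng, low = jica(C, seed=seed, n_restarts=n_restarts)
    A_ica = np.linalg.pinv(W)
    A = [Dk @ A_ica for Dk in D]
    ev = np.array(
        [
            1.0
            - np.linalg.norm(_center(X) - Dk @ Ck) ** 2 / np.linalg.norm(_center(X)) ** 2
            for X, Dk, Ck in zip(X_list, D, C)
        ]
    )
    return FusionResult(
        modality_names=names,
        D=D,
        C=C,
        S=S,
        W=W,
        A=A,
        explained_variance=ev,
        canonical_ssq=ssq,
        negentropy=ng,
        low_nongaussianity=low,
    )


def component_group_test(
    A_list: list[np.ndarray],
    labels: np.ndarray,
    modality_names: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample t on mixing coefficients, per component and modality.

    The returned frame carries a ``joint_significant`` column marking
    components with p < alpha in every modality.
    """
    labels = np.asarray(labels, dtype=bool)
    names = modality_names or [f"modality-{k}" for k in range(len(A_list))]
    rows = []
    for k, Ak in enumerate(A_list):
        for c in range(Ak.shape[1]):
            a, b = Ak[labels, c], Ak[~labels, c]
            t, p = stats.ttest_ind(a, b)
            sp = np.sqrt(
                ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                / (a.size + b.size - 2)
            )
            d = (a.mean() - b.mean()) / sp if sp > 0 else 0.0
            rows.append(
                {"component": c, "modality": names[k], "t": float(t), "cohen_d": float(d), "p": float(p)}
            )
    df = pd.DataFrame(rows)
    joint = df.groupby("component")["p"].apply(lambda s: bool((s < alpha).all()))
    df["joint_significant"] = df["component"].map(joint)
    return df


def select_component_count(
    X_list: list[np.ndarray], variance_floor: float = 0.8, max_components: int | None = None
) -> int:
    """Smallest count whose reconstruction EV exceeds the floor in all modalities."""
    n = X_list[0].shape[0]
    cap = min(n - 1, *[X.shape[1] for X in X_list])
    if max_components is not None:
        cap = min(cap, max_components)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank reduction handled below
        D, C, _ = mcca(X_list, cap)
    cap = D[0].shape[1]
    denom = [np.linalg.norm(_center(X)) ** 2 for X in X_list]
    for m in range(1, cap + 1):
        ev = [
            1.0 - np.linalg.norm(_center(X) - Dk[:, :m] @ Ck[:m]) ** 2 / dn
            for X, Dk, Ck, dn in zip(X_list, D, C, denom)
        ]
        if all(e >= variance_floor for e in ev):
            return m
    return cap
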