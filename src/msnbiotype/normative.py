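"""Normative modeling of nodal topology with warped Bayesian linear regression.

Each node x metric phenotype is modeled in a reference (control) sample as

    t = sinh(delta * asinh(y_std) - epsilon)   (sinh-arcsinh likelihood warp)
    t | x ~ N(w' phi(x), 1/beta),   w ~ N(0, alpha^{-1} I)

where ``phi(x)`` stacks an intercept, a cubic B-spline basis over age
(interior knots at training-age quantiles) and a sex indicator.  The warp
parameters (epsilon: skew, delta > 0: tail weight) are fitted by outer
numerical optimization of the type-II marginal likelihood including the
warp Jacobian; (alpha, beta) are fitted by closed-form evidence iteration.
A subject's deviation is the z-score of their warped observation under the
posterior predictive distribution.

Site transfer: a pretrained model is recalibrated to a new site from
adaptation controls by re-estimating an offset and scale of the
standardized predictive residuals in warped space; the regression
coefficients are untouched, and recalibration is idempotent (it always
restarts from the uncalibrated model).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import balanced_accuracy_score
from sklearn.svm import LinearSVC

__all__ = [
    "NormativeConfig",
    "NormativeModel",
    "DeviationTensor",
    "fit_normative",
    "deviation_z",
    "transfer_recalibrate",
    "check_site_effects",
    "fit_normative_battery",
    "compute_deviation_tensor",
]

EXTREME_Z = 2.0


@dataclass
class NormativeConfig:
    n_knots: int = 5  # interior knots, at training-age quantiles
    degree: int = 3  # cubic
    warp: str = "sinh-arcsinh"  # or "identity"
    min_train: int = 50
    age_tolerance: float = 0.5  # years beyond the training range still scored
    epsilon_bounds: tuple[float, float] = (-2.0, 2.0)
    log_delta_bounds: tuple[float, float] = (np.log(0.25), np.log(4.0))


@dataclass
class NormativeModel:
    """Fitted per-phenotype normative model (see module docstring)."""

    node: int
    metric: str
    knots: np.ndarray = field(repr=False)  # full (augmented) knot vector
    degree: int = 3
    coef: np.ndarray = field(default=None, repr=False)  # posterior mean
    coef_cov: np.ndarray = field(default=None, repr=False)
    noise_precision: float = 1.0
    epsilon: float = 0.0
    delta: float = 1.0
    warp_converged: bool = True
    y_loc: float = 0.0
    y_scale: float = 1.0
    age_min: float = 6.0
    age_max: float = 18.0
    age_tolerance: float = 0.5
    n_train: int = 0
    # site recalibration (absolute, re-derived from scratch on each transfer)
    cal_offset: float = 0.0
    cal_scale: float = 1.0

    # -- warp -----------------------------------------------------------
    def warp_y(self, y: np.ndarray) -> np.ndarray:
        ys = (np.asarray(y, dtype=float) - self.y_loc) / self.y_scale
        return np.sinh(self.delta * np.arcsinh(ys) - self.epsilon)

    def unwarp_t(self, t: np.ndarray) -> np.ndarray:
        ys = np.sinh((np.arcsinh(np.asarray(t, dtype=float)) + self.epsilon) / self.delta)
        return ys * self.y_scale + self.y_loc

    # -- design ---------------------------------------------------------
    def design(self, age: np.ndarray, sex: np.ndarray, check_support: bool = True) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        lo = self.age_min - self.age_tolerance
        hi = self.age_max + self.age_tolerance
        if check_support and (np.any(age < lo) or np.any(age > hi)):
            raise ValueError(
                f"age outside training support [{self.age_min}, {self.age_max}] "
                f"(tolerance {self.age_tolerance})"
            )
        a = np.clip(age, self.knots[0], self.knots[-1] - 1e-9)
        B = BSpline.design_matrix(a, self.knots, self.degree).toarray()
        return np.column_stack([np.ones_like(a), B, np.asarray(sex, dtype=float)])

    def predictive(self, age: np.ndarray, sex: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior predictive mean and variance in warped space."""
        Phi = self.design(age, sex)
        mu = Phi @ self.coef
        var = np.einsum("ij,jk,ik->i", Phi, self.coef_cov, Phi) + 1.0 / self.noise_precision
        return mu, var

    def to_dict(self) -> dict:
        return {
            "node": int(self.node),
            "metric": self.metric,
            "knots": self.knots.tolist(),
            "degree": int(self.degree),
            "coef": self.coef.tolist(),
            "coef_cov": self.coef_cov.tolist(),
            "noise_precision": float(self.noise_precision),
            "epsilon": float(self.epsilon),
            "delta": float(self.delta),
            "warp_converged": bool(self.warp_converged),
            "y_loc": float(self.y_loc),
            "y_scale": float(self.y_scale),
            "age_min": float(self.age_min),
            "age_max": float(self.age_max),
            "age_tolerance": float(self.age_tolerance),
            "n_train": int(self.n_train),
            "cal_offset": float(self.cal_offset),
            "cal_scale": float(self.cal_scale),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModel":
        d = dict(d)
        for k in ("knots", "coef", "coef_cov"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


@dataclass
class DeviationTensor:
    """subjects x nodes x metrics normative z-scores with extreme masks."""

    z: np.ndarray = field(repr=False)
    metric_names: tuple[str, ...] = ()
    subject_ids: list[str] = field(default_factory=list)

    @property
    def extreme_mask_pos(self) -> np.ndarray:
        return self.z >= EXTREME_Z

    @property
    def extreme_mask_neg(self) -> np.ndarray:
        return self.z <= -EXTREME_Z

    def flatten_features(self) -> tuple[np.ndarray, list[str]]:
        """subjects x (nodes * metrics) matrix plus feature names."""
        n, R, M = self.z.shape
        names = [
            f"node{r:03d}:{self.metric_names[m] if self.metric_names else m}"
            for m in range(M)
            for r in range(R)
        ]
        return self.z.transpose(0, 2, 1).reshape(n, R * M), names


# ---------------------------------------------------------------------------
# evidence-optimized Bayesian linear regression


def _evidence_blr(Phi: np.ndarray, t: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """Type-II ML Gaussian linear model; returns (mu, Sigma, alpha, beta, logml)."""
    n, p = Phi.shape
    G = Phi.T @ Phi
    evals, evecs = np.linalg.eigh(G)
    evals = np.maximum(evals, 0.0)
    Pt = Phi.T @ t
    alpha, beta = 1e-3, 1.0 / max(np.var(t), 1e-12)
    for _ in range(max_iter):
        lam = beta * evals
        Sigma_diag = 1.0 / (alpha + lam)
        mu = evecs @ (Sigma_diag * (beta * (evecs.T @ Pt)))
        gamma = np.sum(lam / (alpha + lam))
        alpha_new = gamma / max(mu @ mu, 1e-300)
        resid = t - Phi @ mu
        beta_new = max(n - gamma, 1e-12) / max(resid @ resid, 1e-300)
        if abs(alpha_new - alpha) < tol * alpha and abs(beta_new - beta) < tol * beta:
            alpha, beta = alpha_new, beta_new
            break
        alpha, beta = alpha_new, beta_new
    lam = beta * evals
    Sigma = (evecs * (1.0 / (alpha + lam))) @ evecs.T
    mu = beta * (Sigma @ Pt)
    resid = t - Phi @ mu
    logml = 0.5 * (
        p * np.log(alpha)
        + n * np.log(beta)
        - beta * (resid @ resid)
        - alpha * (mu @ mu)
        - np.sum(np.log(alpha + lam))
        - n * np.log(2 * np.pi)
    )
    return mu, Sigma, alpha, beta, float(logml)


def _knot_vector(age: np.ndarray, n_knots: int, degree: int, tolerance: float) -> np.ndarray:
    lo, hi = float(age.min()) - tolerance, float(age.max()) + tolerance
    interior = np.quantile(age, np.linspace(0, 1, n_knots + 2)[1:-1])
    interior = np.clip(interior, lo + 1e-6, hi - 1e-6)
    return np.concatenate([[lo] * (degree + 1), np.sort(interior), [hi] * (degree + 1)])


def fit_normative(
    y: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    config: NormativeConfig | None = None,
    node: int = 0,
    metric: str = "phenotype",
) -> NormativeModel:
    """Fit one warped-BLR normative model on training controls."""
    config = config or NormativeConfig()
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if y.size < config.min_train:
        raise ValueError(f"need >= {config.min_train} training controls, got {y.size}")
    y_loc, y_scale = float(np.mean(y)), float(np.std(y))
    if y_scale == 0:
        raise ValueError("response has zero variance")

    knots = _knot_vector(age, config.n_knots, config.degree, config.age_tolerance)
    model = NormativeModel(
        node=node,
        metric=metric,
        knots=knots,
        degree=config.degree,
        y_loc=y_loc,
        y_scale=y_scale,
        age_min=float(age.min()),
        age_max=float(age.max()),
        age_tolerance=config.age_tolerance,
        n_train=int(y.size),
    )
    Phi = model.design(age, sex)
    ys = (y - y_loc) / y_scale

    def neg_profile_ll(params) -> float:
        eps, logd = params
        delta = np.exp(logd)
        u = delta * np.arcsinh(ys) - eps
        t = np.sinh(u)
        # d t / d y_std = delta * cosh(u) / sqrt(1 + y_std^2)
        log_jac = np.log(delta) + np.log(np.cosh(u)) - 0.5 * np.log1p(ys**2)
        try:
            *_, logml = _evidence_blr(Phi, t)
        except np.linalg.LinAlgError:
            return 1e12
        val = -(logml + log_jac.sum())
        return val if np.isfinite(val) else 1e12

    epsilon, delta, converged = 0.0, 1.0, True
    if config.warp == "sinh-arcsinh":
        res = minimize(
            neg_profile_ll,
            x0=np.array([0.0, 0.0]),
            method="L-BFGS-B",
            bounds=[config.epsilon_bounds, config.log_delta_bounds],
            options={"ftol": 1e-6, "gtol": 1e-6},
        )
        if res.success and np.isfinite(res.fun):
            epsilon, delta = float(res.x[0]), float(np.exp(res.x[1]))
        else:
            converged = False  # identity-warp fallback
    elif config.warp != "identity":
        raise ValueError(f"unknown warp {config.warp!r}")

    model.epsilon, model.delta, model.warp_converged = epsilon, delta, converged
    t = model.warp_y(y)
    mu, Sigma, _, beta, _ = _evidence_blr(Phi, t)
    model.coef, model.coef_cov, model.noise_precision = mu, Sigma, float(beta)
    return model


def deviation_z(
    model: NormativeModel, y: np.ndarray, age: np.ndarray, sex: np.ndarray
) -> np.ndarray:
    """Deviation z-score under the posterior predictive, site-calibrated.

    ``z = [(t(y) - mu_pred) / sqrt(var_pred) - cal_offset] / cal_scale``;
    strictly increasing in y for fixed covariates.
    """
    t = model.warp_y(y)
    mu, var = model.predictive(age, sex)
    z = (t - mu) / np.sqrt(var)
    return (z - model.cal_offset) / model.cal_scale


def transfer_recalibrate(
    model: NormativeModel,
    y: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    min_adaptation: int = 20,
    site: str = "adaptation-site",
) -> NormativeModel:
    """Recalibrate a pretrained model to a new site from adaptation controls.

    The offset and scale are the mean and SD of the *uncalibrated*
    standardized residuals on the adaptation sample, so applying the
    function twice with the same data yields the same model.
    """
    y = np.asarray(y, dtype=float)
    if y.size < min_adaptation:
        raise ValueError(
            f"site {site!r}: need >= {min_adaptation} adaptation controls, got {y.size}"
        )
    base = replace(model, cal_offset=0.0, cal_scale=1.0)
    r = deviation_z(base, y, age, sex)
    return replace(model, cal_offset=float(np.mean(r)), cal_scale=float(np.std(r, ddof=1)))


def check_site_effects(z_features: np.ndarray, sites: np.ndarray, seed: int = 0) -> float:
    """2-fold linear-SVM balanced accuracy predicting site from deviations.

    Values near chance (1 / n_sites) indicate residual site information
    was removed by the normative model; clearly above-chance accuracy
    flags un-modeled site effects.
    """
    sites = np.asarray(sites)
    if np.unique(sites).size < 2:
        raise ValueError("need >= 2 sites")
    skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(z_features, sites):
        clf = LinearSVC(C=1.0, dual="auto", max_iter=5000)
        clf.fit(z_features[train], sites[train])
        accs.append(balanced_accuracy_score(sites[test], clf.predict(z_features[test])))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# battery helpers (one model per node x metric)


def fit_normative_battery(
    Y: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    metric_names: tuple[str, ...],
    config: NormativeConfig | None = None,
) -> list[list[NormativeModel]]:
    """Fit a model per node x metric from a subjects x nodes x metrics array."""
    n, R, M = Y.shape
    config = config or NormativeConfig()
    out: list[list[NormativeModel]] = []
    for r in range(R):
        row = []
        for m in range(M):
            y = Y[:, r, m]
            if np.std(y) == 0:
                # degenerate phenotype (e.g. participation coefficient
                # identically 0 at a node): deviations become raw offsets
                # from the constant, in original units
                knots = _knot_vector(np.asarray(age, dtype=float), config.n_knots, config.degree, config.age_tolerance)
                p = 2 + knots.size - config.degree - 1
                row.append(
                    NormativeModel(
                        node=r,
                        metric=metric_names[m],
                        knots=knots,
                        degree=config.degree,
                        coef=np.zeros(p),
                        coef_cov=np.eye(p) * 1e-12,
                        noise_precision=1.0,
                        y_loc=float(y[0]),
                        y_scale=1.0,
                        age_min=float(np.min(age)),
                        age_max=float(np.max(age)),
                        age_tolerance=config.age_tolerance,
                        n_train=int(n),
                    )
                )
            else:
                row.append(fit_normative(y, age, sex, config, node=r, metric=metric_names[m]))
        out.append(row)
    return out


def compute_deviation_tensor(
    models: list[list[NormativeModel]],
    Y: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    metric_names: tuple[str, ...] = (),
    subject_ids: list[str] | None = None,
) -> DeviationTensor:
    n, R, M = Y.shape
    z = np.empty_like(Y, dtype=float)
    for r in range(R):
        for m in range(M):
            z[:, r, m] = deviation_z(models[r][m], Y[:, r, m], age, sex)
    return DeviationTensor(z=z, metric_names=tuple(metric_names), subject_ids=subject_ids or [])
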