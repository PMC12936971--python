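"""Seeded synthetic multisite cohorts with planted network biotypes.

The generator emulates the statistical structure of a multisite pediatric
case-control morphometry study:

* typically developing controls (TDC) and cases aged 6-18 with sex
  imbalance, spread over several acquisition sites with additive site
  offsets and per-site noise-scale multipliers;
* per-region gray-matter value distributions whose subject-level means
  follow ``b0_r + f_r(age) + c_r * sex + s_site`` with a smooth nonlinear
  age curve ``f_r``, and which share module-level latent factors so that
  MSN edges carry community structure;
* ``k_true`` latent case biotypes, each *decoupling* a disjoint set of
  designated hub nodes: independent noise scaled by ``effect_size`` is
  injected on top of the shared-factor signal, so the planted effect
  lives in network topology (distributional concordance), not in a mean
  shift — the space the MSN measures;
* symptom scores in [0, 1] with biotype-graded severity (biotype 1
  highest on both scales);
* quasi-uniform node coordinates on the unit sphere (Fibonacci lattice)
  with spatially contiguous module labels, so spin-permutation nulls are
  well behaved;
* spatially smooth annotation maps (Gaussian fields on the sphere) that
  stand in for receptor-density and meta-analytic task maps, optionally
  linked to a target map at a prescribed expected correlation.

Everything is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "CohortSpec",
    "NodeGeometry",
    "GroundTruth",
    "AnnotationMap",
    "generate_cohort",
    "generate_annotation_maps",
    "fibonacci_sphere",
]


@dataclass
class CohortSpec:
    """Study-condition parameters for one synthetic cohort."""

    n_controls: int = 300
    n_cases: int = 200
    n_sites: int = 4
    n_regions: int = 100
    n_samples_per_region: int = 200
    age_range: tuple[float, float] = (6.0, 18.0)
    male_fraction: float = 0.7
    k_true: int = 3
    effect_size: float = 3.0
    seed: int = 0
    # Seed for the population-level "biology" (geometry, regional
    # parameters, planted node sets).  Defaults to ``seed``.  An
    # independent validation cohort drawn from the same population uses
    # the same biology_seed with a different sampling seed: new subjects
    # and new sites, same underlying generative structure.
    biology_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_regions < 8:
            raise ValueError("n_regions must be >= 8")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        lo, hi = self.age_range
        if not (6.0 <= lo < hi <= 18.0):
            raise ValueError("age_range must lie within [6, 18]")
        if self.k_true > self.n_cases:
            raise ValueError("k_true cannot exceed n_cases")
        if self.n_regions < 2 * self.k_true:
            raise ValueError("n_regions must be >= 2 * k_true (disjoint node sets)")


@dataclass
class NodeGeometry:
    """Unit-sphere node coordinates and true community labels."""

    coords: np.ndarray = field(repr=False)  # n_regions x 3, unit norm rows
    true_module: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("coordinates must have unit norm to 1e-9")
        if self.true_module.shape[0] != self.coords.shape[0]:
            raise ValueError("module labels must cover all regions")

    @property
    def n_regions(self) -> int:
        return self.coords.shape[0]


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort (for evaluation only)."""

    biotype_nodes: dict[int, np.ndarray]  # 1-based biotype -> perturbed node indices
    case_biotypes: np.ndarray  # per case, 1-based
    module_of_region: np.ndarray
    site_offsets: np.ndarray
    site_noise_scale: np.ndarray
    symptom_means: dict[str, np.ndarray]  # per-biotype means, index 0 = biotype 1


@dataclass
class AnnotationMap:
    """Node-wise spatial map (receptor-density / cognitive-term stand-in)."""

    name: str
    values: np.ndarray = field(repr=False)
    smoothness: float = 0.5

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("annotation values must be finite")


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _spatial_modules(coords: np.ndarray, n_modules: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=n_modules, n_init=4, random_state=seed)
    return km.fit_predict(coords)


# Fixed generator scales (volume-like arbitrary units).  Chosen once to give
# clearly modular MSNs with realistic overlap between modules; see the
# methods note for the rationale.
_MODULE_BASE_LO, _MODULE_BASE_HI = 4.0, 6.0
_REGION_OFFSET_SD = 0.08
_AGE_AMPLITUDE = 0.15
_SEX_EFFECT_SD = 0.05
_SITE_OFFSET_SD = 0.10
_FACTOR_LOADING = 0.25
_IDIO_SD = 0.05
_SAMPLE_SD = 0.30
_SET_FRAC = 0.1

# Symptom-score study conditions: per-biotype means for k_true = 3
# (biotype 1 most severe on both scales), SDs matched to typical rescaled
# rating-scale spread; controls sit well below the clinical range.
_SYMPTOM_MEANS_K3 = {
    "inattention": np.array([0.77, 0.71, 0.75]),
    "hyperactivity": np.array([0.68, 0.65, 0.60]),
}
_SYMPTOM_SDS = {"inattention": 0.16, "hyperactivity": 0.23}
_CONTROL_SYMPTOM_MEANS = {"inattention": 0.25, "hyperactivity": 0.20}
_CONTROL_SYMPTOM_SD = 0.15


def _symptom_means(k: int) -> dict[str, np.ndarray]:
    if k == 3:
        return {m: v.copy() for m, v in _SYMPTOM_MEANS_K3.items()}
    out = {}
    for m, v in _SYMPTOM_MEANS_K3.items():
        top = v[0]
        out[m] = np.linspace(top, max(top - 0.05 * max(k - 1, 1), 0.4), k)
    return out


def _truncated_scores(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    """Draw Normal(mean, sd) resampling out-of-[0,1] values (truncation)."""
    x = rng.normal(mean, sd)
    bad = (x < 0) | (x > 1)
    for _ in range(100):
        if not np.any(bad):
            break
        x[bad] = rng.normal(np.asarray(mean, dtype=float)[bad] if np.ndim(mean) else mean, sd, size=bad.sum())
        bad = (x < 0) | (x > 1)
    return np.clip(x, 0.0, 1.0)


def _age_curves(rng: np.random.Generator, n_regions: int):
    """Smooth nonlinear age effect per region: linear trend + Gaussian bump."""
    lin = rng.normal(0.0, _AGE_AMPLITUDE / 2, n_regions)
    amp = rng.normal(0.0, _AGE_AMPLITUDE, n_regions)
    peak = rng.uniform(8.0, 16.0, n_regions)
    width = rng.uniform(2.0, 5.0, n_regions)

    def f(age: np.ndarray) -> np.ndarray:
        # subjects x regions
        a = np.asarray(age, dtype=float)[:, None]
        return lin[None, :] * (a - 12.0) / 6.0 + amp[None, :] * np.exp(
            -(((a - peak[None, :]) / width[None, :]) ** 2)
        )

    return f


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], NodeGeometry, GroundTruth]:
    """Generate one synthetic multisite cohort.

    Returns
    -------
    cohort : DataFrame
        Columns ``subject_id, age, sex, site, group, true_biotype,
        inattention, hyperactivity``; ``true_biotype`` is a nullable
        integer present only for cases.
    samples : dict
        ``subject_id -> (n_regions x n_samples_per_region)`` array of
        positive morphometry values.
    geometry : NodeGeometry
    truth : GroundTruth
    """
    bio_rng = np.random.default_rng(
        spec.seed if spec.biology_seed is None else spec.biology_seed
    )
    rng = np.random.default_rng(spec.seed + 1_000_003)
    R = spec.n_regions
    n = spec.n_controls + spec.n_cases

    # --- geometry and modules (population-level, from bio_rng) -----------
    coords = fibonacci_sphere(R)
    n_modules = int(np.clip(R // 12, 3, 8))
    modules = _spatial_modules(coords, n_modules, seed=int(bio_rng.integers(2**31 - 1)))
    geometry = NodeGeometry(coords=coords, true_module=modules)

    # --- fixed regional parameters --------------------------------------
    module_base = np.linspace(_MODULE_BASE_LO, _MODULE_BASE_HI, n_modules)
    b0 = module_base[modules] + bio_rng.normal(0.0, _REGION_OFFSET_SD, R)
    age_f = _age_curves(bio_rng, R)
    sex_eff = bio_rng.normal(0.0, _SEX_EFFECT_SD, R)

    # --- sites and demographics -----------------------------------------
    site_offsets = rng.normal(0.0, _SITE_OFFSET_SD, spec.n_sites)
    site_noise_scale = rng.uniform(0.8, 1.25, spec.n_sites)
    site = rng.integers(0, spec.n_sites, n)
    age = rng.uniform(spec.age_range[0], spec.age_range[1], n)
    sex = (rng.random(n) < spec.male_fraction).astype(int)  # 1 = male
    group = np.array(["control"] * spec.n_controls + ["case"] * spec.n_cases)

    # --- planted biotypes ------------------------------------------------
    set_size = max(2, int(round(_SET_FRAC * R)))
    set_size = min(set_size, R // spec.k_true)
    # designate hub node sets inside distinct modules where possible
    order = np.argsort(modules, kind="stable")
    biotype_nodes = {
        k + 1: np.sort(order[k * set_size : (k + 1) * set_size]) for k in range(spec.k_true)
    }
    case_biotypes = rng.integers(1, spec.k_true + 1, spec.n_cases)

    # --- latent factors and regional means ------------------------------
    factors = rng.normal(0.0, 1.0, (n, n_modules))
    idio = rng.normal(0.0, _IDIO_SD, (n, R))
    mean = (
        b0[None, :]
        + age_f(age)
        + sex_eff[None, :] * sex[:, None]
        + site_offsets[site][:, None]
        + _FACTOR_LOADING * factors[:, modules]
        + idio * site_noise_scale[site][:, None]
    )

    # decoupling perturbation: independent zero-mean noise added to every
    # *sample* of a designated node, with SD effect_size * loading.  This
    # widens the node's value distribution so it decouples from all
    # regions at once (its KLS edges collapse), rather than shifting it
    # toward some other module's operating range; exactly zero for
    # controls and at effect 0.
    decouple_sd = np.zeros((n, R))
    for k, nodes in biotype_nodes.items():
        rows = np.where(group == "case")[0][case_biotypes == k]
        decouple_sd[np.ix_(rows, nodes)] = spec.effect_size * _FACTOR_LOADING

    # --- per-region samples ----------------------------------------------
    samples: dict[str, np.ndarray] = {}
    subject_ids = [f"sub-{i:04d}" for i in range(n)]
    for i, sid in enumerate(subject_ids):
        sd = np.sqrt(
            (_SAMPLE_SD * site_noise_scale[site[i]]) ** 2 + decouple_sd[i] ** 2
        )
        vals = rng.normal(mean[i][:, None], sd[:, None], (R, spec.n_samples_per_region))
        samples[sid] = np.maximum(vals, 1e-6)  # morphometry values are positive

    # --- symptoms ---------------------------------------------------------
    sym_means = _symptom_means(spec.k_true)
    inatt = np.empty(n)
    hyper = np.empty(n)
    ctrl = group == "control"
    inatt[ctrl] = _truncated_scores(
        rng, np.full(ctrl.sum(), _CONTROL_SYMPTOM_MEANS["inattention"]), _CONTROL_SYMPTOM_SD
    )
    hyper[ctrl] = _truncated_scores(
        rng, np.full(ctrl.sum(), _CONTROL_SYMPTOM_MEANS["hyperactivity"]), _CONTROL_SYMPTOM_SD
    )
    case_rows = np.where(~ctrl)[0]
    inatt[case_rows] = _truncated_scores(
        rng, sym_means["inattention"][case_biotypes - 1], _SYMPTOM_SDS["inattention"]
    )
    hyper[case_rows] = _truncated_scores(
        rng, sym_means["hyperactivity"][case_biotypes - 1], _SYMPTOM_SDS["hyperactivity"]
    )

    true_bio = np.full(n, pd.NA, dtype=object)
    true_bio[case_rows] = case_biotypes
    cohort = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": age,
            "sex": sex,
            "site": pd.Categorical([f"site-{s}" for s in site]),
            "group": pd.Categorical(group, categories=["control", "case"]),
            "true_biotype": pd.array(true_bio, dtype="Int64"),
            "inattention": inatt,
            "hyperactivity": hyper,
        }
    )
    truth = GroundTruth(
        biotype_nodes=biotype_nodes,
        case_biotypes=case_biotypes,
        module_of_region=modules,
        site_offsets=site_offsets,
        site_noise_scale=site_noise_scale,
        symptom_means=sym_means,
    )
    return cohort, samples, geometry, truth


# ---------------------------------------------------------------------------
# annotation maps


def _sphere_covariance(coords: np.ndarray, smoothness: float) -> np.ndarray:
    """exp(-d/lambda) with d the great-circle distance (radians)."""
    g = np.clip(coords @ coords.T, -1.0, 1.0)
    d = np.arccos(g)
    return np.exp(-d / smoothness)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate_annotation_maps(
    geometry: NodeGeometry,
    n_maps: int,
    smoothness: float = 0.5,
    link: tuple[np.ndarray, float] | None = None,
    seed: int = 0,
    names: list[str] | None = None,
) -> list[AnnotationMap]:
    """Smooth Gaussian random fields on the sphere, optionally linked.

    Parameters
    ----------
    smoothness
        Correlation length (radians of great-circle distance) of the
        exponential covariance; must be > 0.  Small values approach
        white noise.
    link
        Optional ``(target_values, rho)``: each generated map is mixed
        with the standardized target so its *expected* spatial
        correlation with the target equals ``rho`` (0 <= rho < 1).
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    if link is not None:
        target, rho = link
        if not (0 <= rho < 1):
            raise ValueError("link rho must be in [0, 1)")
        target_std = _standardize(np.asarray(target, dtype=float))
    rng = np.random.default_rng(seed)
    K = _sphere_covariance(geometry.coords, smoothness)
    L = np.linalg.cholesky(K + 1e-8 * np.eye(K.shape[0]))
    maps = []
    for m in range(n_maps):
        z = _standardize(L @ rng.normal(0.0, 1.0, K.shape[0]))
        if link is not None:
            z = rho * target_std + np.sqrt(1.0 - rho**2) * z
        name = names[m] if names is not None else f"map-{m:03d}"
        maps.append(AnnotationMap(name=name, values=z, smoothness=smoothness))
    return maps
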