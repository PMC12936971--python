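"""Spatial decoding of fused deviation maps.

The three metric-wise difference maps are fused into one node map
(default: mean of per-map z-scores, which makes the metrics
commensurate), then contextualized two ways:

* correlation with each annotation map (receptor-density stand-ins) under
  a spin-permutation null, with BH correction across the annotation set
  ("spin-FDR") — rank correlation by default, product-moment by config;
* partial least-squares regression of the fused map on a term-map matrix
  (cognitive-term stand-ins): the first PLS component's explained
  variance is tested against spin surrogates of the fused map, and term
  weights are stabilized by a bootstrap over nodes (Z = weight /
  bootstrap SE, signs aligned across resamples).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from msnbiotype.deviations import fdr_bh, spin_permutations
from msnbiotype.synthetic import AnnotationMap, NodeGeometry

__all__ = ["FusedDeviationMap", "PLSResult", "fuse_maps", "annotation_correlation", "pls_decode"]


@dataclass
class FusedDeviationMap:
    values: np.ndarray = field(repr=False)
    aggregation: str = "mean-z"


@dataclass
class PLSResult:
    component_weights: pd.DataFrame  # term, weight, z, ci_lo, ci_hi
    scores: np.ndarray = field(repr=False)  # per node
    explained_variance: float = 0.0
    p_spin: float = 1.0


def fuse_maps(diff_maps: list[np.ndarray], aggregation: str = "mean-z") -> FusedDeviationMap:
    """Aggregate metric-wise difference maps into one fused node map.

    ``"mean-z"`` (default) z-scores each map across nodes and averages;
    ``"sum"`` and ``"max-abs"`` operate on the raw maps.  Zero-variance
    maps are excluded with a warning (they carry no spatial signal).
    """
    maps = [np.asarray(m, dtype=float) for m in diff_maps]
    if aggregation == "mean-z":
        usable = []
        for i, m in enumerate(maps):
            if m.std() == 0:
                warnings.warn(f"map {i} has zero variance; excluded from fusion", stacklevel=2)
            else:
                usable.append((m - m.mean()) / m.std())
        if not usable:
            raise ValueError("all maps degenerate; nothing to fuse")
        fused = np.mean(usable, axis=0)
    elif aggregation == "sum":
        fused = np.sum(maps, axis=0)
    elif aggregation == "max-abs":
        stack = np.stack(maps)
        fused = stack[np.argmax(np.abs(stack), axis=0), np.arange(stack.shape[1])]
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return FusedDeviationMap(values=fused, aggregation=aggregation)


def annotation_correlation(
    fused: FusedDeviationMap,
    annotations: list[AnnotationMap],
    geometry: NodeGeometry,
    n_surrogates: int = 1000,
    seed: int = 0,
    method: str = "spearman",
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Spatial correlation of the fused map with each annotation map.

    Spin surrogates are generated once from the fused map and reused
    across annotations; BH ("spin-FDR") is applied across the annotation
    set.  Columns: name, r, p_spin, q, significant_fdr.
    """
    x = fused.values
    perms = spin_permutations(geometry, n_surrogates, seed=seed)
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for ann in annotations:
        r_obs = float(corr(x, ann.values).statistic)
        null = np.array([corr(x[p], ann.values).statistic for p in perms])
        p = (1.0 + np.sum(np.abs(null) >= abs(r_obs) - 1e-12)) / (n_surrogates + 1.0)
        rows.append({"name": ann.name, "r": r_obs, "p_spin": float(p)})
    out = pd.DataFrame(rows)
    out["q"], out["significant_fdr"] = fdr_bh(out["p_spin"].to_numpy(), q_level)
    return out


def pls_decode(
    fused: FusedDeviationMap,
    term_maps: np.ndarray,
    term_names: list[str],
    geometry: NodeGeometry,
    n_boot: int = 1000,
    n_surrogates: int = 1000,
    seed: int = 0,
) -> PLSResult:
    """First-component PLS of the fused map (response) on term maps (predictors).

    Explained variance is the squared correlation between the response
    and the first component's fitted values; its significance comes from
    spin-rotating the fused map.  Term weights are assessed by a
    bootstrap over nodes with sign alignment (component scores of each
    resample are correlated with the original scores and flipped if
    negative).
    """
    X = np.asarray(term_maps, dtype=float)
    y = np.asarray(fused.values, dtype=float)
    n_nodes, n_terms = X.shape
    if n_terms < 2:
        raise ValueError("need >= 2 term maps")
    if n_nodes < 30:
        raise ValueError("need >= 30 nodes for a stable bootstrap over nodes")
    if n_nodes != geometry.n_regions:
        raise ValueError("term maps and geometry must be aligned")

    def first_component(Xm: np.ndarray, ym: np.ndarray):
        pls = PLSRegression(n_components=1, scale=True)
        pls.fit(Xm, ym)
        scores = pls.x_scores_[:, 0]
        weights = pls.x_weights_[:, 0]
        yhat = pls.predict(Xm).ravel()
        ev = float(np.corrcoef(ym, yhat)[0, 1] ** 2) if np.std(yhat) > 0 else 0.0
        return weights, scores, ev

    w_obs, scores, ev_obs = first_component(X, y)

    perms = spin_permutations(geometry, n_surrogates, seed=seed)
    null_ev = np.array([first_component(X, y[p])[2] for p in perms])
    p_spin = (1.0 + np.sum(null_ev >= ev_obs - 1e-12)) / (n_surrogates + 1.0)

    rng = np.random.default_rng(seed + 1)
    boot = np.empty((n_boot, n_terms))
    for b in range(n_boot):
        idx = rng.integers(0, n_nodes, n_nodes)
        if np.std(y[idx]) == 0:
            boot[b] = w_obs
            continue
        w_b, s_b, _ = first_component(X[idx], y[idx])
        # sign alignment: compare resampled scores with original scores
        if np.corrcoef(s_b, scores[idx])[0, 1] < 0:
            w_b = -w_b
        boot[b] = w_b
    se = boot.std(axis=0, ddof=1)
    z = np.where(se > 0, w_obs / np.where(se > 0, se, 1.0), 0.0)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    table = (
        pd.DataFrame({"term": term_names, "weight": w_obs, "z": z, "ci_lo": lo, "ci_hi": hi})
        .sort_values("z", key=np.abs, ascending=False)
        .reset_index(drop=True)
    )
    return PLSResult(
        component_weights=table, scores=scores, explained_variance=ev_obs, p_spin=float(p_spin)
    )
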