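"""Extreme-deviation cartography and its permutation inference.

Per-node overlap proportions (fraction of a group with |z| >= 2 at the
node), case-control and between-biotype difference maps, group-label
permutation nulls, spatial (spin) permutation nulls that respect spatial
autocorrelation, Benjamini-Hochberg FDR, and proportion/burden effect
sizes (Cohen h and d).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.stats import special_ortho_group
from statsmodels.stats.multitest import multipletests

from msnbiotype.normative import DeviationTensor
from msnbiotype.synthetic import NodeGeometry

__all__ = [
    "OverlapMap",
    "overlap_map",
    "difference_map",
    "group_permutation_test",
    "spin_permutations",
    "spin_test",
    "fdr_bh",
    "cohen_h",
    "extreme_burden_compare",
    "biotype_node_chisq",
    "case_control_difference_analysis",
]


@dataclass
class OverlapMap:
    """Per-node fraction of a group showing extreme deviation."""

    group: str
    metric: str
    direction: str  # positive | negative | either
    proportion: np.ndarray = field(repr=False)


def _direction_mask(devs: DeviationTensor, direction: str) -> np.ndarray:
    if direction == "positive":
        return devs.extreme_mask_pos
    if direction == "negative":
        return devs.extreme_mask_neg
    if direction == "either":
        return devs.extreme_mask_pos | devs.extreme_mask_neg
    raise ValueError(f"unknown direction {direction!r}")


def overlap_map(
    devs: DeviationTensor,
    group_members: np.ndarray,
    metric: int | str,
    direction: str = "either",
    group: str = "group",
) -> OverlapMap:
    """Fraction of group members with an extreme deviation at each node."""
    members = np.asarray(group_members)
    if members.dtype == bool:
        members = np.where(members)[0]
    if members.size == 0:
        raise ValueError("group is empty")
    m = devs.metric_names.index(metric) if isinstance(metric, str) else metric
    mask = _direction_mask(devs, direction)[members, :, m]
    return OverlapMap(
        group=group,
        metric=str(metric),
        direction=direction,
        proportion=mask.mean(axis=0),
    )


def difference_map(case_map: OverlapMap, control_map: OverlapMap) -> np.ndarray:
    """Case minus control overlap proportions, in percentage points."""
    return 100.0 * (case_map.proportion - control_map.proportion)


def group_permutation_test(
    devs: DeviationTensor,
    labels: np.ndarray,
    metric: int | str,
    direction: str = "either",
    n_perm: int = 1000,
    seed: int = 0,
    within: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided permutation test of per-node case-control proportion differences.

    ``labels`` is boolean (True = case).  If ``within`` (e.g. site labels)
    is given, group labels are shuffled within each stratum, preserving
    the per-stratum group sizes.  p follows the add-one rule
    ``(1 + #{|null| >= |obs|}) / (n_perm + 1)``.

    Returns (observed difference in percentage points, per-node p).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = np.asarray(labels, dtype=bool)
    m = devs.metric_names.index(metric) if isinstance(metric, str) else metric
    mask = _direction_mask(devs, direction)[:, :, m].astype(float)
    n = labels.size

    def diff(lab: np.ndarray) -> np.ndarray:
        return 100.0 * (mask[lab].mean(axis=0) - mask[~lab].mean(axis=0))

    observed = diff(labels)
    rng = np.random.default_rng(seed)
    strata = (
        [np.arange(n)]
        if within is None
        else [np.where(np.asarray(within) == s)[0] for s in np.unique(within)]
    )
    exceed = np.zeros(mask.shape[1])
    for _ in range(n_perm):
        perm = labels.copy()
        for idx in strata:
            perm[idx] = labels[idx][rng.permutation(idx.size)]
        exceed += np.abs(diff(perm)) >= np.abs(observed) - 1e-12
    p = (1.0 + exceed) / (n_perm + 1.0)
    return observed, p


# ---------------------------------------------------------------------------
# spin (spatial permutation) test


def spin_permutations(
    geometry: NodeGeometry,
    n_surrogates: int,
    seed: int = 0,
    assignment: str = "nearest",
) -> np.ndarray:
    """Surrogate reassignment indices from random 3-D sphere rotations.

    Each surrogate rotates the node coordinates with a uniformly random
    rotation and maps every node to a source node.  ``"nearest"``
    (default) takes, for each original node, the node whose rotated
    coordinate is closest — duplicates are permitted.  ``"hungarian"``
    solves the one-to-one linear assignment, preserving the value
    multiset exactly.

    Returns an (n_surrogates x n_nodes) integer index array.
    """
    coords = geometry.coords
    if np.unique(np.round(coords, 9), axis=0).shape[0] != coords.shape[0]:
        raise ValueError("duplicate node coordinates: nearest-neighbor mapping ill-defined")
    rng = np.random.default_rng(seed)
    perms = np.empty((n_surrogates, coords.shape[0]), dtype=int)
    for s in range(n_surrogates):
        Rot = special_ortho_group.rvs(3, random_state=rng)
        rotated = coords @ Rot.T
        d = -rotated @ coords.T  # (source, target) negative cosine similarity
        if assignment == "nearest":
            perms[s] = np.argmin(d, axis=0)
        elif assignment == "hungarian":
            row, col = linear_sum_assignment(d)
            inv = np.empty_like(col)
            inv[col] = row
            perms[s] = inv
        else:
            raise ValueError(f"unknown assignment {assignment!r}")
    return perms


def spin_test(
    map_a: np.ndarray,
    map_b: np.ndarray,
    geometry: NodeGeometry,
    n_surrogates: int = 1000,
    seed: int = 0,
    stat: str = "correlation",
    method: str = "spearman",
    assignment: str = "nearest",
    perms: np.ndarray | None = None,
) -> tuple[float, float]:
    """Spatial-permutation p for the association of two node maps.

    ``map_a`` is spun (rotated + reassigned); ``map_b`` stays fixed.
    ``stat="correlation"`` uses Spearman (default) or Pearson
    correlation; ``stat="difference"`` uses the mean difference.
    Two-sided add-one p on |stat|.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != geometry.n_regions:
        raise ValueError("maps and geometry must be aligned")
    if perms is None:
        if n_surrogates < 100:
            raise ValueError("n_surrogates must be >= 100")
        perms = spin_permutations(geometry, n_surrogates, seed=seed, assignment=assignment)

    def statistic(x: np.ndarray) -> float:
        if stat == "correlation":
            if method == "spearman":
                return float(stats.spearmanr(x, b).statistic)
            return float(stats.pearsonr(x, b).statistic)
        if stat == "difference":
            return float(np.mean(x - b))
        raise ValueError(f"unknown stat {stat!r}")

    observed = statistic(a)
    null = np.array([statistic(a[p]) for p in perms])
    p_spin = (1.0 + np.sum(np.abs(null) >= abs(observed) - 1e-12)) / (len(perms) + 1.0)
    return observed, float(p_spin)


def fdr_bh(p: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted q, rejection mask at q_level)."""
    p = np.asarray(p, dtype=float)
    reject, q, *_ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, reject


def cohen_h(p1: float | np.ndarray, p2: float | np.ndarray) -> float | np.ndarray:
    """Arcsine effect size for two proportions: 2 asin sqrt(p1) - 2 asin sqrt(p2)."""
    return 2.0 * np.arcsin(np.sqrt(p1)) - 2.0 * np.arcsin(np.sqrt(p2))


def extreme_burden_compare(
    devs: DeviationTensor, labels: np.ndarray, direction: str = "either"
) -> pd.DataFrame:
    """Per-metric comparison of extreme-deviation counts per individual.

    Counts the extreme nodes per subject and metric, then compares cases
    vs controls with a two-sample t test and pooled-SD Cohen d.
    """
    labels = np.asarray(labels, dtype=bool)
    counts = _direction_mask(devs, direction).sum(axis=1)  # subjects x metrics
    rows = []
    for m in range(counts.shape[1]):
        a, b = counts[labels, m], counts[~labels, m]
        t, p = stats.ttest_ind(a, b)
        sp = np.sqrt(
            ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
        )
        d = (a.mean() - b.mean()) / sp if sp > 0 else 0.0
        rows.append(
            {
                "metric": devs.metric_names[m] if devs.metric_names else str(m),
                "case_mean": a.mean(),
                "case_sd": a.std(ddof=1),
                "control_mean": b.mean(),
                "control_sd": b.std(ddof=1),
                "t": float(t),
                "cohen_d": float(d),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def biotype_node_chisq(
    devs: DeviationTensor,
    biotype_labels: np.ndarray,
    metric: int | str,
    direction: str = "either",
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Per-node chi-square test of extreme-deviation frequency across biotypes.

    Builds a k x 2 (extreme vs not) contingency table per node across the
    case biotypes; Pearson chi-square without continuity correction, BH
    across nodes.  Cells with expected count < 5 trigger a warning and a
    Fisher-exact fallback when the table is 2 x 2.
    """
    bl = np.asarray(biotype_labels)
    m = devs.metric_names.index(metric) if isinstance(metric, str) else metric
    mask = _direction_mask(devs, direction)[:, :, m]
    groups = np.unique(bl)
    rows = []
    for node in range(mask.shape[1]):
        table = np.array(
            [[mask[bl == g, node].sum(), (~mask[bl == g, node]).sum()] for g in groups]
        )
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            chi2, p = 0.0, 1.0
        else:
            expected = stats.contingency.expected_freq(table)
            if (expected < 5).any():
                warnings.warn(
                    f"node {node}: expected count < 5 in biotype contingency table",
                    stacklevel=2,
                )
                if table.shape[0] == 2:
                    p = float(stats.fisher_exact(table)[1])
                    chi2 = float(stats.chi2_contingency(table, correction=False)[0])
                else:
                    chi2, p, *_ = stats.chi2_contingency(table, correction=False)
            else:
                chi2, p, *_ = stats.chi2_contingency(table, correction=False)
        rows.append({"node": node, "chi2": float(chi2), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"], out["significant_fdr"] = fdr_bh(out["p"].to_numpy(), q_level)
    return out


def case_control_difference_analysis(
    devs: DeviationTensor,
    case_labels: np.ndarray,
    geometry: NodeGeometry,
    metric: int | str,
    direction: str = "either",
    n_perm: int = 1000,
    seed: int = 0,
    within: np.ndarray | None = None,
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Full per-node difference map with group and spin p-values, FDR and Cohen h."""
    labels = np.asarray(case_labels, dtype=bool)
    case = overlap_map(devs, labels, metric, direction, group="case")
    ctrl = overlap_map(devs, ~labels, metric, direction, group="control")
    diff = difference_map(case, ctrl)
    _, p_group = group_permutation_test(
        devs, labels, metric, direction, n_perm=n_perm, seed=seed, within=within
    )
    # spin null: compare the observed difference map against rotations of itself
    perms = spin_permutations(geometry, n_perm, seed=seed + 1)
    null = diff[perms.T]  # nodes x surrogates
    p_spin = (1.0 + np.sum(np.abs(null) >= np.abs(diff)[:, None] - 1e-12, axis=1)) / (
        n_perm + 1.0
    )
    q, sig = fdr_bh(p_group, q_level)
    return pd.DataFrame(
        {
            "node": np.arange(diff.size),
            "case_proportion": case.proportion,
            "control_proportion": ctrl.proportion,
            "difference_pct": diff,
            "p_group": p_group,
            "p_spin": p_spin,
            "q": q,
            "significant_fdr": sig,
            "cohen_h": cohen_h(case.proportion, ctrl.proportion),
        }
    )
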