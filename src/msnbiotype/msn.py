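"""Morphometric similarity network (MSN) construction.

A subject's MSN is an R x R similarity matrix over brain regions whose
(i, j) entry quantifies the concordance of the two regions' gray-matter
value distributions.  Concordance is measured by Kullback-Leibler
divergence similarity (KLS),

    KLS(p, q) = exp(-[KL(p || q) + KL(q || p)]),

which lies in (0, 1] and equals 1 iff the two distributions coincide.
Distributions are estimated on a shared per-subject grid so that the
divergences are comparable across region pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "DegenerateDistributionError",
    "MorphometricSimilarityMatrix",
    "estimate_density",
    "kls_similarity",
    "build_msn",
    "build_msn_batch",
]

DEFAULT_N_BINS = 128
DEFAULT_FLOOR = 1e-10


class DegenerateDistributionError(ValueError):
    """Raised when a regional sample has no spread (density undefined)."""


@dataclass
class MorphometricSimilarityMatrix:
    """Per-subject MSN: symmetric, unit diagonal, entries in (0, 1]."""

    subject_id: str
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("MSN matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("MSN matrix must be symmetric to 1e-12")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("MSN diagonal must be exactly 1")
        if np.any(m <= 0) or np.any(m > 1 + 1e-12):
            raise ValueError("MSN entries must lie in (0, 1]")
        self.matrix = m

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


def _shared_grid(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi <= lo:
        raise DegenerateDistributionError("pooled sample range is degenerate")
    # widen slightly so boundary samples fall strictly inside the bins
    pad = 1e-9 * (hi - lo)
    return np.linspace(lo - pad, hi + pad, n_bins + 1)


def estimate_density(
    values: np.ndarray,
    grid: np.ndarray,
    *,
    floor: float = DEFAULT_FLOOR,
    method: str = "histogram",
) -> np.ndarray:
    """Discretize a sample of positive morphometry values onto a shared grid.

    Parameters
    ----------
    values
        Sample vector (>= 10 observations, positive spread required).
    grid
        Bin edges (length G+1) covering the pooled sample range; shared
        across the regions being compared.
    floor
        Probability floor epsilon added to every bin before renormalizing,
        guaranteeing strictly positive output:
        ``min(p) >= floor / (1 + floor * G)``.
    method
        ``"histogram"`` (default) or ``"kde"`` (Gaussian KDE evaluated at
        bin centers).

    Returns
    -------
    Probability vector of length G, non-negative, summing to 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise ValueError(f"need >= 10 samples, got {v.size}")
    if np.ptp(v) == 0:
        raise DegenerateDistributionError("all samples equal; density is degenerate")
    if floor <= 0:
        raise ValueError("floor must be > 0 (KL requires strictly positive bins)")
    edges = np.asarray(grid, dtype=float)
    if v.min() < edges[0] or v.max() > edges[-1]:
        raise ValueError("grid does not cover the sample range")

    if method == "histogram":
        counts, _ = np.histogram(v, bins=edges)
        p = counts / counts.sum()
    elif method == "kde":
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = gaussian_kde(v)(centers)
        p = dens / dens.sum()
    else:
        raise ValueError(f"unknown density method {method!r}")

    p = (p + floor) / (1.0 + floor * p.size)
    return p / p.sum()


def kls_similarity(p: np.ndarray, q: np.ndarray) -> float:
    """Kullback-Leibler divergence similarity exp(-[KL(p||q) + KL(q||p)]).

    Both arguments must be strictly positive probability vectors of equal
    length.  Returns a value in (0, 1]; 1 iff p == q; symmetric.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("distributions must be strictly positive; apply the floor upstream")
    if not (np.isclose(p.sum(), 1.0) and np.isclose(q.sum(), 1.0)):
        raise ValueError("p and q must each sum to 1")
    lr = np.log(p) - np.log(q)
    sym_kl = float(np.sum(p * lr) - np.sum(q * lr))
    return float(np.exp(-sym_kl))


def build_msn(
    samples: dict[int, np.ndarray],
    subject_id: str = "subject",
    *,
    n_bins: int = DEFAULT_N_BINS,
    floor: float = DEFAULT_FLOOR,
    method: str = "histogram",
) -> MorphometricSimilarityMatrix:
    """Build one subject's MSN from per-region sample vectors.

    ``samples`` maps region index (0..R-1, all present) to that region's
    morphometry sample vector.  Densities are estimated on a common grid
    spanning the subject's pooled range, then all region pairs are scored
    with :func:`kls_similarity`.
    """
    regions = sorted(samples)
    R = len(regions)
    if regions != list(range(R)):
        raise ValueError("regions must be exactly 0..R-1")
    pooled = np.concatenate([np.asarray(samples[r], dtype=float) for r in regions])
    if np.any(pooled <= 0):
        raise ValueError("morphometry samples must be positive")
    grid = _shared_grid(pooled, n_bins)

    dens = np.empty((R, grid.size - 1))
    for r in regions:
        try:
            dens[r] = estimate_density(samples[r], grid, floor=floor, method=method)
        except DegenerateDistributionError as err:
            raise DegenerateDistributionError(f"region {r}: {err}") from err

    # vectorized symmetrized KL over all pairs:
    # KL(p_i||p_j)+KL(p_j||p_i) = sum_g (p_i - p_j) (log p_i - log p_j)
    logd = np.log(dens)
    cross = dens @ logd.T
    diag = np.sum(dens * logd, axis=1)
    sym_kl = diag[:, None] + diag[None, :] - cross - cross.T
    sym_kl = np.maximum(0.5 * (sym_kl + sym_kl.T), 0.0)
    mat = np.exp(-sym_kl)
    np.fill_diagonal(mat, 1.0)
    return MorphometricSimilarityMatrix(subject_id=subject_id, matrix=mat)


def build_msn_batch(
    sample_sets: dict[str, dict[int, np.ndarray]],
    **kwargs,
) -> dict[str, MorphometricSimilarityMatrix]:
    """Build MSNs for a collection of subjects (subject_id -> region samples)."""
    return {sid: build_msn(regs, subject_id=sid, **kwargs) for sid, regs in sample_sets.items()}
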