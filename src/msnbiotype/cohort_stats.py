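"""Clinical-profile statistics across biotypes.

Kruskal-Wallis (tie-corrected) with the eta-squared effect size
``(H - k + 1) / (n - k)``, post-hoc pairwise two-sample t tests with
pooled-SD Cohen d and familywise adjustment (Holm by default), and the
0-1 rescaling applied to symptom subscales.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["kruskal_wallis", "posthoc_pairwise", "rescale_scores"]


def kruskal_wallis(scores: np.ndarray, groups: np.ndarray) -> dict:
    """Rank-based H test across k groups with eta-squared effect size.

    All-tied input (zero rank variance) is defined as H = 0, p = 1.
    Returns a dict with keys ``H, eta_squared, p, k, n`` and an
    ``effect_size_formula`` tag recording the eta-squared variant used.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k, n = labels.size, scores.size
    if k < 2:
        raise ValueError("need >= 2 groups")
    samples = [scores[groups == g] for g in labels]
    if np.ptp(scores) == 0:
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*samples)
    eta2 = (H - k + 1) / (n - k)
    return {
        "H": float(H),
        "eta_squared": float(eta2),
        "p": float(p),
        "k": int(k),
        "n": int(n),
        "effect_size_formula": "(H - k + 1) / (n - k)",
    }


def posthoc_pairwise(
    scores: np.ndarray, groups: np.ndarray, adjust: str = "holm"
) -> pd.DataFrame:
    """Pairwise two-sample t tests with pooled-SD Cohen d and adjustment.

    ``adjust`` is any method statsmodels' ``multipletests`` accepts
    (default Holm; ``"bonferroni"`` and ``"fdr_bh"`` are common
    alternatives).  Pairs are labeled ``biotype_i_vs_j``.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    rows = []
    for i in range(labels.size):
        for j in range(i + 1, labels.size):
            a, b = scores[groups == labels[i]], scores[groups == labels[j]]
            t, p = stats.ttest_ind(a, b)
            sp = np.sqrt(
                ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                / (a.size + b.size - 2)
            )
            d = (a.mean() - b.mean()) / sp if sp > 0 else 0.0
            rows.append(
                {
                    "pair": f"biotype_{labels[i]}_vs_{labels[j]}",
                    "t": float(t),
                    "cohen_d": float(d),
                    "p": float(p),
                }
            )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = multipletests(out["p"].to_numpy(), method=adjust)[1]
    return out


def rescale_scores(raw: np.ndarray, lo: float, hi: float) -> tuple[np.ndarray, int]:
    """Rescale raw symptom scores to [0, 1]: (x - lo) / (hi - lo), clipped.

    Returns the rescaled vector and the number of out-of-range inputs
    that were clipped.
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    x = np.asarray(raw, dtype=float)
    scaled = (x - lo) / (hi - lo)
    n_clipped = int(np.sum((scaled < 0) | (scaled > 1)))
    return np.clip(scaled, 0.0, 1.0), n_clipped
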