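"""In-memory convenience chain: samples -> MSNs -> topology -> deviations.

The file-based pipeline (:mod:`msnbiotype.pipeline`) is the reproducible
workflow; this module exposes the same chain as plain function calls for
interactive use, simulations and tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from msnbiotype.msn import build_msn
from msnbiotype.normative import (
    DeviationTensor,
    NormativeConfig,
    NormativeModel,
    compute_deviation_tensor,
    deviation_z,
    fit_normative_battery,
    transfer_recalibrate,
)
from msnbiotype.topology import (
    METRIC_NAMES,
    consensus_partition,
    threshold_network,
    topology_profile,
)

__all__ = ["derive_deviations", "transfer_deviations"]


def _hub_tensor(samples, subject_ids, partition, sparsity):
    Y = []
    for sid in subject_ids:
        mat = samples[sid]
        msn = build_msn({r: mat[r] for r in range(mat.shape[0])}, sid).matrix
        Y.append(topology_profile(msn, partition, sid, sparsity=sparsity).metrics)
    return np.stack(Y)


def derive_deviations(
    cohort: pd.DataFrame,
    samples: dict[str, np.ndarray],
    sparsity: float = 0.3,
    normative_config: NormativeConfig | None = None,
    partition: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[DeviationTensor, np.ndarray, list[list[NormativeModel]]]:
    """Full discovery chain on an in-memory cohort.

    Returns the deviation tensor (all subjects), the consensus partition
    used for the participation coefficient, and the fitted normative
    model battery (trained on the cohort's controls).
    """
    ids = cohort["subject_id"].tolist()
    ctrl = (cohort["group"] == "control").to_numpy()
    if partition is None:
        adjs = []
        for sid, c in zip(ids, ctrl):
            if not c:
                continue
            mat = samples[sid]
            msn = build_msn({r: mat[r] for r in range(mat.shape[0])}, sid).matrix
            adjs.append(threshold_network(msn, sparsity))
        partition = consensus_partition(adjs, seed=seed)
    Y = _hub_tensor(samples, ids, partition, sparsity)
    age = cohort["age"].to_numpy()
    sex = cohort["sex"].to_numpy()
    models = fit_normative_battery(Y[ctrl], age[ctrl], sex[ctrl], METRIC_NAMES, normative_config)
    devs = compute_deviation_tensor(models, Y, age, sex, METRIC_NAMES, ids)
    return devs, partition, models


def transfer_deviations(
    cohort: pd.DataFrame,
    samples: dict[str, np.ndarray],
    models: list[list[NormativeModel]],
    partition: np.ndarray,
    sparsity: float = 0.3,
) -> DeviationTensor:
    """Score a new cohort against pretrained normative models.

    Each site's controls serve as adaptation data for the site's
    recalibration; the pretrained regression coefficients are untouched.
    """
    ids = cohort["subject_id"].tolist()
    Y = _hub_tensor(samples, ids, partition, sparsity)
    age = cohort["age"].to_numpy()
    sex = cohort["sex"].to_numpy()
    ctrl = (cohort["group"] == "control").to_numpy()
    sites = cohort["site"].to_numpy()
    z = np.empty_like(Y)
    for s in np.unique(sites):
        s_mask = sites == s
        adapt = s_mask & ctrl
        for r in range(Y.shape[1]):
            for m in range(Y.shape[2]):
                recal = transfer_recalibrate(
                    models[r][m], Y[adapt, r, m], age[adapt], sex[adapt], site=str(s)
                )
                z[s_mask, r, m] = deviation_z(recal, Y[s_mask, r, m], age[s_mask], sex[s_mask])
    return DeviationTensor(z=z, metric_names=METRIC_NAMES, subject_ids=ids)
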