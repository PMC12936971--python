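"""Shared fixtures: one small synthetic cohort processed through the chain.

The cohort is deliberately small (fast) but large enough that every
downstream stage has signal to work with; session scope keeps the MSN /
topology / normative work from being repeated across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from msnbiotype.synthetic import CohortSpec, generate_cohort
from msnbiotype.msn import build_msn
from msnbiotype.topology import (
    METRIC_NAMES,
    consensus_partition,
    threshold_network,
    topology_profile,
)
from msnbiotype.normative import (
    NormativeConfig,
    compute_deviation_tensor,
    fit_normative_battery,
)


@pytest.fixture(scope="session")
def small_cohort():
    spec = CohortSpec(
        n_controls=90,
        n_cases=75,
        n_sites=3,
        n_regions=30,
        n_samples_per_region=120,
        k_true=3,
        effect_size=3.0,
        seed=42,
    )
    return spec, *generate_cohort(spec)


@pytest.fixture(scope="session")
def processed_cohort(small_cohort):
    """Cohort taken through MSN -> topology -> normative deviations."""
    spec, cohort, samples, geometry, truth = small_cohort
    R = spec.n_regions
    msns = {
        sid: build_msn({r: samples[sid][r] for r in range(R)}, sid).matrix
        for sid in samples
    }
    ctrl = (cohort["group"] == "control").to_numpy()
    ids = cohort["subject_id"].tolist()
    adjs = [threshold_network(msns[sid], 0.3) for sid, c in zip(ids, ctrl) if c]
    partition = consensus_partition(adjs, seed=7)
    Y = np.stack([topology_profile(msns[sid], partition).metrics for sid in ids])
    age = cohort["age"].to_numpy()
    sex = cohort["sex"].to_numpy()
    models = fit_normative_battery(Y[ctrl], age[ctrl], sex[ctrl], METRIC_NAMES, NormativeConfig())
    devs = compute_deviation_tensor(models, Y, age, sex, METRIC_NAMES, ids)
    return {
        "spec": spec,
        "cohort": cohort,
        "geometry": geometry,
        "truth": truth,
        "msns": msns,
        "partition": partition,
        "Y": Y,
        "models": models,
        "devs": devs,
        "ctrl": ctrl,
    }
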