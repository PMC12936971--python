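"""Normative modeling of hub topology and extreme deviations.

Processes a small cohort end to end (MSN -> hub metrics -> warped-BLR
normative models) and reports how extreme |z| >= 2 deviations separate
cases from controls.
"""

import numpy as np

from msnbiotype import CohortSpec, generate_cohort
from msnbiotype.workflow import derive_deviations
from msnbiotype.deviations import extreme_burden_compare

spec = CohortSpec(
    n_controls=100, n_cases=80, n_regions=30, n_samples_per_region=120,
    k_true=2, effect_size=3.0, seed=1,
)
cohort, samples, *_ = generate_cohort(spec)
devs, partition, models = derive_deviations(cohort, samples, seed=2)

ctrl = (cohort["group"] == "control").to_numpy()
print(f"control |z| >= 2 rate: {np.mean(np.abs(devs.z[ctrl]) >= 2):.3f}  (theory: 0.0455)")
print("\nExtreme-deviation burden per subject (cases vs controls):")
print(extreme_burden_compare(devs, ~ctrl).round(3).to_string(index=False))
print("\nCases carry more extreme hub deviations than controls; the")
print("control rate sits at the Gaussian tail expectation, showing the")
print("normative models are calibrated.")
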