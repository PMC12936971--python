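"""Spin-test decoding of a fused deviation map.

Builds a case-control extreme-deviation difference map, fuses the three
metrics, and correlates the fused map with synthetic receptor-density
maps under a spatial-rotation (spin) null.  One annotation is linked to
the fused map by construction; it should be the one that survives.
"""

import numpy as np

from msnbiotype import CohortSpec, generate_cohort
from msnbiotype.synthetic import generate_annotation_maps
from msnbiotype.workflow import derive_deviations
from msnbiotype.deviations import overlap_map, difference_map
from msnbiotype.decode import fuse_maps, annotation_correlation

spec = CohortSpec(
    n_controls=100, n_cases=80, n_regions=40, n_samples_per_region=120,
    k_true=1, effect_size=3.0, seed=5,
)
cohort, samples, geometry, _ = generate_cohort(spec)
devs, *_ = derive_deviations(cohort, samples, seed=6)
case = (cohort["group"] == "case").to_numpy()

fused = fuse_maps([
    difference_map(overlap_map(devs, case, m), overlap_map(devs, ~case, m))
    for m in range(3)
])

null_maps = generate_annotation_maps(geometry, 9, smoothness=0.5, seed=7)
linked = generate_annotation_maps(
    geometry, 1, smoothness=0.5, seed=8, link=(fused.values, 0.7), names=["linked-receptor"]
)
table = annotation_correlation(fused, null_maps + linked, geometry, n_surrogates=500, seed=9)

print(table.sort_values("p_spin").round(4).to_string(index=False))
print("\nOnly the deliberately linked map shows a strong spin-surviving")
print("correlation; the smooth null maps are controlled at the nominal rate.")
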