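"""Run the complete file-based pipeline and print the report.

Equivalent to:
    msnbiotype run-all --seed 11 --workspace <dir>
with a reduced-size config.
"""

from pathlib import Path
import tempfile

from msnbiotype.pipeline import DEFAULT_CONFIG, RunConfig, _merge, run

cfg = _merge(DEFAULT_CONFIG, {
    "seed": 11,
    "cohort": {"n_controls": 80, "n_cases": 60, "n_regions": 32,
               "n_samples_per_region": 100, "n_sites": 2, "k_true": 2},
    "validation": {"n_controls": 56, "n_cases": 40, "n_sites": 2},
    "annotations": {"n_receptor_maps": 6, "n_term_maps": 8},
    "deviations": {"n_perm": 200},
    "fusion": {"n_restarts": 5, "max_components": 6},
    "hydra": {"k_grid": [2, 3], "n_folds": 5, "n_restarts": 3, "n_splits": 2},
    "decode": {"n_surrogates": 200, "n_boot": 100},
})

workspace = Path(tempfile.mkdtemp(prefix="msnbiotype-demo-"))
manifest = run(RunConfig(cfg, workspace))
print((workspace / "report.md").read_text())
print(f"(artifacts and manifest under {workspace})")
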