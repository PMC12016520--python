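"""Simulate a full study and reduce it end to end.

Generates a seeded synthetic study (peak tables, standards co-runs,
water values, growth curves), runs the reduction pipeline
(calibration → hydrogenation correction → ε → weighted means → ring
metrics), and compares the recovered fractionations against the hidden
truth table.
"""

import tempfile
import warnings
from pathlib import Path

import numpy as np

from bpiso import PipelineConfig, SyntheticConfig, generate_study, run_pipeline, write_study

workdir = Path(tempfile.mkdtemp(prefix="bpiso_example_"))

cfg = SyntheticConfig(n_treatments=5, replicates_per_treatment=3, seed=42)
dataset = generate_study(cfg)
paths = write_study(dataset, workdir / "study")
print(f"simulated {len(dataset.metadata)} cultures "
      f"({len(dataset.sample_runs)} sample peaks, "
      f"{len(dataset.standards_runs)} standards peaks) → {workdir}")

pipe = PipelineConfig(
    standards_path=str(paths["standards"]),
    samples_path=str(paths["samples"]),
    metadata_path=str(paths["metadata"]),
    growth_path=str(paths["growth"]),
    standard_defs_path=str(paths["standard_defs"]),
    out_dir=str(workdir / "reduced"),
    delta_added=cfg.delta_added_H,  # δ²H of the H added during hydrogenation
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # low-abundance BP-3 exclusions
    bundle = run_pipeline(pipe)

print("\ncalibration recovered:",
      f"offset {bundle.calibration['offset_permil']:.2f}‰ (true {cfg.cal_offset}),",
      f"scale {bundle.calibration['scale']:.4f} (true {cfg.cal_scale})")

truth = dataset.truth.set_index("culture_id")
err = [
    abs(r["eps_permil"] - truth.at[r["culture_id"], f"eps_bp{int(r['ring'])}"])
    for _, r in bundle.per_culture.iterrows()
]
print(f"per-moiety ε recovery: median |error| = {np.median(err):.1f}‰ "
      f"over {len(err)} culture×moiety values (noise σ ≈ 2–4‰)")

print("\nper-treatment table (weighted ε, ‰):")
cols = ["treatment", "ring_index", "weighted_eps_permil", "mean_ring_difference_permil"]
print(bundle.per_treatment[cols].round(2).to_string(index=False))
print(f"\nfull results bundle written to {workdir / 'reduced'} "
      f"(TSV tables + JSON summary + text report)")
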