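"""Run the whole pipeline from a declarative config.

Simulates the configured models, sweeps both TPM methods over the τ grid,
computes Φ, fits the quadratic peak model to log Φ, and writes every
artifact (series, tidy sweep tables, Φ curves, fits, summary) into the
output directory, stamped with the config hash and seed.  Reduced scale so
it finishes in about a minute.
"""

import json
from pathlib import Path

import phitau as pt

config = pt.PipelineConfig(
    models=("nl2",),
    methods=("skipping", "downsampling"),
    tau_grid=(1, 2, 3, 5, 8, 10, 13, 16, 25, 40, 64),
    n_timepoints=6000,
    n_runs=3,
    seed=11,
    out_dir="scratch/pipeline_demo",
)
out = pt.run_pipeline(config)
summary = json.loads((out / "summary.json").read_text())
print(f"artifacts in {out} (config hash {summary['config_hash']}):")
for name in sorted(p.name for p in Path(out).iterdir()):
    print(f"  {name}")
for cell, info in summary["cells"].items():
    print(f"{cell}: peak Phi {info['peak_phi']:.4f} at tau = {info['argmax_tau']} "
          f"(true interaction lag 10)")
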