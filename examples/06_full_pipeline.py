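"""Run the full pipeline and list the artifacts it writes.

Equivalent to `rdistrat run-all --seed 5 --outdir scratch/example-run`.
"""

from pathlib import Path

from rdistrat import SimulationConfig
from rdistrat.pipeline import PipelineConfig, run_pipeline

outdir = Path("scratch/example-run")
config = PipelineConfig(
    outdir=str(outdir),
    seed=5,
    simulation=SimulationConfig(n_patients=300, seed=5),
)
manifest = run_pipeline(config)

print("strata per scenario:")
for scenario, info in manifest["scenarios"].items():
    print(f"  {scenario}: {info['n_strata']} strata, sizes {info['strata_sizes']}")
print(f"\nselection: {manifest['selection']}")
print(f"\n{len(manifest['outputs'])} CSV artifacts under {outdir}/ (SHA-256 in manifest.json);")
print("plots: tau-delta plane, per-stratum KM curves, adaptation bars per scenario.")
# Re-running with the same config reproduces every CSV byte-for-byte —
# the digests in manifest.json prove it.
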