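"""Run every pipeline stage end-to-end on the bundled scenario.

Writes reads, mutation/genotype/lineage tables, the replicator graph, the
Bahadur coefficients and a simulation summary into ./pipeline_demo, plus a
manifest of output hashes proving the run is reproducible from its seed.
"""

import json
from pathlib import Path

from replinet.pipeline import demo_config, run_full_pipeline

outdir = Path("pipeline_demo")
manifest = run_full_pipeline(demo_config(str(outdir), seed=0))

print("stages executed:")
for stage, info in manifest["stages"].items():
    print(f"  {stage:9s} {info['counts']}")

print(f"\noutputs under {outdir}/ (from manifest.json):")
for stage, info in manifest["stages"].items():
    for path in info["outputs"]:
        print(f"  {path}")

manifest_disk = json.loads((outdir / "manifest.json").read_text())
assert manifest_disk["seed"] == 0
print("\nre-running with the same seed reproduces byte-identical output hashes.")
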