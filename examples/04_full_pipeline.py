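"""End-to-end pipeline run from the bundled demo configuration.

Equivalent to `collmot all --config examples/demo_config.yaml --out out/`:
generates a movie, masks and a cohort, then runs PIV, motility metrics,
wetting and TMA scoring, leaving CSV artifacts and a JSON run report.
"""

import json
import os
import tempfile

from collmot.pipeline import PipelineConfig, run_pipeline

here = os.path.dirname(os.path.abspath(__file__))
cfg = PipelineConfig.from_yaml(os.path.join(here, "demo_config.yaml"))

out = tempfile.mkdtemp(prefix="collmot_demo_")
report = run_pipeline(cfg, out)

print(f"artifacts written to {out}:")
for name in sorted(os.listdir(out)):
    print(f"  {name}")
print("\nrun report:")
print(json.dumps(report, indent=2))
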