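"""Run the bundled demo pipeline: simulate -> QC -> deconvolve -> call
aDMPs -> overlap/concordance/validation/power/panel, into ./demo_run/.

The same run is available from the shell as:
    epidrift run --config src/epidrift/configs/demo.yaml --out demo_run
"""

import importlib.resources as ir
import json
from pathlib import Path

from epidrift import RunConfig, run_pipeline

config_path = ir.files("epidrift") / "configs" / "demo.yaml"
outdir = Path("demo_run")
manifest = run_pipeline(RunConfig.from_yaml(config_path), outdir)

for stage in manifest["stages"]:
    print(f"{stage['stage']:20s} {stage['duration_s']:7.2f}s  "
          f"{len(stage['outputs'])} output file(s)")

overlap = json.loads((outdir / "overlap.json").read_text())
print(f"\naDMPs shared by all three datasets: {overlap['triple_count']} "
      f"(nested hypergeometric p = {overlap['triple_p']:.3g})")
pi0 = json.loads((outdir / "pi0.json").read_text())
for label, vals in pi0.items():
    print(f"estimated drifting fraction in {label}: {vals['admp_fraction']:.2f}")
# Every stage's tabular outputs are under demo_run/; rerunning with the
# same config reproduces them byte for byte.
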