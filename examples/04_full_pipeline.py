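"""The orchestrated end-to-end run on a complete synthetic input bundle.

Writes a full input set (OTU table, gene annotations + Salmon-style quant,
qPCR copy numbers), runs diversity -> network -> cycles with one seed, and
shows the manifest that makes the run reproducible.
"""

import json
from pathlib import Path

from biogeocycler import run_all, simulate_bundle

workdir = Path("pipeline_demo")
inputs = simulate_bundle(workdir / "inputs", seed=5, n_taxa=80)
print("inputs written:", *sorted(Path(p).name for p in inputs.values()))

config = {
    "seed": 5,
    "inputs": inputs,
    # scaled down so the demo finishes in seconds; defaults are 999 / 20
    "params": {"n_permutations": 199, "nmds_restarts": 5},
}
manifest = run_all(config, out_dir=workdir / "results")

print("\nresult tables:", *manifest["outputs"], sep="\n  ")
print("\nper-stage seeds derived from the top-level seed "
      "(re-running any stage alone reproduces it):")
print(json.dumps(manifest["stage_seeds"], indent=2))
print("\nre-running with this config writes byte-identical tables; "
      "the manifest records input hashes and all parameters.")
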