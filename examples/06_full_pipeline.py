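"""Run the whole study from one config: corpus -> generator ->
library -> evaluation -> predictor -> biasing.

Equivalent to `memomol run config.yaml`; every stage writes its
artifacts under the output directory and the manifest records enough to
re-run the experiment.  Takes a couple of minutes on one CPU.
"""

import json

from memomol.pipeline import run_pipeline

config = {
    "seed": 3,
    "outdir": "scratch/example_pipeline",
    "corpus": {"n": 1500, "seed": 0},
    "generator": {"arch": "stackrnn", "units": 24, "iterations": 1200,
                  "batch_size": 32, "eval_every": 400,
                  "learning_rate": 3e-3},
    "generation": {"count": 300, "max_length": 60},
    "evaluation": {"property": "logP"},
    "predictor": {"property": "logP", "n_train": 1000, "epochs": 5},
    "bias": {"direction": "minimize", "steps": 100, "reward": "oracle"},
}

manifest = run_pipeline(config)

print("stages run:", manifest["stages"])
print("\ncheckpoint table (iteration vs valid %):")
for row in manifest["checkpoint_table"]:
    print(f"  {row['iteration']:6d}   {row['valid_pct']:6.1f}")
print("\nunbiased library:", json.dumps(manifest["report"], indent=2))
print("\nbiased library:  ", json.dumps(manifest["biased_report"], indent=2))
print("\nCompare the two reports: after minimize-biasing the logP"
      " quartiles shift down while valid % stays high; all artifacts"
      f" are under {config['outdir']}/.")
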