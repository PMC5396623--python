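"""Call two-fold differentially expressed probes on a simulated experiment.

Runs the whole pipeline on the zero-noise default panel and shows the DE
table: with no measurement noise the |delta log2| >= 1 rule recovers the
planted effects exactly.
"""

import tempfile

import pandas as pd

from mirspot.pipeline import run_pipeline, simulate_inputs
from mirspot.simulate import zero_noise_config

with tempfile.TemporaryDirectory() as workdir:
    config, truth = simulate_inputs(workdir, zero_noise_config())
    manifest = run_pipeline(config)
    de = pd.read_csv(manifest["outputs"]["de"], sep="\t", index_col="probe_id")

called = de[de["any_de"]]
print(f"{len(called)} probes show a >= 2-fold difference versus control "
      f"(planted: {len(truth.de_probes)})")
top = called.head(5)[["delta_over", "fold_change_over", "direction_over"]]
print("strongest five calls (log2 delta, fold change, direction):")
print(top.round(3).to_string())
# fold_change_over = 2**|delta|: a delta of +1.8 means the probe is
# 2**1.8 = 3.5x brighter in the overexpression group than in controls.
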