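"""Run the whole chain from one config and one seed.

Equivalent to ``python -m delaylick.pipeline --seed 1``: simulates every
modality and prints the summary each analysis stage computes.  Running it
twice with the same seed gives bit-identical output.
"""

import json

from delaylick import run_pipeline

summary = run_pipeline(seed=1)
print(json.dumps(summary, indent=2, default=float))
# frac_selective is the fraction of ROIs flagged side-selective in any
# epoch; decoding accuracies are held-out means with their shuffled-label
# chance controls.
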