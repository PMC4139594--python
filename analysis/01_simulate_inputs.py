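"""Simulate every pipeline input: mouse atlas, human panels, networks, annotations.

The mouse atlas carries 2104 genes over 12 structures x 7 stages with a
13-gene module planted on VZ at E15.5 (10-fold, log-normal noise sigma 0.3).
The two human panels share one 3000-gene universe whose planted modules
intersect in a 407-gene core containing 7 mouse-module orthologs.  Evidence
networks wire a 50-gene associated tier to the mouse module; annotation sets
echo the published pathway-table sizes.
"""

import json

from _common import INPUT_DIR, SEED, ensure_inputs

ensure_inputs()
truth = json.loads((INPUT_DIR / "ground_truth.json").read_text())
print(f"inputs ready under {INPUT_DIR} (seed={SEED})")
for key, value in truth.items():
    size = len(value) if isinstance(value, list) else value
    print(f"  ground truth {key}: {size}")
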