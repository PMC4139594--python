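"""Extend the 13-gene mouse module over the association-network compendium.

Label propagation over the uniform combination of the five evidence channels
ranks every non-query gene; the top 50 join the module, giving a 63-node
extended network.
"""

import json

from _common import INPUT_DIR, RESULTS_DIR, ensure_inputs
from cortexseek import PipelineConfig
from cortexseek.extension import extend_list
from cortexseek.netio import read_network, write_network
from cortexseek.symbols import GeneList

ensure_inputs()
truth = json.loads((INPUT_DIR / "ground_truth.json").read_text())
query = GeneList("mouse_vz_module", truth["mouse_planted"], species="mouse")
networks = {p.stem: read_network(p) for p in sorted((INPUT_DIR / "networks").glob("*.graphml"))}

extended = extend_list(networks, query, PipelineConfig())
write_network(extended.graph, RESULTS_DIR / "mouse_extended_network.sif", fmt="sif")

tier = set(truth["associated_tier"])
print(f"evidence channels: {', '.join(networks)}")
print(f"extended network: {len(extended)} nodes "
      f"({len(extended.query)} query + {len(extended.associated)} associated)")
print(f"associated tier recovered: {len(set(extended.associated) & tier)}/{len(tier)}")
print(f"wrote {RESULTS_DIR / 'mouse_extended_network.sif'}")
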