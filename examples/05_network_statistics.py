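"""Tripartite network topology statistics of a metabolic model.

Builds the metabolite-reaction-gene graph of the toy core model and prints
the degree/distance statistics a network analyzer would report.
"""

from dataclasses import asdict

import gsmm
from gsmm.netstats import build_model_graph, graph_statistics

model, _ = gsmm.make_toy_core_model()
graph = build_model_graph(model)
print(f"nodes = metabolites + reactions + genes = "
      f"{len(model.metabolites)} + {len(model.reactions)} + "
      f"{len(model.genes)} = {graph.number_of_nodes()}")

rep = graph_statistics(graph)
for key, value in asdict(rep).items():
    print(f"{key}: {value}")
# diameter/radius/path length are over the largest connected component;
# density = 2E/N(N-1); centralization is Freeman degree centralization
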