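"""First/second-degree protein-interaction association with prior SCAD genes.

Builds a small confidence-weighted interaction network and asks, for each
query gene, the shortest-path degree (capped at 2) to the previously
implicated SCAD gene set using only high-confidence (>= 0.7) edges. A
degree of 1 is a direct interaction; 2 is via one intermediate protein;
None means no high-confidence association within two steps.
"""

from famscad.prioritization import (
    PRIOR_SCAD_GENES,
    InteractionNetwork,
    network_degree,
)

net = InteractionNetwork(
    [
        ("IQGAP1", "TLN1", 0.92),   # direct, high confidence
        ("COL3A1", "FBN1", 0.85),
        ("LRP2", "LRP1", 0.55),     # below threshold: ignored
        ("LRP2", "APOE", 0.80),
        ("APOE", "LRP1", 0.88),     # LRP2 -> APOE -> LRP1: degree 2
        ("CDH4", "CDH2", 0.90),     # no seed within two steps
    ]
)

seeds = set(PRIOR_SCAD_GENES)
for gene in ("IQGAP1", "COL3A1", "LRP2", "CDH4"):
    degree = network_degree(net, gene, seeds, conf_min=0.7, max_degree=2)
    print(f"{gene:8s} -> degree {degree}")
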