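"""Multivariate transfer-entropy network inference with known ground truth.

Simulates 10 sparsely firing neurons wired by a random acyclic coupling
graph (2 parents per neuron, transmission 0.6), infers the effective
network with the two-stage mTE procedure, and scores the recovered edges
against the generator's ledger. Precision and recall near 1 mean the
inferred edges are the true couplings at their true lags.
"""

from spikedyn import NetworkConfig, infer_network, network_metrics
from spikedyn.synthetic import (
    GeneratorConfig,
    gen_coupled_raster,
    random_dag,
    score_edge_recovery,
)

edges = random_dag(10, parents_per_target=2, transmission=0.6, seed=1)
cfg = GeneratorConfig(
    n_neurons=10, duration_ms=200_000, base_rate=10.0, coupling_graph=edges, seed=2
)
raster, true_edges = gen_coupled_raster(cfg)
print(f"raster: {raster.n_neurons} neurons x {raster.n_bins} one-ms bins, "
      f"occupancy {raster.matrix.mean():.3%}")

net = infer_network(raster, NetworkConfig(seed=3))
score = score_edge_recovery(
    [(f"n{e.source}", f"n{e.target}") for e in true_edges],
    [(e.source, e.target) for e in net.edges],
)
print(f"true edges {score['n_true']}, inferred {score['n_inferred']}, "
      f"precision {score['precision']:.2f}, recall {score['recall']:.2f}")

print("\nper-edge conditional TE (bits), normalized by target entropy:")
print(net.edge_table().round(4).to_string(index=False))

print("\nper-node metrics (in-degree, total inflow, directed clustering):")
print(network_metrics(net).round(4).to_string(index=False))
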