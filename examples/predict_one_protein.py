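"""Iterative function prediction for a single protein.

Generates a synthetic homophilous PPI network with annotated proteins,
hides one protein's annotations, and predicts them with the iterative
cosine predictor, showing the per-round trajectory.
"""

from ppigo import (
    SynthConfig,
    generate_annotated_network,
    generate_ontology,
    predict_cia,
)

cfg = SynthConfig(seed=7)
onto = generate_ontology(cfg)
network, annotations = generate_annotated_network(cfg, onto)

target = "P0001"
true_terms = annotations[target]
result = predict_cia(target, network, annotations.without([target]), onto)

print(f"network: {len(network)} proteins, {network.n_edges} interactions, "
      f"{len(onto)} ontology terms")
print(f"target {target}: {network.degree(target)} neighbours, "
      f"true annotations {sorted(true_terms)}")
print()
print(f"initial (threshold-selected) set: {sorted(result.initial_set)}")
for i, step in enumerate(result.trajectory[1:], start=1):
    print(f"after round {i}: {sorted(step)}")
print()
print(f"predicted (rank order): {result.predicted}")
print(f"converged after {result.iterations} scoring rounds: "
      f"{result.converged}")
hits = set(result.predicted) & true_terms
print(f"{len(hits)} of {len(result.predicted)} predictions are exactly "
      f"correct: {sorted(hits)}")
print()
print("The trajectory shows the fixed-point behaviour: the predicted set")
print("stops changing once the protein similarities it induces reproduce")
print("the same top-k selection, typically within two or three rounds.")
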