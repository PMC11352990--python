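"""Recovery benchmark: classification plus affected-node retrieval.

Generates a cohort with five perturbed nodes, runs the pipeline, and
compares the nodes called significant (p_FDR < 0.05) against the
generator's ground truth.
"""

import json

from cdonbd import SyntheticSpec, run_synthetic_benchmark
from cdonbd.pipeline import scaled_config

spec = SyntheticSpec(
    n_nodes=30,
    subjects_per_group=20,
    affected_nodes=(0, 1, 2, 3, 4),
    delta=0.5,
    seed=0,
)
report = run_synthetic_benchmark(spec, scaled_config(spec.n_nodes, seed=0))

print("metrics:", json.dumps(report["metrics"]))
print("ground-truth affected nodes:", report["ground_truth"]["affected_nodes"])
print("significant nodes (vs healthy template):", report["significant_nodes"])
print(f"node recall: {report['node_recall']:.2f}  precision: {report['node_precision']:.2f}")
print(
    "Classification is near-perfect; node-level recovery is partial —\n"
    "the diffusion embedding spreads a local perturbation into every\n"
    "node's walk context (see docs/methods.md for the analysis)."
)
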