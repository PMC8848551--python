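"""Draw a random Bayesian network and sample a synthetic dataset from it.

Builds an 8-node tertiary network with per-edge wiring probability 0.8 and
flat-Dirichlet conditional tables, samples 10,000 rows by exact ancestral
sampling, and writes both artifacts to disk.
"""

import numpy as np

import bnforge as bf

rng = np.random.default_rng(0)
model = bf.random_model(8, 3, bf.DensitySpec("prob", p=0.8), alpha=1.0, rng=rng)
print(f"structure: {model.n_nodes} nodes, {model.structure.density} edges")
print(f"roots: {[model.labels[v] for v in model.structure.roots()]}")
print(f"joint event space: {model.n_joint_events()} events")

dataset = bf.sample_dataset(model, 10_000, seed=1)
print(f"sampled {dataset.n_rows} rows; first row: {dataset.values[0].tolist()}")

bf.write_model(model, "scratch_model.json")
bf.write_dataset(dataset, "scratch_data.csv")
print("wrote scratch_model.json and scratch_data.csv")
# The row lists one 0-based state per node in model order; re-running with
# the same seeds reproduces both files byte-for-byte.
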