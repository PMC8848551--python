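"""Distributional diagnostics: entropy drift and how much data is enough.

Naive flat-Dirichlet table construction biases descendant-node marginals
toward the maximum-entropy center of the simplex; and the analytic joint
lets you size a dataset so empirical event counts stay close to their
expectations.
"""

import numpy as np

import bnforge as bf

rng = np.random.default_rng(0)

# 1. the induced-marginal law for a binary child of a binary ancestor:
#    density 2*H(z), peaked at 1/2 — confirmed by simulation
rep = bf.prop1_simulation(100_000, rng)
print(f"KS distance to the 2H(z) law: {rep.ks_statistic:.4f} "
      f"(mean {rep.sample_mean:.3f}, expected 0.5)")

# 2. entropy drift across whole networks: terminal marginals carry more
#    entropy than root marginals (1000 random 8-node tertiary networks)
bias = bf.fig1_replication(1_000, rng)
print(f"mean root entropy     {bias.mean_entropy_root:.3f} nats")
print(f"mean terminal entropy {bias.mean_entropy_terminal:.3f} nats "
      f"(max possible ln 3 = {np.log(3):.3f})")

# 3. sample-size criterion: N such that every joint-event count stays
#    within 2% of its expectation with probability 0.95
model = bf.random_model(4, 2, bf.DensitySpec("prob", p=0.5), 1.0, rng)
p = bf.enumerate_joint(model)
n_needed = bf.required_sample_size(p, delta=0.02, eps=0.05, rng=rng)
print(f"rows needed for 2%-accurate counts over {p.n_events} events: {n_needed}")
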