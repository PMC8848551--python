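"""Local inference through a node's Markov blanket.

The blanket (immediate ancestors, immediate descendants, and the
descendants' other ancestors) screens the center node off from the rest of
the network, so conditionals can be computed from a handful of local
factors instead of the full joint.
"""

import numpy as np

import bnforge as bf

rng = np.random.default_rng(11)
model = bf.random_model(6, 3, bf.DensitySpec("prob", p=0.5), 1.0, rng)

center = 2
b = bf.blanket(model, center)
print(f"blanket of {model.labels[center]}:")
print(f"  ancestors    {[model.labels[v] for v in b.ancestors]}")
print(f"  descendants  {[model.labels[v] for v in b.descendants]}")
print(f"  co-ancestors {[model.labels[v] for v in b.co_ancestors]}")

periphery = {v: 0 for v in b.periphery}
cond = bf.center_conditional(model, center, periphery)
print(f"P({model.labels[center]} | periphery all 0) = {np.round(cond, 4)}")

# Bayes-invert: which ancestor state best explains the center being in
# state 1, holding the rest of the periphery fixed?
if b.ancestors:
    target = b.ancestors[0]
    rest = {v: 0 for v in b.periphery if v != target}
    post = bf.periphery_inference(model, center, 1, target, rest)
    print(f"P({model.labels[target]} | {model.labels[center]}=1, rest=0) = "
          f"{np.round(post, 4)}")

# cross-check against the exhaustive joint: the Markov property says the
# blanket conditional equals conditioning on *all* other variables
jt = bf.enumerate_joint(model)
full = jt.probs.reshape(jt.arities)
event = np.zeros(model.n_nodes, dtype=int)
idx = tuple(event[v] if v != center else slice(None) for v in range(model.n_nodes))
brute = full[idx] / full[idx].sum()
print(f"brute-force conditional at the same event: {np.round(brute, 4)}")
print(f"max abs difference: {np.abs(cond - brute).max():.2e}")
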