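"""Guaranteeing and controlling conditional dependence in a table.

A conditional table encodes dependence iff its rank is at least two, and
its structurally dependent ancestor events are the vertices of the convex
hull of its columns.  ``n_vertex_columns`` pins the number of vertices.
"""

import numpy as np

import bnforge as bf

rng = np.random.default_rng(3)

# default: every column an independent flat-Dirichlet draw
table = bf.build_cpt(3, (2, 2), alpha=1.0, rng=rng)
print(f"table: {table.child_arity} states x {table.n_events} ancestor events")
print(f"dependent (rank >= 2): {bf.is_dependent(table)}")
print(f"hull vertices (structurally dependent events): {sorted(bf.hull_vertices(table))}")

# the rank criterion agrees with the event-wise definition of dependence
prior = rng.dirichlet(np.ones(4))
print(f"event-wise criterion under a random prior: {bf.dependence_oracle(table, prior)}")

# vertex control: only 2 of the 4 ancestor events are structurally dependent
pinned = bf.build_cpt(3, (2, 2), alpha=1.0, rng=rng, n_vertex_columns=2)
print(f"with n_vertex_columns=2: vertices = {sorted(bf.hull_vertices(pinned))}")
# the induced child marginal always lies inside the hull of the columns
print(f"induced marginal: {np.round(bf.induced_marginal(pinned, prior), 4)}")
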