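# bnforge

Fully probabilistic synthetic-data generation for discrete Bayesian
networks — for benchmarking network-inference methods in computational and
systems biology.

Evaluating a Bayesian-network (BN) structure-learning algorithm requires
datasets whose generating model is known exactly. `bnforge` produces such
ground truth end to end, with every step defined probabilistically rather
than by ad-hoc rules:

- **Random structures.** A DAG on `n` ordered nodes is a subset of the
  `D = n(n−1)/2` forward edges, so acyclicity is structural. Sampling modes:
  uniform over all `2^D` structures, uniform within a fixed edge count `d`
  (a `C(D, d)` stratum), or independent per-edge inclusion with probability
  `p`. The density distribution `P(δ(G)=d) = C(D,d)/2^D` is exposed exactly
  in arbitrary-precision arithmetic.
- **Dependence-guaranteed tables.** The conditional distribution of an
  `n`-state child given `m` ancestor joint events is an `n × m`
  column-stochastic matrix `D` with columns on the probability simplex,
  sampled from a Dirichlet. The child depends on its ancestors **iff**
  `rank(D) ≥ 2`, and the ancestor events that are dependent under *every*
  full-support prior are exactly the vertices of the convex hull of the
  columns — both criteria are implemented, and the number of hull vertices
  can be pinned at construction.
- **Exact sampling and exact joints.** Datasets are drawn by ancestral
  sampling (`P(X = x* | Y = y*)` column lookups in topological order); the
  analytic joint `P(∩ᵢ Xᵢ) = Πᵢ P(Xᵢ | parents(Xᵢ))` is enumerated exactly
  at desk scale (8 tertiary nodes ⇒ 3⁸ = 6561 events).
- **Markov-blanket inference.** `P(X | M−X)` and periphery posteriors from
  the factored blanket joint
  `P(M) = P(a(X) ∪ ad(X)) · P(X|a(X)) · Π P(Yᵢ|a(Yᵢ))`.
- **Distributional diagnostics.** The induced-marginal law
  `f(z) = 2H(z)` for naive Dirichlet construction, the `β(1, m−1)` column
  moments, the central-limit drift of descendant marginals toward maximum
  entropy, Jensen–Shannon divergence (JSD) between empirical and analytic
  joints, and a multinomial sample-size criterion
  `P(maxᵢ |Npᵢ − xᵢ| > δ) < ε`.

## Worked example

```python
import numpy as np
import bnforge as bf

rng = np.random.default_rng(0)
model = bf.random_model(8, 3, bf.DensitySpec("prob", p=0.8), alpha=1.0, rng=rng)
data  = bf.sample_dataset(model, 10_000, seed=1)

analytic  = bf.enumerate_joint(model)
empirical = bf.empirical_joint(data, model)
print(analytic.n_events, round(bf.jsd(empirical, analytic), 4))
```

prints `6561 0.0714`: the model's joint event space has 6561 events, and at
10,000 rows the sampled distribution is still 0.07 bits of JSD away from
the analytic one (it falls to 0.0012 bits at a million rows — event spaces
are easy to under-sample). The diagnostics make the construction's biases
visible:

```python
rep = bf.prop1_simulation(100_000, rng)       # induced-marginal law
bias = bf.fig1_replication(1_000, rng)        # entropy drift across networks
print(round(rep.ks_statistic, 4))
print(round(bias.mean_entropy_root, 3), round(bias.mean_entropy_terminal, 3))
```

prints `0.0031` (the simulated induced marginal matches the 2H(z) density
to KS distance 0.003) and `0.832 1.094`: terminal-node marginals sit near
the maximum-entropy value ln 3 ≈ 1.099 nats while root marginals average
0.832 — descendant distributions are *not* uniform on the simplex under
naive Dirichlet construction.

The `examples/` scripts walk each capability; the `bnforge` CLI
(`generate-model`, `sample`, `analyze`, `blanket`, `diagnose`) wraps the
same functions for shell pipelines, with `--seed` everywhere and
byte-reproducible outputs.

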