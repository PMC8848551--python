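# Methods

## The model

A discrete Bayesian network over nodes `X₁ … Xₙ` is specified by (i) a DAG
and (ii), for each node, a conditional probability table over its immediate
ancestors. The joint factorises as
`P(∩ᵢ Xᵢ) = Πᵢ P(Xᵢ | a(Xᵢ))`, where `a(·)` denotes the immediate-ancestor
set. Everything in the package is exact with respect to this
factorisation: sampling is ancestral (no MCMC), joints and marginals are
enumerated or propagated analytically, and conditionals are ratios of
exact quantities. The package assumes purely discrete variables with
arity ≥ 2; mixed continuous/discrete models are out of scope.

## Random structures

Structures are generated as subsets of the upper triangle of an adjacency
matrix under the identity topological ordering, which makes acyclicity a
construction invariant rather than a post-hoc check. A random label
permutation can be applied afterwards (`permute_labels`, off by default so
repeated runs are directly comparable node-by-node).

Three density modes:

- `uniform` — every edge independently with probability ½, so each of the
  `2^D` structures (`D = n(n−1)/2`) is equiprobable and the realised edge
  count follows `C(D, d)/2^D`;
- `fixed` — exactly `d` edges, uniform over the `C(D, d)` stratum;
- `prob` — every edge independently with probability `p`.

Counts use Python integers throughout (`C(120, 60) ≈ 9.7 × 10³⁴` overflows
any fixed width). We deliberately do **not** offer forced uniform sampling
across density strata: the stratum sizes differ by ~34 orders of magnitude
at `n = 16`, so equalising sampling error across strata is computationally
out of reach; `fixed` mode plus the exact density pmf is the supported way
to study density effects. "Average edge density 0.8" for the 8-node
reference experiments is interpreted as per-edge probability `p = 0.8`.

## Conditional tables and dependence

A table is an `n × m` column-stochastic matrix (child arity `n`, ancestor
joint events `m`; `m = 1` for roots). Ancestor joint events are encoded
mixed-radix with the first ancestor (by topological position) most
significant; the encoding is bijective and documented so datasets, joints
and tables all agree on event indices.

Columns are sampled `Dirichlet(α)`; `α = 1` (the default) is uniform on
the simplex. Key facts the implementation exposes and tests:

- dependence ⇔ `rank(D) ≥ 2`. Numerical rank uses the standard cutoff
  `max(n, m) · eps · σ_max`. The event-wise criterion
  (`∃ yᵢ : D·eᵢ ≠ D·P(Y)` under a full-support prior) is kept as an
  independent brute-force oracle, never as the implementation.
- the induced marginal `D · P(Y)` lies in the convex hull of the columns;
  the columns that are vertices of that hull are the ancestor events that
  remain dependent under *every* full-support prior ("structurally
  dependent"). A non-vertex column can still differ from the induced
  marginal under a particular prior; we reserve the vertex ⇔ dependent
  identification for the structural notion and treat the rank-1
  (single-point-hull) case as having zero dependent events.
- vertex tests are per-column linear programs (`min t` s.t. the column is
  within `t` of a convex combination of the other distinct columns,
  declared interior when `t ≤ 1e−9`), solved with HiGHS. Duplicate columns
  are collapsed before testing — two identical columns are mutually
  representable and would otherwise both fail a strict test — and all
  duplicates of a vertex representative are reported as vertices.
- `build_cpt(n_vertex_columns=k)` draws `k` independent columns and fills
  the rest with flat-Dirichlet convex combinations of them, capping the
  number of structurally dependent events at `k` (`k ≥ 2`, since a
  dependent table's hull has at least two vertices). Built tables with
  `m ≥ 2` are verified `rank ≥ 2`; coincidentally degenerate draws — a
  probability-zero event in exact arithmetic — are resampled up to 100
  times before a hard error.

Tables are defined independently of any ancestor prior (the ratio
definition of conditional probability fails on zero-probability events),
so every column exists even for unreachable ancestor events; no
special-casing.

## Sampling

One uniform variate per (row, node) cell, inverse-CDF over the selected
column with state 0 first. `sample_dataset` draws the `(N, n)` variate
block in C order, which consumes the generator stream identically to `N`
sequential `sample_row` calls; the two paths are interchangeable under a
shared seed (tested), and the dataset path is vectorised per node. A
single generator stream serves the whole dataset — a simpler
reproducibility contract than per-node streams.

## Joints, divergence, sample size

`enumerate_joint` computes all `Π arityᵢ` event probabilities (cap 10⁷,
explicit error above it — approximating silently would change the
framework's exactness semantics). `ancestral_marginal` gives exact
marginals over any node subset by enumerating only the subset's ancestral
closure; it doubles as an independent route for testing full-joint
marginalisation.

JSD is reported in bits (base 2, bounded by 1; the base is configurable —
it rescales values but never reorders them). `0·log 0 = 0`.

`required_sample_size` searches (doubling, then bisection, integer grid)
for the least `N` with `P(maxᵢ |Npᵢ − xᵢ| > δ) < ε`, estimating the
exceedance probability either by Monte-Carlo multinomial replication
(seeded, default 400 replicates) or by a per-event binomial-tail union
bound (conservative). The default `delta_mode="fraction"` reads δ as a
fraction of `N`: with an absolute count tolerance the criterion is
non-monotone in `N` (count deviations grow like √N) and generally
unattainable, so the absolute mode exists but raises a typed
bound-not-attained error at its cap.

## Markov blankets

`M = {X} ∪ a(X) ∪ d(X) ∪ ad(X)` with `ad(X) = a(d(X)) − X − a(X) − d(X)`.
The blanket joint is evaluated as

```
P(M) = P(a(X) ∪ ad(X)) · P(X | a(X)) · Π_{Y ∈ d(X)} P(Y | a(Y))
```

where the upstream block is computed exactly over its ancestral closure.
Grouping the co-ancestors into one joint factor (rather than a product of
per-node factors) keeps the expression exact when co-ancestors share
out-of-blanket ancestors. The one structure it cannot absorb is a
co-ancestor that is itself a deeper descendant of `X` (e.g.
`X→Y₁→Z→Y₂←X`): no upstream/downstream split represents that cycle of
influence, and there the factored `P(M)` may deviate from the true blanket
marginal. Center conditionals are unaffected — the upstream block does not
depend on the center's state and cancels in
`P(X|M−X) = P(X, M−X)/Σⱼ P(xⱼ, M−X)` — which the tests confirm against
brute-force full-joint conditionals on unscreened random models.

Zero-probability periphery assignments raise a typed error rather than
returning NaN or a uniform vector; silent imputation would mask model
defects.

## Diagnostics

- `prop1_simulation`: `z = tp + (1−t)q` with `t, p, q ~ U(0,1)` against
  the closed-form density `f(z) = 2(−z ln z − (1−z) ln(1−z))` and its
  antiderivative CDF (Kolmogorov–Smirnov).
- `beta_column_moments`: flat-Dirichlet component moments `1/m` and
  `(m−1)/(m²(m+1))`.
- `clt_experiment`: the induced component `z₁ = Σⱼ d₁ⱼ tⱼ` recovers mean
  `1/m`, its variance shrinks as the number of ancestor events grows, and
  it drifts toward normality. We test mean recovery, variance shrinkage
  and qualitative normality only — the limiting variance constant depends
  on conditions of the underlying weighted-sum CLT that we do not
  re-derive.
- `fig1_replication`: per replicate, a fresh 8-node tertiary structure
  (per-edge `p = 0.8`, the density of the companion convergence
  experiment; a fixed structure can be passed instead), flat-Dirichlet
  tables, exact marginal propagation, recording the first root's and last
  terminal's marginals. Terminal entropies stochastically dominate root
  entropies (Mann–Whitney). Root-cloud components follow the flat-Dirichlet
  component marginal `β(1, arity−1)` — uniform only in the binary case.

Entropies are natural-log to match the density derivation; bits are a flag
away.

## What the generator does and does not emulate

Defaults reproduce the reference study conditions: 8 tertiary nodes,
per-edge density 0.8, `α = 1` everywhere, sample sizes 10², 10⁴, 10⁶ for
convergence runs, and 10⁴ replicates for the entropy-bias experiment.
These are synthetic ideal conditions: variables are purely categorical,
tables are drawn independently of one another, and no measurement noise,
missingness, selection bias, or real-biology arity/effect-size structure
is modelled. Passing diagnostics therefore validate the *mechanics* of
generation and inference, not fidelity to any particular biological
dataset. The known entropy drift of descendant marginals is a property of
naive `α = 1` construction that the package measures and reports; it
deliberately prescribes no corrective concentration schedule (α is fully
exposed).

## Numerical choices and problem sizes

- Simplex/column normalisation tolerance 1e−12 at construction; serialized
  models re-validated on read (1e−9) with errors naming the offending node.
- Rank cutoff `max(n, m)·eps·σ_max`; LP vertex tolerance 1e−9; joint
  normalisation asserted to 1e−10; blanket-vs-brute agreement asserted to
  1e−10.
- JSON floats use shortest-repr encoding, so write → read → write is
  byte-stable; datasets are plain CSV with 0-based integer states.
- Test-suite problem sizes are chosen to keep the default run fast while
  leaving the headline checks at full strength: unit sweeps use 2–3 × 10⁴
  structure draws for the chi-square uniformity checks and 200-instance
  oracle sweeps, while the end-to-end suite runs the full-size versions
  (10³ tables × 10 priors, 100 models for the blanket oracle, 20 replicas
  at N up to 10⁶, 10⁴ entropy-bias replicates, 10⁵-draw KS fits).

## Known limitations

- Exact enumeration caps the tractable joint event space (default 10⁷);
  no variable-elimination fallback is provided, by design.
- The factored blanket joint is exact only under the structural condition
  above (`is_locally_factorable`); center conditionals are always exact.
- Fixed-density sampling is uniform *within* a stratum; sampling uniformly
  across strata at scale is intentionally unsupported.
- `α` schedules that would counteract the entropy drift are left to the
  user.
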