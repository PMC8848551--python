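"""Distributional limits of naively Dirichlet-built networks.

Sampling every conditional-table column uniformly from the simplex does not
produce uniformly distributed *descendant* marginals.  For a binary child of
a binary ancestor the induced marginal component ``z = t*p + (1-t)*q`` (with
``t``, ``p``, ``q`` independent uniform) has density ``f(z) = 2*H(z)`` —
twice the binary entropy, peaked at 1/2.  As the number of ancestor joint
events grows, the induced component is a randomly weighted mean of many
flat-Dirichlet components (each ``beta(1, m-1)`` with mean ``1/m`` and
variance ``(m-1)/(m^2 (m+1))``) and drifts toward a concentrated,
asymptotically normal law: descendant nodes are biased toward the
maximum-entropy centre of the simplex.  The experiments here make that bias
executable and measurable.

Entropies are in nats (natural log) throughout, matching the density
derivation; pass ``base=2`` where offered to report bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .cpt import build_cpt
from .errors import InvalidArgumentError
from .graphs import DagStructure, DensitySpec, sample_dag
from .joint import ancestral_marginal

__all__ = [
    "entropy_density",
    "entropy_density_cdf",
    "prop1_simulation",
    "beta_column_moments",
    "clt_experiment",
    "fig1_replication",
    "EntropyBiasReport",
]


def entropy_density(z):
    """Density of the induced binary marginal component: ``2*H(z)`` in nats.

    ``H`` is the binary entropy; the density is symmetric about 1/2,
    maximal there (``2 ln 2``), and integrates to one over (0, 1).
    Defined on the open interval; extended by continuity to 0 at the
    endpoints, which are rejected as arguments.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0.0) or np.any(z >= 1.0):
        raise InvalidArgumentError("z must lie strictly inside (0, 1)")
    val = 2.0 * (-z * np.log(z) - (1.0 - z) * np.log(1.0 - z))
    return float(val) if val.ndim == 0 else val


def entropy_density_cdf(z):
    """Closed-form CDF of :func:`entropy_density` (antiderivative of 2H)."""
    z = np.asarray(z, dtype=float)
    z = np.clip(z, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(z > 0.0, -(z**2) * np.log(z), 0.0)
        t2 = np.where(z < 1.0, (1.0 - z) ** 2 * np.log(1.0 - z), 0.0)
    val = t1 + 0.5 * z**2 + t2 - 0.5 * (1.0 - z) ** 2 + 0.5
    val = np.clip(val, 0.0, 1.0)
    return float(val) if val.ndim == 0 else val


@dataclass(frozen=True)
class GofReport:
    """Goodness-of-fit summary of simulated draws against a reference law."""

    n_draws: int
    ks_statistic: float
    ks_pvalue: float
    sample_mean: float
    sample_variance: float


def prop1_simulation(n_draws: int, rng: np.random.Generator) -> GofReport:
    """Simulate ``z = t*p + (1-t)*q`` and test it against the 2H(z) law.

    ``t``, ``p``, ``q`` are the first components of independent flat draws
    on the 1-simplex, i.e. independent Uniform(0, 1).  Reports the
    Kolmogorov-Smirnov statistic against the closed-form CDF.
    """
    if n_draws < 10**4:
        raise InvalidArgumentError(
            "n_draws must be >= 1e4 for a meaningful fit"
        )
    t = rng.random(n_draws)
    p = rng.random(n_draws)
    q = rng.random(n_draws)
    z = t * p + (1.0 - t) * q
    ks = stats.kstest(z, entropy_density_cdf)
    return GofReport(
        n_draws=n_draws,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        sample_mean=float(z.mean()),
        sample_variance=float(z.var(ddof=1)),
    )


def check_density_normalization() -> float:
    """Quadrature of the entropy density over (0, 1); must be 1."""
    val, _ = integrate.quad(lambda u: entropy_density(u), 0.0, 1.0)
    return float(val)


def beta_column_moments(m: int) -> tuple[float, float]:
    """Mean and variance of one component of a flat Dirichlet on the
    ``(m-1)``-simplex: ``beta(1, m-1)`` moments ``1/m`` and
    ``(m-1)/(m^2 (m+1))``."""
    if m < 2:
        raise InvalidArgumentError("m must be >= 2")
    return 1.0 / m, (m - 1) / (m**2 * (m + 1))


@dataclass(frozen=True)
class CltReport:
    """Summary of the weighted-column-mean drift experiment."""

    m: int
    n: int
    n_reps: int
    sample_mean: float
    sample_variance: float
    normality_statistic: float
    normality_pvalue: float
    samples: np.ndarray = field(repr=False)


def clt_experiment(
    m: int, n: int, n_reps: int, rng: np.random.Generator
) -> CltReport:
    """Drift of an induced marginal component toward normality.

    Each replicate draws an ``m x n`` matrix of flat-Dirichlet columns and a
    flat-Dirichlet weight vector ``t`` of length ``n`` and records the first
    component of the induced marginal ``D @ t``.  Reports mean, variance and
    an omnibus normality statistic of the standardized values; the mean
    recovers ``1/m`` and the variance shrinks as ``n`` grows.
    """
    if m < 2 or n < 2:
        raise InvalidArgumentError("m and n must be >= 2")
    if n_reps < 2:
        raise InvalidArgumentError("n_reps must be >= 2")
    d_first = rng.dirichlet(np.ones(m), size=(n_reps, n))[:, :, 0]
    t = rng.dirichlet(np.ones(n), size=n_reps)
    z1 = np.einsum("rn,rn->r", d_first, t)
    standardized = (z1 - z1.mean()) / z1.std(ddof=1)
    nt = stats.normaltest(standardized)
    return CltReport(
        m=m,
        n=n,
        n_reps=n_reps,
        sample_mean=float(z1.mean()),
        sample_variance=float(z1.var(ddof=1)),
        normality_statistic=float(nt.statistic),
        normality_pvalue=float(nt.pvalue),
        samples=z1,
    )


@dataclass(frozen=True)
class EntropyBiasReport:
    """Root vs terminal marginal clouds from repeated random networks."""

    root_samples: np.ndarray
    terminal_samples: np.ndarray
    mean_entropy_root: float
    mean_entropy_terminal: float
    n_reps: int
    seed: int | None = None

    def mannwhitney_pvalue(self) -> float:
        """One-sided test that terminal entropies exceed root entropies."""
        root_h = stats.entropy(self.root_samples, axis=1)
        term_h = stats.entropy(self.terminal_samples, axis=1)
        return float(
            stats.mannwhitneyu(term_h, root_h, alternative="greater").pvalue
        )


def fig1_replication(
    n_reps: int,
    rng: np.random.Generator,
    *,
    n_nodes: int = 8,
    arity: int = 3,
    edge_p: float = 0.8,
    structure: DagStructure | None = None,
) -> EntropyBiasReport:
    """Entropy bias of terminal nodes in random tertiary networks.

    Each replicate draws a fresh random structure (per-edge probability
    ``edge_p``; pass ``structure`` to hold it fixed), fills every table with
    flat-Dirichlet columns, propagates exact marginals from the roots, and
    records the first root's and the last terminal's marginal.  The
    terminal cloud concentrates near the maximum-entropy centre of the
    simplex while the root cloud stays flat-Dirichlet distributed.
    """
    if n_reps < 10**3:
        raise InvalidArgumentError("n_reps must be >= 1e3")
    from .cpt import BayesNetModel

    spec = DensitySpec(mode="prob", p=edge_p)
    roots = np.empty((n_reps, arity))
    terminals = np.empty((n_reps, arity))
    for r in range(n_reps):
        dag = structure if structure is not None else sample_dag(n_nodes, spec, rng)
        tables = tuple(
            build_cpt(
                arity, tuple(arity for _ in dag.parents(v)), 1.0, rng
            )
            for v in range(n_nodes)
        )
        model = BayesNetModel(
            structure=dag, arities=(arity,) * n_nodes, tables=tables
        )
        root = dag.order[0]
        terminal = dag.order[-1]
        roots[r] = model.tables[root].columns[:, 0]
        _, terminals[r] = ancestral_marginal(model, [terminal])
    return EntropyBiasReport(
        root_samples=roots,
        terminal_samples=terminals,
        mean_entropy_root=float(stats.entropy(roots, axis=1).mean()),
        mean_entropy_terminal=float(stats.entropy(terminals, axis=1).mean()),
        n_reps=n_reps,
    )
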