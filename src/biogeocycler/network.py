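"""Compositional (SparCC-style) co-occurrence networks at genus level.

Sequencing counts are compositional: per-sample totals are arbitrary, so
Pearson correlations of relative abundances are spurious. The basis
(absolute-abundance) correlation is instead inferred from log-ratio variances

    t_ij = Var[ log(x_i / x_j) ] = w_i^2 + w_j^2 - 2 rho_ij w_i w_j,

where ``w_i^2`` are basis log-variances. Under sparsity (most rho ~ 0) the
row sums of ``t`` give a linear system for ``w^2``; strongly correlated pairs
are then iteratively excluded from the system and it is re-solved. Edge
significance comes from permutation: shuffling each taxon's counts across
samples destroys co-variation while preserving marginals.

Edges are kept at the strict thresholds |rho| > 0.65 and p < 0.01 (raw,
unadjusted p-values; an optional Benjamini-Hochberg flag exists but is off).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import CorrelationNetwork, OtuTable, ValidationError, lineage_rank

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Genus aggregation
# ---------------------------------------------------------------------------

def aggregate_rank(table: OtuTable, rank: str = "genus",
                   min_prevalence: int = 3) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse OTU counts to a rank and drop rare/unclassified taxa.

    Returns (samples x taxa counts, taxon -> phylum). Taxa present in fewer
    than ``min_prevalence`` samples are dropped (and logged): with a handful
    of samples their log-ratio variances are meaningless. Unclassified taxa
    at the rank are dropped too — they are mixtures, not units.
    """
    taxa = table.lineage.map(lambda l: lineage_rank(l, rank))
    phyla = table.lineage.map(lambda l: lineage_rank(l, "phylum"))
    counts = table.counts.T.groupby(taxa.values).sum().T
    phylum_of = {t: phyla[taxa == t].iloc[0] for t in counts.columns}
    if "unclassified" in counts.columns:
        counts = counts.drop(columns=["unclassified"])
    prevalence = (counts > 0).sum(axis=0)
    rare = prevalence.index[prevalence < min_prevalence]
    for taxon in rare:
        logger.info("dropping %s (present in %d samples)", taxon,
                    prevalence[taxon])
    counts = counts.drop(columns=list(rare))
    return counts, pd.Series(phylum_of).reindex(counts.columns)


# ---------------------------------------------------------------------------
# Log-ratio variances
# ---------------------------------------------------------------------------

def _fractions(counts: np.ndarray, pseudocount: float, n_draws: int,
               rng: np.random.Generator) -> np.ndarray:
    """Per-sample fraction estimates: Dirichlet draws averaged, or the
    posterior mean when ``n_draws`` is 0."""
    alpha = counts + pseudocount
    if n_draws <= 0:
        return alpha / alpha.sum(axis=1, keepdims=True)
    acc = np.zeros_like(alpha, dtype=float)
    for _ in range(n_draws):
        g = rng.standard_gamma(alpha)
        acc += g / g.sum(axis=1, keepdims=True)
    return acc / n_draws


def log_ratio_variances(
    counts,
    pseudocount: float = 1.0,
    n_fraction_draws: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """The variation matrix t_ij = Var over samples of log(f_i/f_j).

    ``counts`` is a samples x taxa array or DataFrame. Fractions are estimated
    by averaging ``n_fraction_draws`` Dirichlet(counts + pseudocount) draws
    (0 draws = posterior mean, deterministic). By construction ``t`` is
    symmetric with a zero diagonal and invariant to per-sample rescaling of
    the counts.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2:
        raise ValidationError("counts must be 2-D (samples x taxa)")
    n, d = x.shape
    if n < 4:
        raise ValidationError(
            f"need >= 4 samples for log-ratio variances, got {n}"
        )
    if (x.sum(axis=0) == 0).any():
        raise ValidationError("taxa with zero total count must be removed first")
    rng = np.random.default_rng(seed)
    logf = np.log(_fractions(x, pseudocount, n_fraction_draws, rng))
    cov = np.cov(logf.T, ddof=1)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return t


# ---------------------------------------------------------------------------
# Basis correlation estimation
# ---------------------------------------------------------------------------

@dataclass
class BasisCorrelationEstimate:
    """Inferred basis correlations, basis variances and excluded pairs."""

    rho: np.ndarray
    omega2: np.ndarray
    excluded_pairs: list[tuple[int, int]] = field(default_factory=list)


def correlation_from_variances(t: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    """Invert t_ij = w_i^2 + w_j^2 - 2 rho_ij w_i w_j given basis variances.

    This is the exact algebraic core of the estimator: with the true basis
    variances it recovers the planted correlations to machine precision
    (including the 3-taxon case, where the sparsity-approximated solve is
    biased).
    """
    t = np.asarray(t, dtype=float)
    w2 = np.asarray(omega2, dtype=float)
    w = np.sqrt(w2)
    denom = 2.0 * np.outer(w, w)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, (w2[:, None] + w2[None, :] - t) / denom, 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _solve_basis_variances(t: np.ndarray,
                           excluded: set[tuple[int, int]]) -> np.ndarray:
    d = t.shape[0]
    m = np.ones((d, d)) + np.diag(np.full(d, d - 2.0))
    v = t.sum(axis=1).copy()
    for i, j in excluded:
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        v[i] -= t[i, j]
        v[j] -= t[i, j]
    w2 = np.linalg.solve(m, v)
    if (w2 <= 0).any():
        for i in np.where(w2 <= 0)[0]:
            positives = t[i][t[i] > 0]
            repl = positives.min() / 2.0 if positives.size else 1e-6
            logger.warning(
                "basis variance for taxon %d solved non-positive; set to %g",
                i, repl)
            w2[i] = repl
    return w2


def estimate_basis_correlations(
    t,
    exclusion_threshold: float = 0.1,
    max_exclusions: int | None = None,
) -> BasisCorrelationEstimate:
    """Solve the sparse-basis system for omega^2 and derive rho.

    After the initial solve, the strongest-|rho| pair above
    ``exclusion_threshold`` is excluded from the linear system and it is
    re-solved, repeating up to ``max_exclusions`` times (default D - 3).
    rho is clipped to [-1, 1] with a unit diagonal.
    """
    t = np.asarray(t, dtype=float)
    d = t.shape[0]
    if d < 3:
        raise ValidationError("need >= 3 taxa to solve the basis system")
    if max_exclusions is None:
        max_exclusions = max(0, d - 3)
    excluded: set[tuple[int, int]] = set()
    while True:
        w2 = _solve_basis_variances(t, excluded)
        rho = correlation_from_variances(t, w2)
        if len(excluded) >= max_exclusions:
            break
        masked = np.abs(rho.copy())
        np.fill_diagonal(masked, 0.0)
        for i, j in excluded:
            masked[i, j] = masked[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
    return BasisCorrelationEstimate(rho=rho, omega2=w2,
                                    excluded_pairs=sorted(excluded))


def sparcc_correlations(
    counts,
    pseudocount: float = 1.0,
    n_fraction_draws: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusions: int | None = None,
    seed: int = 0,
) -> BasisCorrelationEstimate:
    """Variation matrix + basis solve in one call (samples x taxa counts)."""
    t = log_ratio_variances(counts, pseudocount=pseudocount,
                            n_fraction_draws=n_fraction_draws, seed=seed)
    return estimate_basis_correlations(t, exclusion_threshold=exclusion_threshold,
                                       max_exclusions=max_exclusions)


# ---------------------------------------------------------------------------
# Permutation p-values
# ---------------------------------------------------------------------------

def permutation_pvalues(
    counts,
    rho_observed: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    pseudocount: float = 1.0,
    n_fraction_draws: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusions: int | None = None,
) -> np.ndarray:
    """Two-sided pseudo p-values from independent per-taxon shuffles.

    The null is built by shuffling each taxon's counts across samples
    independently and re-estimating the full basis correlation matrix each
    time; p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_permutations), so
    p is always in [1/(n+1), 1] and ties count against significance.
    """
    if n_permutations < 99:
        raise ValidationError("need at least 99 permutations")
    x = np.asarray(counts, dtype=float)
    n, d = x.shape
    rho_obs = np.abs(np.asarray(rho_observed, dtype=float))
    rng = np.random.default_rng(seed)
    exceed = np.zeros((d, d))
    for _ in range(n_permutations):
        perm = np.empty_like(x)
        for j in range(d):
            perm[:, j] = x[rng.permutation(n), j]
        t = log_ratio_variances(perm, pseudocount=pseudocount,
                                n_fraction_draws=n_fraction_draws,
                                seed=int(rng.integers(2 ** 31)))
        est = estimate_basis_correlations(
            t, exclusion_threshold=exclusion_threshold,
            max_exclusions=max_exclusions)
        exceed += np.abs(est.rho) >= rho_obs
    p = (1.0 + exceed) / (1.0 + n_permutations)
    np.fill_diagonal(p, 1.0)
    return p


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def build_network(
    rho,
    p,
    r_threshold: float = 0.65,
    p_threshold: float = 0.01,
    taxonomy: pd.Series | dict | None = None,
    labels: list | None = None,
    bh_adjust: bool = False,
) -> CorrelationNetwork:
    """Threshold correlations into an undirected genus co-occurrence network.

    An edge requires |rho| STRICTLY above ``r_threshold`` and p STRICTLY
    below ``p_threshold`` (so rho = 0.65 exactly is excluded). Isolated
    genera are dropped; node degree is the incident edge count and edge sign
    follows the sign of rho. ``bh_adjust`` applies Benjamini-Hochberg to the
    p-values first (off by default: the emulated workflow thresholds raw p).
    """
    rho = np.asarray(rho, dtype=float)
    p = np.asarray(p, dtype=float)
    if rho.shape != p.shape:
        raise ValidationError("rho and p matrices are not conformable")
    if not 0 < r_threshold < 1:
        raise ValidationError(f"r_threshold outside (0, 1): {r_threshold}")
    if not 0 < p_threshold <= 1:
        raise ValidationError(f"p_threshold outside (0, 1]: {p_threshold}")
    d = rho.shape[0]
    if labels is None:
        labels = [f"taxon_{i}" for i in range(d)]
    if bh_adjust:
        p = _bh_adjust_symmetric(p)
    graph = nx.Graph()
    for i in range(d):
        for j in range(i + 1, d):
            if abs(rho[i, j]) > r_threshold and p[i, j] < p_threshold:
                graph.add_edge(labels[i], labels[j],
                               correlation=float(rho[i, j]),
                               p_value=float(p[i, j]))
    if taxonomy is not None:
        tax = pd.Series(taxonomy)
        for node in graph.nodes:
            graph.nodes[node]["phylum"] = str(tax.get(node, "unclassified"))
    return CorrelationNetwork(graph=graph)


def _bh_adjust_symmetric(p: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(p, k=1)
    raw = p[iu]
    order = np.argsort(raw)
    m = len(raw)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((raw[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.ones_like(p)
    out[iu] = np.minimum(adj, 1.0)
    return np.minimum(out, out.T)


def cooccurrence_network(
    table: OtuTable,
    rank: str = "genus",
    r_threshold: float = 0.65,
    p_threshold: float = 0.01,
    n_permutations: int = 999,
    min_prevalence: int = 3,
    seed: int = 0,
    **sparcc_kwargs,
) -> CorrelationNetwork:
    """End-to-end: aggregate to a rank, estimate SparCC rho, permute, threshold.

    With fewer than 10 samples correlation estimates are statistically
    fragile; a warning is emitted rather than refusing, because small designs
    (the emulated study has 6 samples) must remain runnable.
    """
    counts, phylum_of = aggregate_rank(table, rank=rank,
                                       min_prevalence=min_prevalence)
    if counts.shape[0] < 10:
        logger.warning(
            "only %d samples: SparCC correlation estimates will be fragile",
            counts.shape[0])
    est = sparcc_correlations(counts.to_numpy(), seed=seed, **sparcc_kwargs)
    p = permutation_pvalues(counts.to_numpy(), est.rho,
                            n_permutations=n_permutations, seed=seed + 1,
                            **sparcc_kwargs)
    return build_network(est.rho, p, r_threshold=r_threshold,
                         p_threshold=p_threshold, taxonomy=phylum_of,
                         labels=list(counts.columns))
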