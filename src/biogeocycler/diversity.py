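"""Alpha diversity, composition summaries, and Bray-Curtis beta diversity
with NMDS ordination and UPGMA similarity clustering.

Index conventions (chosen where the emulated workflow is silent): Shannon uses
the natural log; Chao1 is the bias-corrected form ``S + F1(F1-1)/(2(F2+1))``
so doubleton-free samples are defined; Pielou at a single observed taxon is 0;
Good's coverage is ``1 - F1/N``. No rarefaction is applied by default — beta
diversity works on relative abundances (``normalize='relative'``), and the
normalisation choice is an explicit argument because it changes the indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .io import RANKS, UNCLASSIFIED, CopyNumberTable, OtuTable, ValidationError, lineage_rank

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: OtuTable, log_base: float = np.e) -> pd.DataFrame:
    """Per-sample richness, Chao1, Shannon, Pielou and Good's coverage.

    Returns a DataFrame indexed by sample with columns ``reads``, ``otus``,
    ``chao1``, ``shannon``, ``pielou``, ``goods_coverage``.
    """
    rows = {}
    for sample, counts in table.counts.iterrows():
        x = counts.to_numpy()
        n = int(x.sum())
        if n == 0:
            raise ValidationError(f"sample {sample!r} has no reads")
        nz = x[x > 0]
        s_obs = len(nz)
        f1 = int((nz == 1).sum())
        f2 = int((nz == 2).sum())
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        p = nz / n
        shannon = float(-(p * (np.log(p) / np.log(log_base))).sum())
        pielou = shannon / (np.log(s_obs) / np.log(log_base)) if s_obs > 1 else 0.0
        rows[sample] = {
            "reads": n, "otus": s_obs, "chao1": chao1, "shannon": shannon,
            "pielou": pielou, "goods_coverage": 1.0 - f1 / n,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[table.sample_ids]


def relative_abundance(table: OtuTable, rank: str = "phylum") -> pd.DataFrame:
    """Sample x taxon fractions at a rank; unclassified OTUs pool together."""
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    taxa = table.lineage.map(lambda l: lineage_rank(l, rank))
    grouped = table.counts.T.groupby(taxa.values).sum().T
    fractions = grouped.div(grouped.sum(axis=1), axis=0)
    ordered = sorted(fractions.columns, key=lambda t: (t == UNCLASSIFIED, t))
    return fractions[ordered]


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: OtuTable, transform: str = "relative") -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity: 1 - 2*sum(min)/sum(x+y).

    Computed on relative abundances by default, making it invariant to
    sequencing depth; ``transform='none'`` uses raw counts.
    """
    if transform not in {"relative", "none"}:
        raise ValidationError(f"unknown transform {transform!r}")
    if len(table.sample_ids) < 2:
        raise ValidationError("Bray-Curtis needs at least 2 samples")
    data = table.relative() if transform == "relative" else table.counts.astype(float)
    if transform == "none" and (data.sum(axis=1) == 0).any():
        empty = data.index[data.sum(axis=1) == 0][0]
        raise ValidationError(f"sample {empty!r} has zero total count")
    d = squareform(pdist(data.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def _validate_dissimilarity(d) -> tuple[np.ndarray, list]:
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        mat = d.to_numpy(dtype=float)
    else:
        mat = np.asarray(d, dtype=float)
        ids = list(range(mat.shape[0]))
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValidationError("dissimilarity matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValidationError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0, atol=1e-10):
        raise ValidationError("dissimilarity matrix must have zero diagonal")
    return mat, ids


# ---------------------------------------------------------------------------
# NMDS (Kruskal stress-1)
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """A non-metric MDS configuration and its final Kruskal stress-1."""

    coordinates: pd.DataFrame   # samples x dims, centred
    stress: float
    n_restarts_used: int
    stress_history: list[float]  # per-iteration stress of the winning run


def kruskal_stress(d_config: np.ndarray, disparities: np.ndarray) -> float:
    """Stress-1 = sqrt(sum (d - dhat)^2 / sum d^2) over condensed distances."""
    denom = float((d_config ** 2).sum())
    if denom == 0:
        return 1.0
    return float(np.sqrt(((d_config - disparities) ** 2).sum() / denom))


def nmds(
    d,
    dims: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    Alternates isotonic regression (pool-adjacent-violators on the rank order
    of the input dissimilarities, ties pooled) with Guttman-transform
    configuration updates, under a monotone safeguard: an update that would
    increase stress-1 terminates the run, so stress is non-increasing across
    iterations by construction. The first restart starts from the classical
    (metric) MDS solution, the rest from random configurations; the lowest-
    stress configuration over all restarts is returned, centred.
    """
    delta_mat, ids = _validate_dissimilarity(d)
    n = delta_mat.shape[0]
    if n <= dims:
        raise ValidationError("need more samples than ordination dimensions")
    delta = squareform(delta_mat, checks=False)
    order = np.argsort(delta, kind="stable")
    rng = np.random.default_rng(seed)

    best_stress = np.inf
    best_x = None
    best_history: list[float] = []
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            x = _classical_mds(delta_mat, dims)
        else:
            x = rng.standard_normal((n, dims))
        x, history = _nmds_single(x, delta, order, max_iter, tol)
        if history[-1] < best_stress:
            best_stress = history[-1]
            best_x = x
            best_history = history
    best_x = best_x - best_x.mean(axis=0)
    coords = pd.DataFrame(best_x, index=ids,
                          columns=[f"NMDS{i + 1}" for i in range(dims)])
    return OrdinationResult(coordinates=coords, stress=best_stress,
                            n_restarts_used=max(1, n_restarts),
                            stress_history=best_history)


def _classical_mds(delta: np.ndarray, dims: int) -> np.ndarray:
    n = delta.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (delta ** 2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:dims]
    return v[:, idx] * np.sqrt(np.clip(w[idx], 0, None))


def _nmds_single(x, delta, order, max_iter, tol):
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    ranks = np.arange(len(delta), dtype=float)
    d = pdist(x)
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(ranks, d[order])
    stress = kruskal_stress(d, dhat)
    history = [stress]
    for _ in range(max_iter):
        x_new = _guttman(x, d, dhat)
        d_new = pdist(x_new)
        dhat_new = np.empty_like(d_new)
        dhat_new[order] = iso.fit_transform(ranks, d_new[order])
        stress_new = kruskal_stress(d_new, dhat_new)
        if stress_new > stress:  # monotone safeguard
            break
        x, d, dhat = x_new, d_new, dhat_new
        improved = stress - stress_new
        stress = stress_new
        history.append(stress)
        if improved < tol:
            break
    return x, history


def _guttman(x: np.ndarray, d: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, dhat / d, 0.0)
    b = -squareform(ratio, checks=False)
    np.fill_diagonal(b, -b.sum(axis=1))
    return (b @ x) / n


# ---------------------------------------------------------------------------
# UPGMA similarity clustering
# ---------------------------------------------------------------------------

def similarity_clusters(d, similarity_cut: float = 40.0) -> pd.Series:
    """Flat clusters from a UPGMA dendrogram cut at a similarity level.

    ``similarity_cut`` is a percent similarity; the average-linkage tree on
    the dissimilarities is cut at height ``1 - cut/100`` (e.g. a 40%%
    similarity cut groups samples whose average dissimilarity is below 0.6).
    """
    if not 0 < similarity_cut <= 100:
        raise ValidationError(
            f"similarity_cut must be in (0, 100], got {similarity_cut}"
        )
    mat, ids = _validate_dissimilarity(d)
    z = linkage(squareform(mat, checks=False), method="average")
    labels = fcluster(z, t=1.0 - similarity_cut / 100.0, criterion="distance")
    return pd.Series(labels, index=ids, name="cluster")


# ---------------------------------------------------------------------------
# qPCR biomass summaries
# ---------------------------------------------------------------------------

def qpcr_summary(table: CopyNumberTable) -> pd.DataFrame:
    """Total 16S copies and the archaeal share, per sample.

    Reports both conventions for the archaeal share — percent of bacterial
    copies (``archaea_pct_of_bacteria``) and percent of the total
    (``archaea_pct_of_total``) — since published spans are ambiguous between
    the two. Missing measurements propagate as missing.
    """
    df = table.frame
    both = df["bacteria_copies"].notna() & df["archaea_copies"].notna()
    if not both.any():
        raise ValidationError("no sample has both bacterial and archaeal counts")
    if (df.loc[df["bacteria_copies"].notna(), "bacteria_copies"] == 0).any():
        raise ValidationError("zero bacterial copies")
    total = df["bacteria_copies"] + df["archaea_copies"]
    out = pd.DataFrame({
        "sample_id": df["sample_id"],
        "total_copies": total,
        "archaea_pct_of_bacteria": 100.0 * df["archaea_copies"] / df["bacteria_copies"],
        "archaea_pct_of_total": 100.0 * df["archaea_copies"] / total,
    })
    return out.set_index("sample_id")
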