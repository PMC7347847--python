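"""Nonnegative matrix factorization and consensus clustering of samples.

The panel-gene submatrix X (genes x samples, nonnegative log2 intensities)
is factorized as X ~ W H with W (genes x K) holding per-cluster gene
contributions and H (K x samples) holding sample memberships; samples are
assigned to the cluster with the largest membership coefficient. The
factorization minimizes the Frobenius reconstruction error with Lee-Seung
multiplicative updates, whose objective is non-increasing by construction.

Cluster stability is assessed the standard way: many seeded restarts, an
I x I consensus matrix of co-clustering frequencies, an average-linkage tree
on the consensus dissimilarity, and the cophenetic correlation between the
two; the rank K maximizing the cophenetic correlation is recommended.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

_EPS = 1e-10


@dataclass
class NMFModel:
    """A fitted factorization X ~ W H at rank K.

    W columns are normalized to unit sum (the scale moves into H), which
    pins down the scaling indeterminacy of the factor pair.
    """

    W: np.ndarray  # J x K
    H: np.ndarray  # K x I
    K: int
    objective_trace: list = field(default_factory=list)
    seed: int = 0
    converged: bool = False
    n_iter: int = 0
    gene_ids: list | None = None
    sample_ids: list | None = None

    @property
    def reconstruction_error(self) -> float:
        return self.objective_trace[-1] if self.objective_trace else np.nan


@dataclass
class ConsensusResult:
    """Consensus matrix, tree, and cophenetic correlation at one rank K."""

    K: int
    consensus: np.ndarray  # I x I in [0, 1]
    cophenetic: float
    linkage: np.ndarray  # scipy linkage matrix (the dendrogram)
    cluster_labels: np.ndarray  # per sample, 0-based


def nmf_factorize(
    matrix: np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NMFModel:
    """Lee-Seung multiplicative-update NMF of a nonnegative matrix.

    Stops when the relative drop of the Frobenius objective between
    iterations falls below ``tol`` or at ``max_iter``.
    """
    x = np.asarray(matrix, dtype=float)
    if (x < 0).any():
        raise ValueError("NMF input must be nonnegative")
    j, i = x.shape
    if not 1 <= K <= min(i, j):
        raise ValueError(f"rank K={K} infeasible for a {j}x{i} matrix")
    rng = np.random.default_rng(seed)
    # half-normal init at the scale making (W H) match the data mean; far
    # less prone to spurious local minima here than a flat uniform draw
    scale = np.sqrt((x.mean() or 1.0) / K)
    w = np.abs(rng.standard_normal((j, K))) * scale + _EPS
    h = np.abs(rng.standard_normal((K, i))) * scale + _EPS

    trace = [float(np.linalg.norm(x - w @ h))]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w *= (x @ h.T) / (w @ h @ h.T + _EPS)
        h *= (w.T @ x) / (w.T @ w @ h + _EPS)
        err = float(np.linalg.norm(x - w @ h))
        prev = trace[-1]
        trace.append(err)
        if prev > 0 and (prev - err) / prev < tol:
            converged = True
            break

    colsum = w.sum(axis=0)
    colsum[colsum <= 0] = 1.0
    w = w / colsum
    h = h * colsum[:, None]
    return NMFModel(
        W=w, H=h, K=K, objective_trace=trace, seed=seed,
        converged=converged, n_iter=it,
    )


def assign_clusters(model: NMFModel) -> np.ndarray:
    """Per-sample 0-based cluster: argmax membership (ties -> lower index)."""
    return np.argmax(model.H, axis=0)


def gene_contributions(model: NMFModel, gene_ids: list | None = None) -> dict:
    """Per-cluster gene ranking by descending contribution w_jk.

    Ties fall back to gene-id (input) order. Returns ``{k: [gene, ...]}``.
    """
    ids = gene_ids if gene_ids is not None else model.gene_ids
    if ids is None:
        ids = list(range(model.W.shape[0]))
    out = {}
    for k in range(model.K):
        w = model.W[:, k]
        order = np.lexsort((np.arange(len(ids)), -w))
        out[k] = [ids[i] for i in order]
    return out


def _connectivity(labels: np.ndarray) -> np.ndarray:
    return (labels[:, None] == labels[None, :]).astype(float)


def consensus_cluster(
    matrix: np.ndarray,
    K_range=(2, 3, 4),
    n_restarts: int = 30,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[dict, int]:
    """Consensus NMF over seeded restarts for each rank in ``K_range``.

    Returns ``(results, recommended_K)`` where ``results[K]`` is a
    :class:`ConsensusResult` and the recommendation maximizes the cophenetic
    correlation (ties -> smaller K).
    """
    if n_restarts < 2:
        raise ValueError("consensus needs at least two restarts")
    x = np.asarray(matrix, dtype=float)
    i = x.shape[1]
    feasible = min(x.shape)
    results: dict[int, ConsensusResult] = {}
    ss = np.random.SeedSequence(seed)
    for K in K_range:
        if not 2 <= K <= feasible:
            raise ValueError(f"rank K={K} outside feasible range for consensus")
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_restarts)]
        consensus = np.zeros((i, i))
        for s in child_seeds:
            model = nmf_factorize(x, K, seed=s, max_iter=max_iter, tol=tol)
            consensus += _connectivity(assign_clusters(model))
        consensus /= n_restarts
        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        z = hierarchy.linkage(condensed, method="average")
        if condensed.size and condensed.std() > 0:
            coph = float(hierarchy.cophenet(z, condensed)[0])
        else:
            # all pairwise dissimilarities identical: the tree is a perfect
            # representation of the (degenerate) consensus
            coph = 1.0
        labels = hierarchy.fcluster(z, t=K, criterion="maxclust") - 1
        results[K] = ConsensusResult(
            K=K, consensus=consensus, cophenetic=coph, linkage=z,
            cluster_labels=labels,
        )
    recommended = min(results, key=lambda k: (-results[k].cophenetic, k))
    return results, recommended


def match_labels(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Relabel ``pred`` to best agree with ``truth`` (Hungarian matching)."""
    from scipy.optimize import linear_sum_assignment

    pred = np.asarray(pred)
    truth_codes, truth_levels = pd.factorize(pd.Series(truth))
    k = max(pred.max(), truth_codes.max()) + 1
    cost = np.zeros((k, k))
    for p, t in zip(pred, truth_codes):
        cost[p, t] -= 1
    _, col = linear_sum_assignment(cost)
    remap = {p: col[p] for p in range(k)}
    return np.array([truth_levels[remap[p]] if remap[p] < len(truth_levels) else f"C{remap[p]}" for p in pred])
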