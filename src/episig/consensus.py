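"""Resampling-based consensus clustering with PAC model selection.

The stability of a k-group partition is assessed by repeatedly subsampling
both samples and features (default 80% of each), clustering every subsample
by k-means on Spearman-correlation distance, and tallying how often each
sample pair lands in the same cluster among the runs where both were drawn.
The resulting consensus matrix feeds:

* PAC — the proportion of ambiguous clustering, the fraction of pairwise
  consensus values that are neither clearly 0 nor clearly 1;
* cluster consensus (mean within-cluster consensus) and item consensus
  (a sample's mean consensus with each cluster's members);
* optimal-k selection: among k whose every cluster consensus exceeds a
  threshold, the k with the smallest PAC.

Because rank-correlation distance is not an inner-product space, k-means is
run on classical multidimensional-scaling coordinates of the Spearman
distance matrix — deterministic and faithful to "k-means on Spearman's
distance".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, spearmanr

__all__ = ["ConsensusResult", "consensus_cluster", "compute_pac",
           "select_optimal_k", "item_consensus", "cluster_consensus",
           "assign_to_cluster"]


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, labels, consensus summaries and PAC."""

    k_range: list[int]
    consensus: dict[int, pd.DataFrame] = field(default_factory=dict)
    labels: dict[int, pd.Series] = field(default_factory=dict)
    cluster_consensus: dict[int, pd.Series] = field(default_factory=dict)
    item_consensus: dict[int, pd.DataFrame] = field(default_factory=dict)
    pac: dict[int, float] = field(default_factory=dict)
    reps: int = 0
    item_fraction: float = 0.8
    feature_fraction: float = 0.8
    seed: int = 0


def _spearman_distance(x: np.ndarray) -> np.ndarray:
    """1 − Spearman rank correlation between rows of x."""
    ranks = np.apply_along_axis(rankdata, 1, x)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks ** 2).sum(axis=1))
    norms[norms == 0] = 1.0
    rho = (ranks @ ranks.T) / np.outer(norms, norms)
    return 1.0 - np.clip(rho, -1.0, 1.0)


def _cmdscale(d: np.ndarray) -> np.ndarray:
    """Classical MDS coordinates of a distance matrix (positive eigenvalues)."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    keep = vals > 1e-10
    if not keep.any():
        return np.zeros((n, 1))
    return vecs[:, keep] * np.sqrt(vals[keep])


def _kmeans(x: np.ndarray, k: int, rng: np.random.Generator,
            restarts: int = 10, iters: int = 100) -> np.ndarray:
    """Seeded Lloyd k-means with multiple restarts; best inertia kept."""
    n = x.shape[0]
    best_labels, best_inertia = None, np.inf
    for _ in range(restarts):
        centers = x[rng.choice(n, size=k, replace=False)].copy()
        labels = None
        for _it in range(iters):
            d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new_labels = d2.argmin(axis=1)
            if labels is not None and (new_labels == labels).all():
                break
            labels = new_labels
            for c in range(k):
                mask = labels == c
                if mask.any():
                    centers[c] = x[mask].mean(axis=0)
                else:                                   # re-seed empty cluster
                    centers[c] = x[rng.integers(n)]
        inertia = ((x - centers[labels]) ** 2).sum()
        if inertia < best_inertia:
            best_inertia, best_labels = inertia, labels
    return best_labels


def consensus_cluster(data: pd.DataFrame, k_range=range(2, 11), reps: int = 1000,
                      item_fraction: float = 0.8, feature_fraction: float = 0.8,
                      seed: int = 0) -> ConsensusResult:
    """Subsampled k-means consensus clustering on Spearman distance.

    ``data`` is sample × feature.  For each of ``reps`` repetitions a
    fraction of samples and features is drawn without replacement, pairwise
    Spearman distance is computed on the subsample, k-means (10 restarts)
    is run on its classical-MDS embedding for every k, and co-clustering is
    tallied.  consensus(i,j) = co-clustered / co-sampled.  Final labels per
    k come from average-linkage hierarchical clustering of 1 − consensus.
    """
    k_range = list(k_range)
    n, n_feat = data.shape
    if n < max(k_range) + 1:
        raise ValueError("need more samples than the largest k")
    x = data.to_numpy(dtype=float)
    ids = data.index
    n_items = max(2, int(round(item_fraction * n)))
    n_features = max(2, int(round(feature_fraction * n_feat)))

    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(reps)
    connect = {k: np.zeros((n, n)) for k in k_range}
    together = np.zeros((n, n))
    used = 0
    for r in range(reps):
        rng = np.random.default_rng(rep_seeds[r])
        items = np.sort(rng.choice(n, size=n_items, replace=False))
        feats = rng.choice(n_feat, size=n_features, replace=False)
        if n_items <= max(k_range):
            warnings.warn(f"rep {r}: subsample smaller than max k; skipped")
            continue
        sub = x[np.ix_(items, feats)]
        coords = _cmdscale(_spearman_distance(sub))
        together[np.ix_(items, items)] += 1
        for k in k_range:
            labels = _kmeans(coords, k, rng)
            same = labels[:, None] == labels[None, :]
            connect[k][np.ix_(items, items)] += same
        used += 1
    if used == 0:
        raise RuntimeError("every consensus repetition was skipped")

    result = ConsensusResult(k_range=k_range, reps=reps,
                             item_fraction=item_fraction,
                             feature_fraction=feature_fraction, seed=seed)
    for k in k_range:
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(together > 0, connect[k] / together, 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0
        cm = pd.DataFrame(cons, index=ids, columns=ids)
        dist = 1.0 - cons
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="average")
        labels = pd.Series(fcluster(z, t=k, criterion="maxclust"), index=ids)
        result.consensus[k] = cm
        result.labels[k] = labels
        result.cluster_consensus[k] = cluster_consensus(cm, labels)
        result.item_consensus[k] = item_consensus(cm, labels)
        result.pac[k] = compute_pac(cm)
    return result


def compute_pac(consensus_matrix, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: fraction of upper-triangular
    consensus entries strictly inside (lower, upper)."""
    if not 0 <= lower < upper <= 1:
        raise ValueError("need 0 ≤ lower < upper ≤ 1")
    c = np.asarray(consensus_matrix, dtype=float)
    if c.shape[0] != c.shape[1] or not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("consensus matrix must be square and symmetric")
    iu = np.triu_indices(c.shape[0], k=1)
    vals = c[iu]
    if vals.size == 0:
        return 0.0
    return float(((vals > lower) & (vals < upper)).mean())


def cluster_consensus(consensus_matrix: pd.DataFrame,
                      labels: pd.Series) -> pd.Series:
    """Mean within-cluster consensus (upper-triangular entries) per cluster.

    Singleton clusters get 1 by convention (a lone sample is trivially
    stable with itself).
    """
    c = consensus_matrix.to_numpy()
    out = {}
    for cl in sorted(labels.unique()):
        idx = np.flatnonzero((labels == cl).to_numpy())
        if len(idx) == 1:
            out[cl] = 1.0
        else:
            block = c[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            out[cl] = float(block[iu].mean())
    return pd.Series(out, name="cluster_consensus")


def item_consensus(consensus_matrix: pd.DataFrame,
                   labels: pd.Series) -> pd.DataFrame:
    """Mean consensus of each sample with each cluster's members.

    Entry (i, c) averages consensus(i, j) over j in cluster c, excluding i
    itself when i belongs to c; a sample alone in its own cluster scores 1
    there by convention.
    """
    if set(labels.index) != set(consensus_matrix.index):
        raise ValueError("labels must cover exactly the consensus samples")
    labels = labels.loc[consensus_matrix.index]
    clusters = sorted(labels.unique())
    if any((labels == cl).sum() == 0 for cl in clusters):
        raise ValueError("empty cluster")
    c = consensus_matrix.to_numpy()
    n = c.shape[0]
    out = np.zeros((n, len(clusters)))
    lab = labels.to_numpy()
    for ci, cl in enumerate(clusters):
        members = np.flatnonzero(lab == cl)
        for i in range(n):
            others = members[members != i]
            out[i, ci] = 1.0 if others.size == 0 else c[i, others].mean()
    return pd.DataFrame(out, index=consensus_matrix.index, columns=clusters)


def select_optimal_k(result: ConsensusResult,
                     min_cluster_consensus: float = 0.9) -> int:
    """Smallest-PAC k among those whose every cluster consensus passes.

    Ties in PAC break toward the smaller k.  If no k clears the cluster-
    consensus threshold, the PAC-minimal k is returned with a warning.
    """
    qualifying = [k for k in result.k_range
                  if (result.cluster_consensus[k] > min_cluster_consensus).all()]
    pool = qualifying
    if not pool:
        warnings.warn("no k reaches the cluster-consensus threshold; "
                      "returning the PAC-minimal k unqualified")
        pool = result.k_range
    return min(pool, key=lambda k: (result.pac[k], k))


def cluster_centroids(betas: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-cluster mean beta profile (probe × cluster) from training samples."""
    cols = {}
    for cl in sorted(labels.unique()):
        members = labels.index[labels == cl]
        cols[cl] = betas[members].mean(axis=1)
    return pd.DataFrame(cols)


def assign_to_cluster(sample_betas: pd.Series, cluster_profiles: pd.DataFrame
                      ) -> tuple[object, pd.Series]:
    """Assign a new sample to the discovered cluster it correlates with best.

    Uses Spearman correlation against each cluster's centroid over the
    shared probes; returns the winning label and all correlations.
    """
    shared = sample_betas.index.intersection(cluster_profiles.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 probes shared with the cluster profiles")
    x = sample_betas.loc[shared].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("sample has zero variance on the shared probes")
    corrs = {}
    for cl in cluster_profiles.columns:
        rho = spearmanr(x, cluster_profiles.loc[shared, cl].to_numpy()).statistic
        corrs[cl] = float(rho)
    scores = pd.Series(corrs, name="spearman")
    return scores.idxmax(), scores
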