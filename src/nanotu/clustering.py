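"""Dimensionality reduction and density clustering of read k-mer signatures.

The CLR feature matrix is reduced with PCA to 30 components (noise
suppression and speed), embedded into 2-D with UMAP, and clustered with
HDBSCAN under the Euclidean metric. HDBSCAN's noise label (-1) marks reads
that join no cluster. Within each cluster only a filtered subset of reads
feeds the consensus: reads whose length deviates from the cluster mean by
more than 10 bp, or whose GC fraction deviates by more than two population
standard deviations, are set aside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    """2-D UMAP coordinates, row-aligned with the feature matrix."""

    coords: np.ndarray
    read_ids: list[str]
    seed: int


@dataclass
class ClusterSet:
    """HDBSCAN labels plus the per-cluster read subsets selected for consensus."""

    labels: np.ndarray
    read_ids: list[str]
    clusters: dict[int, list[str]] = field(default_factory=dict)
    selected: dict[int, list[str]] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def reduce_pca(values: np.ndarray, n_components: int = 30, seed: int = 0) -> np.ndarray:
    """Project the feature matrix onto its leading principal components.

    The effective dimensionality is min(n_components, N, n_features);
    requires at least two rows.
    """
    n, p = values.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 reads")
    n_eff = min(n_components, n, p)
    pca = PCA(n_components=n_eff, svd_solver="auto", random_state=seed)
    return pca.fit_transform(values)


def embed_umap(pcs: np.ndarray, seed: int = 42, n_neighbors: int = 15,
               min_dist: float = 0.1) -> np.ndarray:
    """Embed the PCA scores into 2-D with UMAP.

    A fixed ``seed`` makes the embedding deterministic (UMAP then runs
    single-threaded). ``n_neighbors`` is clamped to N-1 for small inputs.
    """
    import umap  # deferred: heavy numba JIT on first import

    n = pcs.shape[0]
    if n_neighbors >= n:
        logger.warning("n_neighbors=%d >= N=%d; clamping to %d", n_neighbors, n, n - 1)
        n_neighbors = max(2, n - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about forced single-threading
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            min_dist=min_dist, random_state=seed, metric="euclidean")
        coords = reducer.fit_transform(pcs)
    return np.asarray(coords, dtype=np.float64)


def cluster_hdbscan(coords: np.ndarray, read_ids: list[str],
                    min_cluster_size: int = 5) -> ClusterSet:
    """Cluster the 2-D embedding with HDBSCAN (Euclidean metric).

    Labels are renumbered by decreasing cluster size for stable output
    ordering; -1 remains the noise label. All points landing in noise is a
    valid outcome (empty cluster map). ``allow_single_cluster`` is enabled so
    a sample containing a single taxon still yields one cluster instead of
    pure noise; ``min_cluster_size`` is clamped to the number of points.
    """
    if min_cluster_size > len(coords):
        # no cluster can reach the minimum size: everything is noise
        logger.warning("min_cluster_size=%d exceeds the %d available points; "
                       "all points labelled noise", min_cluster_size, len(coords))
        return ClusterSet(labels=np.full(len(coords), -1, dtype=np.int64),
                          read_ids=list(read_ids))
    raw = HDBSCAN(min_cluster_size=max(2, min_cluster_size), metric="euclidean",
                  allow_single_cluster=True, copy=True).fit_predict(coords)
    # renumber by decreasing size, ties broken by original label for determinism
    uniq, counts = np.unique(raw[raw >= 0], return_counts=True)
    order = sorted(zip(uniq, counts), key=lambda t: (-t[1], t[0]))
    remap = {old: new for new, (old, _) in enumerate(order)}
    labels = np.array([remap[l] if l >= 0 else -1 for l in raw], dtype=np.int64)
    if not order:
        logger.warning("HDBSCAN labelled all %d points as noise", len(labels))
    clusters: dict[int, list[str]] = {}
    for rid, lab in zip(read_ids, labels):
        if lab >= 0:
            clusters.setdefault(int(lab), []).append(rid)
    return ClusterSet(labels=labels, read_ids=list(read_ids), clusters=clusters)


def default_min_cluster_size(n_reads: int) -> int:
    """Default HDBSCAN min_cluster_size: max(5, 0.1% of the read count)."""
    return max(5, int(np.ceil(0.001 * n_reads)))


def select_cluster_reads(lengths: np.ndarray, gcs: np.ndarray,
                         len_window: float = 10.0, gc_sigmas: float = 2.0) -> np.ndarray:
    """Boolean mask of cluster members retained for alignment.

    Keeps members with |len - mean_len| <= len_window bp and
    |GC - mean_GC| <= gc_sigmas * population-sd(GC), both computed over the
    cluster's own members (uncompressed reads). With a single member or zero
    spread everything passes (deviations are 0 <= 0).
    """
    lengths = np.asarray(lengths, dtype=np.float64)
    gcs = np.asarray(gcs, dtype=np.float64)
    mu_len = lengths.mean()
    mu_gc = gcs.mean()
    sd_gc = gcs.std()  # population sd
    return (np.abs(lengths - mu_len) <= len_window) & (np.abs(gcs - mu_gc) <= gc_sigmas * sd_gc)


def cluster_reads(values: np.ndarray, read_ids: list[str], reads_by_id: dict,
                  seed: int = 42, min_cluster_size: int | None = None,
                  n_components: int = 30, n_neighbors: int = 15,
                  min_dist: float = 0.1, min_support: int = 3) -> tuple[ClusterSet, np.ndarray]:
    """Full chain PCA -> UMAP -> HDBSCAN -> per-cluster read selection.

    Returns the ClusterSet (with ``selected`` populated; clusters whose
    selection falls below ``min_support`` keep an empty selection and are
    skipped for consensus) and the 2-D embedding coordinates.
    """
    if min_cluster_size is None:
        min_cluster_size = default_min_cluster_size(len(read_ids))
    if np.allclose(values, values[0], atol=1e-12):
        # zero spread (e.g. error-free duplicates): one cluster by definition;
        # UMAP on identical points would scatter them arbitrarily
        logger.info("all %d feature rows identical; assigning a single cluster", len(read_ids))
        coords = np.zeros((len(read_ids), 2))
        cs = ClusterSet(labels=np.zeros(len(read_ids), dtype=np.int64),
                        read_ids=list(read_ids), clusters={0: list(read_ids)})
    else:
        pcs = reduce_pca(values, n_components, seed=seed)
        coords = embed_umap(pcs, seed=seed, n_neighbors=n_neighbors, min_dist=min_dist)
        cs = cluster_hdbscan(coords, read_ids, min_cluster_size)
    for label, members in cs.clusters.items():
        lens = np.array([len(reads_by_id[r].seq) for r in members])
        gcs = np.array([reads_by_id[r].gc for r in members])
        mask = select_cluster_reads(lens, gcs)
        selected = [r for r, m in zip(members, mask) if m]
        if len(selected) < min_support:
            logger.warning("cluster %d: only %d reads after selection (< %d); "
                           "skipped for consensus", label, len(selected), min_support)
            selected = []
        cs.selected[label] = selected
    return cs, coords
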