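"""Inter-subject correlation networks and equi-sparse binarization.

Each in-mask voxel is a node. The weight of the edge between nodes i and j
is w_ij = |z_ij| where z_ij = arctanh(r_ij) is the Fisher transform of the
Pearson correlation r_ij between the two voxels' response amplitudes
across subjects. The weighted complete network is reduced to a binary one
by retaining exactly the strongest ``sparsity`` fraction of the
N(N-1)/2 possible edges (equi-sparse thresholding), so networks from
different cohorts share the same edge count and differ only in topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial.distance import squareform

from .errors import DataError
from .preprocess import ResponseMatrix

logger = logging.getLogger(__name__)

#: |r| is clipped below 1 by this margin before the Fisher transform so
#: perfect sample correlations (possible at small cohort sizes) keep a
#: finite weight without disturbing the rank order.
R_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric nonnegative edge weights, stored in condensed
    upper-triangular (scipy ``squareform``) order."""

    triu_weights: np.ndarray  # (N(N-1)/2,)
    n_nodes: int
    node_coords: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        w = np.asarray(self.triu_weights, dtype=float)
        object.__setattr__(self, "triu_weights", w)
        m = self.n_nodes * (self.n_nodes - 1) // 2
        if w.shape != (m,):
            raise ValueError(f"expected {m} condensed weights, got {w.shape}")
        if not np.isfinite(w).all() or (w < 0).any():
            raise DataError("edge weights must be finite and >= 0")

    def to_matrix(self) -> np.ndarray:
        """Full symmetric weight matrix with zero diagonal."""
        return squareform(self.triu_weights, checks=False)


@dataclass(frozen=True)
class BinaryNetwork:
    """Sparse symmetric 0/1 adjacency with the threshold provenance."""

    adjacency: sparse.csr_matrix
    z_thresh: float
    sparsity: float
    node_coords: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def to_networkx(self):
        import networkx as nx

        return nx.from_scipy_sparse_array(self.adjacency)


def intersubject_correlation(rm: ResponseMatrix) -> np.ndarray:
    """Pearson correlation between every pair of node response vectors.

    Raises :class:`DataError` naming the first node whose response is
    constant across subjects (undefined correlation).
    """
    values = rm.values
    sd = values.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        x, y, z = rm.node_coords[bad[0]]
        raise DataError(
            f"node {bad[0]} at voxel ({x}, {y}, {z}) has zero variance "
            "across subjects"
        )
    r = np.corrcoef(values)
    np.clip(r, -1.0, 1.0, out=r)
    return r


def fisher_weight(r):
    """Edge weight |z| from correlation r: z = 0.5*ln((1+r)/(1-r)).

    Even in r and strictly increasing in |r|; r = +-1 is clipped to keep
    the weight finite (rank order unchanged).
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("|r| must be <= 1")
    out = np.abs(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))
    return float(out) if out.ndim == 0 else out


def build_weighted_network(rm: ResponseMatrix) -> WeightedNetwork:
    """Correlate nodes across subjects and Fisher-transform to weights."""
    r = intersubject_correlation(rm)
    w = fisher_weight(squareform(r, checks=False))
    return WeightedNetwork(
        triu_weights=w,
        n_nodes=rm.n_nodes,
        node_coords=rm.node_coords,
        voxel_size_mm=rm.voxel_size_mm,
    )


def n_edges_at_sparsity(n_nodes: int, sparsity: float) -> int:
    """Retained edge count E = round(sparsity * N(N-1)/2), half away
    from zero."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(sparsity * m + 0.5))


def _binarize_from_order(
    wn: WeightedNetwork, keep: np.ndarray, z_thresh: float, sparsity: float
) -> BinaryNetwork:
    ii, jj = np.triu_indices(wn.n_nodes, k=1)
    rows = np.concatenate([ii[keep], jj[keep]])
    cols = np.concatenate([jj[keep], ii[keep]])
    adj = sparse.coo_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)),
        shape=(wn.n_nodes, wn.n_nodes),
    ).tocsr()
    return BinaryNetwork(
        adjacency=adj,
        z_thresh=float(z_thresh),
        sparsity=float(sparsity),
        node_coords=wn.node_coords,
        voxel_size_mm=wn.voxel_size_mm,
    )


def equisparse_binarize(wn: WeightedNetwork, sparsity: float = 0.02) -> BinaryNetwork:
    """Retain exactly the E = round(sparsity * N(N-1)/2) strongest edges.

    Ties at the threshold weight are ordered lexicographically by (i, j)
    node pair and truncated to exactly E edges, so the equi-sparse contract
    holds deterministically. ``z_thresh`` records the weakest retained
    weight.
    """
    if not 0 < sparsity < 1:
        raise ValueError("sparsity must be in (0, 1)")
    if wn.n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    e = n_edges_at_sparsity(wn.n_nodes, sparsity)
    if e == 0:
        raise ValueError("sparsity rounds to an empty network")
    w = wn.triu_weights
    ii, jj = np.triu_indices(wn.n_nodes, k=1)
    # descending weight, then ascending (i, j); lexsort: last key primary
    order = np.lexsort((jj, ii, -w))[:e]
    keep = np.zeros(w.size, dtype=bool)
    keep[order] = True
    z_thresh = w[order[-1]]
    logger.info(
        "equi-sparse binarization: N=%d, E=%d (%.3g%%), z_thresh=%.4f",
        wn.n_nodes, e, 100 * sparsity, z_thresh,
    )
    return _binarize_from_order(wn, keep, z_thresh, sparsity)


def threshold_by_value(wn: WeightedNetwork, z_thresh: float) -> BinaryNetwork:
    """Alternative binarization keeping every edge with weight >= z_thresh.

    Edge density then varies between cohorts; provided for comparison with
    fixed-threshold workflows.
    """
    keep = wn.triu_weights >= z_thresh
    e = int(keep.sum())
    if e == 0:
        raise ValueError("threshold retains no edges")
    m = wn.triu_weights.size
    return _binarize_from_order(wn, keep, z_thresh, e / m)
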