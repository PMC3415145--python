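"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse

from phmrinet.network import BinaryNetwork
from phmrinet.synthetic import VOIAtlas, generate_atlas


def bn_from_dense(a: np.ndarray, sparsity: float = 0.0) -> BinaryNetwork:
    """Wrap a dense symmetric 0/1 matrix as a BinaryNetwork with dummy
    voxel coordinates (node i at (i, 0, 0))."""
    a = np.asarray(a, dtype=np.int8)
    n = a.shape[0]
    coords = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
    return BinaryNetwork(
        adjacency=sparse.csr_matrix(a),
        z_thresh=0.0,
        sparsity=sparsity,
        node_coords=coords,
        voxel_size_mm=(1.0, 1.0, 1.0),
    )


def bn_from_networkx(g) -> BinaryNetwork:
    import networkx as nx

    n = g.number_of_nodes()
    adj = nx.to_scipy_sparse_array(g, nodelist=range(n), format="csr",
                                   dtype=np.int8)
    coords = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
    return BinaryNetwork(
        adjacency=sparse.csr_matrix(adj),
        z_thresh=0.0,
        sparsity=0.0,
        node_coords=coords,
        voxel_size_mm=(1.0, 1.0, 1.0),
    )


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T


def brute_degree(a: np.ndarray) -> np.ndarray:
    """O(N^2) literal count of 1-entries per row."""
    return np.array([int(sum(row)) for row in a])


def brute_clustering(a: np.ndarray) -> np.ndarray:
    """O(N^3) triangle enumeration per node, straight from the definition."""
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            a[u, v] for ai, u in enumerate(nbrs) for v in nbrs[ai + 1:]
        )
        out[i] = 2.0 * links / (k * (k - 1))
    return out


@pytest.fixture(scope="session")
def small_atlas() -> VOIAtlas:
    return generate_atlas((12, 12, 6), 4, seed=2, voxel_size_mm=(0.6, 0.6, 0.3))
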