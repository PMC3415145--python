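"""Nodewise and global topological metrics with rewired null models.

Per node: degree k_i (edges incident on the node) and clustering
coefficient c_i = 2 E(G_i) / (k_i (k_i - 1)), the fraction of possible
edges among the node's neighbours that exist. Globally: mean degree K,
mean clustering C, characteristic path length L, the power-law slope of
the degree histogram, and the small-world indices

    gamma    = C / C_random,
    sigma_SW = (C / C_random) / (L / L_random),

where C_random and L_random are means over an ensemble of degree-
preserving rewired (Maslov-Sneppen double-edge-swap) null networks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csgraph

from .network import BinaryNetwork

logger = logging.getLogger(__name__)

#: Accepted double-edge swaps per null realization, as a multiple of E.
REWIRE_SWAPS_PER_EDGE = 10


@dataclass(frozen=True)
class NodeMetrics:
    """Per-node degree and clustering coefficient, joinable to voxel
    coordinates through ``node_coords``."""

    k: np.ndarray
    c: np.ndarray
    node_coords: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=np.int64)
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "c", c)
        if k.shape != c.shape:
            raise ValueError("k and c must have equal length")
        if (c < 0).any() or (c > 1).any():
            raise ValueError("clustering coefficients must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.k.size


@dataclass(frozen=True)
class DegreeHistogram:
    bin_centers: np.ndarray  # mean k of the nodes in each (nonempty) bin
    counts: np.ndarray
    binning: str

    def __post_init__(self) -> None:
        centers = np.asarray(self.bin_centers, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "counts", counts)
        if np.any(np.diff(centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")


@dataclass(frozen=True)
class GlobalMetrics:
    """Global summary of one network plus its rewired null ensemble."""

    n_nodes: int
    n_edges: int
    K: float
    C: float
    L: float
    power_law_slope: float
    C_random: float
    L_random: float
    gamma: float
    sigma_SW: float
    n_null: int
    fit_window: tuple[float, float] = (1.0, float("inf"))
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "K": self.K,
            "C": self.C,
            "L": self.L,
            "power_law_slope": self.power_law_slope,
            "C_random": self.C_random,
            "L_random": self.L_random,
            "gamma": self.gamma,
            "sigma_SW": self.sigma_SW,
            "n_null": self.n_null,
            "fit_window": list(self.fit_window),
        }
        d.update(self.extra)
        return d


def degree(bn: BinaryNetwork) -> np.ndarray:
    """k_i = row sum of the adjacency matrix."""
    return np.asarray(bn.adjacency.sum(axis=1)).ravel().astype(np.int64)


def clustering(bn: BinaryNetwork) -> np.ndarray:
    """c_i = 2 * (edges among neighbours of i) / (k_i (k_i - 1)).

    Nodes with k_i < 2 are assigned c_i = 0 (the ratio is 0/0 there), the
    common convention that keeps C a mean over all nodes.
    """
    a = bn.adjacency.astype(np.int64)
    k = degree(bn)
    # (A^2 ∘ A) row sum counts ordered neighbour pairs of i that are
    # connected, i.e. 2 * E(G_i).
    paths = (a @ a).multiply(a).sum(axis=1)
    two_ei = np.asarray(paths).ravel()
    denom = k * (k - 1)
    c = np.zeros_like(two_ei, dtype=float)
    ok = denom > 0
    c[ok] = two_ei[ok] / denom[ok]
    return c


def node_metrics(bn: BinaryNetwork) -> NodeMetrics:
    return NodeMetrics(k=degree(bn), c=clustering(bn), node_coords=bn.node_coords)


def characteristic_path_length(bn: BinaryNetwork) -> float:
    """Mean shortest-path length over ordered node pairs.

    Computed within the largest connected component; a warning reports the
    component sizes when the network is disconnected.
    """
    if bn.n_edges == 0:
        raise ValueError("network has no edges")
    n_comp, labels = csgraph.connected_components(bn.adjacency, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        warnings.warn(
            f"network is disconnected ({n_comp} components, sizes "
            f"{sorted(sizes.tolist(), reverse=True)[:5]}...); "
            "L computed on the largest component",
            stacklevel=2,
        )
        giant = np.argmax(np.bincount(labels))
        idx = np.flatnonzero(labels == giant)
        sub = bn.adjacency[np.ix_(idx, idx)]
    else:
        sub = bn.adjacency
    dist = csgraph.shortest_path(sub, method="D", unweighted=True)
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    return float(dist[off].mean())


def rewire_null(
    bn: BinaryNetwork, n_realizations: int = 10, seed: int = 0
) -> list[BinaryNetwork]:
    """Degree-preserving rewired null ensemble (double-edge swaps).

    Each realization applies ``REWIRE_SWAPS_PER_EDGE * E`` accepted
    Maslov-Sneppen swaps, rejecting self-loops and duplicate edges, so the
    full degree sequence is preserved exactly. Deterministic given seed.
    Graphs with no valid swap (e.g. complete graphs) are returned as
    copies with a warning.
    """
    if bn.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    n = bn.n_nodes
    if bn.n_edges == n * (n - 1) // 2:
        warnings.warn("complete graph admits no swaps; returning copies",
                      stacklevel=2)
        return [bn] * n_realizations
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_realizations)
    g = bn.to_networkx()
    out = []
    nswap = REWIRE_SWAPS_PER_EDGE * bn.n_edges
    for s in sub_seeds:
        h = g.copy()
        try:
            nx.double_edge_swap(h, nswap=nswap, max_tries=100 * nswap,
                                seed=int(s))
        except nx.NetworkXError as exc:  # pragma: no cover - degenerate input
            warnings.warn(f"rewiring stopped early: {exc}", stacklevel=2)
        adj = nx.to_scipy_sparse_array(h, nodelist=range(n), format="csr",
                                       dtype=np.int8)
        out.append(
            BinaryNetwork(
                adjacency=adj,
                z_thresh=bn.z_thresh,
                sparsity=bn.sparsity,
                node_coords=bn.node_coords,
                voxel_size_mm=bn.voxel_size_mm,
            )
        )
    return out


def null_ensemble_means(ensemble: list[BinaryNetwork]) -> tuple[float, float]:
    """(C_random, L_random): ensemble means of mean clustering and of the
    characteristic path length."""
    cs = [float(clustering(b).mean()) for b in ensemble]
    ls = [characteristic_path_length(b) for b in ensemble]
    return float(np.mean(cs)), float(np.mean(ls))


def small_world_indices(
    C: float, L: float, C_random: float, L_random: float
) -> tuple[float, float]:
    """gamma = C/C_random and sigma_SW = (C/C_random)/(L/L_random)."""
    if C_random <= 0:
        raise ValueError("null ensemble clustering is zero; gamma undefined")
    if L_random <= 0:
        raise ValueError("null ensemble path length is zero; sigma undefined")
    gamma = C / C_random
    sigma = gamma / (L / L_random)
    return float(gamma), float(sigma)


def degree_histogram(k: np.ndarray, binning: str = "log2") -> DegreeHistogram:
    """Histogram of node degrees.

    ``binning="log2"`` uses bins [0,1), [1,2), [2,4), [4,8), ... (factor-2
    logarithmic bins); ``binning="linear"`` gives one bin per distinct
    degree. Bin centers are the mean degree of the nodes in each bin and
    empty bins are dropped, so counts always sum to the node count.
    """
    k = np.asarray(k)
    if k.size == 0:
        raise ValueError("no degrees to bin")
    if binning == "linear":
        vals, counts = np.unique(k, return_counts=True)
        return DegreeHistogram(
            bin_centers=vals.astype(float), counts=counts, binning="linear"
        )
    if binning != "log2":
        raise ValueError(f"unknown binning scheme {binning!r}")
    kmax = int(k.max())
    edges = [0, 1]
    while edges[-1] <= kmax:
        edges.append(edges[-1] * 2)
    idx = np.digitize(k, edges[1:], right=False)
    centers, counts = [], []
    for b in range(len(edges) - 1):
        members = k[idx == b]
        if members.size:
            centers.append(members.mean())
            counts.append(members.size)
    return DegreeHistogram(
        bin_centers=np.array(centers), counts=np.array(counts), binning="log2"
    )


def fit_power_law(
    h: DegreeHistogram, k_min: float = 1.0, k_max: float = np.inf
) -> float:
    """Least-squares slope of log10(count) on log10(bin center) over the
    nonzero bins inside [k_min, k_max]; negative for a decaying
    distribution."""
    centers = h.bin_centers
    counts = h.counts
    use = (counts > 0) & (centers >= k_min) & (centers <= k_max) & (centers > 0)
    if use.sum() < 3:
        raise ValueError(
            f"power-law fit needs >= 3 usable bins in [{k_min}, {k_max}], "
            f"found {int(use.sum())}"
        )
    slope, _ = np.polyfit(np.log10(centers[use]), np.log10(counts[use]), 1)
    return float(slope)


def global_summary(
    bn: BinaryNetwork,
    nm: NodeMetrics | None = None,
    null_ensemble: list[BinaryNetwork] | None = None,
    n_null: int = 10,
    seed: int = 0,
    fit_window: tuple[float, float] = (1.0, np.inf),
    binning: str = "log2",
) -> GlobalMetrics:
    """Assemble the global topological summary of one network.

    Computes the null ensemble with :func:`rewire_null` unless one is
    passed in. Warns when K <= ln(N), below which topological properties
    of density-matched random comparators are not reliably estimable.
    """
    if nm is None:
        nm = node_metrics(bn)
    n, e = bn.n_nodes, bn.n_edges
    K = 2 * e / n
    if K <= np.log(n):
        warnings.warn(
            f"mean degree K={K:.2f} <= ln(N)={np.log(n):.2f}: topological "
            "properties may not be estimable",
            stacklevel=2,
        )
    C = float(nm.c.mean())
    L = characteristic_path_length(bn)
    if null_ensemble is None:
        null_ensemble = rewire_null(bn, n_realizations=n_null, seed=seed)
    C_random, L_random = null_ensemble_means(null_ensemble)
    gamma, sigma = small_world_indices(C, L, C_random, L_random)
    hist = degree_histogram(nm.k, binning=binning)
    try:
        slope = fit_power_law(hist, *fit_window)
    except ValueError:
        slope = float("nan")
        warnings.warn("power-law fit window too narrow; slope set to NaN",
                      stacklevel=2)
    return GlobalMetrics(
        n_nodes=n,
        n_edges=e,
        K=float(K),
        C=C,
        L=L,
        power_law_slope=slope,
        C_random=C_random,
        L_random=L_random,
        gamma=gamma,
        sigma_SW=sigma,
        n_null=len(null_ensemble),
        fit_window=(float(fit_window[0]), float(fit_window[1])),
    )
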