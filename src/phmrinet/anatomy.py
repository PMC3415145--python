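"""VOI-level statistics, vehicle-referenced cutoffs and foci maps.

Node metrics are mapped back onto the voxel grid, profiled per volume of
interest (VOI), and compared between a drug network and the vehicle
(saline control) network by two-sided Mann-Whitney U tests with Bonferroni
correction over the VOIs tested. The vehicle network also supplies
percentile cutoffs (95th of k; 2.5th and 97.5th of c) used to label each
drug node as a high-degree and/or high-clustering focus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .metrics import NodeMetrics
from .synthetic import VOIAtlas

logger = logging.getLogger(__name__)

#: Categorical codes of the conjunction/disjunction foci map.
FOCI_CODES = {"none": 0, "high_k": 1, "high_c": 2, "high_k_and_c": 3, "low_c": 4}

#: Largest per-group size at which the exact Mann-Whitney distribution is
#: enumerated (tie-free data only); larger groups use the normal
#: approximation with continuity and tie corrections.
EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class Cutoffs:
    """Vehicle-referenced cutoffs: k_high = 95th percentile of vehicle k,
    (c_low, c_high) = 2.5th / 97.5th percentiles of vehicle c."""

    k_high: float
    c_low: float
    c_high: float

    def __post_init__(self) -> None:
        if not self.c_low < self.c_high:
            raise ValueError(
                f"degenerate clustering cutoffs: c_low={self.c_low} must be "
                f"< c_high={self.c_high}"
            )
        if self.k_high < 0:
            raise ValueError("k_high must be >= 0")


def _labels_for(nm: NodeMetrics, atlas: VOIAtlas) -> np.ndarray:
    grid = np.asarray(atlas.label_grid)
    if np.any(nm.node_coords.max(axis=0) >= grid.shape):
        raise DataError("atlas grid does not cover node coordinates")
    x, y, z = nm.node_coords.T
    return grid[x, y, z]


def metric_to_map(
    nm: NodeMetrics,
    shape: tuple[int, int, int],
    which: str = "k",
    quartile_overlay: bool = False,
) -> np.ndarray:
    """Voxel-wise map of a node metric; zero off the mask.

    With ``quartile_overlay`` only the upper quartile (75%-100%) of the
    metric distribution is shown, values below the 75th percentile being
    zeroed — the display convention for highlighting the most connected /
    most cliquish nodes.
    """
    if which not in ("k", "c"):
        raise ValueError("which must be 'k' or 'c'")
    values = np.asarray(getattr(nm, which), dtype=float)
    if quartile_overlay:
        cut = np.percentile(values, 75)
        values = np.where(values >= cut, values, 0.0)
    out = np.zeros(shape)
    x, y, z = nm.node_coords.T
    out[x, y, z] = values
    return out


def voi_profile(nm: NodeMetrics, atlas: VOIAtlas) -> pd.DataFrame:
    """Median k and c per VOI, rank-ordered by median degree (rank 1 =
    highest median k). Empty VOIs are excluded with a warning."""
    labels = _labels_for(nm, atlas)
    rows = []
    for lab in atlas.labels:
        sel = labels == lab
        if not sel.any():
            warnings.warn(f"VOI {lab} ({atlas.label_names[lab]}) has no nodes",
                          stacklevel=2)
            continue
        rows.append(
            {
                "voi": lab,
                "name": atlas.label_names[lab],
                "n_nodes": int(sel.sum()),
                "median_k": float(np.median(nm.k[sel])),
                "median_c": float(np.median(nm.c[sel])),
            }
        )
    df = pd.DataFrame(rows)
    df["rank_by_median_k"] = (
        df["median_k"].rank(ascending=False, method="min").astype(int)
    )
    return df.sort_values("rank_by_median_k").reset_index(drop=True)


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U of the first sample) and its p-value.

    Exact enumeration for tie-free small samples, normal approximation
    with continuity and tie corrections otherwise.
    """
    combined = np.concatenate([x, y])
    tie_free = np.unique(combined).size == combined.size
    if len(x) <= EXACT_MW_MAX_N and len(y) <= EXACT_MW_MAX_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_voi(
    drug_nm: NodeMetrics,
    vehicle_nm: NodeMetrics,
    atlas: VOIAtlas,
    metric: str = "k",
    alpha_tiers: tuple[float, float, float] = (0.05, 0.01, 0.001),
) -> pd.DataFrame:
    """Per-VOI two-sided Mann-Whitney comparison of a drug network's node
    metric against the vehicle network's, Bonferroni-corrected over the
    family of VOIs tested (one family per metric per comparison).

    The significance tier encodes corrected p and direction of the median
    shift: '+++'/'---' for p_c < 0.001, '++'/'--' for p_c < 0.01,
    '+'/'-' for p_c < 0.05, 'ns' otherwise.
    """
    if metric not in ("k", "c"):
        raise ValueError("metric must be 'k' or 'c'")
    if drug_nm.node_coords.shape != vehicle_nm.node_coords.shape or np.any(
        drug_nm.node_coords != vehicle_nm.node_coords
    ):
        raise DataError("drug and vehicle networks must share the node index")
    d_lab = _labels_for(drug_nm, atlas)
    d_val = np.asarray(getattr(drug_nm, metric), dtype=float)
    v_val = np.asarray(getattr(vehicle_nm, metric), dtype=float)

    rows = []
    for lab in atlas.labels:
        sel = d_lab == lab
        x = d_val[sel]
        y = v_val[sel]
        if len(x) < 2 or len(y) < 2:
            warnings.warn(
                f"VOI {lab} has fewer than 2 nodes; reported as ns",
                stacklevel=2,
            )
            rows.append(
                {"voi": lab, "name": atlas.label_names[lab],
                 "n_drug": len(x), "n_vehicle": len(y), "U": np.nan,
                 "p_raw": np.nan}
            )
            continue
        u, p = _mannwhitney(x, y)
        rows.append(
            {"voi": lab, "name": atlas.label_names[lab],
             "n_drug": len(x), "n_vehicle": len(y), "U": u, "p_raw": p,
             "median_drug": float(np.median(x)),
             "median_vehicle": float(np.median(y))}
        )
    df = pd.DataFrame(rows)
    m = int(df["p_raw"].notna().sum())
    df["m_family"] = m
    df["p_corrected"] = np.minimum(df["p_raw"] * m, 1.0)
    a1, a2, a3 = alpha_tiers

    def tier(row) -> str:
        p = row.get("p_corrected", np.nan)
        if not np.isfinite(p) or p >= a1:
            return "ns"
        n = 3 if p < a3 else (2 if p < a2 else 1)
        sign = "+" if row["median_drug"] > row["median_vehicle"] else "-"
        return sign * n

    df["direction"] = np.where(
        df.get("median_drug", np.nan) > df.get("median_vehicle", np.nan),
        "greater", "less",
    )
    df["tier"] = df.apply(tier, axis=1)
    df["metric"] = metric
    return df


def vehicle_cutoffs(
    vehicle_nm: NodeMetrics,
    pct: tuple[float, float, float] = (95.0, 2.5, 97.5),
) -> Cutoffs:
    """Percentile cutoffs of the vehicle k and c distributions (linear
    interpolation between order statistics)."""
    if vehicle_nm.n_nodes == 0:
        raise ValueError("vehicle metrics are empty")
    if vehicle_nm.n_nodes < 20:
        warnings.warn(
            "fewer than 20 vehicle nodes: percentile cutoffs are unstable",
            stacklevel=2,
        )
    k_pct, c_lo_pct, c_hi_pct = pct
    return Cutoffs(
        k_high=float(np.percentile(vehicle_nm.k, k_pct)),
        c_low=float(np.percentile(vehicle_nm.c, c_lo_pct)),
        c_high=float(np.percentile(vehicle_nm.c, c_hi_pct)),
    )


def classify_nodes(nm: NodeMetrics, cut: Cutoffs) -> np.ndarray:
    """Foci category code per node (see :data:`FOCI_CODES`).

    A node is high_k if k > k_high, high_c if c > c_high, both ->
    high_k_and_c; low_c (c < c_low) applies only when neither high label
    does.
    """
    high_k = nm.k > cut.k_high
    high_c = nm.c > cut.c_high
    low_c = nm.c < cut.c_low
    codes = np.zeros(nm.n_nodes, dtype=np.int16)
    codes[high_k] = FOCI_CODES["high_k"]
    codes[high_c] = FOCI_CODES["high_c"]
    codes[high_k & high_c] = FOCI_CODES["high_k_and_c"]
    codes[low_c & ~high_k & ~high_c] = FOCI_CODES["low_c"]
    return codes


def foci_map(
    nm: NodeMetrics, cut: Cutoffs, shape: tuple[int, int, int]
) -> np.ndarray:
    """Conjunction/disjunction map of high-k and high-c foci as an
    integer-coded 3D grid (0 outside the mask)."""
    codes = classify_nodes(nm, cut)
    out = np.zeros(shape, dtype=np.int16)
    x, y, z = nm.node_coords.T
    out[x, y, z] = codes
    return out


def kc_scatter_export(nm: NodeMetrics, atlas: VOIAtlas) -> pd.DataFrame:
    """Long-format (node, k, c, voi, cortical_flag) table for c-vs-k
    scatter plots grouped by cortical/subcortical membership."""
    labels = _labels_for(nm, atlas)
    if atlas.cortical:
        flag = np.array(
            [
                "cortical" if atlas.cortical.get(int(lab), False)
                else ("subcortical" if lab > 0 else "unknown")
                for lab in labels
            ]
        )
    else:
        warnings.warn("atlas carries no cortical attribute; nodes flagged "
                      "unknown", stacklevel=2)
        flag = np.full(labels.shape, "unknown")
    return pd.DataFrame(
        {
            "node": np.arange(nm.n_nodes),
            "k": nm.k,
            "c": nm.c,
            "voi": labels,
            "cortical_flag": flag,
        }
    )
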