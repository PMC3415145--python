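"""VOI statistics, vehicle-referenced cutoffs and foci classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phmrinet.anatomy import (
    Cutoffs,
    FOCI_CODES,
    classify_nodes,
    compare_voi,
    foci_map,
    kc_scatter_export,
    metric_to_map,
    vehicle_cutoffs,
    voi_profile,
)
from phmrinet.metrics import NodeMetrics
from phmrinet.synthetic import VOIAtlas


def atlas_1d(labels, cortical=None):
    """Atlas on an (n,1,1) grid with the given per-voxel labels."""
    grid = np.asarray(labels, dtype=np.int32).reshape(-1, 1, 1)
    present = sorted(set(labels) - {0})
    return VOIAtlas(
        label_grid=grid,
        label_names={l: f"voi_{l}" for l in present},
        voxel_size_mm=(1.0, 1.0, 1.0),
        cortical=cortical or {},
    )


def nm_1d(k, c=None):
    k = np.asarray(k)
    n = k.size
    coords = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
    c = np.zeros(n) if c is None else np.asarray(c, dtype=float)
    return NodeMetrics(k=k, c=c, node_coords=coords)


def exact_mannwhitney_p(x, y):
    """Brute-force two-sided p by enumerating all rank assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    mu = n1 * len(y) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMetricToMap:
    def test_constant_metric_fills_mask_only(self):
        nm = nm_1d(np.full(5, 3))
        out = metric_to_map(nm, (8, 1, 1), "k")
        assert np.array_equal(out[:5, 0, 0], np.full(5, 3.0))
        assert np.all(out[5:] == 0)

    def test_quartile_overlay_keeps_top_quarter(self):
        nm = nm_1d(np.arange(100))
        out = metric_to_map(nm, (100, 1, 1), "k", quartile_overlay=True)
        assert (out > 0).sum() == 25

    def test_round_trip_recovers_metric_vector(self):
        rng = np.random.default_rng(0)
        k = rng.integers(1, 50, 20)
        nm = nm_1d(k)
        out = metric_to_map(nm, (20, 1, 1), "k")
        x, y, z = nm.node_coords.T
        assert np.array_equal(out[x, y, z], k.astype(float))


class TestVoiProfile:
    def test_medians_and_rank_order(self):
        atlas = atlas_1d([1, 1, 1, 2, 2])
        nm = nm_1d([1, 2, 3, 10, 11])
        df = voi_profile(nm, atlas)
        assert df.loc[df.voi == 1, "median_k"].iloc[0] == 2.0
        assert df.loc[df.voi == 2, "median_k"].iloc[0] == 10.5
        assert df.loc[df.voi == 2, "rank_by_median_k"].iloc[0] == 1
        assert df.loc[df.voi == 1, "rank_by_median_k"].iloc[0] == 2

    def test_single_voi_rank_one(self):
        df = voi_profile(nm_1d([4, 5]), atlas_1d([1, 1]))
        assert df["rank_by_median_k"].tolist() == [1]

    def test_order_invariance(self):
        atlas = atlas_1d([1, 1, 2, 2])
        a = voi_profile(nm_1d([4, 8, 1, 3]), atlas)
        b = voi_profile(nm_1d([8, 4, 3, 1]), atlas)
        pd.testing.assert_frame_equal(a, b)


class TestCompareVoi:
    def test_identical_groups_all_ns(self):
        atlas = atlas_1d([1] * 6 + [2] * 6)
        k = np.array([3, 4, 5, 6, 7, 8] * 2)
        df = compare_voi(nm_1d(k), nm_1d(k), atlas, metric="k")
        assert (df["tier"] == "ns").all()

    def test_complete_separation_maximal_u(self):
        atlas = atlas_1d([1] * 200)
        drug = nm_1d(np.arange(1000, 1200))
        veh = nm_1d(np.arange(200))
        df = compare_voi(drug, veh, atlas, metric="k")
        assert df["U"].iloc[0] == 40_000
        assert df["tier"].iloc[0] == "+++"
        assert df["direction"].iloc[0] == "greater"

    def test_small_groups_match_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        atlas = atlas_1d([1] * 7)
        for _ in range(5):
            pool = rng.permutation(1000)[:14].astype(float)
            x, y = pool[:7], pool[7:]
            df = compare_voi(nm_1d(x), nm_1d(y), atlas, metric="k")
            p = exact_mannwhitney_p(x, y)
            assert df["p_raw"].iloc[0] == pytest.approx(p, abs=1e-9)

    def test_bonferroni_family_is_voi_count(self):
        atlas = atlas_1d([1] * 10 + [2] * 10 + [3] * 10)
        rng = np.random.default_rng(2)
        drug = nm_1d(rng.integers(0, 50, 30))
        veh = nm_1d(rng.integers(0, 50, 30))
        df = compare_voi(drug, veh, atlas, metric="k")
        assert (df["m_family"] == 3).all()
        assert np.allclose(
            df["p_corrected"], np.minimum(df["p_raw"] * 3, 1.0)
        )

    def test_tier_monotone_under_upward_shift(self):
        rng = np.random.default_rng(3)
        atlas = atlas_1d([1] * 40)
        veh = nm_1d(rng.integers(10, 30, 40))
        order = ["---", "--", "-", "ns", "+", "++", "+++"]
        last = 0
        for shift in (0, 5, 15, 40):
            drug = nm_1d(veh.k + shift)
            tier = compare_voi(drug, veh, atlas, metric="k")["tier"].iloc[0]
            assert order.index(tier) >= last
            last = order.index(tier)

    def test_tiny_voi_reported_ns_with_warning(self):
        atlas = atlas_1d([1, 2, 2, 2, 2])
        with pytest.warns(UserWarning, match="fewer than 2"):
            df = compare_voi(nm_1d([1, 2, 3, 4, 5]), nm_1d([5, 4, 3, 2, 1]),
                             atlas, metric="k")
        assert df.loc[df.voi == 1, "tier"].iloc[0] == "ns"


class TestCutoffs:
    def test_percentiles_linear_interpolation(self):
        nm = nm_1d(np.arange(1, 101), c=np.linspace(0.01, 1, 100))
        cut = vehicle_cutoffs(nm)
        assert cut.k_high == pytest.approx(95.05)
        assert cut.c_low == pytest.approx(np.percentile(nm.c, 2.5))
        assert cut.c_high == pytest.approx(np.percentile(nm.c, 97.5))

    def test_constant_clustering_degenerate(self):
        nm = nm_1d(np.arange(30), c=np.full(30, 0.4))
        with pytest.raises(ValueError, match="c_low"):
            vehicle_cutoffs(nm)

    def test_few_nodes_warns(self):
        nm = nm_1d(np.arange(10), c=np.linspace(0, 1, 10))
        with pytest.warns(UserWarning, match="unstable"):
            vehicle_cutoffs(nm)


class TestFociMap:
    cut = Cutoffs(k_high=10.0, c_low=0.2, c_high=0.6)

    @pytest.mark.parametrize(
        "k,c,expected",
        [
            (11, 0.7, "high_k_and_c"),
            (11, 0.4, "high_k"),
            (5, 0.7, "high_c"),
            (0, 0.1, "low_c"),
            (11, 0.1, "high_k"),  # high labels take precedence over low_c
            (5, 0.4, "none"),
        ],
    )
    def test_single_node_classification(self, k, c, expected):
        codes = classify_nodes(nm_1d([k], c=[c]), self.cut)
        assert codes[0] == FOCI_CODES[expected]

    def test_counts_match_per_node_oracle(self):
        rng = np.random.default_rng(9)
        k = rng.integers(0, 20, 200)
        c = rng.random(200)
        nm = nm_1d(k, c=c)
        codes = classify_nodes(nm, self.cut)
        for i in range(200):
            if k[i] > 10 and c[i] > 0.6:
                want = "high_k_and_c"
            elif k[i] > 10:
                want = "high_k"
            elif c[i] > 0.6:
                want = "high_c"
            elif c[i] < 0.2:
                want = "low_c"
            else:
                want = "none"
            assert codes[i] == FOCI_CODES[want]

    def test_map_places_codes_at_node_voxels(self):
        nm = nm_1d([11, 0], c=[0.7, 0.1])
        grid = foci_map(nm, self.cut, (4, 1, 1))
        assert grid[0, 0, 0] == FOCI_CODES["high_k_and_c"]
        assert grid[1, 0, 0] == FOCI_CODES["low_c"]
        assert grid[2, 0, 0] == 0


class TestKcScatter:
    def test_rows_and_cortical_grouping(self):
        atlas = atlas_1d([1, 1, 2, 2], cortical={1: True, 2: False})
        df = kc_scatter_export(nm_1d([1, 2, 3, 4], c=[0.1] * 4), atlas)
        assert len(df) == 4
        assert df["cortical_flag"].tolist() == [
            "cortical", "cortical", "subcortical", "subcortical"
        ]

    def test_missing_attribute_flags_unknown(self):
        atlas = atlas_1d([1, 1], cortical={})
        with pytest.warns(UserWarning, match="unknown"):
            df = kc_scatter_export(nm_1d([1, 2], c=[0, 0]), atlas)
        assert (df["cortical_flag"] == "unknown").all()

    def test_group_medians_match_direct_computation(self):
        atlas = atlas_1d([1, 1, 2, 2, 2], cortical={1: True, 2: False})
        nm = nm_1d([5, 7, 1, 2, 3], c=[0.5, 0.7, 0.1, 0.2, 0.3])
        df = kc_scatter_export(nm, atlas)
        med = df.groupby("cortical_flag")["k"].median()
        assert med["cortical"] == 6.0
        assert med["subcortical"] == 2.0
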