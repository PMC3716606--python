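"""Stock arithmetic, the equal-BD correction, and paired change statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socchrono import (
    cluster_changes,
    interval_stock,
    litter_stock,
    basal_areas,
    profile_stocks,
    summarize_changes,
)
from socchrono.schemas import CANONICAL_INTERVALS, ConfigurationError, DepthInterval
from socchrono.stocks import StockProfile, loss_partition


def _horizons(plot_id, c_bd_pairs):
    rows = []
    for iv, (c, bd) in zip(CANONICAL_INTERVALS, c_bd_pairs):
        rows.append(
            {"plot_id": plot_id, "top_m": iv.top_m, "bottom_m": iv.bottom_m,
             "c_pct": c, "bd_g_cm3": bd}
        )
    return pd.DataFrame(rows)


class TestIntervalStock:
    @pytest.mark.parametrize(
        "c_pct, bd, interval, expected",
        [
            (0.0, 1.3, DepthInterval(0.3, 0.6), 0.0),
            (2.0, 1.0, DepthInterval(0.0, 0.15), 30.0),
            (1.0, 1.5, DepthInterval(0.3, 0.6), 45.0),
        ],
    )
    def test_hand_values(self, c_pct, bd, interval, expected):
        assert interval_stock(c_pct, bd, interval) == pytest.approx(expected)

    def test_domain_errors(self):
        iv = DepthInterval(0.0, 0.15)
        with pytest.raises(ValueError):
            interval_stock(-0.1, 1.0, iv)
        with pytest.raises(ValueError):
            interval_stock(1.0, 0.0, iv)

    @settings(derandomize=True, max_examples=50)
    @given(
        c=st.floats(0.01, 10), bd=st.floats(0.3, 2.0),
        a=st.floats(0.1, 5), b=st.floats(0.1, 5),
    )
    def test_linear_in_concentration_and_bulk_density(self, c, bd, a, b):
        iv = DepthInterval(0.15, 0.3)
        base = interval_stock(c, bd, iv)
        assert interval_stock(a * c, bd, iv) == pytest.approx(a * base, rel=1e-12)
        assert interval_stock(c, b * bd, iv) == pytest.approx(b * base, rel=1e-12)


class TestProfileStocks:
    def test_uniform_profile_total(self):
        prof = profile_stocks(_horizons("F", [(1.0, 1.0)] * 5))
        for iv in CANONICAL_INTERVALS:
            assert prof[iv] == pytest.approx(100.0 * iv.thickness_m)
        assert prof.total == pytest.approx(120.0)
        assert prof.bd_source == "own"

    def test_reference_bd_scales_stock(self):
        own = profile_stocks(_horizons("R", [(2.0, 1.1)] + [(1.0, 1.3)] * 4))
        ref_bd = {iv: (1.0 if iv.top_m == 0 else 1.3) for iv in CANONICAL_INTERVALS}
        corr = profile_stocks(_horizons("R", [(2.0, 1.1)] + [(1.0, 1.3)] * 4), ref_bd)
        top = CANONICAL_INTERVALS[0]
        assert corr.bd_source == "reference"
        assert corr[top] == pytest.approx(own[top] / 1.1, rel=1e-12)
        for iv in CANONICAL_INTERVALS[1:]:
            assert corr[iv] == pytest.approx(own[iv], rel=1e-12)

    def test_identical_c_and_reference_bd_reproduces_forest(self):
        forest = profile_stocks(_horizons("F", [(2.0, 1.0)] * 5))
        ref_bd = {iv: 1.0 for iv in CANONICAL_INTERVALS}
        rubber = profile_stocks(_horizons("R", [(2.0, 1.4)] * 5), ref_bd)
        for iv in CANONICAL_INTERVALS:
            assert rubber[iv] == pytest.approx(forest[iv], rel=1e-12)

    def test_missing_reference_bd_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            profile_stocks(_horizons("R", [(1.0, 1.0)] * 5), {CANONICAL_INTERVALS[0]: 1.0})

    def test_total_matches_fine_repartition_oracle(self):
        """Brute force: split each interval into random sub-intervals with the
        same C and BD; the summed sub-stocks must equal the profile total."""
        rng = np.random.default_rng(11)
        pairs = [(rng.uniform(0.3, 4), rng.uniform(0.8, 1.6)) for _ in CANONICAL_INTERVALS]
        prof = profile_stocks(_horizons("F", pairs))
        brute = 0.0
        for iv, (c, bd) in zip(CANONICAL_INTERVALS, pairs):
            cuts = np.sort(rng.uniform(iv.top_m, iv.bottom_m, 3))
            edges = np.r_[iv.top_m, cuts, iv.bottom_m]
            for a, b in zip(edges, edges[1:]):
                brute += interval_stock(c, bd, DepthInterval(a, b))
        assert brute == pytest.approx(prof.total, rel=1e-9)


def _flat_profile(plot_id, per_interval):
    return StockProfile(
        plot_id, {iv: v for iv, v in zip(CANONICAL_INTERVALS, per_interval)}, "own"
    )


class TestClusterChanges:
    def test_rubber_equal_forest_gives_zero(self):
        f = _flat_profile("F", [40, 40, 40, 40, 40])
        ch = cluster_changes(f, [_flat_profile("R", [40] * 5)])
        assert all(v == 0 for v in ch.absolute.values())
        assert ch.total_absolute == 0 and ch.total_relative == 0

    def test_single_rubber_hand_values(self):
        f = _flat_profile("F", [40] * 5)  # total 200
        r = _flat_profile("R", [32] * 5)  # total 160
        ch = cluster_changes(f, [r])
        assert ch.total_absolute == pytest.approx(-40.0)
        assert ch.total_relative == pytest.approx(-20.0)

    def test_mean_then_difference_order(self):
        f = _flat_profile("F", [40] * 5)  # total 200
        r1 = _flat_profile("R1", [30] * 5)  # 150
        r2 = _flat_profile("R2", [34] * 5)  # 170
        ch = cluster_changes(f, [r1, r2])
        assert ch.total_absolute == pytest.approx(-40.0)
        assert ch.total_relative == pytest.approx(-20.0)

    def test_invariant_to_rubber_plot_order(self):
        rng = np.random.default_rng(5)
        f = _flat_profile("F", rng.uniform(20, 60, 5))
        rs = [_flat_profile(f"R{i}", rng.uniform(10, 60, 5)) for i in range(3)]
        a = cluster_changes(f, rs)
        b = cluster_changes(f, rs[::-1])
        for iv in CANONICAL_INTERVALS:
            assert a.absolute[iv] == pytest.approx(b.absolute[iv])
        assert a.total_relative == pytest.approx(b.total_relative)

    def test_zero_forest_stock_flags_relative_missing(self):
        f = _flat_profile("F", [0, 40, 40, 40, 40])
        ch = cluster_changes(f, [_flat_profile("R", [10, 30, 30, 30, 30])])
        assert ch.relative[CANONICAL_INTERVALS[0]] is None
        assert ch.absolute[CANONICAL_INTERVALS[0]] == pytest.approx(10.0)


class TestSummaries:
    def test_identical_clusters_have_zero_se(self):
        f = _flat_profile("F", [40] * 5)
        r = _flat_profile("R", [30] * 5)
        changes = [cluster_changes(f, [r], cluster_id=i) for i in range(7)]
        s = summarize_changes(changes)
        assert (s["abs_se"].abs() < 1e-12).all()
        assert s.loc[s["interval"] == "total", "abs_mean"].iloc[0] == pytest.approx(-50.0)

    def test_se_hand_value(self):
        f = _flat_profile("F", [40] * 5)  # total 200
        totals = {-30: 34, -40: 32, -50: 30}  # per-interval stocks giving the totals
        changes = [
            cluster_changes(f, [_flat_profile("R", [v] * 5)], cluster_id=i)
            for i, v in enumerate(totals.values())
        ]
        s = summarize_changes(changes).set_index("interval")
        assert s.loc["total", "abs_mean"] == pytest.approx(-40.0)
        assert s.loc["total", "abs_se"] == pytest.approx(10 / math.sqrt(3), rel=1e-9)

    def test_loss_partition_shares(self):
        abs_changes = {iv: v for iv, v in zip(CANONICAL_INTERVALS, [-12, -8, -8, -6, -3])}
        part = loss_partition(abs_changes)
        assert part["top_share_pct"] == pytest.approx(100 * 12 / 37, rel=1e-9)
        assert part["top30_abs"] == pytest.approx(-20.0)


class TestLitterAndTrees:
    def test_zero_mass_gives_zero_stock(self):
        df = pd.DataFrame(
            {"plot_id": "P", "sample_id": range(10), "mass_g": 0.0,
             "frame_area_m2": 0.04, "c_pct": 40.0, "n_pct": 1.0}
        )
        assert litter_stock(df)["stock_mg_ha"] == 0.0

    def test_single_frame_hand_value(self):
        # 40 g C on 0.04 m^2 -> 1000 g C m^-2 -> 10 Mg C ha^-1
        df = pd.DataFrame(
            [{"plot_id": "P", "sample_id": 1, "mass_g": 100.0,
              "frame_area_m2": 0.04, "c_pct": 40.0, "n_pct": 1.0}]
        )
        assert litter_stock(df)["stock_mg_ha"] == pytest.approx(10.0)

    def test_replicated_constant_samples(self):
        df = pd.DataFrame(
            {"plot_id": "P", "sample_id": range(10), "mass_g": 100.0,
             "frame_area_m2": 0.04, "c_pct": 40.0, "n_pct": 1.0}
        )
        out = litter_stock(df)
        assert out["stock_mg_ha"] == pytest.approx(10.0)
        assert out["stock_se"] == pytest.approx(0.0, abs=1e-12)

    def test_bad_frame_area(self):
        df = pd.DataFrame(
            [{"plot_id": "P", "sample_id": 1, "mass_g": 10.0,
              "frame_area_m2": 0.0, "c_pct": 40.0, "n_pct": 1.0}]
        )
        with pytest.raises(ValueError):
            litter_stock(df)

    def test_basal_areas(self):
        empty = pd.DataFrame(columns=["plot_id", "stem_kind", "dbh_cm", "stems_in_clump"])
        assert basal_areas(empty, 400.0) == (0.0, 0.0)

        one_tree = pd.DataFrame(
            [{"plot_id": "P", "stem_kind": "tree", "dbh_cm": 20.0, "stems_in_clump": 1}]
        )
        tree_ba, total_ba = basal_areas(one_tree, 400.0)
        assert tree_ba == pytest.approx(math.pi * 0.01 * 25, rel=1e-12)
        assert total_ba == pytest.approx(tree_ba)

        clump = pd.DataFrame(
            [{"plot_id": "P", "stem_kind": "bamboo_clump", "dbh_cm": 5.0,
              "stems_in_clump": 10}]
        )
        tree_ba, total_ba = basal_areas(clump, 400.0)
        assert tree_ba == 0.0
        assert total_ba == pytest.approx(10 * math.pi * 6.25e-4 * 25, rel=1e-9)
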