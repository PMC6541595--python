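import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull

from cyclotrace.datamodel import DatasetMetadata, TrackingTable
from cyclotrace.motility import (
    classify_peripheral,
    colony_metrics,
    convex_hull_area,
    motility_summary,
    nuclear_area_summary,
    path_length,
)
from cyclotrace.survival import mann_whitney
from tests.conftest import make_records

META = DatasetMetadata()


def static_table(positions, n_frames=4, colony="C0", areas=None):
    """Table with each cell sitting at a fixed position for n_frames."""
    rows = []
    for i, (cid, (x, y)) in enumerate(positions.items()):
        for f in range(n_frames):
            rows.append({
                "cell_id": cid, "colony_id": colony, "condition": "2i+LIF",
                "frame": f, "time_h": f * 0.25, "x": x, "y": y,
                "nuclear_area": (areas or {}).get(cid, 100.0),
                "cherry": 1.0, "venus": 1.0, "parent_id": "",
            })
    return TrackingTable(df=pd.DataFrame(rows), metadata=META)


class TestPathLength:
    def test_open_unit_square_path(self):
        f = np.arange(4)
        x = np.array([0.0, 1, 1, 0])
        y = np.array([0.0, 0, 1, 1])
        assert path_length(f, x, y) == pytest.approx(3.0)

    def test_stationary_cell(self):
        f = np.arange(5)
        assert path_length(f, np.zeros(5), np.zeros(5)) == 0.0

    def test_single_point_warns_zero(self):
        with pytest.warns(UserWarning):
            assert path_length(np.array([0]), np.array([1.0]), np.array([2.0])) == 0.0

    def test_long_gap_splits_path(self):
        f = np.array([0, 1, 10, 11])
        x = np.array([0.0, 1.0, 100.0, 101.0])
        y = np.zeros(4)
        assert path_length(f, x, y) == pytest.approx(2.0)  # 99-unit jump dropped

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        f = np.arange(30)
        xy = rng.normal(size=(30, 2)).cumsum(axis=0)
        base = path_length(f, xy[:, 0], xy[:, 1])
        th = 1.1
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = xy @ rot.T + np.array([5.0, -3.0])
        assert path_length(f, moved[:, 0], moved[:, 1]) == pytest.approx(base)


class TestConvexHullArea:
    def test_unit_square(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        assert convex_hull_area(pts) == pytest.approx(1.0)

    def test_collinear_zero(self):
        pts = np.array([[0, 0], [1, 1], [2, 2.0], [3, 3]])
        assert convex_hull_area(pts) == 0.0

    def test_fewer_than_three_points(self):
        assert convex_hull_area(np.array([[1.0, 2.0]])) == 0.0
        assert convex_hull_area(np.array([[0, 0], [1.0, 1]])) == 0.0

    def test_matches_reference_hull_on_random_points(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            pts = rng.normal(size=(100, 2))
            ref = ConvexHull(pts).volume  # 2D: volume == area
            assert convex_hull_area(pts) == pytest.approx(ref, rel=1e-10)


def _square_trajectory_table(cc_l=4.0):
    rows = []
    # parent p frames 0..19 -> birth 5.125 h... use record table directly instead
    pos = [(0, 0), (1, 0), (1, 1), (0, 1)]
    for f in range(4):
        rows.append({
            "cell_id": "c", "colony_id": "C0", "condition": "2i+LIF",
            "frame": 20 + f, "time_h": (20 + f) * 0.25, "x": pos[f][0],
            "y": pos[f][1], "nuclear_area": 100.0, "cherry": 1.0,
            "venus": 1.0, "parent_id": "p",
        })
    table = TrackingTable(df=pd.DataFrame(rows), metadata=META)
    rec = make_records([{
        "cell_id": "c", "parent_id": "p", "generation": 2, "complete": True,
        "cc_l_h": cc_l, "birth_time_h": 5.0, "end_time_h": 5.0 + cc_l,
    }])
    return table, rec


class TestMotilitySummary:
    def test_square_trajectory_hand_values(self):
        table, rec = _square_trajectory_table(cc_l=4.0)
        out = motility_summary(rec, table).set_index("cell_id")
        assert out.at["c", "path_length"] == pytest.approx(3.0)
        assert out.at["c", "mean_speed"] == pytest.approx(0.75)
        assert out.at["c", "hull_area"] == pytest.approx(1.0)
        assert out.at["c", "exploration"] == pytest.approx(0.25)

    def test_doubling_cc_halves_normalized_metrics(self):
        t1, r1 = _square_trajectory_table(cc_l=4.0)
        t2, r2 = _square_trajectory_table(cc_l=8.0)
        o1 = motility_summary(r1, t1).iloc[0]
        o2 = motility_summary(r2, t2).iloc[0]
        assert o2["mean_speed"] == pytest.approx(o1["mean_speed"] / 2)
        assert o2["exploration"] == pytest.approx(o1["exploration"] / 2)

    def test_zero_motion_all_speeds_zero(self):
        table = static_table({"c": (3.0, 4.0)}, n_frames=6)
        df = table.df.copy()
        df["parent_id"] = "p"
        table = TrackingTable(df=df, metadata=META)
        rec = make_records([{
            "cell_id": "c", "parent_id": "p", "generation": 2, "complete": True,
            "cc_l_h": 2.0, "birth_time_h": 0.0, "end_time_h": 2.0,
        }])
        out = motility_summary(rec, table)
        assert (out["mean_speed"] == 0).all()
        assert (out["exploration"] == 0).all()

    def test_diff_moves_faster_than_ground(self, ground_table, diff_table):
        from cyclotrace.extraction import extract_records

        speeds = {}
        for cond, table in [("g", ground_table), ("d", diff_table)]:
            rec = extract_records(table)
            out = motility_summary(rec, table)
            speeds[cond] = out["mean_speed"].to_numpy()
        assert np.median(speeds["d"]) > np.median(speeds["g"])
        _, p = mann_whitney(speeds["g"], speeds["d"])
        assert p < 0.05


class TestColonyMetrics:
    def test_four_corner_colony(self):
        table = static_table({
            "a": (0, 0), "b": (1, 0), "c": (1, 1), "d": (0, 1),
        })
        out = colony_metrics(table)
        assert (out["colony_area"] == 1.0).all()
        assert (out["density"] == 4.0).all()
        assert (out["n_cells"] == 4).all()

    def test_single_cell_colony_density_undefined(self):
        out = colony_metrics(static_table({"a": (5, 5)}))
        assert (out["colony_area"] == 0.0).all()
        assert out["density"].isna().all()

    def test_diff_colony_area_grows_density_falls(self, diff_table):
        out = colony_metrics(diff_table)
        mean_t = out.groupby("time_h")[["colony_area", "density"]].mean()
        early = mean_t.loc[mean_t.index <= 10].mean()
        late = mean_t.loc[mean_t.index >= 35].mean()
        assert late["colony_area"] > early["colony_area"]
        assert late["density"] < early["density"]


class TestClassifyPeripheral:
    def test_corners_peripheral_center_not(self):
        table = static_table({
            "a": (0, 0), "b": (10, 0), "c": (10, 10), "d": (0, 10),
            "center": (5, 5),
        }, areas={k: 0.5 for k in "abcd"} | {"center": 0.5})
        flags = classify_peripheral(table, eps=0.5)
        assert flags[["a", "b", "c", "d"]].all()
        assert not flags["center"]

    def test_tiny_colony_everyone_peripheral(self):
        table = static_table({"a": (0, 0), "b": (1, 0), "c": (2.0, 0)})
        flags = classify_peripheral(table)
        assert flags.all()

    def test_trajectory_hull_within_colony_hull(self, ground_table):
        colony = colony_metrics(ground_table)
        from cyclotrace.extraction import extract_records

        rec = extract_records(ground_table)
        mot = motility_summary(rec, ground_table)
        max_colony_area = colony.groupby("colony_id")["colony_area"].max()
        for _, row in mot.iterrows():
            assert row["hull_area"] <= max_colony_area[row["colony_id"]] + 1e-6


class TestNuclearArea:
    def test_constant_area_mean(self):
        table = static_table({"a": (0, 0)}, areas={"a": 77.0})
        rec = make_records([{"cell_id": "a", "generation": 1}])
        out = nuclear_area_summary(table, rec)
        assert out.at[0, "mean_area"] == pytest.approx(77.0)

    def test_diff_nuclei_larger_at_generation_two(self, ground_table, diff_table):
        from cyclotrace.extraction import extract_records

        areas = {}
        for key, table in [("g", ground_table), ("d", diff_table)]:
            rec = extract_records(table)
            out = nuclear_area_summary(table, rec)
            areas[key] = out.loc[out["generation"] == 2, "mean_area"].to_numpy()
        _, p = mann_whitney(areas["g"], areas["d"])
        assert np.median(areas["d"]) > np.median(areas["g"])
        assert p < 0.05
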