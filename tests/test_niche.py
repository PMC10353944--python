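"""Section geometry: border distances, marker panels, bands, region counts."""

import numpy as np
import pandas as pd
import pytest

from nichemech.niche import (
    classify_cell,
    count_in_regions,
    distance_to_border,
    filter_band,
    labeling_efficiency,
    make_polyline,
    per_animal_distance_summary,
)


def dense_oracle(point, vertices, n=100_000):
    """Brute-force minimum distance to densely sampled polyline points."""
    from shapely.geometry import LineString

    line = LineString(vertices)
    ts = np.linspace(0, line.length, n)
    pts = np.array([line.interpolate(t).coords[0] for t in ts])
    return np.sqrt(((pts - np.asarray(point)) ** 2).sum(axis=1)).min()


class TestDistanceToBorder:
    def test_point_on_segment(self):
        assert distance_to_border((5.0, 0.0), [(0, 0), (10, 0)]) == 0.0

    def test_perpendicular_distance(self):
        assert distance_to_border((5.0, 3.0), [(0, 0), (10, 0)]) == pytest.approx(3.0)

    def test_matches_dense_sampling_oracle(self, rng):
        for _ in range(20):
            verts = rng.uniform(0, 100, size=(5, 2))
            point = rng.uniform(-20, 120, size=2)
            mine = distance_to_border(point, verts)
            extent = np.ptp(verts, axis=0).max()
            assert abs(mine - dense_oracle(point, verts, 20_000)) <= 1e-3 * extent

    def test_rigid_transform_invariance(self, rng):
        verts = rng.uniform(0, 50, size=(4, 2))
        point = rng.uniform(0, 50, size=2)
        base = distance_to_border(point, verts)
        theta = 1.1
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        shift = np.array([30.0, -12.0])
        assert distance_to_border(
            point @ rot.T + shift, verts @ rot.T + shift
        ) == pytest.approx(base, abs=1e-9)

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(ValueError):
            make_polyline([(0, 0)])
        with pytest.raises(ValueError):
            make_polyline([(0, 0), (0, 0)])

    def test_non_finite_point_rejected(self):
        with pytest.raises(ValueError):
            distance_to_border((np.nan, 0.0), [(0, 0), (1, 0)])


class TestClassifyCell:
    @pytest.mark.parametrize(
        "panel, flags, expected",
        [
            ("GFAP/Ki67", {"GFAP": True, "Ki67": False}, "qNSC/astrocyte"),
            ("GFAP/Ki67", {"GFAP": True, "Ki67": True}, "aNSC"),
            ("GFAP/Ki67", {"GFAP": False, "Ki67": True}, "unclassified"),
            ("S100a6/Ki67", {"S100a6": True, "Ki67": False}, "qNSC"),
            ("S100a6/Ki67", {"S100a6": True, "Ki67": True}, "aNSC"),
            ("EdU/Ki67/DCX", {"EdU": True, "Ki67": False, "DCX": True}, "neuroblast"),
            ("EdU/Ki67/DCX", {"EdU": True, "Ki67": True, "DCX": True}, "neuroblast"),
            ("EdU/Ki67/DCX", {"EdU": True, "Ki67": True, "DCX": False}, "aNSC/NPC"),
            ("EdU/Ki67/DCX", {"EdU": False, "Ki67": True, "DCX": False}, "unclassified"),
        ],
    )
    def test_decision_tables(self, panel, flags, expected):
        assert classify_cell(flags, panel) == expected

    def test_vessel_adjacent_censored(self):
        flags = {"GFAP": True, "Ki67": False, "vessel_adjacent": True}
        assert classify_cell(flags, "GFAP/Ki67") == "censored"

    def test_missing_flag_rejected(self):
        with pytest.raises(KeyError):
            classify_cell({"GFAP": True}, "GFAP/Ki67")

    def test_unknown_panel_rejected(self):
        with pytest.raises(ValueError):
            classify_cell({"GFAP": True, "Ki67": False}, "nope")


class TestFilterBand:
    BORDER = [(0.0, 0.0), (100.0, 0.0)]

    def test_boundary_inclusive(self):
        cells = pd.DataFrame({"x": [50.0, 50.0, 50.0], "y": [50.0, 200.0, 200.1]})
        kept = filter_band(cells, self.BORDER, 200.0)
        assert kept["y"].tolist() == [50.0, 200.0]

    def test_idempotent(self, rng):
        cells = pd.DataFrame(
            {"x": rng.uniform(0, 100, 50), "y": rng.uniform(0, 400, 50)}
        )
        once = filter_band(cells, self.BORDER, 200.0)
        twice = filter_band(once, self.BORDER, 200.0)
        pd.testing.assert_frame_equal(once, twice)

    def test_matches_per_point_oracle(self, rng):
        verts = rng.uniform(0, 100, size=(4, 2))
        cells = pd.DataFrame(
            {"x": rng.uniform(-50, 150, 80), "y": rng.uniform(-50, 150, 80)}
        )
        kept = filter_band(cells, verts, 60.0)
        expected = [
            i
            for i, row in cells.iterrows()
            if distance_to_border((row.x, row.y), verts) <= 60.0
        ]
        assert list(kept.index) == expected


class TestCountInRegions:
    SQUARE = [(0, 0), (10, 0), (10, 10), (0, 10)]

    def test_no_cells(self):
        counts = count_in_regions(
            pd.DataFrame(columns=["x", "y"]), {"OB": self.SQUARE}
        )
        assert counts == {"OB": 0}

    def test_cells_inside_single_region(self):
        cells = pd.DataFrame({"x": np.full(10, 5.0), "y": np.linspace(1, 9, 10)})
        far = [(100, 100), (110, 100), (110, 110), (100, 110)]
        counts = count_in_regions(cells, {"OB": self.SQUARE, "RMS": far})
        assert counts == {"OB": 10, "RMS": 0}

    def test_boundary_counts_inside(self):
        cells = pd.DataFrame({"x": [0.0, 10.0], "y": [5.0, 10.0]})
        assert count_in_regions(cells, {"r": self.SQUARE}) == {"r": 2}

    def test_convex_half_plane_oracle(self, rng):
        """Counts in a convex polygon match the all-half-planes test."""
        poly = np.array([(0, 0), (20, 0), (25, 15), (10, 25), (-5, 12)], float)
        cells = pd.DataFrame(
            {"x": rng.uniform(-10, 30, 200), "y": rng.uniform(-10, 30, 200)}
        )
        counts = count_in_regions(cells, {"p": poly})
        inside = np.ones(len(cells), bool)
        pts = cells[["x", "y"]].to_numpy()
        for a, b in zip(poly, np.roll(poly, -1, axis=0)):
            edge = b - a
            rel = pts - a
            inside &= edge[0] * rel[:, 1] - edge[1] * rel[:, 0] >= -1e-12
        assert counts["p"] == int(inside.sum())

    def test_overlapping_regions_warn_and_double_count(self):
        cells = pd.DataFrame({"x": [5.0], "y": [5.0]})
        shifted = [(3, 3), (13, 3), (13, 13), (3, 13)]
        with pytest.warns(UserWarning):
            counts = count_in_regions(
                cells, {"a": self.SQUARE, "b": shifted}
            )
        assert counts == {"a": 1, "b": 1}


class TestSummariesAndEfficiency:
    def test_single_animal_mean_distance(self):
        cells = pd.DataFrame(
            {"x": [0.0, 0.0], "y": [10.0, 20.0], "animal": ["m1", "m1"],
             "group": ["young", "young"], "cell_type": ["qNSC", "qNSC"]}
        )
        res = per_animal_distance_summary(cells, [(-10, 0), (10, 0)])
        assert res["animal_means"]["distance"].iloc[0] == pytest.approx(15.0)

    def test_identical_groups_p1(self):
        rows = []
        for group in ("young", "old"):
            for a in range(4):
                rows.append(
                    {"x": 0.0, "y": 10.0 + a, "animal": f"{group}{a}",
                     "group": group, "cell_type": "qNSC"}
                )
        res = per_animal_distance_summary(pd.DataFrame(rows), [(-10, 0), (10, 0)])
        assert res["comparisons"]["qNSC"].pvalue == pytest.approx(1.0)

    def test_labeling_efficiency_fixture(self):
        cells = pd.DataFrame(
            {"EdU": [True] * 30 + [False] * 90, "Ki67": [True] * 120}
        )
        assert labeling_efficiency(cells) == pytest.approx(0.25)

    def test_labeling_efficiency_extremes(self):
        all_pos = pd.DataFrame({"EdU": [True] * 5, "Ki67": [True] * 5})
        assert labeling_efficiency(all_pos) == 1.0
        none = pd.DataFrame({"EdU": [False] * 5, "Ki67": [True] * 5})
        assert labeling_efficiency(none) == 0.0

    def test_zero_denominator_rejected(self):
        cells = pd.DataFrame({"EdU": [True], "Ki67": [False]})
        with pytest.raises(ValueError):
            labeling_efficiency(cells)
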