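"""Efficiency computation, calibration inversion, and adhesion segmentation."""

import numpy as np
import pandas as pd
import pytest

from nichemech.fret import (
    AdhesionSet,
    CalibrationCurve,
    compare_groups_force,
    compute_efficiency,
    force_from_efficiency,
    match_adhesions,
    profile_cell,
    segment_adhesions,
)
from nichemech.synth import SimConfig, simulate_tension_images


class TestCalibration:
    def test_node_round_trip(self, cal):
        assert np.allclose(
            cal.force_at(cal.efficiency_at(cal.forces)), cal.forces, atol=1e-12
        )

    def test_midpoint_linear_interpolation(self, cal):
        e_mid = (cal.efficiencies[0] + cal.efficiencies[1]) / 2
        f_mid = (cal.forces[0] + cal.forces[1]) / 2
        assert cal.force_at(e_mid) == pytest.approx(f_mid, abs=1e-12)

    def test_clamping(self, cal):
        assert cal.force_at(1.0) == 0.0  # above resting efficiency
        assert cal.force_at(0.0) == cal.f_max

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            CalibrationCurve([0, 1, 2], [0.9, 0.95, 0.5])
        with pytest.raises(ValueError):
            CalibrationCurve([0, 2, 1], [0.9, 0.5, 0.3])

    def test_csv_round_trip(self, cal, tmp_path):
        path = tmp_path / "cal.csv"
        pd.DataFrame(
            {"force_pN": cal.forces, "efficiency": cal.efficiencies}
        ).to_csv(path, index=False)
        loaded = CalibrationCurve.from_csv(path)
        assert np.array_equal(loaded.forces, cal.forces)
        assert np.array_equal(loaded.efficiencies, cal.efficiencies)


class TestComputeEfficiency:
    @pytest.mark.parametrize(
        "donor, acceptor, expected",
        [
            (10.0, 0.0, 0.0),  # no acceptor signal
            (0.0, 10.0, 1.0),  # no donor signal
            (10.0, 10.0, 0.5),  # balanced channels
        ],
    )
    def test_pointwise_formula(self, donor, acceptor, expected):
        emap = compute_efficiency(
            np.full((2, 2), donor), np.full((2, 2), acceptor)
        )
        assert np.allclose(emap.values, expected)

    def test_background_and_bleedthrough_correction(self):
        # D' = 100, A' = 200 - 50 - 0.1*100 = 140; E = 140/(140+2*100)
        emap = compute_efficiency(
            np.full((1, 1), 150.0),
            np.full((1, 1), 200.0),
            bg_donor=50.0,
            bg_acceptor=50.0,
            bleedthrough=0.1,
            detection_ratio=2.0,
        )
        assert emap.values[0, 0] == pytest.approx(140 / 340)

    def test_intensity_floor_marks_invalid(self):
        donor = np.array([[100.0, 1.0]])
        acceptor = np.array([[100.0, 1.0]])
        emap = compute_efficiency(donor, acceptor, intensity_floor=50.0)
        assert emap.valid.tolist() == [[True, False]]
        assert np.isnan(emap.values[0, 1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_efficiency(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_all_invalid_warns(self):
        with pytest.warns(UserWarning):
            emap = compute_efficiency(
                np.ones((2, 2)), np.ones((2, 2)), intensity_floor=100.0
            )
        assert not emap.valid.any()


class TestForceFromEfficiency:
    def test_monotonicity(self, cal):
        """Pointwise lower efficiency can never give lower force."""
        e = np.linspace(0.0, 1.0, 101).reshape(1, -1)
        from nichemech.fret import EfficiencyMap

        fmap = force_from_efficiency(
            EfficiencyMap(e, np.ones_like(e, bool)), cal
        )
        assert np.all(np.diff(fmap.values[0]) <= 1e-12)

    def test_uniform_high_efficiency_gives_zero_force(self, cal):
        from nichemech.fret import EfficiencyMap

        e = np.full((4, 4), 1.0)
        fmap = force_from_efficiency(EfficiencyMap(e, np.ones_like(e, bool)), cal)
        assert np.all(fmap.values == 0.0)

    def test_threshold_consistency(self, cal):
        """Thresholding force at F_t equals thresholding E at cal(F_t)."""
        from nichemech.fret import EfficiencyMap

        rng = np.random.default_rng(0)
        e = rng.uniform(0.2, 0.88, size=(30, 30))
        emap = EfficiencyMap(e, np.ones_like(e, bool))
        fmap = force_from_efficiency(emap, cal)
        f_t = 3.0
        assert np.array_equal(
            fmap.values > f_t, e < cal.efficiency_at(f_t)
        )


def _uniform_force_map(shape, value, pixel_size=1.0):
    from nichemech.fret import ForceMap

    v = np.full(shape, float(value))
    return ForceMap(v, np.ones(shape, bool), pixel_size)


class TestSegmentation:
    def test_below_threshold_gives_empty_set(self):
        fmap = _uniform_force_map((20, 20), 1.0)
        adh = segment_adhesions(fmap, np.ones((20, 20), bool), 2.0, 1.0)
        assert len(adh) == 0

    def test_single_ellipse_recovered(self, cal):
        cfg = SimConfig(seed=3, noise=False, image_shape=(160, 160))
        imgs = simulate_tension_images(cfg, 1, adhesions_per_cell=1)
        emap = compute_efficiency(
            imgs.donor, imgs.acceptor, 100.0, 100.0,
            intensity_floor=1000.0, pixel_size=cfg.pixel_size,
        )
        fmap = force_from_efficiency(emap, cal)
        adh = segment_adhesions(
            fmap, imgs.cell_mask, float(cal.force_at(0.8)), 0.5
        )
        assert len(adh) == 1
        gt_mask = imgs.gt_labels == 1
        det_mask = adh.labels == 1
        assert (gt_mask & det_mask).sum() >= 0.9 * gt_mask.sum()

    def test_bridged_adhesions_split_by_watershed(self):
        """Two plateaus joined by a 1-px bridge: split when asked."""
        force = np.zeros((40, 60))
        force[15:25, 10:22] = 8.0
        force[15:25, 28:40] = 5.0
        force[19, 22:28] = 3.0  # 1-px-high bridge above threshold
        from nichemech.fret import ForceMap

        fmap = ForceMap(force, np.ones_like(force, bool))
        mask = np.ones_like(force, bool)
        merged = segment_adhesions(fmap, mask, 2.0, 1.0, split=False)
        split = segment_adhesions(fmap, mask, 2.0, 1.0, split=True)
        assert len(merged) == 1
        assert len(split) == 2

    def test_labels_disjoint_and_inside_mask(self, cal):
        cfg = SimConfig(seed=11, noise=True, image_shape=(300, 300))
        imgs = simulate_tension_images(cfg, 4, adhesions_per_cell=3)
        emap = compute_efficiency(
            imgs.donor, imgs.acceptor, 100.0, 100.0,
            intensity_floor=1000.0, pixel_size=cfg.pixel_size,
        )
        fmap = force_from_efficiency(emap, cal)
        adh = segment_adhesions(
            fmap, imgs.cell_mask, float(cal.force_at(0.8)), 0.5
        )
        assert np.all(imgs.cell_mask[adh.labels > 0] > 0)
        # every labeled pixel belongs to exactly one adhesion by construction
        assert set(np.unique(adh.labels)) == set(range(len(adh) + 1))

    def test_min_area_must_be_positive(self):
        fmap = _uniform_force_map((10, 10), 5.0)
        with pytest.raises(ValueError):
            segment_adhesions(fmap, np.ones((10, 10), bool), 1.0, 0.0)


def _adhesion_set(rows, cell_ids=frozenset({1})):
    table = pd.DataFrame(
        rows,
        columns=["label", "cell_id", "area_px", "area_um2", "mean_force_pN"],
    )
    return AdhesionSet(np.zeros((1, 1), np.int32), table, 1.0, cell_ids)


class TestProfileCell:
    def test_weighted_means(self):
        """10 px @ 4 pN and 30 px @ 8 pN: pixel-weighted 7, unweighted 6."""
        adh = _adhesion_set(
            [
                {"label": 1, "cell_id": 1, "area_px": 10, "area_um2": 10.0,
                 "mean_force_pN": 4.0},
                {"label": 2, "cell_id": 1, "area_px": 30, "area_um2": 30.0,
                 "mean_force_pN": 8.0},
            ]
        )
        assert profile_cell(adh, 1, "pixel").average_force_pN == pytest.approx(7.0)
        assert profile_cell(adh, 1, "adhesion").average_force_pN == pytest.approx(6.0)

    def test_uniform_single_adhesion(self):
        adh = _adhesion_set(
            [{"label": 1, "cell_id": 1, "area_px": 20, "area_um2": 20.0,
              "mean_force_pN": 5.0}]
        )
        prof = profile_cell(adh, 1)
        assert prof.average_force_pN == pytest.approx(5.0)
        assert prof.force_producing

    def test_cell_without_adhesions(self):
        adh = _adhesion_set([], cell_ids=frozenset({1, 2}))
        prof = profile_cell(adh, 2)
        assert not prof.force_producing
        assert prof.average_force_pN is None
        assert prof.total_area_um2 == 0.0

    def test_unknown_cell_rejected(self):
        adh = _adhesion_set([], cell_ids=frozenset({1}))
        with pytest.raises(KeyError):
            profile_cell(adh, 99)


class TestCompareGroups:
    def _profiles(self, forces_by_group, prevalence=None):
        rows = []
        for group, forces in forces_by_group.items():
            for i, f in enumerate(forces):
                rows.append(
                    {"cell_id": f"{group}{i}", "group": group,
                     "animal": f"{group}-a{i % 3}",
                     "average_force_pN": f, "force_producing": f is not None}
                )
        return pd.DataFrame(rows)

    def test_identical_groups_p1(self):
        profiles = self._profiles(
            {"young": [3.0, 4.0, 5.0, 6.0, 7.0, None],
             "old": [3.0, 4.0, 5.0, 6.0, 7.0, None]}
        )
        rep = compare_groups_force(profiles)
        assert rep["force_mwu"].pvalue == pytest.approx(1.0)
        assert rep["prevalence_fisher"].pvalue == pytest.approx(1.0)

    def test_all_producing_in_both_groups_is_degenerate_p1(self):
        profiles = self._profiles(
            {"young": [3.0, 4.0, 5.0], "old": [3.0, 4.0, 5.0]}
        )
        rep = compare_groups_force(profiles)
        assert rep["prevalence_fisher"].pvalue == 1.0
        assert "degenerate" in rep["prevalence_fisher"].method

    def test_equal_proportions_fisher_p1(self):
        profiles = self._profiles(
            {"young": [5.0] * 10 + [None] * 10, "old": [5.0] * 10 + [None] * 10}
        )
        rep = compare_groups_force(profiles)
        assert rep["prevalence_fisher"].pvalue == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        profiles = self._profiles({"young": [5.0], "old": [4.0]})
        profiles = profiles[profiles.group == "young"].copy()
        with pytest.raises(ValueError):
            compare_groups_force(profiles)


class TestMatchAdhesions:
    def test_perfect_match(self):
        labels = np.zeros((20, 20), np.int32)
        labels[2:6, 2:6] = 1
        labels[10:15, 10:15] = 2
        table = pd.DataFrame(
            [{"label": 1, "cell_id": 1, "area_px": 16},
             {"label": 2, "cell_id": 1, "area_px": 25}]
        )
        adh = AdhesionSet(labels, table, 1.0, frozenset({1}))
        ref = np.zeros_like(labels)
        ref[2:6, 2:6] = 7  # ids need not match
        ref[10:15, 10:15] = 9
        res = match_adhesions(adh, ref)
        assert res["precision"] == 1.0 and res["recall"] == 1.0
        assert np.allclose(res["pairs"]["iou"], 1.0)
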