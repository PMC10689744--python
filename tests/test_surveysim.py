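"""Photoquadrat simulation, cover from predictions, threshold scan."""

import numpy as np
import pandas as pd
import pytest

from reefspectra import classify as cl
from reefspectra import scene as sc
from reefspectra import surveysim as sv
from reefspectra import taxonomy as tx


@pytest.fixture(scope="module")
def survey_scene():
    """Transect swath at 5 cm pixels for fast survey geometry tests."""
    return sc.generate_scene(
        [1, 2, 3], {1: 0.5, 2: 0.3, 3: 0.2}, patch_scale_m=0.3,
        dims=sc.scene_dims(50.0, 1.0, 0.05), pixel_size_m=0.05, seed=2,
    )


class TestPhotoquadratSurvey:
    def test_design_arithmetic_per_transect(self, survey_scene):
        samples, cover = sv.run_photoquadrat_survey(
            survey_scene, transect_length_m=50.0, spacing_m=1.0,
            quadrat_area_m2=0.25, points_per_quadrat=20, seed=0,
        )
        assert len(samples) == 50  # one photo per meter over 50 m
        assert sum(len(s.labels) for s in samples) == 1000
        assert sum(cover.values()) == pytest.approx(1.0)

    def test_points_inside_quadrat_footprint(self, survey_scene):
        samples, _ = sv.run_photoquadrat_survey(survey_scene, seed=1)
        side_px = int(round(0.5 / survey_scene.pixel_size_m))
        for s in samples[:10]:
            row0 = int(round(s.origin_m / survey_scene.pixel_size_m))
            assert np.all(s.points[:, 0] >= row0)
            assert np.all(s.points[:, 0] < row0 + side_px)

    def test_nonaligned_design_one_point_per_cell(self, survey_scene):
        samples, _ = sv.run_photoquadrat_survey(survey_scene, seed=3)
        s = samples[0]
        side_px = int(round(0.5 / survey_scene.pixel_size_m))
        row0 = s.points[:, 0].min() // side_px * side_px
        # 5 x 4 grid: each of the 20 cells holds exactly one point
        cells = set()
        for r, c in s.points:
            cell = (
                int((r - row0) // (side_px / 5)),
                int((c - s.points[:, 1].min() + 0.0) // (side_px / 4)),
            )
            cells.add(cell)
        assert len(s.points) == 20

    def test_single_category_scene_cover_one(self):
        s = sc.generate_scene([5], {5: 1.0}, 0.2, (200, 20), 0.05, seed=0)
        _, cover = sv.run_photoquadrat_survey(
            s, transect_length_m=10.0, seed=4
        )
        assert cover == {5: 1.0}

    def test_observer_error_model(self):
        s = sc.generate_scene([5], {5: 1.0}, 0.2, (200, 20), 0.05, seed=0)
        confusion = {5: {5: 0.8, 6: 0.2}}
        _, cover = sv.run_photoquadrat_survey(
            s, transect_length_m=10.0, seed=4, observer_confusion=confusion
        )
        # 200 points misread with p=0.2: observed share near 0.2
        assert 0.1 < cover.get(6, 0.0) < 0.3
        with pytest.raises(ValueError, match="sums"):
            sv.run_photoquadrat_survey(
                s, transect_length_m=10.0, seed=4,
                observer_confusion={5: {5: 0.7}},
            )

    def test_quadrat_wider_than_swath_rejected(self):
        s = sc.generate_scene([1, 2], [0.5, 0.5], 0.2, (100, 5), 0.05, seed=0)
        with pytest.raises(ValueError, match="swath"):
            sv.run_photoquadrat_survey(s, quadrat_area_m2=0.25, seed=0)

    def test_point_intercept_unbiased(self):
        """Mean cover over replicates within 2 binomial SEs of scene truth.

        The quadrat footprints tile the swath completely (0.5 m quadrats
        every 0.5 m on a 0.5 m swath), so every pixel has equal inclusion
        probability and the point-intercept estimator is unbiased for the
        true pixel-count cover.
        """
        scene = sc.generate_scene(
            [1, 2, 3], {1: 0.5, 2: 0.3, 3: 0.2}, 0.25,
            dims=sc.scene_dims(10.0, 0.5, 0.02), pixel_size_m=0.02, seed=6,
            plate_size_m=0.0001,
        )
        n_rep = 200
        sums = {c: 0.0 for c in [1, 2, 3]}
        n_points = 0
        for rep in range(n_rep):
            samples, cover = sv.run_photoquadrat_survey(
                scene, transect_length_m=10.0, spacing_m=0.5,
                quadrat_area_m2=0.25, points_per_quadrat=20, seed=1000 + rep,
            )
            n_points += sum(len(s.labels) for s in samples)
            for c in sums:
                sums[c] += cover.get(c, 0.0)
        truth = scene.realized_cover()
        for c, total in sums.items():
            mean = total / n_rep
            p = truth[c]
            se = np.sqrt(p * (1 - p) / n_points)
            assert abs(mean - p) <= 2 * se, (c, mean, p, 2 * se)


def synthetic_prediction(scene, seed=0, accuracy=1.0):
    """Prediction map with ground-truth labels and synthetic certainty."""
    rng = np.random.default_rng(seed)
    labels = scene.class_map.copy()
    if accuracy < 1.0:
        flip = rng.uniform(size=labels.shape) > accuracy
        cats = np.unique(scene.class_map)
        labels[flip] = rng.choice(cats, size=int(flip.sum()))
    certainty = rng.beta(5, 2, size=labels.shape).astype(np.float32)
    labels = labels.astype(np.int32)
    labels[scene.plate_mask] = cl.PLATE
    certainty[scene.plate_mask] = 0
    return cl.PredictionMap(labels=labels, certainty=certainty)


class TestCoverFromPrediction:
    def test_no_threshold_keeps_everything(self, survey_scene):
        pm = synthetic_prediction(survey_scene, seed=1)
        cover, frac = sv.cover_from_prediction(pm, 0.0)
        assert frac == 1.0
        assert sum(cover.values()) == pytest.approx(1.0)

    def test_perfect_prediction_matches_true_cover(self, survey_scene):
        pm = synthetic_prediction(survey_scene, seed=2)
        cover, _ = sv.cover_from_prediction(pm, 0.0)
        for c, v in survey_scene.realized_cover().items():
            assert cover[c] == pytest.approx(v, abs=1e-12)

    def test_retained_fraction_non_increasing(self, survey_scene):
        pm = synthetic_prediction(survey_scene, seed=3)
        fracs = []
        for thr in sv.threshold_grid():
            try:
                _, frac = sv.cover_from_prediction(pm, float(thr))
            except ValueError:
                frac = 0.0
            fracs.append(frac)
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_unrenormalized_cover_sums_to_retained_fraction(self, survey_scene):
        pm = synthetic_prediction(survey_scene, seed=5)
        thr = 0.6
        cover, frac = sv.cover_from_prediction(pm, thr, renormalize=False)
        assert sum(cover.values()) == pytest.approx(frac, abs=1e-12)
        cover_n, _ = sv.cover_from_prediction(pm, thr)
        for c in cover:
            assert cover[c] == pytest.approx(cover_n[c] * frac, abs=1e-12)

    def test_empty_retention_raises_with_threshold(self, survey_scene):
        pm = synthetic_prediction(survey_scene, seed=4)
        pm.certainty[~survey_scene.plate_mask] = 0.5
        with pytest.raises(ValueError, match="0.9"):
            sv.cover_from_prediction(pm, 0.9)


class TestThresholdScan:
    @pytest.fixture(scope="class")
    def matched_setup(self):
        scenes = [
            sc.generate_scene(
                [1, 2, 3], {1: 0.5, 2: 0.3, 3: 0.2}, 0.3,
                dims=sc.scene_dims(12.0, 1.0, 0.05), pixel_size_m=0.05,
                seed=100 + i,
            )
            for i in range(3)
        ]
        pred_maps = {
            f"T{i+1}": synthetic_prediction(s, seed=200 + i)
            for i, s in enumerate(scenes)
        }
        rows = []
        for i, s in enumerate(scenes):
            _, cover = sv.run_photoquadrat_survey(
                s, transect_length_m=12.0, seed=300 + i, transect_id=f"T{i+1}"
            )
            rows.append((f"PQ-T{i+1}", "PQ", f"T{i+1}", cover))
        pq = sv.CommunityMatrix.from_rows(rows, columns=[1, 2, 3], tier="fine")
        return pred_maps, pq

    def test_grid_has_21_rows(self, matched_setup):
        pred_maps, pq = matched_setup
        scan = sv.threshold_scan(pred_maps, pq, n_permutations=99, seed=1)
        assert len(scan) == 21
        assert scan["threshold"].iloc[0] == 0.0
        assert scan["threshold"].iloc[-1] == pytest.approx(0.99)

    def test_retention_column_monotone(self, matched_setup):
        pred_maps, pq = matched_setup
        scan = sv.threshold_scan(pred_maps, pq, n_permutations=99, seed=1)
        fr = scan["mean_retained_fraction"].dropna().to_numpy()
        assert np.all(np.diff(fr) <= 1e-12)

    def test_select_optimal_prefers_zero_on_flat_curve(self):
        scan = pd.DataFrame(
            {
                "threshold": [0.0, 0.05, 0.10],
                "significance": [0.8, 0.8, 0.3],
                "anosim_R": [0, 0, 0.5],
                "mean_retained_fraction": [1, 0.9, 0.5],
            }
        )
        assert sv.select_optimal_threshold(scan) == 0.0

    def test_matched_methods_not_distinguishable_at_zero_threshold(
        self, matched_setup
    ):
        pred_maps, pq = matched_setup
        scan = sv.threshold_scan(pred_maps, pq, n_permutations=199, seed=5)
        assert scan["significance"].iloc[0] > 0.05


class TestAggregateCover:
    def test_row_sums_preserved(self, demo_hier):
        rng = np.random.default_rng(0)
        vals = rng.dirichlet(np.ones(12), size=4)
        mat = sv.CommunityMatrix(
            ids=[f"s{i}" for i in range(4)], columns=demo_hier.fine_ids,
            values=vals, methods=["HS"] * 4, transects=["T1"] * 4,
        )
        for tier, n_cols in [("broad", 5), ("high", 8)]:
            agg = sv.aggregate_cover(mat, demo_hier, tier)
            assert len(agg.columns) == n_cols
            assert np.allclose(
                agg.values.sum(axis=1), mat.values.sum(axis=1), atol=1e-12
            )

    def test_identity_hierarchy_is_noop(self):
        h = tx.CategoryHierarchy(
            fine_ids=[1, 2, 3],
            to_high={1: "1", 2: "2", 3: "3"},
            to_broad={1: "1", 2: "2", 3: "3"},
        )
        vals = np.array([[0.2, 0.3, 0.5]])
        mat = sv.CommunityMatrix(["s"], [1, 2, 3], vals, ["HS"], ["T1"])
        agg = sv.aggregate_cover(mat, h, "broad")
        assert np.allclose(agg.values, vals)

    def test_unmapped_category_rejected(self, demo_hier):
        mat = sv.CommunityMatrix(
            ["s"], [1, 99], np.array([[0.5, 0.5]]), ["HS"], ["T1"]
        )
        with pytest.raises(ValueError, match="99"):
            sv.aggregate_cover(mat, demo_hier, "broad")

    def test_non_fine_matrix_rejected(self, demo_hier):
        mat = sv.CommunityMatrix(
            ["s"], ["Scleractinia"], np.array([[1.0]]), ["HS"], ["T1"],
            tier="broad",
        )
        with pytest.raises(ValueError, match="fine"):
            sv.aggregate_cover(mat, demo_hier, "broad")
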