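"""The morphological segmentation pipeline and successive localization."""

import dataclasses

import numpy as np
import pytest

from mpsl4d import (ConfigurationError, IntensityRange, MPSLConfig,
                    NoTargetFoundError, PhaseVolume, Series4D, build_mask,
                    compute_trajectory, generate_phantom, label_regions,
                    overlap_metrics, segment_phase, segment_phase_with_seed,
                    segment_series, threshold_baseline)
from conftest import two_sphere_volume


def _small_config(**overrides):
    base = dict(
        tumor_range=IntensityRange(-150, 150),
        surround_range=IntensityRange(-150, 150),
        volume_min_cc=0.5,
        volume_max_cc=20.0,
        radius_mm=2.0,
        element_shape="ball",
    )
    base.update(overrides)
    return MPSLConfig(**base)


def _two_cube_volume():
    """Lung background with two tumor-HU cubes of different sizes."""
    vol = np.full((40, 40, 20), -800.0, dtype=np.float32)
    vol[5:13, 5:13, 5:13] = 0.0      # 8^3 voxels
    vol[25:31, 25:31, 5:11] = 0.0    # 6^3 voxels
    return PhaseVolume(vol, (2.0, 2.0, 2.5))


class TestBuildMask:
    def test_union_of_two_closed_intervals(self):
        vol = PhaseVolume(np.array([[[-75.0, 300.0, -100.0, 200.0, -101.0]]]),
                          (1, 1, 1))
        mask = build_mask(vol, IntensityRange(-100, 200), IntensityRange(-50, 50))
        assert mask.voxels.ravel().tolist() == [True, False, True, True, False]

    def test_disjoint_ranges_covering_nothing(self):
        vol = PhaseVolume(np.full((4, 4, 4), -800.0), (1, 1, 1))
        mask = build_mask(vol, IntensityRange(0, 50), IntensityRange(100, 150))
        assert mask.voxel_count == 0

    def test_equal_ranges_reduce_to_single_threshold_band(self):
        rng = np.random.default_rng(0)
        vol = PhaseVolume(rng.normal(0, 300, (6, 6, 6)), (1, 1, 1))
        r = IntensityRange(-50, 50)
        mask = build_mask(vol, r, r)
        expected = (vol.voxels >= -50) & (vol.voxels <= 50)
        assert np.array_equal(mask.voxels, expected)


class TestThresholdBaseline:
    def test_all_below_threshold_gives_empty_mask(self):
        vol = PhaseVolume(np.full((4, 4, 4), -1000.0), (1, 1, 1))
        assert threshold_baseline(vol, -83.0).voxel_count == 0

    def test_exactly_at_threshold_is_excluded(self):
        vol = PhaseVolume(np.array([[[-83.0, -82.9, -83.1]]]), (1, 1, 1))
        assert threshold_baseline(vol, -83.0).voxels.ravel().tolist() == \
            [False, True, False]

    def test_baseline_superset_of_tumor_band_above_threshold(self):
        vol = _two_cube_volume()
        baseline = threshold_baseline(vol, -83.0)
        tumor = build_mask(vol, IntensityRange(-50, 50), IntensityRange(-50, 50))
        assert not (tumor.voxels & ~baseline.voxels).any()


class TestConfigValidation:
    def test_volume_window_must_be_ordered(self):
        with pytest.raises(ConfigurationError):
            _small_config(volume_min_cc=5.0, volume_max_cc=1.0)

    def test_radius_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            _small_config(radius_mm=0.0)

    def test_intensity_range_ordering(self):
        with pytest.raises(ConfigurationError):
            IntensityRange(10, -10)

    def test_dict_round_trip(self):
        cfg = _small_config(seed_point=(3, 4, 5))
        back = MPSLConfig.from_dict(cfg.to_dict())
        assert back == cfg


class TestSegmentPhase:
    def test_recovers_baseline_sphere(self, baseline_case):
        case, series, truth, _ = baseline_case
        res = segment_phase(series.phases[0], case.config)
        m = overlap_metrics(truth[0], res.gtv_mask)
        assert m.dice >= 0.95

    def test_stage_monotonicity_and_window(self, baseline_case):
        case, series, truth, _ = baseline_case
        vol = series.phases[0]
        res = segment_phase(vol, case.config)
        stage1 = build_mask(vol, case.config.tumor_range,
                            case.config.surround_range)
        assert not (res.gtv_mask.voxels & ~stage1.voxels).any()
        assert res.diagnostics["post_erosion_voxels"] <= \
            res.diagnostics["mask_voxels"]
        selected = res.candidate_table.region(res.selected_label)
        assert case.config.volume_min_cc <= selected.volume_cc \
            <= case.config.volume_max_cc

    def test_result_is_single_connected_component(self, baseline_case):
        case, series, _, _ = baseline_case
        res = segment_phase(series.phases[0], case.config)
        assert label_regions(res.gtv_mask,
                             case.config.connectivity).n_regions == 1

    def test_rerun_is_voxel_identical(self):
        vol = _two_cube_volume()
        cfg = _small_config()
        a = segment_phase(vol, cfg)
        b = segment_phase(vol, cfg)
        assert np.array_equal(a.gtv_mask.voxels, b.gtv_mask.voxels)

    def test_empty_volume_raises_no_target(self):
        vol = PhaseVolume(np.full((10, 10, 10), -1000.0), (2, 2, 2.5))
        with pytest.raises(NoTargetFoundError) as exc:
            segment_phase(vol, _small_config())
        assert exc.value.candidate_table is not None

    def test_window_excluding_everything_raises_with_candidates(self):
        vol = _two_cube_volume()
        with pytest.raises(NoTargetFoundError) as exc:
            segment_phase(vol, _small_config(volume_min_cc=500.0,
                                             volume_max_cc=600.0))
        assert exc.value.candidate_table.n_regions >= 2

    def test_largest_survivor_wins_with_warning(self):
        vol = _two_cube_volume()
        with pytest.warns(UserWarning, match="largest"):
            res = segment_phase(vol, _small_config())
        # the 8^3 cube (vox 2x2x2.5 mm) is the larger candidate
        assert res.gtv_mask.voxels[8, 8, 8]
        assert not res.gtv_mask.voxels[27, 27, 8]

    def test_erosion_disconnects_wall_neck(self):
        # tumor cube joined to a thick slab by a thin one-voxel neck
        vol = np.full((40, 40, 16), -800.0, dtype=np.float32)
        vol[5:13, 5:13, 4:12] = 0.0       # tumor
        vol[30:40, 0:40, 0:16] = 0.0      # wall slab
        vol[13:30, 8, 8] = 0.0            # 1-voxel-thick neck
        pv = PhaseVolume(vol, (2.0, 2.0, 2.5))
        cfg = _small_config(radius_mm=3.0)
        mask = build_mask(pv, cfg.tumor_range, cfg.surround_range)
        assert label_regions(mask).n_regions == 1  # all merged pre-erosion
        res = segment_phase(pv, cfg)
        assert not res.gtv_mask.voxels[30:, :, :].any()
        assert res.gtv_mask.voxels[8, 8, 8]


class TestSeededSegmentation:
    def test_seed_outside_bounds_rejected(self):
        vol = _two_cube_volume()
        cfg = _small_config(seed_point=(100, 0, 0))
        with pytest.raises(ConfigurationError):
            segment_phase_with_seed(vol, cfg)

    def test_seed_neighborhood_brackets_tumor(self, noise_free_case):
        case, series, truth, _ = noise_free_case
        cfg = dataclasses.replace(case.config, seed_point=(60, 60, 32))
        res = segment_phase_with_seed(series.phases[0], cfg)
        m = overlap_metrics(truth[0], res.gtv_mask)
        assert m.dice >= 0.99

    def test_seed_consistency_with_unseeded_result(self, noise_free_case):
        case, series, _, _ = noise_free_case
        plain = segment_phase(series.phases[0], case.config)
        # an interior voxel of the unseeded result: its center-of-mass index
        idx = np.nonzero(plain.gtv_mask.voxels)
        seed = tuple(int(round(np.mean(c))) for c in idx)
        cfg = dataclasses.replace(case.config, seed_point=seed)
        seeded = segment_phase_with_seed(series.phases[0], cfg)
        assert np.array_equal(seeded.gtv_mask.voxels, plain.gtv_mask.voxels)

    def test_seed_in_uniform_background_finds_nothing(self, noise_free_case):
        case, series, _, _ = noise_free_case
        cfg = dataclasses.replace(case.config, seed_point=(5, 5, 32))
        with pytest.raises(NoTargetFoundError):
            segment_phase_with_seed(series.phases[0], cfg)

    def test_seed_selects_containing_region_among_survivors(self):
        vol = _two_cube_volume()
        cfg = _small_config(seed_point=(27, 27, 8))
        res = segment_phase_with_seed(vol, cfg)
        # the smaller cube contains the seed and must win over the larger
        assert res.gtv_mask.voxels[27, 27, 8]
        assert not res.gtv_mask.voxels[8, 8, 8]


class TestSegmentSeries:
    def test_tracks_moving_sphere_without_fallback(self, baseline_case):
        case, series, truth, _ = baseline_case
        results = segment_series(series, case.config)
        assert len(results) == 10
        assert not any(r.diagnostics.get("localization_fallback")
                       for r in results)
        for t, r in zip(truth, results):
            assert overlap_metrics(t, r.gtv_mask).dice >= 0.95

    def test_static_phantom_yields_identical_masks(self, noise_free_case):
        import mpsl4d.phantom_synth as ps

        case, _, _, _ = noise_free_case
        spec = dataclasses.replace(case.spec, motion=ps.Motion(kind="none"))
        series, _, _ = generate_phantom(spec)
        results = segment_series(series, case.config)
        first = results[0].gtv_mask.voxels
        assert all(np.array_equal(r.gtv_mask.voxels, first) for r in results[1:])

    def test_successive_localization_tracks_the_seeded_mover(self):
        # two equal-volume spheres; the seed selects the mover in phase 0
        # and the localization box must keep following it
        dz = [0, 2, 4, 6, 8, 10, 8, 6, 4, 2]
        phases = [two_sphere_volume(d, p * 10) for p, d in enumerate(dz)]
        series = Series4D(phases)
        cfg = _small_config(seed_point=(42, 42, 20),
                            localization_margin_mm=12.0)
        results = segment_series(series, cfg)
        traj = compute_trajectory(results, series.phase_labels)
        cogs = traj.cogs()
        assert np.allclose(cogs[:, 0], 85.0, atol=1.5)  # mover's x
        assert cogs[:, 2].max() - cogs[:, 2].min() == pytest.approx(10.0, abs=1.5)

    def test_failure_names_the_phase(self, noise_free_case):
        case, series, _, _ = noise_free_case
        cfg = dataclasses.replace(case.config, volume_min_cc=190.0,
                                  volume_max_cc=200.0)
        with pytest.raises(NoTargetFoundError, match="phase 0"):
            segment_series(series, cfg)


class TestTwoDimensionalMode:
    def test_slicewise_pipeline_recovers_sphere(self, noise_free_case):
        case, series, truth, _ = noise_free_case
        cfg = dataclasses.replace(case.config, mode="2d",
                                  volume_min_cc=0.5, volume_max_cc=8.0)
        res = segment_phase(series.phases[0], cfg)
        m = overlap_metrics(truth[0], res.gtv_mask)
        assert m.dice >= 0.95
        assert res.diagnostics["mode"] == "2d"

    def test_2d_no_survivor_raises(self):
        vol = PhaseVolume(np.full((10, 10, 4), -1000.0), (2, 2, 2.5))
        cfg = _small_config(mode="2d")
        with pytest.raises(NoTargetFoundError):
            segment_phase(vol, cfg)
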