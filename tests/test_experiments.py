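import numpy as np
import pandas as pd
import pytest

from brachytrack.errors import ConfigurationError
from brachytrack.experiments import (
    DOCUMENTED_OUTLIER_CELLS,
    DOCUMENTED_OUTLIER_SUMMARIES,
    DisplacementScan,
    PipelineConfig,
    ReferenceTables,
    SweepGrid,
    recompute_reference_metrics,
    run_collimator_sweep,
    run_displacement_scan,
    run_patient_scenario,
    track_source,
)
from brachytrack.geometry import SourceState
from brachytrack.recon import SIRTConfig, VolumeGrid
from brachytrack.transport import TransportConfig


@pytest.fixture(scope="module")
def tables():
    return ReferenceTables.load()


@pytest.fixture(scope="module")
def coarse_pipeline():
    """Fast end-to-end settings: 4 mm voxels, no up-sampling, noiseless."""
    return PipelineConfig(
        transport=TransportConfig(source_subsamples=1, emitted_photons=1e5),
        grid=VolumeGrid.centered(160.0, 4.0),
        upsample_factor=1,
        gaussian_sigma=0.6,
        sirt=SIRTConfig(iterations=3),
        threshold_fraction=0.3,
        refine_passes=0,
        noiseless=True,
    )


class TestReferenceTables:
    def test_shapes_and_labels(self, tables):
        assert len(tables.patient) == 19
        labels = list(tables.patient["label"])
        assert labels[0] == "Ovoid1_1" and labels[-1] == "Tandem_9"
        assert {len(f) for f in tables.solid_frames()} == {9}

    def test_every_distance_cell_recomputes_except_documented_misprints(self, tables):
        """Each printed distance matches sqrt(sum(delta^2)) of its own row to
        0.001; exactly the two documented printed-rounding outliers do not."""
        bad = []
        for frame in tables.solid_frames() + [tables.patient]:
            for res, printed in zip(
                tables._to_results(frame), frame["distance_printed"]
            ):
                if abs(res.euclidean_distance - printed) > 1e-3 + 1e-12:
                    bad.append((res.label, round(res.euclidean_distance, 3)))
        assert dict(bad) == DOCUMENTED_OUTLIER_CELLS

    def test_patient_positions_are_labelled_coordinates(self, tables):
        pos = tables.patient_positions()
        assert len(pos) == 19
        label, xyz = pos[10]
        assert label == "Tandem_1"
        np.testing.assert_allclose(xyz, [-0.129, 0.64, 55.0374])


class TestRecomputeReferenceMetrics:
    def test_report_passes_with_documented_outliers(self, tables):
        report = recompute_reference_metrics(tables)
        assert report["all_pass"]
        assert report["n_undocumented_mismatches"] == 0
        assert report["n_unique_solid_positions"] == 25

    def test_summary_values(self, tables):
        s = recompute_reference_metrics(tables)["summaries"]
        assert s["solid_mean_distance"]["recomputed_rounded"] == 1.146
        assert s["solid_mean_distance_excl_70_80"]["recomputed_rounded"] == 0.889
        assert s["patient_mean_distance"]["recomputed_rounded"] == 0.586
        assert s["solid_mean_abs_error_z"]["documented_outlier"]
        assert s["solid_mean_abs_error_z"]["recomputed_rounded"] == pytest.approx(
            DOCUMENTED_OUTLIER_SUMMARIES["solid_mean_abs_error_z"]
        )

    def test_perturbed_cell_fails_loudly(self, tables):
        corrupted = ReferenceTables(
            tables.solid_x.copy(),
            tables.solid_y.copy(),
            tables.solid_z.copy(),
            tables.patient.copy(),
        )
        corrupted.solid_x.loc[3, "distance_printed"] += 0.01
        report = recompute_reference_metrics(corrupted)
        assert not report["all_pass"]
        assert report["n_undocumented_mismatches"] >= 1


class TestSweepGrid:
    def test_default_grid_has_28_collimators(self):
        assert len(list(SweepGrid().collimators())) == 28

    def test_full_pitch_septum_rejected(self):
        with pytest.raises(ConfigurationError):
            SweepGrid(septal_thicknesses=(0.6,))

    def test_thick_septum_with_open_hole_allowed(self):
        grid = SweepGrid(septal_thicknesses=(0.5,))
        col = next(grid.collimators())
        assert col.hole_size_d == pytest.approx(0.1)


class TestDisplacementScan:
    def test_nine_positions_for_default_scan(self):
        scan = DisplacementScan(axis="y", step=10.0, max=80.0)
        pos = scan.positions()
        assert len(pos) == 9
        np.testing.assert_allclose(pos[0], [0, 0, 0])
        np.testing.assert_allclose(pos[-1], [0, 80, 0])

    def test_diagonal_direction_is_unit_yz(self):
        scan = DisplacementScan(axis="diagonal-yz", step=10.0, max=20.0)
        np.testing.assert_allclose(scan.positions()[1], [0, 10 / np.sqrt(2), 10 / np.sqrt(2)])

    @pytest.mark.parametrize("kwargs", [{"axis": "w"}, {"step": 0.0}, {"max": 25.0}])
    def test_invalid_scan_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            DisplacementScan(**{"axis": "y", "step": 10.0, "max": 80.0, **kwargs})


class TestCollimatorSweep:
    def test_sweep_table_layout_and_metrics(self):
        grid = SweepGrid(heights=(20.0, 30.0), septal_thicknesses=(0.3,))
        src = SourceState(exposure_time=5.0)
        cfg = TransportConfig(n_photons=100_000, rng_seed=0, ambient_background=2.0)
        table = run_collimator_sweep(grid, source=src, transport=cfg)
        assert len(table) == 4  # 2 heights x 2 profile directions
        assert set(table.columns) >= {"h", "t", "d", "direction", "fwhm_mm", "snr", "total_counts"}
        sub = table[table.direction == "vertical"].sort_values("h")
        assert np.all(np.isfinite(sub.fwhm_mm))

    def test_doubling_exposure_doubles_expected_counts(self):
        grid = SweepGrid(heights=(30.0,), septal_thicknesses=(0.3,))
        cfg = TransportConfig(n_photons=100_000, rng_seed=1)
        t1 = run_collimator_sweep(grid, source=SourceState(exposure_time=2.0), transport=cfg)
        t2 = run_collimator_sweep(grid, source=SourceState(exposure_time=4.0), transport=cfg)
        c1 = t1.total_counts.iloc[0]
        c2 = t2.total_counts.iloc[0]
        assert abs(c2 - 2 * c1) < 5 * np.sqrt(2 * c1 + 1) + 5 * np.sqrt(c2 + 1)


class TestPipelineCampaigns:
    def test_track_source_recovers_an_origin_source(self, coarse_pipeline, ring_layout):
        src = SourceState(diameter=1e-9, length=1e-9)
        result, images = track_source(coarse_pipeline, src)
        assert len(images) == 6
        assert result.euclidean_distance < 4.0  # one 4 mm voxel at the coarse grid

    def test_displacement_scan_rows(self, coarse_pipeline):
        scan = DisplacementScan(axis="y", step=20.0, max=40.0)
        table = run_displacement_scan(scan, coarse_pipeline)
        assert len(table) == 3 * 6  # positions x panels
        assert set(table.displacement_mm) == {0.0, 20.0, 40.0}
        assert np.all(np.isfinite(table.euclidean_distance))

    def test_patient_scenario_tracks_all_19_dwells(self, coarse_pipeline, tables):
        results = run_patient_scenario(coarse_pipeline, tables)
        assert [r.label for r in results] == list(tables.patient["label"])
        # every dwell position lies inside the default reconstruction volume
        extent = coarse_pipeline.grid.extent / 2
        for _, pos in tables.patient_positions():
            assert np.all(np.abs(pos) < extent)
        dists = [r.euclidean_distance for r in results]
        assert np.isfinite(dists).all()

    def test_campaign_rerun_is_bit_identical(self, ring_layout):
        cfg = PipelineConfig(
            transport=TransportConfig(n_photons=50_000, rng_seed=11),
            grid=VolumeGrid.centered(160.0, 4.0),
            upsample_factor=1,
            refine_passes=0,
            noiseless=False,
        )
        scan = DisplacementScan(axis="x", step=30.0, max=30.0)
        t1 = run_displacement_scan(scan, cfg)
        t2 = run_displacement_scan(scan, cfg)
        pd.testing.assert_frame_equal(t1, t2)
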