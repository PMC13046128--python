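"""Generator: geometry symmetry, placement, determinism, rendering, I/O."""

import numpy as np
import pandas as pd
import pytest
import tifffile

from cordpolar import synthdata as sd
from cordpolar.circstats import circular_mean
from cordpolar.detect import MARKERS
from cordpolar.imgproc import max_project

from conftest import small_config


class TestGeometry:
    def test_gray_mask_is_mirror_symmetric(self, small_geometry):
        mask = small_geometry.gray_mask
        assert (mask == mask[:, ::-1]).all()

    def test_canal_centroid_on_midline(self, small_geometry):
        w = small_geometry.gray_mask.shape[1]
        assert abs(small_geometry.canal_centroid[0] - (w - 1) / 2) <= 0.5

    def test_canal_disk_inside_gray(self, small_geometry):
        assert (small_geometry.canal_mask <= small_geometry.gray_mask).all()

    def test_oversized_canal_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.make_section_geometry(small_config(canal_radius_um=300.0))


class TestPlacement:
    def test_zero_count_population_is_empty(self, small_geometry, rng):
        spec = small_config().populations[0]
        spec = sd.PopulationSpec(spec.name, spec.markers, 0, spec.angular,
                                 spec.radial, spec.diameter_um)
        assert sd.sample_population(spec, small_geometry, 1.0, rng) == []

    def test_all_centroids_inside_gray_outside_canal(self, small_geometry, rng):
        for spec in small_config().populations:
            cells = sd.sample_population(spec, small_geometry, 1.0, rng)
            for c in cells:
                r, col = int(round(c.y_px)), int(round(c.x_px))
                assert small_geometry.gray_mask[r, col]
                assert not small_geometry.canal_mask[r, col]

    def test_same_seed_identical_sections(self):
        cfg = small_config(seed=42)
        a = sd.make_section(cfg)
        b = sd.make_section(cfg)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for m in MARKERS:
            assert (a.stacks[m].voxels == b.stacks[m].voxels).all()

    def test_von_mises_mean_recovered(self, small_geometry, rng):
        # Monte-Carlo tolerance from the circular SE at n=500, kappa=2
        spec = sd.PopulationSpec(
            "probe", ("GAD67",), 500,
            (sd.VonMisesComponent(315.0, 2.0),),
            sd.RadialLaw("uniform", 0.2, 0.8), (8.0, 12.0))
        cells = sd.sample_population(spec, small_geometry, 1.0, rng)
        mean = circular_mean([c.angle_deg for c in cells])
        assert abs((mean - 315.0 + 180.0) % 360.0 - 180.0) < 3.0

    def test_coexpression_counts_exact(self, small_geometry, rng):
        spec = sd.PopulationSpec(
            "pv", ("Parvalbumin",), 45,
            (sd.VonMisesComponent(0.0, 0.0),),
            sd.RadialLaw("uniform", 0.2, 0.8), (10.0, 14.0),
            coexpression={"GAD67": 0.30, "Calbindin": 0.20})
        cells = sd.sample_population(spec, small_geometry, 1.0, rng)
        n_gad = sum("GAD67" in c.markers for c in cells)
        n_cb = sum("Calbindin" in c.markers for c in cells)
        assert n_gad == round(0.30 * 45)
        assert n_cb == round(0.20 * 45)

    def test_retry_budget_exhaustion_raises(self, small_geometry, rng):
        # far more large cells than the small mask can hold apart
        spec = sd.PopulationSpec(
            "crowd", ("ChAT",), 500,
            (sd.VonMisesComponent(305.0, 4.0),),
            sd.RadialLaw("uniform", 0.4, 0.7), (30.0, 40.0))
        with pytest.raises(sd.PlacementError):
            sd.sample_population(spec, small_geometry, 1.0, rng,
                                 enforce_separation=True)


class TestRendering:
    def _one_cell_section(self):
        cfg = small_config(populations=(
            sd.PopulationSpec("solo", ("ChAT",), 1,
                              (sd.VonMisesComponent(0.0, 1.0),),
                              sd.RadialLaw("uniform", 0.3, 0.6),
                              (20.0, 20.0)),
        ))
        return sd.make_section(cfg), cfg

    def test_single_cell_single_component(self):
        from scipy import ndimage as ndi
        section, cfg = self._one_cell_section()
        proj = max_project(section.stacks["ChAT"])
        _, n = ndi.label(proj > cfg.background)
        assert n == 1

    def test_unflagged_channel_stays_at_background(self):
        section, cfg = self._one_cell_section()
        proj = max_project(section.stacks["GAD67"])
        assert proj.max() <= cfg.background

    @pytest.mark.parametrize("d_um", [10.0, 16.0, 24.0, 32.0, 40.0])
    def test_rendered_disk_area_close_to_analytic(self, d_um):
        cfg = small_config(populations=(
            sd.PopulationSpec("probe", ("ChAT",), 1,
                              (sd.VonMisesComponent(0.0, 1.0),),
                              sd.RadialLaw("uniform", 0.3, 0.5),
                              (d_um, d_um)),
        ))
        section = sd.make_section(cfg)
        proj = max_project(section.stacks["ChAT"])
        area = int((proj > cfg.background).sum())  # pixel_size = 1 um
        analytic = np.pi * (d_um / 2) ** 2
        assert abs(area - analytic) / analytic < 0.10


class TestFixtureIO:
    def test_round_trip(self, tmp_path):
        section = sd.make_section(small_config(seed=3))
        sd.write_fixture(section, tmp_path)
        stacks, geometry, truth = sd.read_fixture(tmp_path)
        for m in MARKERS:
            assert (stacks[m].voxels == section.stacks[m].voxels).all()
        assert (geometry.gray_mask == section.geometry.gray_mask).all()
        assert len(truth) == len(section.truth)

    def test_truth_csv_row_count(self, tmp_path):
        section = sd.make_section(small_config(seed=3))
        sd.write_fixture(section, tmp_path)
        truth = pd.read_csv(tmp_path / "truth.csv")
        assert len(truth) == len(section.truth)

    def test_missing_directory_raises(self, tmp_path):
        section = sd.make_section(small_config(seed=3))
        with pytest.raises(IOError):
            sd.write_fixture(section, tmp_path / "does_not_exist")

    def test_tiff_pages_are_z_planes(self, tmp_path):
        section = sd.make_section(small_config(seed=3))
        sd.write_fixture(section, tmp_path)
        voxels = tifffile.imread(tmp_path / "ChAT.tif")
        assert voxels.shape == section.stacks["ChAT"].voxels.shape
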