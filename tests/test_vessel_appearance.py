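import numpy as np
import pytest

import bluevein as bv
from bluevein.vessel_appearance import (
    ExperimentGrid,
    RoiPair,
    roi_mean_lab,
)


class TestNormalizeImageSet:
    def test_single_image_max_is_one(self):
        out = bv.normalize_image_set([np.array([[1.0, 2.0], [0.5, 4.0]])])
        assert out[0].max() == 1.0

    def test_global_maximum_shared(self):
        a = np.ones((2, 2))
        out = bv.normalize_image_set([a, 2 * a])
        assert out[1].max() == 1.0
        assert out[0].max() == 0.5

    def test_scalar_scaling_preserves_ratios(self):
        rng = np.random.default_rng(0)
        img = rng.random((4, 4, 3)) + 0.1
        (out,) = bv.normalize_image_set([img])
        np.testing.assert_allclose(
            out[..., 0] / out[..., 1], img[..., 0] / img[..., 1]
        )

    def test_all_zero_set_rejected(self):
        with pytest.raises(ValueError):
            bv.normalize_image_set([np.zeros((2, 2))])


class TestRoiPair:
    def test_disjoint_and_nonempty_enforced(self):
        m = np.zeros((4, 4), dtype=bool)
        v = m.copy()
        v[0, 0] = True
        with pytest.raises(ValueError):
            RoiPair(vein=v, tissue=m)  # empty tissue
        with pytest.raises(ValueError):
            RoiPair(vein=v, tissue=v)  # overlapping

    def test_default_rois_centered_and_offset(self, small_render, venous_scene):
        rois = bv.vein_tissue_rois(small_render, venous_scene)
        nx = rois.vein.shape[1]
        x = (
            small_render.image.origin[0]
            + (np.arange(nx) + 0.5) * small_render.image.pixel_pitch
        )
        assert np.all(np.abs(x[rois.vein[0]]) <= venous_scene.d / 4)
        assert np.all(
            np.abs(x[rois.tissue[0]] - 8.0) <= venous_scene.d / 4
        )


class TestRoiDeltaE:
    def test_render_vs_itself_is_zero(self, small_render, venous_scene):
        rois = bv.vein_tissue_rois(small_render, venous_scene)
        assert bv.roi_delta_e(small_render, small_render, rois.vein) == 0.0

    def test_symmetry(self, small_render, venous_scene, camera, light):
        other = bv.render_phantom(
            venous_scene,
            camera,
            light,
            small_render.image.wavelengths,
            n_photons_per_wavelength=60_000,
            seed=43,
        )
        rois = bv.vein_tissue_rois(small_render, venous_scene)
        assert bv.roi_delta_e(small_render, other, rois.vein) == (
            bv.roi_delta_e(other, small_render, rois.vein)
        )

    def test_known_homogeneous_lab_distance(self, small_render):
        # synthetic renders with uniform Lab values (50,0,0) vs (50,3,4)
        import copy

        a = copy.copy(small_render)
        b = copy.copy(small_render)
        ny, nx = small_render.lab.shape[:2]
        white = small_render.white_xyz
        # build XYZ fields that map exactly to the target Lab values
        from scipy.optimize import least_squares

        def xyz_for(lab_target):
            sol = least_squares(
                lambda v: bv.xyz_to_lab(v, white) - np.asarray(lab_target),
                white * 0.2,
            )
            return sol.x

        a.xyz = np.tile(xyz_for((50.0, 0.0, 0.0)), (ny, nx, 1))
        b.xyz = np.tile(xyz_for((50.0, 3.0, 4.0)), (ny, nx, 1))
        roi = np.zeros((ny, nx), dtype=bool)
        roi[2:5, 2:5] = True
        assert bv.roi_delta_e(a, b, roi) == pytest.approx(5.0, abs=1e-6)


class TestSpectralContrast:
    def test_null_cube_contrast_near_zero(self):
        rng = np.random.default_rng(1)
        data = 0.5 * (1 + 0.01 * rng.standard_normal((3, 16, 16)))
        cube = bv.HyperspectralCube(
            data=data, wavelengths=np.array([450.0, 550.0, 650.0]),
            pixel_pitch=1.0,
        )
        vein = np.zeros((16, 16), dtype=bool)
        vein[:, 6:10] = True
        tissue = np.zeros((16, 16), dtype=bool)
        tissue[:, 12:16] = True
        c = bv.spectral_contrast(cube, RoiPair(vein=vein, tissue=tissue))
        assert np.all(np.abs(c.values) < 0.01)

    def test_darkened_vein_gives_positive_contrast(self):
        data = np.full((2, 8, 8), 0.6)
        data[:, :, 3:5] = 0.3
        cube = bv.HyperspectralCube(
            data=data, wavelengths=np.array([500.0, 600.0]), pixel_pitch=1.0
        )
        vein = np.zeros((8, 8), dtype=bool)
        vein[:, 3:5] = True
        tissue = np.zeros((8, 8), dtype=bool)
        tissue[:, 6:8] = True
        c = bv.spectral_contrast(cube, RoiPair(vein=vein, tissue=tissue))
        np.testing.assert_allclose(c.values, 0.5)

    def test_zero_tissue_mean_rejected(self):
        data = np.zeros((1, 4, 4))
        data[:, :, 0] = 1.0
        cube = bv.HyperspectralCube(
            data=data, wavelengths=np.array([500.0]), pixel_pitch=1.0
        )
        vein = np.zeros((4, 4), dtype=bool)
        vein[:, 0] = True
        tissue = np.zeros((4, 4), dtype=bool)
        tissue[:, 2] = True
        with pytest.raises(ValueError):
            bv.spectral_contrast(cube, RoiPair(vein=vein, tissue=tissue))


class TestCrossSections:
    def test_profile_length_equals_image_width(self, small_render):
        cube = bv.make_hyperspectral_cube(small_render.image, noise_sigma=0)
        df = bv.cross_sections(cube, [450.0, 690.0])
        assert len(df) == small_render.image.weights.shape[2]
        assert set(df.columns) == {"x_mm", "450 nm", "690 nm"}

    def test_homogeneous_cube_flat_profiles(self):
        cube = bv.HyperspectralCube(
            data=np.full((1, 8, 8), 0.4),
            wavelengths=np.array([550.0]),
            pixel_pitch=1.0,
        )
        df = bv.cross_sections(cube, [550.0])
        np.testing.assert_allclose(df["550 nm"], 0.4)

    def test_out_of_range_wavelength_rejected(self, small_render):
        cube = bv.make_hyperspectral_cube(small_render.image, noise_sigma=0)
        with pytest.raises(ValueError):
            bv.cross_sections(cube, [900.0])


class TestHyperspectralCube:
    def test_noise_seed_reproducible(self, small_render):
        c1 = bv.make_hyperspectral_cube(small_render.image, seed=5)
        c2 = bv.make_hyperspectral_cube(small_render.image, seed=5)
        np.testing.assert_array_equal(c1.data, c2.data)

    def test_default_pitch_is_subhalf_millimetre(self, small_render):
        # 30 mm block over 64 pixels: just under half a millimetre per pixel
        assert small_render.image.pixel_pitch == pytest.approx(30 / 64)


class TestExperimentGrid:
    def test_default_grid_yields_16_scenes(self, media):
        grid = ExperimentGrid(
            tissue=media["tissue"],
            vessel_media={
                "venous": media["venous"],
                "arterial": media["arterial"],
            },
        )
        scenes = list(grid.scenes())
        assert len(scenes) == 16
        zs = {z for z, _, _, _ in scenes}
        ds = {d for _, d, _, _ in scenes}
        assert zs == {0.5, 1.0, 1.5, 2.0}
        assert ds == {2.0, 4.0}

    def test_invalid_grid_rejected(self, media):
        with pytest.raises(ValueError):
            ExperimentGrid(
                tissue=media["tissue"],
                vessel_media={"venous": media["venous"]},
                depths=(0.0,),
            )
        with pytest.raises(ValueError):
            ExperimentGrid(tissue=media["tissue"], vessel_media={})


class TestPropertySwapStudy:
    def test_structure_and_null_case(self, media, camera, light):
        scene = bv.VesselScene(
            tissue=media["tissue"],
            vessel=media["venous"],
            d=2.0,
            z=1.0,
            detector=bv.Detector(n_pixels=32),
        )
        cases = [
            ("same_as_base", media["venous"].props),
            ("no_absorption_vessel", bv.OpticalProperties.from_reduced(
                bv.Spectrum.constant(1e-6),
                media["venous"].props.mu_s_prime,
                g=media["venous"].props.g,
                n=media["venous"].props.n,
            )),
        ]
        wl = np.array([490.0, 570.0, 650.0])
        table = bv.property_swap_study(
            scene, cases, camera, light, wavelengths=wl,
            n_photons_per_wavelength=60_000, seed=21,
        )
        assert list(table["case"]) == [c[0] for c in cases]
        assert (table["delta_e_above_vein"] >= 0).all()
        null_de = table.loc[
            table["case"] == "same_as_base", "delta_e_above_vein"
        ].item()
        # identical optical properties re-rendered with the same seed
        assert null_de == pytest.approx(0.0, abs=1e-9)
        swap_de = table.loc[
            table["case"] == "no_absorption_vessel", "delta_e_above_vein"
        ].item()
        assert swap_de > null_de
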