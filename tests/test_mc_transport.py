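import math

import numpy as np
import pytest

import bluevein as bv
from bluevein.mc_transport import distance_to_scene_boundary
from bluevein.sphere_inversion import monochromatic_medium

from oracles import ray_march_cylinder_distance


def _nonscattering_medium(mu_a, n=1.0):
    return bv.Medium(
        "clear",
        bv.OpticalProperties.from_reduced(
            bv.Spectrum.constant(mu_a), bv.Spectrum.constant(0.0), g=0.0, n=n
        ),
    )


class TestRunSlab:
    def test_conservation_without_absorption(self):
        m = bv.Medium(
            "scat",
            bv.OpticalProperties.from_reduced(
                bv.Spectrum.constant(0.0),
                bv.Spectrum.constant(1.0),
                g=0.7,
                n=1.0,
            ),
        )
        r = bv.run_slab(bv.SlabSample(2.0, m), 550, 50_000, seed=1)
        sigma = math.hypot(r.se_R, r.se_T)
        assert abs(r.R_diffuse + r.T_diffuse - 1.0) < 3 * sigma + 1e-9

    def test_beer_lambert_limit(self):
        s = bv.SlabSample(1.0, _nonscattering_medium(1.0))
        r = bv.run_slab(s, 550, 200_000, seed=2)
        assert r.T_diffuse == pytest.approx(math.exp(-1.0), abs=3 * r.se_T)

    def test_seed_reproducibility(self):
        s = bv.SlabSample(2.0, monochromatic_medium(0.1, 1.0))
        a = bv.run_slab(s, 550, 20_000, seed=11)
        b = bv.run_slab(s, 550, 20_000, seed=11)
        c = bv.run_slab(s, 550, 20_000, seed=12)
        assert a.R_diffuse == b.R_diffuse and a.T_diffuse == b.T_diffuse
        assert a.R_diffuse != c.R_diffuse

    def test_standard_error_scales_inverse_sqrt_n(self):
        s = bv.SlabSample(2.0, monochromatic_medium(0.1, 1.0))
        ses = [
            bv.run_slab(s, 550, n, seed=4).se_R
            for n in (10_000, 100_000, 1_000_000)
        ]
        for k in range(2):
            ratio = ses[k] / ses[k + 1]
            assert 0.6 * math.sqrt(10) < ratio < 1.6 * math.sqrt(10)

    def test_transparent_mismatched_slab_rejected(self):
        s = bv.SlabSample(1.0, _nonscattering_medium(0.0, n=1.4))
        with pytest.raises(ValueError):
            bv.run_slab(s, 550, 10_000, seed=0)

    def test_minimum_photon_count_enforced(self):
        s = bv.SlabSample(1.0, monochromatic_medium(0.1, 1.0))
        with pytest.raises(ValueError):
            bv.run_slab(s, 550, 10, seed=0)


class TestRunSemiInfinite:
    def test_absorption_dominated_limit(self):
        med = monochromatic_medium(100.0, 1.0)
        r = bv.run_semi_infinite(med, 550, 20_000, seed=3)
        assert r.R_diffuse < 0.01

    def test_reflectance_monotone_in_absorption(self):
        Rs = [
            bv.run_semi_infinite(
                monochromatic_medium(mu_a, 1.0), 550, 30_000, seed=5
            ).R_diffuse
            for mu_a in (0.05, 0.1, 1.0)
        ]
        assert Rs[0] > Rs[1] > Rs[2]

    def test_zero_absorption_rejected(self):
        with pytest.raises(ValueError):
            bv.run_semi_infinite(
                monochromatic_medium(0.0, 1.0), 550, 10_000, seed=0
            )


class TestSceneGeometry:
    def test_vessel_must_fit_in_block(self):
        media = bv.default_phantom_media()
        with pytest.raises(ValueError):
            bv.VesselScene(
                tissue=media["tissue"], vessel=media["venous"], d=4.0, z=-0.5
            )
        with pytest.raises(ValueError):
            bv.VesselScene(
                tissue=media["tissue"], vessel=media["venous"], d=20.0, z=15.0
            )

    @pytest.mark.parametrize(
        "origin, direction",
        [
            ((0.0, 0.0, 2.0), (0.0, 0.0, 1.0)),  # inside, toward axis depth
            ((0.5, 1.0, 2.0), (0.6, 0.0, 0.8)),  # inside, oblique
            ((-3.0, 0.0, 0.5), (0.8, 0.0, 0.6)),  # outside, entering
        ],
    )
    def test_cylinder_distance_matches_ray_marcher(self, origin, direction):
        media = bv.default_phantom_media()
        scene = bv.VesselScene(
            tissue=media["tissue"], vessel=media["venous"], d=4.0, z=1.0
        )
        direction = np.asarray(direction) / np.linalg.norm(direction)
        d_analytic, which = distance_to_scene_boundary(
            scene, origin, direction
        )
        d_march = ray_march_cylinder_distance(
            origin, direction, 0.0, scene.axis_depth, scene.radius
        )
        if which == "cylinder":
            assert abs(d_analytic - d_march) < 1e-6
        else:
            # the nearest boundary is a block face before the cylinder
            assert d_march > d_analytic - 1e-6


class TestTracePhoton:
    def test_ballistic_photon_attenuates_beer_lambert(self):
        clear = _nonscattering_medium(0.5)
        scene = bv.VesselScene(
            tissue=clear, vessel=clear, d=2.0, z=1.0
        )
        state = bv.PhotonState(
            position=np.array([0.0, 0.0, 0.0]),
            direction=np.array([0.0, 0.0, 1.0]),
        )
        rec = bv.trace_photon(state, scene, np.random.default_rng(0))
        assert rec["event"] == "exit_bottom"
        np.testing.assert_allclose(rec["position"], [0, 0, 30.0], atol=1e-9)
        assert rec["weight"] == pytest.approx(math.exp(-0.5 * 30.0))

    def test_nonunit_direction_rejected(self):
        with pytest.raises(ValueError):
            bv.PhotonState(
                position=np.zeros(3), direction=np.array([0.0, 0.0, 2.0])
            )

    def test_high_attenuation_terminates_near_launch(self):
        dense = monochromatic_medium(500.0, 500.0)
        scene = bv.VesselScene(
            tissue=dense, vessel=dense, d=2.0, z=1.0
        )
        state = bv.PhotonState(
            position=np.array([0.0, 0.0, 1.0]),
            direction=np.array([0.0, 0.0, 1.0]),
        )
        rec = bv.trace_photon(state, scene, np.random.default_rng(1))
        assert rec["event"] == "absorbed"
        assert rec["path_length"] < 0.5


@pytest.fixture(scope="module")
def homogeneous_image():
    media = bv.default_phantom_media()
    scene = bv.VesselScene(
        tissue=media["tissue"],
        vessel=media["tissue"],  # vessel medium identical to tissue
        d=4.0,
        z=1.0,
        detector=bv.Detector(n_pixels=16),
    )
    return bv.render_scene(scene, [630.0], 400_000, seed=9)


class TestRenderScene:
    def test_homogeneous_scene_is_uniform_in_interior(self, homogeneous_image):
        # edge pixels are dimmer because photons leak through the block's
        # lateral faces; the interior must be uniform to counting error
        counts = homogeneous_image.weights[0][2:-2, 2:-2]
        mean = counts.mean()
        resid = np.abs(counts - mean)
        sigma = np.sqrt(np.maximum(counts, 1.0))  # upper bound: weights <= 1
        assert np.all(resid < 5 * sigma)
        assert resid.mean() < 2 * sigma.mean()

    def test_absorbing_vessel_casts_shadow(self, media):
        strong = bv.Medium(
            "ink",
            bv.OpticalProperties.from_reduced(
                bv.Spectrum(
                    media["tissue"].props.wavelengths_nm,
                    media["tissue"].props.mu_a.values * 100,
                ),
                media["tissue"].props.mu_s_prime,
                g=media["tissue"].props.g,
                n=media["tissue"].props.n,
            ),
        )
        scene = bv.VesselScene(
            tissue=media["tissue"], vessel=strong, d=4.0, z=0.5,
            detector=bv.Detector(n_pixels=32),
        )
        img = bv.render_scene(scene, [630.0], 200_000, seed=13)
        refl = img.reflectance()[0]
        x = img.origin[0] + (np.arange(32) + 0.5) * img.pixel_pitch
        central = refl[:, np.abs(x) < 1.5].mean()
        lateral = refl[:, np.abs(np.abs(x) - 9.0) < 1.5].mean()
        assert central < lateral

    def test_binning_refinement_preserves_roi_totals(self, media):
        kwargs = dict(
            tissue=media["tissue"], vessel=media["venous"], d=4.0, z=1.0
        )
        coarse = bv.render_scene(
            bv.VesselScene(detector=bv.Detector(n_pixels=32), **kwargs),
            [630.0], 100_000, seed=17,
        )
        fine = bv.render_scene(
            bv.VesselScene(detector=bv.Detector(n_pixels=64), **kwargs),
            [630.0], 100_000, seed=17,
        )
        # central half of the surface aligns with pixel edges in both grids
        assert coarse.weights[0][8:24, 8:24].sum() == pytest.approx(
            fine.weights[0][16:48, 16:48].sum(), rel=1e-12
        )

    def test_mirror_symmetry_of_illumination(self, media):
        # the two 45-degree beams are mirror images; with the cylinder on
        # the mirror plane the image must be statistically x-symmetric
        scene = bv.VesselScene(
            tissue=media["tissue"], vessel=media["venous"], d=4.0, z=1.0,
            detector=bv.Detector(n_pixels=16),
        )
        img = bv.render_scene(scene, [630.0], 400_000, seed=19)
        refl = img.reflectance()[0]
        left = refl[:, :8].sum()
        right = refl[:, 8:].sum()
        assert abs(left - right) / (left + right) < 0.05

    def test_zero_acceptance_detector_rejected(self):
        with pytest.raises(ValueError):
            bv.Detector(acceptance_deg=0.0)
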