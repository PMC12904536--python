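import numpy as np
import pytest

import bluevein as bv


@pytest.fixture(scope="session")
def media():
    """Default skin / venous / arterial phantom media."""
    return bv.default_phantom_media()


@pytest.fixture(scope="session")
def camera():
    return bv.make_camera_model()


@pytest.fixture(scope="session")
def light():
    return bv.make_led_illuminant()


@pytest.fixture(scope="session")
def venous_scene(media):
    return bv.VesselScene(
        tissue=media["tissue"], vessel=media["venous"], d=4.0, z=1.0
    )


@pytest.fixture(scope="session")
def small_render(venous_scene, camera, light):
    """A cheap 5-band render of the default venous scene, reused widely."""
    wavelengths = np.array([450.0, 510.0, 570.0, 630.0, 690.0])
    return bv.render_phantom(
        venous_scene,
        camera,
        light,
        wavelengths,
        n_photons_per_wavelength=60_000,
        seed=42,
    )
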