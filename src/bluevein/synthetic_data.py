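"""Synthetic optical-property, camera and illuminant models.

Generates every input the pipeline needs with the spectral structure of the
physical study: skin-like absorption (blood/melanin-shaped bands on a small
baseline) with a power-law reduced scattering coefficient; blood-like
absorption for venous (70 % oxygen saturation) and arterial (100 %)
states built from fixed analytic oxy-/deoxy-hemoglobin shapes (Soret-like
peak near 430 nm, the oxy 540/576 nm double band, the deoxy 555 nm single
band, and the large oxy-deoxy gap in the red near 660 nm); Gaussian RGB
camera channels; and a two-lobe white-LED-like illuminant.

The chromophore shapes are frozen constants of the package: they emulate
the qualitative structure of whole-blood extinction at 45 % hematocrit, not
any particular published table.  A loader for user-supplied tabulated
spectra is available via :meth:`bluevein.optics_core.Spectrum.from_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .colorimetry import CameraModel, Illuminant, derive_rgb_to_xyz_matrix
from .optics_core import (
    DEFAULT_GRID,
    Medium,
    OpticalProperties,
    Spectrum,
)

__all__ = [
    "SkinModelParams",
    "BloodModelParams",
    "make_skin_optics",
    "make_blood_optics",
    "make_camera_model",
    "make_led_illuminant",
    "make_training_reflectances",
    "make_fixture_bundle",
    "default_phantom_media",
    "oxy_extinction",
    "deoxy_extinction",
]


def _gauss(wl, center, sigma, amp):
    wl = np.asarray(wl, dtype=float)
    return amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)


# --------------------------------------------------------------------------
# skin
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SkinModelParams:
    """Forearm-skin-like phantom parameters.

    The absorption bands mimic the blood/melanin structure of lightly
    pigmented skin: a strong blue band (Soret region plus melanin rise) and
    the weak hemoglobin double band in the green, on a small red baseline,
    giving strong blue attenuation and deep red penetration.  mu_s' follows
    a power law mu_s'(lambda) = musp_500 * (lambda/500)^(-b).
    """

    musp_500: float = 3.0  # 1/mm
    scatter_power: float = 1.6
    baseline_mu_a: float = 0.015  # 1/mm
    bands: tuple = (
        (430.0, 35.0, 0.80),  # (center nm, sigma nm, amplitude 1/mm)
        (545.0, 18.0, 0.10),
        (575.0, 12.0, 0.07),
    )
    g: float = 0.7  # phantom mode; literature tissue uses 0.9
    n_mode: str = "constant"  # "constant" (n=1.4) or "silicone" (1.43 -> 1.40)


def _index_spectrum(mode: str, grid: np.ndarray) -> Spectrum:
    if mode == "constant":
        return Spectrum.constant(1.4, grid)
    if mode == "silicone":
        # measured silicone dispersion: 1.43 at 400 nm to 1.40 at 700 nm
        vals = 1.43 + (grid - 400.0) / (700.0 - 400.0) * (1.40 - 1.43)
        return Spectrum(grid, vals)
    raise ValueError(f"unknown refractive-index mode: {mode!r}")


def make_skin_optics(
    params: SkinModelParams = SkinModelParams(), grid=DEFAULT_GRID
) -> OpticalProperties:
    """Skin-like optical properties on the given wavelength grid."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < 400 or grid[-1] > 700:
        raise ValueError("grid must lie within 400-700 nm")
    if (
        params.musp_500 <= 0
        or params.baseline_mu_a < 0
        or any(a < 0 or s <= 0 for _, s, a in params.bands)
    ):
        raise ValueError("skin model parameters must be nonnegative")
    mu_a = np.full(grid.shape, params.baseline_mu_a)
    for center, sigma, amp in params.bands:
        mu_a = mu_a + _gauss(grid, center, sigma, amp)
    musp = params.musp_500 * (grid / 500.0) ** (-params.scatter_power)
    return OpticalProperties.from_reduced(
        Spectrum(grid, mu_a),
        Spectrum(grid, musp),
        g=Spectrum.constant(params.g, grid),
        n=_index_spectrum(params.n_mode, grid),
    )


# --------------------------------------------------------------------------
# blood
# --------------------------------------------------------------------------

# Frozen analytic extinction shapes (1/mm at unit hematocrit scale,
# emulating whole blood at 45 % hematocrit).  Versioned constants: changing
# them changes every phenomenon the package reports.
_OXY_TERMS = (
    (430.0, 18.0, 65.0),  # Soret-like
    (542.0, 13.0, 13.0),  # double band
    (576.0, 9.0, 14.0),
)
_OXY_RED_BASE = 0.12
_DEOXY_TERMS = (
    (430.0, 18.0, 45.0),  # Soret-like
    (555.0, 20.0, 20.0),  # single band
    (700.0, 120.0, 1.3),  # elevated red tail: deoxy >> oxy near 660 nm
)
_DEOXY_RED_BASE = 0.05


def oxy_extinction(grid=DEFAULT_GRID) -> Spectrum:
    """Oxyhemoglobin-like absorption shape (1/mm per unit hematocrit scale)."""
    grid = np.asarray(grid, dtype=float)
    v = np.full(grid.shape, _OXY_RED_BASE)
    for c, s, a in _OXY_TERMS:
        v = v + _gauss(grid, c, s, a)
    return Spectrum(grid, v)


def deoxy_extinction(grid=DEFAULT_GRID) -> Spectrum:
    """Deoxyhemoglobin-like absorption shape (1/mm per unit hematocrit scale)."""
    grid = np.asarray(grid, dtype=float)
    v = np.full(grid.shape, _DEOXY_RED_BASE)
    for c, s, a in _DEOXY_TERMS:
        v = v + _gauss(grid, c, s, a)
    return Spectrum(grid, v)


@dataclass(frozen=True)
class BloodModelParams:
    """Whole-blood-like phantom parameters.

    ``S`` is the oxygen saturation fraction (venous 0.7, arterial 1.0);
    ``hematocrit_scale`` rescales the frozen 45 %-hematocrit shapes.
    """

    S: float = 0.7
    hematocrit_scale: float = 1.0
    g_blood: float = 0.7  # phantom mode; literature blood g is higher
    musp_500: float = 2.0  # 1/mm, elevated by pigment intrinsic scattering
    scatter_power: float = 0.7
    n_mode: str = "constant"


def make_blood_optics(
    params: BloodModelParams = BloodModelParams(), grid=DEFAULT_GRID
) -> OpticalProperties:
    """Blood-like optical properties: mu_a = scale*(S*eps_oxy + (1-S)*eps_deoxy)."""
    if not (0.0 <= params.S <= 1.0):
        raise ValueError("oxygen saturation S must lie in [0, 1]")
    if params.hematocrit_scale <= 0:
        raise ValueError("hematocrit scale must be positive")
    grid = np.asarray(grid, dtype=float)
    mu_a = params.hematocrit_scale * (
        params.S * oxy_extinction(grid).values
        + (1.0 - params.S) * deoxy_extinction(grid).values
    )
    musp = params.musp_500 * (grid / 500.0) ** (-params.scatter_power)
    return OpticalProperties.from_reduced(
        Spectrum(grid, mu_a),
        Spectrum(grid, musp),
        g=Spectrum.constant(params.g_blood, grid),
        n=_index_spectrum(params.n_mode, grid),
    )


def default_phantom_media(grid=DEFAULT_GRID) -> dict[str, Medium]:
    """The study's three default media: skin tissue, venous and arterial blood."""
    return {
        "tissue": Medium("tissue", make_skin_optics(grid=grid)),
        "venous": Medium(
            "venous", make_blood_optics(BloodModelParams(S=0.7), grid=grid)
        ),
        "arterial": Medium(
            "arterial", make_blood_optics(BloodModelParams(S=1.0), grid=grid)
        ),
    }


# --------------------------------------------------------------------------
# camera and illuminant
# --------------------------------------------------------------------------

_CAMERA_CHANNELS = ((600.0, 35.0), (540.0, 35.0), (460.0, 30.0))  # (center, sigma)


def make_led_illuminant(grid=DEFAULT_GRID) -> Illuminant:
    """White-LED-like SPD: blue pump at 450 nm plus a broad phosphor lobe."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < 400 or grid[-1] > 700:
        raise ValueError("grid must lie within 400-700 nm")
    spd = _gauss(grid, 450.0, 12.0, 1.0) + _gauss(grid, 560.0, 60.0, 1.2)
    return Illuminant(Spectrum(grid, spd))


def make_training_reflectances(grid=DEFAULT_GRID) -> list[Spectrum]:
    """Smooth synthetic reflectance set for camera-matrix training."""
    grid = np.asarray(grid, dtype=float)
    span = grid[-1] - grid[0]
    ramp = (grid - grid[0]) / span
    out = [
        Spectrum.constant(1.0, grid),
        Spectrum(grid, 0.2 + 0.6 * ramp),
        Spectrum(grid, 0.8 - 0.6 * ramp),
    ]
    for center in (430, 480, 530, 580, 630, 680):
        out.append(Spectrum(grid, 0.1 + _gauss(grid, center, 40.0, 0.7)))
    return out


def make_camera_model(grid=DEFAULT_GRID) -> CameraModel:
    """Synthetic three-Gaussian RGB camera with a trained raw->XYZ matrix."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < 400 or grid[-1] > 700:
        raise ValueError("grid must lie within 400-700 nm")
    sens = tuple(
        Spectrum(grid, _gauss(grid, c, s, 1.0)) for c, s in _CAMERA_CHANNELS
    )
    matrix = derive_rgb_to_xyz_matrix(
        sens, make_training_reflectances(grid), make_led_illuminant(grid)
    )
    return CameraModel(sensitivities=sens, rgb_to_xyz=matrix)


# --------------------------------------------------------------------------
# pigment basis and fixture bundle
# --------------------------------------------------------------------------

# seven synthetic unit-concentration pigment absorption spectra, chosen so
# their nonnegative span covers the venous/arterial targets
_PIGMENT_BANK = (
    ("soret_violet", ((430.0, 18.0, 1.0),)),
    ("green_narrow", ((542.0, 13.0, 1.0),)),
    ("yellow_band", ((576.0, 9.0, 1.0),)),
    ("olive_band", ((555.0, 20.0, 1.0),)),
    ("red_tail", ((700.0, 120.0, 1.0),)),
    ("broad_blue", ((460.0, 45.0, 1.0),)),
    ("neutral_gray", ()),  # flat unit absorber
)


def make_pigment_basis_spectra(grid=DEFAULT_GRID) -> dict[str, Spectrum]:
    """The seven-pigment synthetic absorption basis (1/mm per unit conc.)."""
    grid = np.asarray(grid, dtype=float)
    out = {}
    for name, terms in _PIGMENT_BANK:
        v = np.zeros(grid.shape) if terms else np.full(grid.shape, 1.0)
        for c, s, a in terms:
            v = v + _gauss(grid, c, s, a)
        out[name] = Spectrum(grid, v)
    return out


def make_fixture_bundle(seed: int, out_dir) -> Path:
    """Write a deterministic CSV/YAML fixture set to ``out_dir``.

    Contains skin, venous and arterial optical-property spectra, camera
    sensitivities, the LED illuminant, the seven-pigment basis with a
    manifest, and a default vessel-scene config.  Byte-identical for equal
    seeds.
    """
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = DEFAULT_GRID
    media = default_phantom_media(grid)
    for label, medium in media.items():
        p = medium.props
        p.mu_a.to_csv(out / f"{label}_mu_a.csv")
        p.mu_s_prime.to_csv(out / f"{label}_musp.csv")
        p.g.to_csv(out / f"{label}_g.csv")
        p.n.to_csv(out / f"{label}_n.csv")
    cam = make_camera_model(grid)
    for ch, spec in zip("rgb", cam.sensitivities):
        spec.to_csv(out / f"camera_{ch}.csv")
    np.savetxt(out / "camera_rgb_to_xyz.csv", cam.rgb_to_xyz, delimiter=",")
    make_led_illuminant(grid).spd.to_csv(out / "illuminant.csv")

    basis_dir = out / "pigments"
    basis_dir.mkdir(exist_ok=True)
    basis = make_pigment_basis_spectra(grid)
    for name, spec in basis.items():
        spec.to_csv(basis_dir / f"{name}.csv")
    manifest = {
        "seed": int(seed),
        "pigments": sorted(basis),
        "grid_nm": {"start": 400, "stop": 700, "step": 5},
    }
    with open(basis_dir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    scene_cfg = {
        "block_edge_mm": 30.0,
        "vessel": {"diameter_mm": 2.0, "depth_mm": 1.0, "medium": "venous"},
        "tissue_medium": "tissue",
        "sources": {
            "count": 2,
            "size_mm": [160.0, 160.0],
            "distance_mm": 270.0,
            "polar_deg": 45.0,
        },
        "detector": {"acceptance_deg": 10.0, "n_pixels": 64},
        "wavelengths_nm": {"start": 450, "stop": 690, "step": 20},
        "n_photons_per_wavelength": 200000,
        "seed": int(seed),
    }
    with open(out / "scene_default.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(scene_cfg, fh, sort_keys=True)
    return out
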