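"""Spectral-to-color conversion: camera raw RGB, CIE XYZ, CIELAB, sRGB, dE.

The simulated reflectance spectra are weighted by the camera channel
sensitivities and the illuminant spectral power distribution to obtain raw
RGB, mapped to XYZ by a camera-specific 3x3 matrix (derived by least squares
against the CIE 1931 2-degree standard observer), and then to CIELAB for
color-difference computation or to sRGB for visualization.

Quadrature is the rectangle rule on the working wavelength grid.  The CIE
1931 color-matching functions are evaluated from the multi-lobe Gaussian
analytic fit of Wyman, Sloan & Shirley (accurate to well under 1 % of peak
over the visible range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .optics_core import Spectrum, resample

__all__ = [
    "CameraModel",
    "Illuminant",
    "ColorRecord",
    "cie_1931_cmfs",
    "spectrum_to_raw_rgb",
    "spectrum_to_xyz",
    "raw_rgb_to_xyz",
    "derive_rgb_to_xyz_matrix",
    "xyz_to_lab",
    "delta_e",
    "xyz_to_srgb",
    "color_record",
]


# --------------------------------------------------------------------------
# standard observer
# --------------------------------------------------------------------------


def _piecewise_gauss(x, amp, mu, s1, s2):
    s = np.where(x < mu, s1, s2)
    return amp * np.exp(-0.5 * ((x - mu) / s) ** 2)


def cie_1931_cmfs(wavelengths_nm) -> np.ndarray:
    """CIE 1931 2-deg color-matching functions, shape (n, 3) = (xbar,ybar,zbar)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    xbar = (
        _piecewise_gauss(wl, 1.056, 599.8, 37.9, 31.0)
        + _piecewise_gauss(wl, 0.362, 442.0, 16.0, 26.7)
        - _piecewise_gauss(wl, 0.065, 501.1, 20.4, 26.2)
    )
    ybar = _piecewise_gauss(wl, 0.821, 568.8, 46.9, 40.5) + _piecewise_gauss(
        wl, 0.286, 530.9, 16.3, 31.1
    )
    zbar = _piecewise_gauss(wl, 1.217, 437.0, 11.8, 36.0) + _piecewise_gauss(
        wl, 0.681, 459.0, 26.0, 13.8
    )
    return np.stack([xbar, ybar, zbar], axis=-1)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraModel:
    """RGB channel spectral sensitivities plus a raw-RGB -> XYZ matrix."""

    sensitivities: tuple[Spectrum, Spectrum, Spectrum]  # (R, G, B)
    rgb_to_xyz: np.ndarray

    def __post_init__(self) -> None:
        for s in self.sensitivities:
            if np.any(s.values < 0):
                raise ValueError("camera sensitivities must be nonnegative")
        m = np.asarray(self.rgb_to_xyz, dtype=float)
        if m.shape != (3, 3) or not np.all(np.isfinite(m)):
            raise ValueError("rgb_to_xyz must be a finite 3x3 matrix")
        object.__setattr__(self, "rgb_to_xyz", m)


@dataclass(frozen=True)
class Illuminant:
    """Relative spectral power distribution of a light source."""

    spd: Spectrum

    def __post_init__(self) -> None:
        if np.any(self.spd.values < 0):
            raise ValueError("illuminant SPD must be nonnegative")
        if not np.any(self.spd.values > 0):
            raise ValueError("illuminant SPD must not be identically zero")


@dataclass(frozen=True)
class ColorRecord:
    """One stimulus through the full chain."""

    rgb_raw: np.ndarray
    xyz: np.ndarray
    lab: np.ndarray
    srgb8: np.ndarray
    clipped: bool


# --------------------------------------------------------------------------
# spectral integration
# --------------------------------------------------------------------------


def _common_grid(*spectra: Spectrum) -> np.ndarray:
    lo = max(s.wavelengths_nm[0] for s in spectra)
    hi = min(s.wavelengths_nm[-1] for s in spectra)
    if lo > hi:
        raise ValueError("spectra have disjoint wavelength supports")
    base = spectra[0].wavelengths_nm
    grid = base[(base >= lo) & (base <= hi)]
    if grid.size < 2:
        raise ValueError("wavelength overlap too small for quadrature")
    return grid


def _grid_step(grid: np.ndarray) -> float:
    return float(np.mean(np.diff(grid)))


def spectrum_to_raw_rgb(
    reflectance: Spectrum, camera: CameraModel, light: Illuminant
) -> np.ndarray:
    """Camera raw response: channel_k = sum reflectance*spd*sens_k*dlambda."""
    grid = _common_grid(reflectance, light.spd, *camera.sensitivities)
    dl = _grid_step(grid)
    refl = resample(reflectance, grid).values
    spd = resample(light.spd, grid).values
    out = np.empty(3)
    for k, sens in enumerate(camera.sensitivities):
        out[k] = np.sum(refl * spd * resample(sens, grid).values) * dl
    return out


def spectrum_to_xyz(reflectance: Spectrum, light: Illuminant) -> np.ndarray:
    """Direct CIE XYZ of a reflectance under an illuminant (standard observer)."""
    grid = _common_grid(reflectance, light.spd)
    dl = _grid_step(grid)
    refl = resample(reflectance, grid).values
    spd = resample(light.spd, grid).values
    cmf = cie_1931_cmfs(grid)
    return np.sum((refl * spd)[:, None] * cmf, axis=0) * dl


def raw_rgb_to_xyz(rgb_raw, camera: CameraModel) -> np.ndarray:
    """Linear camera-specific conversion; broadcasts over leading axes."""
    rgb = np.asarray(rgb_raw, dtype=float)
    return rgb @ camera.rgb_to_xyz.T


def derive_rgb_to_xyz_matrix(
    sensitivities: tuple[Spectrum, Spectrum, Spectrum],
    training_reflectances: list[Spectrum],
    light: Illuminant,
) -> np.ndarray:
    """Least-squares matrix mapping camera raw RGB to standard-observer XYZ.

    Both sides are computed on the same quadrature for each training
    stimulus; a rank-deficient training set raises.
    """
    if len(training_reflectances) < 3:
        raise ValueError("need at least 3 training spectra")
    cam = CameraModel(sensitivities=tuple(sensitivities), rgb_to_xyz=np.eye(3))
    A = np.stack(
        [spectrum_to_raw_rgb(r, cam, light) for r in training_reflectances]
    )
    B = np.stack([spectrum_to_xyz(r, light) for r in training_reflectances])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("training reflectance set is rank-deficient")
    M_T, *_ = np.linalg.lstsq(A, B, rcond=None)
    return M_T.T


# --------------------------------------------------------------------------
# CIELAB / sRGB
# --------------------------------------------------------------------------

_LAB_DELTA = 6.0 / 29.0


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    cube = _LAB_DELTA**3
    return np.where(
        t > cube, np.cbrt(np.maximum(t, 0)), t / (3 * _LAB_DELTA**2) + 4.0 / 29.0
    )


def xyz_to_lab(xyz, white_point_xyz) -> np.ndarray:
    """Standard CIELAB forward transform; broadcasts over leading axes."""
    xyz = np.asarray(xyz, dtype=float)
    wp = np.asarray(white_point_xyz, dtype=float)
    if np.any(wp <= 0):
        raise ValueError("white point must be strictly positive")
    f = _lab_f(xyz / wp)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def delta_e(lab1, lab2, method: str = "cie76") -> float | np.ndarray:
    """Color difference between two Lab triplets.

    ``method`` is ``"cie76"`` (Euclidean, default) or ``"ciede2000"``.
    """
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    if method == "cie76":
        out = np.sqrt(np.sum((lab1 - lab2) ** 2, axis=-1))
    elif method == "ciede2000":
        out = _ciede2000(lab1, lab2)
    else:
        raise ValueError(f"unknown delta-E method: {method!r}")
    return float(out) if np.ndim(out) == 0 else out


def _ciede2000(lab1, lab2):
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]
    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1 + G) * a1
    a2p = (1 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)
    h1p = np.degrees(np.arctan2(b1, a1p)) % 360
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360
    dLp = L2 - L1
    dCp = C2p - C1p
    dh = h2p - h1p
    dh = np.where(np.abs(dh) > 180, dh - np.sign(dh) * 360, dh)
    dh = np.where((C1p * C2p) == 0, 0.0, dh)
    dHp = 2 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2)
    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    hsum = h1p + h2p
    hbp = np.where(
        (C1p * C2p) == 0,
        hsum,
        np.where(
            np.abs(h1p - h2p) <= 180,
            0.5 * hsum,
            np.where(hsum < 360, 0.5 * (hsum + 360), 0.5 * (hsum - 360)),
        ),
    )
    T = (
        1
        - 0.17 * np.cos(np.radians(hbp - 30))
        + 0.24 * np.cos(np.radians(2 * hbp))
        + 0.32 * np.cos(np.radians(3 * hbp + 6))
        - 0.20 * np.cos(np.radians(4 * hbp - 63))
    )
    dtheta = 30 * np.exp(-(((hbp - 275) / 25) ** 2))
    Rc = 2 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    Sl = 1 + 0.015 * (Lbp - 50) ** 2 / np.sqrt(20 + (Lbp - 50) ** 2)
    Sc = 1 + 0.045 * Cbp
    Sh = 1 + 0.015 * Cbp * T
    Rt = -np.sin(np.radians(2 * dtheta)) * Rc
    return np.sqrt(
        (dLp / Sl) ** 2
        + (dCp / Sc) ** 2
        + (dHp / Sh) ** 2
        + Rt * (dCp / Sc) * (dHp / Sh)
    )


# sRGB D65 linear transform (IEC 61966-2-1)
_XYZ_TO_SRGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)
#: XYZ of the sRGB (D65) white, Y normalized to 1
SRGB_WHITE_XYZ = np.array([0.95047, 1.0, 1.08883])


def xyz_to_srgb(xyz, white_point_xyz=None) -> tuple[np.ndarray, bool]:
    """XYZ -> 8-bit sRGB with out-of-gamut clipping flagged.

    If ``white_point_xyz`` is given, the stimulus is first scaled so that the
    scene white maps to the sRGB white (von Kries-style diagonal adaptation
    per XYZ channel).
    """
    xyz = np.asarray(xyz, dtype=float)
    if white_point_xyz is not None:
        wp = np.asarray(white_point_xyz, dtype=float)
        if np.any(wp <= 0):
            raise ValueError("white point must be strictly positive")
        xyz = xyz / wp * SRGB_WHITE_XYZ
    lin = xyz @ _XYZ_TO_SRGB.T
    clipped = bool(np.any(lin < -1e-9) or np.any(lin > 1 + 1e-9))
    lin = np.clip(lin, 0.0, 1.0)
    srgb = np.where(
        lin <= 0.0031308, 12.92 * lin, 1.055 * np.power(lin, 1 / 2.4) - 0.055
    )
    return np.round(srgb * 255).astype(np.uint8), clipped


def color_record(
    reflectance: Spectrum,
    camera: CameraModel,
    light: Illuminant,
    white_reflectance: Spectrum | None = None,
) -> ColorRecord:
    """Run one reflectance spectrum through the full camera color chain.

    The Lab white point is the XYZ of a perfect diffuser under the scene
    illuminant, passed through the same camera pipeline (override with
    ``white_reflectance``).
    """
    if white_reflectance is None:
        white_reflectance = Spectrum.constant(1.0, reflectance.wavelengths_nm)
    rgb = spectrum_to_raw_rgb(reflectance, camera, light)
    xyz = raw_rgb_to_xyz(rgb, camera)
    wp = raw_rgb_to_xyz(
        spectrum_to_raw_rgb(white_reflectance, camera, light), camera
    )
    lab = xyz_to_lab(xyz, wp)
    srgb8, clipped = xyz_to_srgb(xyz, white_point_xyz=wp)
    return ColorRecord(rgb_raw=rgb, xyz=xyz, lab=lab, srgb8=srgb8, clipped=clipped)
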