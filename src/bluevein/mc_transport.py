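"""Monte Carlo solution of the radiative transport equation.

Two geometries are supported:

* laterally infinite slabs (and the semi-infinite half-space limit), used
  for optical characterization — diffuse reflectance ``R`` and
  transmittance ``T``;
* a cubic tissue block with an embedded horizontal cylinder (the vessel
  phantom scene), illuminated by two oblique parallel beams and imaged by a
  pinhole-like detector above the surface, producing a spatially and
  spectrally resolved reflectance image.

The photon random walk is the standard variance-reduced scheme: step length
``s = -ln(xi) / mu_t``, implicit capture (weight attenuation by the single-
scattering albedo), Henyey-Greenstein deflection, Fresnel boundary events,
and Russian roulette below a weight threshold.  Scene tracing is forward
(source to detector) with surface-exit binning into pixels inside an angular
acceptance cone about the surface normal; by optical reciprocity this is
equivalent to reverse tracing from the camera for the radiance quantities
analysed here.

Heavy loops are compiled with numba; :func:`trace_photon` is a readable
pure-Python single-photon reference used for geometric verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .optics_core import Medium, Spectrum, fresnel_unpolarized

__all__ = [
    "SlabSample",
    "VesselScene",
    "PhotonState",
    "TransportResult",
    "ReflectanceImage",
    "run_slab",
    "run_semi_infinite",
    "render_scene",
    "trace_photon",
]

# variance-control constants (MCML-style)
WEIGHT_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1
_EPS = 1e-9


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SlabSample:
    """A laterally infinite layer of one medium in an ambient medium."""

    thickness: float  # mm
    medium: Medium
    n_ambient: float = 1.0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("slab thickness must be positive")


@dataclass(frozen=True)
class RectSource:
    """Rectangular emitter approximated as a uniform parallel beam.

    ``polar_deg`` is the beam angle from the surface normal; ``azimuth_deg``
    selects the side it comes from (0 = +x, 180 = -x).
    """

    width: float = 160.0
    height: float = 160.0
    distance: float = 270.0
    polar_deg: float = 45.0
    azimuth_deg: float = 0.0


@dataclass(frozen=True)
class Detector:
    """Pinhole-like camera on the surface normal with a pixel grid."""

    acceptance_deg: float = 10.0
    n_pixels: int = 64

    def __post_init__(self) -> None:
        if self.acceptance_deg <= 0:
            raise ValueError("detector acceptance half-angle must be positive")
        if self.n_pixels < 1:
            raise ValueError("pixel grid must be at least 1x1")


def default_sources() -> tuple[RectSource, RectSource]:
    """Two 160x160 mm sources at 45 deg, symmetric left/right of the block."""
    return (
        RectSource(azimuth_deg=0.0),
        RectSource(azimuth_deg=180.0),
    )


@dataclass(frozen=True)
class VesselScene:
    """Cubic tissue block with an embedded horizontal cylindrical vessel.

    ``z`` is the depth from the illuminated surface to the TOP of the
    cylinder; the cylinder axis runs along y through the block center.
    """

    tissue: Medium
    vessel: Medium
    d: float  # cylinder diameter, mm
    z: float  # depth of cylinder top below the surface, mm
    block_edge: float = 30.0
    sources: tuple = field(default_factory=default_sources)
    detector: Detector = field(default_factory=Detector)

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError("vessel depth z must be >= 0 (cylinder below surface)")
        if self.d <= 0:
            raise ValueError("vessel diameter must be positive")
        if self.z + self.d > self.block_edge:
            raise ValueError("cylinder does not fit inside the block")

    @property
    def radius(self) -> float:
        return self.d / 2.0

    @property
    def axis_depth(self) -> float:
        """Depth of the cylinder axis below the surface."""
        return self.z + self.radius


@dataclass
class PhotonState:
    """Mutable photon record for the reference tracer."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    medium_label: str = ""
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("photon direction must be a unit vector")
        if self.weight < 0:
            raise ValueError("photon weight must be >= 0")


@dataclass(frozen=True)
class TransportResult:
    """Tallies of one slab / half-space simulation (fractions of launched)."""

    R_diffuse: float
    T_diffuse: float
    A_absorbed: float
    specular: float
    se_R: float
    se_T: float
    se_A: float
    n_photons: int
    seed: int
    wavelength_nm: float | None = None


@dataclass
class ReflectanceImage:
    """Per-pixel, per-wavelength detected photon weight over the surface.

    ``weights`` has shape (n_wavelengths, ny, nx); dividing by the
    per-wavelength launch count gives the detected fraction, and
    :meth:`reflectance` additionally references it to an ideal Lambertian
    white standard in the same detection geometry, giving a quantity
    comparable across wavelengths and close to true reflectance.
    """

    weights: np.ndarray
    n_launched: np.ndarray
    wavelengths: np.ndarray
    pixel_pitch: float  # mm per pixel
    acceptance_deg: float
    origin: tuple[float, float] = (0.0, 0.0)  # surface coords of pixel (0,0) corner
    meta: dict = field(default_factory=dict)

    def detected_fraction(self) -> np.ndarray:
        return self.weights / self.n_launched[:, None, None]

    def reflectance(self) -> np.ndarray:
        """White-standard-referenced reflectance cube, shape (n_wl, ny, nx).

        A unit-albedo Lambertian reflector sends a fraction
        ``sin^2(theta_acc) / n_pixels_illuminated`` of the launched light into
        each pixel's acceptance cone; referencing to that standard removes
        the geometric detection factor.
        """
        theta = math.radians(self.acceptance_deg)
        npx = self.weights.shape[1] * self.weights.shape[2]
        white_per_pixel = math.sin(theta) ** 2 / npx
        return self.detected_fraction() / white_per_pixel

    def wavelength_index(self, wavelength_nm: float, tol: float = 6.0) -> int:
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))
        if abs(self.wavelengths[idx] - wavelength_nm) > tol:
            raise ValueError(
                f"wavelength {wavelength_nm} nm not present in image "
                f"(nearest band {self.wavelengths[idx]} nm)"
            )
        return idx


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------


@njit(cache=True)
def _hg_cos(g: float) -> float:
    u = np.random.random()
    if g == 0.0:
        return 2.0 * u - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - frac * frac) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True)
def _scatter(ux: float, uy: float, uz: float, g: float):
    """New direction after a Henyey-Greenstein deflection (MCML update)."""
    ct = _hg_cos(g)
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    phi = 2.0 * math.pi * np.random.random()
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct * (1.0 if uz >= 0 else -1.0)
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _fresnel_r(n_in: float, n_out: float, ci: float) -> float:
    if n_in == n_out:
        return 0.0
    sin_t2 = (n_in / n_out) ** 2 * (1.0 - ci * ci)
    if sin_t2 >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - sin_t2)
    rs = (n_in * ci - n_out * ct) / (n_in * ci + n_out * ct)
    rp = (n_in * ct - n_out * ci) / (n_in * ct + n_out * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _slab_kernel(
    mu_a: float,
    mu_s: float,
    g: float,
    n_med: float,
    n_amb: float,
    thickness: float,
    n_photons: int,
    seed: int,
    cos_inc_air: float,
):
    """Slab MC with implicit capture; returns tallies and sums of squares."""
    np.random.seed(seed)
    mu_t = mu_a + mu_s
    sum_r = 0.0
    sum_r2 = 0.0
    sum_t = 0.0
    sum_t2 = 0.0
    sum_a = 0.0
    sum_a2 = 0.0
    spec_total = 0.0

    # entry refraction (shared by all photons)
    r_sp = _fresnel_r(n_amb, n_med, cos_inc_air)
    sin_t2 = (n_amb / n_med) ** 2 * (1.0 - cos_inc_air * cos_inc_air)
    uz0 = math.sqrt(max(0.0, 1.0 - sin_t2))
    ux0 = math.sqrt(max(0.0, sin_t2))

    for _ in range(n_photons):
        w = 1.0 - r_sp
        spec_total += r_sp
        z = 0.0
        ux = ux0
        uy = 0.0
        uz = uz0
        r_i = 0.0
        t_i = 0.0
        a_i = 0.0
        alive = True
        if mu_t <= 0.0:
            # transparent medium: ballistic crossing
            t_i = w
            alive = False
        while alive:
            s = -math.log(np.random.random() + 1e-300) / mu_t
            z_new = z + uz * s
            if uz > 0.0 and z_new >= thickness:
                ci = uz
                if np.random.random() < _fresnel_r(n_med, n_amb, ci):
                    z = thickness
                    uz = -uz
                    continue
                t_i = w
                alive = False
            elif uz < 0.0 and z_new <= 0.0:
                ci = -uz
                if np.random.random() < _fresnel_r(n_med, n_amb, ci):
                    z = 0.0
                    uz = -uz
                    continue
                r_i = w
                alive = False
            else:
                z = z_new
                a_i += w * mu_a / mu_t
                w *= mu_s / mu_t
                if w <= 0.0:
                    alive = False
                    break
                ux, uy, uz = _scatter(ux, uy, uz, g)
                if w < WEIGHT_THRESHOLD:
                    if np.random.random() < ROULETTE_SURVIVAL:
                        w /= ROULETTE_SURVIVAL
                    else:
                        alive = False
        sum_r += r_i
        sum_r2 += r_i * r_i
        sum_t += t_i
        sum_t2 += t_i * t_i
        sum_a += a_i
        sum_a2 += a_i * a_i

    return sum_r, sum_r2, sum_t, sum_t2, sum_a, sum_a2, spec_total


@njit(cache=True)
def _semi_albedo_kernel(
    g: float,
    n_med: float,
    n_amb: float,
    k_max: int,
    n_photons: int,
    seed: int,
):
    """Pure-scattering half-space walk: histogram of interaction counts.

    Photons are launched at normal incidence into a half-space with unit
    mu_t and no absorption; for each photon exiting the top surface the
    number of interactions K it underwent is recorded.  The diffuse
    reflectance at any albedo a is then (1-R_sp) * E[a^K].  Walks exceeding
    ``k_max`` interactions are censored (counted as never exiting).
    """
    np.random.seed(seed)
    hist = np.zeros(k_max + 1, dtype=np.float64)
    r_sp = _fresnel_r(n_amb, n_med, 1.0)
    for _ in range(n_photons):
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        k = 0
        while k <= k_max:
            s = -math.log(np.random.random() + 1e-300)
            z_new = z + uz * s
            if uz < 0.0 and z_new <= 0.0:
                ci = -uz
                if np.random.random() < _fresnel_r(n_med, n_amb, ci):
                    z = 0.0
                    uz = -uz
                    continue
                hist[k] += 1.0
                break
            z = z_new
            ux, uy, uz = _scatter(ux, uy, uz, g)
            k += 1
    return hist, r_sp


@njit(cache=True)
def _scene_kernel(
    mu_a_t: float,
    mu_s_t: float,
    g_t: float,
    mu_a_v: float,
    mu_s_v: float,
    g_v: float,
    n_med: float,
    n_amb: float,
    edge: float,
    z_axis: float,
    radius: float,
    polar_deg: float,
    cos_acc: float,
    npix: int,
    n_photons: int,
    seed: int,
    image: np.ndarray,
):
    """Forward MC through the block+cylinder scene; bins exits into pixels.

    Coordinates: surface z=0, block z in [0, edge], x,y in [-edge/2, edge/2];
    cylinder axis along y at (x=0, z=z_axis).  Tissue and vessel share n, so
    the internal boundary only switches interaction coefficients.
    Returns (detected, diffuse_top, lost, absorbed, specular) weight totals.
    """
    np.random.seed(seed)
    half = edge / 2.0
    detected = 0.0
    diffuse_top = 0.0
    lost = 0.0
    absorbed = 0.0
    spec_total = 0.0

    sin_i = math.sin(polar_deg * math.pi / 180.0)
    cos_i = math.cos(polar_deg * math.pi / 180.0)
    r_sp = _fresnel_r(n_amb, n_med, cos_i)
    sin_t = sin_i * n_amb / n_med
    cos_t = math.sqrt(max(0.0, 1.0 - sin_t * sin_t))

    for ip in range(n_photons):
        x = (np.random.random() - 0.5) * edge
        y = (np.random.random() - 0.5) * edge
        z = 0.0
        side = 1.0 if (ip % 2 == 0) else -1.0  # alternate the two 45 deg beams
        ux = side * sin_t
        uy = 0.0
        uz = cos_t
        w = 1.0 - r_sp
        spec_total += r_sp
        alive = True

        while alive:
            # current medium from position
            dx = x
            dz = z - z_axis
            in_vessel = dx * dx + dz * dz < radius * radius
            if in_vessel:
                mu_a = mu_a_v
                mu_s = mu_s_v
                g = g_v
            else:
                mu_a = mu_a_t
                mu_s = mu_s_t
                g = g_t
            mu_t = mu_a + mu_s

            s = -math.log(np.random.random() + 1e-300) / mu_t

            # distance to nearest boundary along direction
            d_b = 1e30
            b_id = -1  # 0 top, 1 bottom, 2 side, 3 cylinder
            if uz < 0.0:
                t = -z / uz
                if t < d_b:
                    d_b = t
                    b_id = 0
            elif uz > 0.0:
                t = (edge - z) / uz
                if t < d_b:
                    d_b = t
                    b_id = 1
            if ux > 0.0:
                t = (half - x) / ux
                if t < d_b:
                    d_b = t
                    b_id = 2
            elif ux < 0.0:
                t = (-half - x) / ux
                if t < d_b:
                    d_b = t
                    b_id = 2
            if uy > 0.0:
                t = (half - y) / uy
                if t < d_b:
                    d_b = t
                    b_id = 2
            elif uy < 0.0:
                t = (-half - y) / uy
                if t < d_b:
                    d_b = t
                    b_id = 2
            # cylinder (axis along y): quadratic in the x-z plane
            a_q = ux * ux + uz * uz
            if a_q > 0.0:
                b_q = 2.0 * (dx * ux + dz * uz)
                c_q = dx * dx + dz * dz - radius * radius
                disc = b_q * b_q - 4.0 * a_q * c_q
                if disc > 0.0:
                    sq = math.sqrt(disc)
                    t1 = (-b_q - sq) / (2.0 * a_q)
                    t2 = (-b_q + sq) / (2.0 * a_q)
                    t_cyl = -1.0
                    if t1 > 1e-9:
                        t_cyl = t1
                    elif t2 > 1e-9:
                        t_cyl = t2
                    if t_cyl > 0.0 and t_cyl < d_b:
                        d_b = t_cyl
                        b_id = 3

            if s < d_b:
                # interaction inside current medium
                x += ux * s
                y += uy * s
                z += uz * s
                absorbed += w * mu_a / mu_t
                w *= mu_s / mu_t
                if w <= 0.0:
                    alive = False
                    break
                ux, uy, uz = _scatter(ux, uy, uz, g)
                if w < WEIGHT_THRESHOLD:
                    if np.random.random() < ROULETTE_SURVIVAL:
                        w /= ROULETTE_SURVIVAL
                    else:
                        alive = False
            elif b_id == 3:
                # matched-index internal boundary: step just across
                t = d_b + 1e-7
                x += ux * t
                y += uy * t
                z += uz * t
            elif b_id == 0:
                # top surface: Fresnel with the ambient medium
                x += ux * d_b
                y += uy * d_b
                z = 0.0
                ci = -uz
                if np.random.random() < _fresnel_r(n_med, n_amb, ci):
                    uz = -uz
                    continue
                diffuse_top += w
                sin_o2 = (n_med / n_amb) ** 2 * (1.0 - ci * ci)
                cos_o = math.sqrt(max(0.0, 1.0 - sin_o2))
                if cos_o >= cos_acc:
                    ixp = int((x + half) / edge * npix)
                    iyp = int((y + half) / edge * npix)
                    if ixp < 0:
                        ixp = 0
                    elif ixp >= npix:
                        ixp = npix - 1
                    if iyp < 0:
                        iyp = 0
                    elif iyp >= npix:
                        iyp = npix - 1
                    image[iyp, ixp] += w
                    detected += w
                alive = False
            else:
                # bottom or lateral face: terminate and tally as lost
                lost += w
                alive = False

    return detected, diffuse_top, lost, absorbed, spec_total


# --------------------------------------------------------------------------
# public drivers
# --------------------------------------------------------------------------


def _subseed(seed: int, k: int) -> int:
    """Derive a stream seed < 2^31 from a base seed and an index."""
    return int((int(seed) * 1000003 + 7919 * (k + 1)) % 2147483647)


def run_slab(
    sample: SlabSample,
    wavelength: float,
    n_photons: int,
    seed: int,
    incidence_deg: float = 0.0,
) -> TransportResult:
    """Diffuse reflectance / transmittance of a laterally infinite slab.

    Specular reflection at the first surface is tallied separately from the
    diffuse reflectance (integrating-sphere convention).
    """
    if n_photons < 1000:
        raise ValueError("n_photons must be >= 1000 for meaningful tallies")
    mu_a, mu_s, g, n_med = sample.medium.props.at(wavelength)
    if mu_a == 0.0 and mu_s == 0.0 and n_med != sample.n_ambient:
        raise ValueError(
            "non-interacting slab with mismatched boundaries has no defined "
            "diffuse split"
        )
    ci = math.cos(math.radians(incidence_deg))
    sums = _slab_kernel(
        mu_a,
        mu_s,
        g,
        n_med,
        sample.n_ambient,
        sample.thickness,
        int(n_photons),
        int(seed) % 2147483647,
        ci,
    )
    return _pack_result(sums, n_photons, seed, wavelength)


def _pack_result(sums, n_photons, seed, wavelength) -> TransportResult:
    sr, sr2, st, st2, sa, sa2, spec = sums
    n = n_photons

    def _mean_se(s, s2):
        m = s / n
        var = max(0.0, s2 / n - m * m)
        return m, math.sqrt(var / n)

    R, se_R = _mean_se(sr, sr2)
    T, se_T = _mean_se(st, st2)
    A, se_A = _mean_se(sa, sa2)
    return TransportResult(
        R_diffuse=R,
        T_diffuse=T,
        A_absorbed=A,
        specular=spec / n,
        se_R=se_R,
        se_T=se_T,
        se_A=se_A,
        n_photons=n,
        seed=int(seed),
        wavelength_nm=float(wavelength),
    )


def run_semi_infinite(
    medium: Medium,
    wavelength: float,
    n_photons: int,
    seed: int,
    n_ambient: float = 1.0,
    incidence_deg: float = 0.0,
) -> TransportResult:
    """Total diffuse reflectance of a half-space (absorbing termination)."""
    mu_a = medium.props.mu_a(wavelength)
    if mu_a <= 0.0:
        raise ValueError("semi-infinite medium requires mu_a > 0 to terminate")
    mu_s, g, n_med = (
        medium.props.mu_s(wavelength),
        medium.props.g(wavelength),
        medium.props.n(wavelength),
    )
    ci = math.cos(math.radians(incidence_deg))
    sums = _slab_kernel(
        mu_a,
        mu_s,
        g,
        n_med,
        n_ambient,
        1e30,  # effectively semi-infinite
        int(n_photons),
        int(seed) % 2147483647,
        ci,
    )
    return _pack_result(sums, n_photons, seed, wavelength)


def render_scene(
    scene: VesselScene,
    wavelengths,
    n_photons_per_wavelength: int,
    seed: int,
    n_ambient: float = 1.0,
) -> ReflectanceImage:
    """Spectrally resolved reflectance image of the vessel-phantom scene.

    One independent photon stream per wavelength (seed-derived), each traced
    through the block with the cylinder's optical properties active inside
    it.  Tissue and vessel must share a refractive index (matched internal
    boundary, the silicone-in-silicone phantom case).
    """
    wavelengths = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    det = scene.detector
    npix = det.n_pixels
    cos_acc = math.cos(math.radians(det.acceptance_deg))
    if cos_acc >= 1.0:
        raise ValueError("detector acceptance cone must have positive width")

    weights = np.zeros((wavelengths.size, npix, npix))
    n_launched = np.full(wavelengths.size, int(n_photons_per_wavelength))
    tallies = []
    polar = scene.sources[0].polar_deg

    for k, wl in enumerate(wavelengths):
        mu_a_t, mu_s_t, g_t, n_t = scene.tissue.props.at(wl)
        mu_a_v, mu_s_v, g_v, n_v = scene.vessel.props.at(wl)
        if abs(n_t - n_v) > 1e-9:
            raise ValueError(
                "tissue and vessel refractive indices must match "
                "(matched internal boundary model)"
            )
        img = weights[k]
        out = _scene_kernel(
            mu_a_t,
            mu_s_t,
            g_t,
            mu_a_v,
            mu_s_v,
            g_v,
            n_t,
            n_ambient,
            scene.block_edge,
            scene.axis_depth,
            scene.radius,
            polar,
            cos_acc,
            npix,
            int(n_photons_per_wavelength),
            _subseed(seed, k),
            img,
        )
        tallies.append(
            dict(
                zip(
                    ("detected", "diffuse_top", "lost", "absorbed", "specular"),
                    (float(v) for v in out),
                )
            )
        )

    return ReflectanceImage(
        weights=weights,
        n_launched=n_launched,
        wavelengths=wavelengths,
        pixel_pitch=scene.block_edge / npix,
        acceptance_deg=det.acceptance_deg,
        origin=(-scene.block_edge / 2.0, -scene.block_edge / 2.0),
        meta={
            "seed": int(seed),
            "n_photons_per_wavelength": int(n_photons_per_wavelength),
            "tallies": tallies,
            "illumination": "two 160x160 mm sources at 45 deg modeled as "
            "uniform parallel beams (270 mm standoff makes the solid-angle "
            "variation over the 30 mm block negligible)",
        },
    )


# --------------------------------------------------------------------------
# reference single-photon tracer (pure Python)
# --------------------------------------------------------------------------


def distance_to_scene_boundary(
    scene: VesselScene, position, direction
) -> tuple[float, str]:
    """Nearest boundary distance and its identity along a ray in the scene.

    Boundary names: ``"top"``, ``"bottom"``, ``"side"``, ``"cylinder"``.
    """
    x, y, z = (float(v) for v in position)
    ux, uy, uz = (float(v) for v in direction)
    edge = scene.block_edge
    half = edge / 2.0
    best = (math.inf, "none")
    if uz < 0:
        best = min(best, ((-z) / uz, "top"))
    elif uz > 0:
        best = min(best, ((edge - z) / uz, "bottom"))
    for u, c in ((ux, x), (uy, y)):
        if u > 0:
            best = min(best, ((half - c) / u, "side"))
        elif u < 0:
            best = min(best, ((-half - c) / u, "side"))
    dx, dz = x, z - scene.axis_depth
    a = ux * ux + uz * uz
    if a > 0:
        b = 2.0 * (dx * ux + dz * uz)
        c = dx * dx + dz * dz - scene.radius**2
        disc = b * b - 4 * a * c
        if disc > 0:
            sq = math.sqrt(disc)
            for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
                if t > 1e-9:
                    if t < best[0]:
                        best = (t, "cylinder")
                    break
    return best


def trace_photon(
    state: PhotonState,
    scene: VesselScene,
    rng: np.random.Generator,
    wavelength_nm: float | None = None,
) -> dict:
    """Trace one photon through the scene; returns a terminal event record.

    The record has keys ``event`` (``"exit_top"``, ``"exit_side"``,
    ``"exit_bottom"``, ``"absorbed"``), ``position``, ``direction``,
    ``weight`` and ``path_length``.  This is the readable reference
    implementation of the same walk the compiled kernel performs.
    """
    if abs(np.linalg.norm(state.direction) - 1.0) > 1e-9:
        raise ValueError("photon direction must be a unit vector")
    pos = state.position.astype(float).copy()
    direc = state.direction.astype(float).copy()
    w = float(state.weight)
    path = 0.0
    wl_props = {}
    wavelength = (
        float(wavelength_nm)
        if wavelength_nm is not None
        else scene.tissue.props.wavelengths_nm[0]
    )

    def props_at(p):
        dx, dz = p[0], p[2] - scene.axis_depth
        medium = (
            scene.vessel
            if dx * dx + dz * dz < scene.radius**2
            else scene.tissue
        )
        if medium.label not in wl_props:
            wl_props[medium.label] = medium.props.at(wavelength)
        return wl_props[medium.label]

    n_amb = 1.0
    while True:
        mu_a, mu_s, g, n_med = props_at(pos)
        mu_t = mu_a + mu_s
        if mu_s > 0:
            s = -math.log(1.0 - rng.random()) / mu_t
        else:
            # non-scattering medium: ballistic flight with Beer-Lambert
            # attenuation to the next boundary
            s = math.inf
        d_b, which = distance_to_scene_boundary(scene, pos, direc)
        if mu_s == 0.0:
            w *= math.exp(-mu_a * d_b)
        if s < d_b:
            pos += direc * s
            path += s
            w *= mu_s / mu_t
            if w <= 0:
                return _record("absorbed", pos, direc, 0.0, path)
            ct = _py_hg(g, rng)
            direc = _py_rotate(direc, ct, 2 * math.pi * rng.random())
            if w < WEIGHT_THRESHOLD:
                if rng.random() < ROULETTE_SURVIVAL:
                    w /= ROULETTE_SURVIVAL
                else:
                    return _record("absorbed", pos, direc, 0.0, path)
        else:
            pos = pos + direc * d_b
            path += d_b
            if which == "cylinder":
                pos = pos + direc * 1e-7
                continue
            if which == "top":
                ci = -direc[2]
                refl, _ = fresnel_unpolarized(n_med, n_amb, max(ci, 1e-12))
                if rng.random() < refl:
                    direc[2] = -direc[2]
                    pos[2] = 0.0
                    continue
                return _record("exit_top", pos, direc, w, path)
            if which == "bottom":
                return _record("exit_bottom", pos, direc, w, path)
            return _record("exit_side", pos, direc, w, path)


def _record(event, pos, direc, w, path) -> dict:
    return {
        "event": event,
        "position": np.asarray(pos, dtype=float).copy(),
        "direction": np.asarray(direc, dtype=float).copy(),
        "weight": float(w),
        "path_length": float(path),
    }


def _py_hg(g: float, rng: np.random.Generator) -> float:
    u = rng.random()
    if g == 0.0:
        return 2 * u - 1
    frac = (1 - g * g) / (1 - g + 2 * g * u)
    return max(-1.0, min(1.0, (1 + g * g - frac * frac) / (2 * g)))


def _py_rotate(direc: np.ndarray, ct: float, phi: float) -> np.ndarray:
    ux, uy, uz = direc
    st = math.sqrt(max(0.0, 1 - ct * ct))
    cp, sp = math.cos(phi), math.sin(phi)
    if abs(uz) > 0.99999:
        new = np.array([st * cp, st * sp, ct * (1 if uz >= 0 else -1)])
    else:
        den = math.sqrt(1 - uz * uz)
        new = np.array(
            [
                st * (ux * uz * cp - uy * sp) / den + ux * ct,
                st * (uy * uz * cp + ux * sp) / den + uy * ct,
                -st * cp * den + uz * ct,
            ]
        )
    return new / np.linalg.norm(new)
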