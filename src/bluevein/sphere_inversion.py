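"""Integrating-sphere style inversion: (R, T) -> (mu_a, mu_s').

A lookup table of forward Monte Carlo diffuse reflectance and transmittance
is built over log-spaced (mu_a, mu_s') grids for a fixed slab context
(thickness, g, n, illumination).  Measured (R, T) pairs are inverted by
Gauss-Newton on the bilinearly interpolated forward map in log-coefficient
space.  The semi-infinite, reflectance-only variant recovers mu_a per
wavelength by a monotone root find with a predefined mu_s' spectrum — the
procedure used for in-vivo forearm measurements where transmittance cannot
be measured.

The sphere's own throughput model (port losses, baffles) is out of scope:
inputs are assumed already reduced to true diffuse R and T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import brentq, least_squares

from .mc_transport import SlabSample, run_semi_infinite, run_slab
from .optics_core import Medium, OpticalProperties, Spectrum, mus_from_reduced

__all__ = [
    "RTPair",
    "LookupTable",
    "build_lut",
    "invert_rt",
    "invert_r_fixed_musp",
    "monochromatic_medium",
]

_LUT_WAVELENGTH = 550.0  # placeholder lambda for monochromatic forward runs


@dataclass(frozen=True)
class RTPair:
    """A diffuse reflectance / transmittance measurement at one wavelength."""

    R: float
    T: float
    wavelength: float = _LUT_WAVELENGTH

    def __post_init__(self) -> None:
        if not (0.0 <= self.R <= 1.0 and 0.0 <= self.T <= 1.0):
            raise ValueError("R and T must lie in [0, 1]")
        if self.R + self.T > 1.0:
            raise ValueError("unphysical pair: R + T exceeds 1")


def monochromatic_medium(
    mu_a: float, mu_s_prime: float, g: float = 0.7, n: float = 1.4
) -> Medium:
    """A wavelength-flat medium for single-wavelength forward runs."""
    return Medium(
        label=f"mono(mu_a={mu_a:g},musp={mu_s_prime:g})",
        props=OpticalProperties.from_reduced(
            Spectrum.constant(mu_a),
            Spectrum.constant(mu_s_prime),
            g=g,
            n=n,
        ),
    )


@dataclass
class LookupTable:
    """Forward (R, T) evaluated on log-spaced (mu_a, mu_s') grids."""

    mu_a_grid: np.ndarray
    mu_s_prime_grid: np.ndarray
    R: np.ndarray  # shape (n_mu_a, n_musp)
    T: np.ndarray
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.all(np.diff(self.mu_a_grid) > 0)
                and np.all(np.diff(self.mu_s_prime_grid) > 0)):
            raise ValueError("LUT grids must be strictly increasing")

    def interpolators(self):
        """Cubic-spline forward maps over (log mu_a, log mu_s')."""
        la = np.log(self.mu_a_grid)
        ls = np.log(self.mu_s_prime_grid)
        fR = RegularGridInterpolator(
            (la, ls), self.R, method="cubic", bounds_error=True
        )
        fT = RegularGridInterpolator(
            (la, ls), self.T, method="cubic", bounds_error=True
        )
        return fR, fT

    def save(self, path) -> None:
        np.savez(
            path,
            mu_a_grid=self.mu_a_grid,
            mu_s_prime_grid=self.mu_s_prime_grid,
            R=self.R,
            T=self.T,
            context=np.array([repr(self.context)]),
        )

    @classmethod
    def load(cls, path) -> "LookupTable":
        import ast

        with np.load(path, allow_pickle=False) as z:
            ctx = ast.literal_eval(str(z["context"][0]))
            return cls(
                mu_a_grid=z["mu_a_grid"],
                mu_s_prime_grid=z["mu_s_prime_grid"],
                R=z["R"],
                T=z["T"],
                context=ctx,
            )


def build_lut(
    mu_a_grid,
    mu_s_prime_grid,
    thickness: float = 2.0,
    g: float = 0.7,
    n: float = 1.4,
    n_ambient: float = 1.0,
    n_photons: int = 100_000,
    seed: int = 0,
) -> LookupTable:
    """Forward-simulate diffuse (R, T) at every (mu_a, mu_s') grid node."""
    mu_a_grid = np.asarray(mu_a_grid, dtype=float)
    mu_s_prime_grid = np.asarray(mu_s_prime_grid, dtype=float)
    if mu_a_grid.size < 4 or mu_s_prime_grid.size < 4:
        raise ValueError("LUT grids need at least 4 nodes each")
    if not (np.all(np.diff(mu_a_grid) > 0)
            and np.all(np.diff(mu_s_prime_grid) > 0)):
        raise ValueError("LUT grids must be strictly increasing")
    R = np.empty((mu_a_grid.size, mu_s_prime_grid.size))
    T = np.empty_like(R)
    for i, mu_a in enumerate(mu_a_grid):
        for j, musp in enumerate(mu_s_prime_grid):
            if mu_a == 0.0 and musp == 0.0:
                raise ValueError("LUT node with mu_a = mu_s' = 0 is undefined")
            sample = SlabSample(
                thickness=thickness,
                medium=monochromatic_medium(mu_a, musp, g=g, n=n),
                n_ambient=n_ambient,
            )
            res = run_slab(
                sample,
                _LUT_WAVELENGTH,
                n_photons,
                seed=_node_seed(seed, i, j),
            )
            R[i, j] = res.R_diffuse
            T[i, j] = res.T_diffuse
    return LookupTable(
        mu_a_grid=mu_a_grid,
        mu_s_prime_grid=mu_s_prime_grid,
        R=R,
        T=T,
        context={
            "thickness": thickness,
            "g": g,
            "n": n,
            "n_ambient": n_ambient,
            "n_photons": n_photons,
            "seed": seed,
        },
    )


def _node_seed(seed: int, i: int, j: int) -> int:
    return int((seed * 1000003 + i * 7919 + j * 104729 + 17) % 2147483647)


def invert_rt(measured: RTPair, lut: LookupTable) -> dict:
    """Invert a measured (R, T) pair on the LUT's interpolated forward map.

    Returns ``mu_a``, ``mu_s_prime``, the forward residual at the solution
    and the (R, T) the LUT predicts there.  Raises if the measurement lies
    outside the region the LUT can attain.
    """
    fR, fT = lut.interpolators()
    la_lo, la_hi = math.log(lut.mu_a_grid[0]), math.log(lut.mu_a_grid[-1])
    ls_lo, ls_hi = (
        math.log(lut.mu_s_prime_grid[0]),
        math.log(lut.mu_s_prime_grid[-1]),
    )

    # nearest grid node as the starting point
    d2 = (lut.R - measured.R) ** 2 + (lut.T - measured.T) ** 2
    i0, j0 = np.unravel_index(int(np.argmin(d2)), d2.shape)
    x0 = np.array(
        [math.log(lut.mu_a_grid[i0]), math.log(lut.mu_s_prime_grid[j0])]
    )

    def resid(x):
        p = np.clip(x, [la_lo, ls_lo], [la_hi, ls_hi])
        return np.array(
            [fR(p).item() - measured.R, fT(p).item() - measured.T]
        )

    sol = least_squares(
        resid,
        x0,
        bounds=([la_lo, ls_lo], [la_hi, ls_hi]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    r_res = resid(sol.x)
    # noise floor of the LUT itself bounds an attainable residual
    tol = max(5e-3, 6.0 / math.sqrt(lut.context.get("n_photons", 10_000)))
    if np.linalg.norm(r_res) > tol:
        raise ValueError(
            "measured (R, T) lies outside the LUT's attainable region; "
            f"nearest attainable pair is (R={measured.R + r_res[0]:.4f}, "
            f"T={measured.T + r_res[1]:.4f})"
        )
    mu_a = math.exp(sol.x[0])
    musp = math.exp(sol.x[1])
    return {
        "mu_a": mu_a,
        "mu_s_prime": musp,
        "residual": float(np.linalg.norm(r_res)),
        "forward_R": measured.R + r_res[0],
        "forward_T": measured.T + r_res[1],
    }


class SemiInfiniteAlbedoLUT:
    """Semi-infinite diffuse reflectance as a function of albedo.

    The half-space has no intrinsic length scale, so its diffuse reflectance
    depends on (mu_a, mu_s) only through the single-scattering albedo
    ``a = mu_s / (mu_a + mu_s)`` (for fixed g and indices).  One pure-
    scattering random walk in units of 1/mu_t, recording the number of
    interactions K before top exit, therefore yields

        R(a) = (1 - R_specular) * E[a^K]

    exactly for every albedo at once.  Walks still inside after ``k_max``
    interactions are censored (treated as absorbed), which biases R(a) by
    less than ``a^k_max`` — negligible for the albedos the cap is chosen for.
    """

    def __init__(
        self,
        g: float = 0.7,
        n: float = 1.4,
        n_ambient: float = 1.0,
        n_photons: int = 300_000,
        seed: int = 0,
        k_max: int = 6_000,
    ):
        from .mc_transport import _semi_albedo_kernel  # compiled helper

        self.g = g
        self.n = n
        self.n_ambient = n_ambient
        self.n_photons = int(n_photons)
        self.k_max = int(k_max)
        hist, r_sp = _semi_albedo_kernel(
            g, n, n_ambient, self.k_max, self.n_photons,
            int(seed) % 2147483647,
        )
        self._hist = hist
        self._ks = np.nonzero(hist)[0]
        self._counts = hist[self._ks]
        self.one_minus_specular = 1.0 - r_sp

    def reflectance(self, albedo: float) -> float:
        """Diffuse reflectance of the half-space at the given albedo."""
        if not (0.0 <= albedo <= 1.0):
            raise ValueError("albedo must lie in [0, 1]")
        mean = np.sum(self._counts * albedo ** self._ks.astype(float))
        return float(self.one_minus_specular * mean / self.n_photons)

    def albedo_from_reflectance(self, R: float) -> float:
        """Invert R(a) (strictly increasing in a) by bracketed root find."""
        ceiling = self.reflectance(1.0)
        if R >= ceiling:
            raise ValueError(
                f"measured R={R:.4f} exceeds the mu_a -> 0 reflectance "
                f"ceiling {ceiling:.4f}"
            )
        if R <= 0:
            raise ValueError("measured R must be positive")
        floor = self.reflectance(0.0)
        if R <= floor:
            raise ValueError(
                f"measured R={R:.4f} below the attainable range "
                f"(floor {floor:.4f})"
            )
        return brentq(lambda a: self.reflectance(a) - R, 0.0, 1.0,
                      xtol=1e-12)


def invert_r_fixed_musp(
    measured_R: Spectrum,
    predefined_mu_s_prime: Spectrum,
    g: float = 0.7,
    n: float = 1.4,
    n_ambient: float = 1.0,
    n_photons: int = 300_000,
    seed: int = 0,
    lut: SemiInfiniteAlbedoLUT | None = None,
) -> Spectrum:
    """Per-wavelength mu_a from semi-infinite reflectance with mu_s' given.

    Solves R(albedo) = R_measured on the albedo reflectance curve of the
    half-space (one Monte Carlo walk shared by all wavelengths — see
    :class:`SemiInfiniteAlbedoLUT`), then converts the recovered albedo to
    mu_a via mu_s = mu_s'/(1-g):  mu_a = mu_s (1 - a) / a.
    """
    if not np.array_equal(
        measured_R.wavelengths_nm, predefined_mu_s_prime.wavelengths_nm
    ):
        raise ValueError("R and mu_s' spectra must share a wavelength grid")
    if lut is None:
        lut = SemiInfiniteAlbedoLUT(
            g=g, n=n, n_ambient=n_ambient, n_photons=n_photons, seed=seed
        )
    out = np.empty(measured_R.values.size)
    for k, (wl, R_meas, musp) in enumerate(
        zip(
            measured_R.wavelengths_nm,
            measured_R.values,
            predefined_mu_s_prime.values,
        )
    ):
        try:
            a = lut.albedo_from_reflectance(float(R_meas))
        except ValueError as exc:
            raise ValueError(f"at {wl:g} nm: {exc}") from exc
        mu_s = mus_from_reduced(float(musp), g)
        out[k] = mu_s * (1.0 - a) / a
    return Spectrum(measured_R.wavelengths_nm, out)
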