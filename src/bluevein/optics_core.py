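"""Spectral containers and single-interaction photon physics.

Units used throughout the package: lengths in mm, absorption and scattering
coefficients in 1/mm, wavelengths in nm.  The canonical working grid is
400-700 nm in 5 nm steps (61 nodes), matching the sampling of visible-range
tissue-optics measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_GRID",
    "Spectrum",
    "OpticalProperties",
    "Medium",
    "resample",
    "sample_hg_cosine",
    "fresnel_unpolarized",
    "mus_from_reduced",
]

#: canonical wavelength grid, 400-700 nm in 5 nm steps
DEFAULT_GRID = np.arange(400.0, 700.0 + 2.5, 5.0)


@dataclass(frozen=True)
class Spectrum:
    """Wavelength-indexed real-valued samples.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing wavelengths in nm.
    values : array-like
        One finite real sample per wavelength.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or v.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if wl.size != v.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {v.size} values"
            )
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)

    @classmethod
    def constant(cls, value: float, grid: np.ndarray = DEFAULT_GRID) -> "Spectrum":
        grid = np.asarray(grid, dtype=float)
        return cls(grid, np.full(grid.shape, float(value)))

    def __call__(self, wavelength_nm: float) -> float:
        """Linear interpolation at a single wavelength (no extrapolation)."""
        wl = float(wavelength_nm)
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if wl < lo or wl > hi:
            raise ValueError(
                f"wavelength {wl} nm outside spectrum range [{lo}, {hi}] nm"
            )
        return float(np.interp(wl, self.wavelengths_nm, self.values))

    def to_csv(self, path) -> None:
        """Write the `wavelength_nm,value` two-column dialect."""
        lines = ["wavelength_nm,value"]
        lines += [
            f"{w:.6g},{v:.10g}" for w, v in zip(self.wavelengths_nm, self.values)
        ]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        data = np.genfromtxt(path, delimiter=",", skip_header=1)
        data = np.atleast_2d(data)
        return cls(data[:, 0], data[:, 1])


def resample(spectrum: Spectrum, target_grid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target_grid``.

    Exact at shared nodes; raises on any extrapolation request.
    """
    grid = np.asarray(target_grid, dtype=float)
    lo, hi = spectrum.wavelengths_nm[0], spectrum.wavelengths_nm[-1]
    bad = grid[(grid < lo) | (grid > hi)]
    if bad.size:
        raise ValueError(
            f"resample would extrapolate: {bad[0]:g} nm outside [{lo:g}, {hi:g}] nm"
        )
    return Spectrum(grid, np.interp(grid, spectrum.wavelengths_nm, spectrum.values))


@dataclass(frozen=True)
class OpticalProperties:
    """Per-wavelength absorption, scattering, anisotropy and refractive index.

    The reduced scattering coefficient is derived: mu_s' = mu_s * (1 - g).
    All four spectra must share one wavelength grid.
    """

    mu_a: Spectrum
    mu_s: Spectrum
    g: Spectrum
    n: Spectrum

    def __post_init__(self) -> None:
        grids = [self.mu_a, self.mu_s, self.g, self.n]
        ref = grids[0].wavelengths_nm
        for s in grids[1:]:
            if not np.array_equal(s.wavelengths_nm, ref):
                raise ValueError("optical-property spectra must share one grid")
        if np.any(self.mu_a.values < 0):
            raise ValueError("mu_a must be nonnegative")
        if np.any(self.mu_s.values < 0):
            raise ValueError("mu_s must be nonnegative")
        if np.any(np.abs(self.g.values) >= 1):
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if np.any(self.n.values < 1):
            raise ValueError("refractive index must be >= 1")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.mu_a.wavelengths_nm

    @property
    def mu_s_prime(self) -> Spectrum:
        return Spectrum(
            self.wavelengths_nm, self.mu_s.values * (1.0 - self.g.values)
        )

    def at(self, wavelength_nm: float) -> tuple[float, float, float, float]:
        """(mu_a, mu_s, g, n) interpolated at one wavelength."""
        return (
            self.mu_a(wavelength_nm),
            self.mu_s(wavelength_nm),
            self.g(wavelength_nm),
            self.n(wavelength_nm),
        )

    @classmethod
    def from_reduced(
        cls,
        mu_a: Spectrum,
        mu_s_prime: Spectrum,
        g,
        n,
    ) -> "OpticalProperties":
        """Build from mu_s' plus g; scalars for g and n are broadcast."""
        grid = mu_a.wavelengths_nm
        g_spec = g if isinstance(g, Spectrum) else Spectrum.constant(float(g), grid)
        n_spec = n if isinstance(n, Spectrum) else Spectrum.constant(float(n), grid)
        mus = Spectrum(
            grid,
            np.array(
                [
                    mus_from_reduced(mp, gg)
                    for mp, gg in zip(mu_s_prime.values, g_spec.values)
                ]
            ),
        )
        return cls(mu_a, mus, g_spec, n_spec)


@dataclass(frozen=True)
class Medium:
    """A labelled material with optical properties."""

    label: str
    props: OpticalProperties


def sample_hg_cosine(g: float, u) -> float | np.ndarray:
    """Sample the deflection cosine of the Henyey-Greenstein phase function.

    Uses the standard inverse-CDF: for g != 0,
    cos(theta) = (1 + g^2 - ((1-g^2)/(1-g+2gu))^2) / (2g); for g = 0 the
    phase function is isotropic and cos(theta) = 2u - 1.  E[cos(theta)] = g.
    """
    if abs(g) >= 1:
        raise ValueError("|g| must be < 1 for Henyey-Greenstein sampling")
    u = np.asarray(u, dtype=float)
    if g == 0.0:
        out = 2.0 * u - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = (1.0 + g * g - frac * frac) / (2.0 * g)
        out = np.clip(out, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def fresnel_unpolarized(
    n_in: float, n_out: float, cos_incident: float
) -> tuple[float, float]:
    """Unpolarized Fresnel reflectance and the refracted direction cosine.

    Returns ``(R, cos_t)``; beyond the critical angle ``R = 1`` and
    ``cos_t = 0``.  ``cos_incident`` must lie in (0, 1].
    """
    if n_in < 1 or n_out < 1:
        raise ValueError("refractive indices must be >= 1")
    ci = float(cos_incident)
    if not (0.0 < ci <= 1.0):
        raise ValueError("cos_incident must lie in (0, 1]")
    if n_in == n_out:
        return 0.0, ci
    sin_i2 = 1.0 - ci * ci
    sin_t2 = (n_in / n_out) ** 2 * sin_i2
    if sin_t2 >= 1.0:  # total internal reflection
        return 1.0, 0.0
    ct = math.sqrt(1.0 - sin_t2)
    rs = (n_in * ci - n_out * ct) / (n_in * ci + n_out * ct)
    rp = (n_in * ct - n_out * ci) / (n_in * ct + n_out * ci)
    return 0.5 * (rs * rs + rp * rp), ct


def mus_from_reduced(mu_s_prime: float, g: float) -> float:
    """Recover mu_s from the reduced coefficient: mu_s = mu_s' / (1 - g)."""
    if g >= 1:
        raise ValueError("g must be < 1 to recover mu_s from mu_s'")
    return float(mu_s_prime) / (1.0 - float(g))
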