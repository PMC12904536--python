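"""Independent oracles for the transport code.

These are deliberately coded differently from the package kernels: the slab
oracle is a vectorized *analog* Monte Carlo (physical absorption at each
interaction, no implicit capture, no Russian roulette), so it shares no
variance-reduction machinery with the implementation it checks.  The
semi-infinite oracle is the diffusion-approximation closed form.
"""

import math

import numpy as np


def _fresnel_vec(ni: float, no: float, ci: np.ndarray) -> np.ndarray:
    if ni == no:
        return np.zeros_like(ci)
    sin_t2 = (ni / no) ** 2 * (1.0 - ci**2)
    out = np.ones_like(ci)
    ok = sin_t2 < 1.0
    ct = np.sqrt(1.0 - np.minimum(sin_t2, 1.0 - 1e-15))
    rs = (ni * ci - no * ct) / (ni * ci + no * ct)
    rp = (ni * ct - no * ci) / (ni * ct + no * ci)
    out[ok] = 0.5 * (rs[ok] ** 2 + rp[ok] ** 2)
    return out


def _scatter_vec(u: np.ndarray, g: float, rng) -> np.ndarray:
    n = u.shape[0]
    xi = rng.random(n)
    if g == 0.0:
        ct = 2 * xi - 1
    else:
        frac = (1 - g * g) / (1 - g + 2 * g * xi)
        ct = np.clip((1 + g * g - frac**2) / (2 * g), -1.0, 1.0)
    st = np.sqrt(1 - ct**2)
    phi = 2 * np.pi * rng.random(n)
    cp, sp = np.cos(phi), np.sin(phi)
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    near_pole = np.abs(uz) > 0.99999
    den = np.sqrt(np.maximum(1 - uz**2, 1e-30))
    nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
    ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
    nz = -st * cp * den + uz * ct
    nx = np.where(near_pole, st * cp, nx)
    ny = np.where(near_pole, st * sp, ny)
    nz = np.where(near_pole, np.sign(uz) * ct, nz)
    new = np.stack([nx, ny, nz], axis=1)
    return new / np.linalg.norm(new, axis=1, keepdims=True)


def analog_slab_rt(
    mu_a: float,
    mu_s: float,
    g: float,
    n_med: float,
    n_amb: float,
    thickness: float,
    n_photons: int,
    seed: int,
) -> tuple[float, float]:
    """Diffuse (R, T) of a slab at normal incidence by analog Monte Carlo.

    Returns fractions of launched photons.  Specular entry reflection is
    removed before launch, matching the diffuse-only convention of the
    implementation under test.
    """
    rng = np.random.default_rng(seed)
    mu_t = mu_a + mu_s
    p_abs = mu_a / mu_t

    r_sp = _fresnel_vec(n_amb, n_med, np.array([1.0]))[0]
    entered = rng.random(n_photons) >= r_sp
    z = np.zeros(int(np.count_nonzero(entered)))
    u = np.zeros((z.size, 3))
    u[:, 2] = 1.0
    R_count = 0
    T_count = 0

    while z.size:
        s = -np.log1p(-rng.random(z.size)) / mu_t
        z_new = z + u[:, 2] * s
        hit_bot = (u[:, 2] > 0) & (z_new >= thickness)
        hit_top = (u[:, 2] < 0) & (z_new <= 0)
        crossing = hit_bot | hit_top

        keep = np.ones(z.size, dtype=bool)
        if crossing.any():
            idx = np.flatnonzero(crossing)
            ci = np.abs(u[idx, 2])
            refl = _fresnel_vec(n_med, n_amb, ci)
            reflected = rng.random(idx.size) < refl
            exit_idx = idx[~reflected]
            T_count += int(np.count_nonzero(z_new[exit_idx] >= thickness))
            R_count += int(np.count_nonzero(z_new[exit_idx] <= 0))
            keep[exit_idx] = False
            refl_idx = idx[reflected]
            z[refl_idx] = np.where(hit_bot[refl_idx], thickness, 0.0)
            u[refl_idx, 2] = -u[refl_idx, 2]

        inter = ~crossing & keep
        if inter.any():
            z[inter] = z_new[inter]
            absorbed = np.zeros(z.size, dtype=bool)
            absorbed[inter] = rng.random(int(np.count_nonzero(inter))) < p_abs
            keep &= ~absorbed
            scat = inter & keep
            if scat.any():
                u[scat] = _scatter_vec(u[scat], g, rng)

        z, u = z[keep], u[keep]

    return R_count / n_photons, T_count / n_photons


def diffusion_semi_infinite_R(mu_a: float, mu_s_prime: float, n_rel: float) -> float:
    """Diffusion-approximation total diffuse reflectance of a half-space.

    Uses the transport albedo a' = mu_s'/(mu_s'+mu_a) and the internal-
    reflection parameter k = (1+r_d)/(1-r_d) with the Groenhuis/Egan
    polynomial fit for r_d(n_rel).  Valid for a' close to 1.
    """
    ap = mu_s_prime / (mu_s_prime + mu_a)
    r_d = (
        -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
        if n_rel != 1.0
        else 0.0
    )
    k = (1 + r_d) / (1 - r_d)
    return ap / (
        1 + 2 * k * (1 - ap) + (1 + 2 * k / 3) * math.sqrt(3 * (1 - ap))
    )


def ray_march_cylinder_distance(
    origin, direction, axis_x: float, axis_z: float, radius: float,
    t_max: float = 100.0, dt: float = 1e-4,
) -> float:
    """Brute-force distance to a y-axis-aligned cylinder surface crossing.

    Marches the ray in steps of ``dt`` until the inside/outside predicate
    flips, then bisects the bracketing interval down to 1e-9 mm.
    """
    ox, _, oz = (float(v) for v in origin)
    ux, _, uz = (float(v) for v in direction)

    def inside(t):
        x = ox + ux * t - axis_x
        z = oz + uz * t - axis_z
        return x * x + z * z < radius * radius

    s0 = inside(0.0)
    t = dt
    while t <= t_max:
        if inside(t) != s0:
            lo, hi = t - dt, t
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if inside(mid) != s0:
                    hi = mid
                else:
                    lo = mid
            return 0.5 * (lo + hi)
        t += dt
    return math.inf
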