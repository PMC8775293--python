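"""Even-asphere surface geometry: sag, normals and ray intersection.

All optical surfaces of the model eye are rotationally symmetric even
aspheres

    z(r) = c r^2 / (1 + sqrt(1 - (1+k) c^2 r^2)) + sum_i a_{2i} r^{2i}

with curvature ``c = 1/R`` (``R = inf`` means a plane), conic constant
``k`` and even polynomial coefficients ``a_2, a_4, ...`` starting at the
quadratic term.  Sign convention: light travels in +z (cornea to retina);
a positive radius puts the centre of curvature on the +z (retinal) side.

The conic part of every surface is a quadric, so ray intersection is
solved in closed form; surfaces with polynomial terms refine the conic
roots by Newton iteration on the exact sag residual.  A hit is only
valid on the sag branch through the vertex (the "near sheet" of a
hyperboloid) and inside the surface's aperture annulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: Newton convergence tolerance on the axial residual, in mm.
INTERSECT_TOL = 1e-9
#: Maximum Newton iterations before a ray is declared a miss.
MAX_NEWTON_ITER = 50
#: Minimum travel distance, in mm, to rule out re-intersection at launch.
LAUNCH_EPS = 1e-6


class Behavior(str, Enum):
    """Interaction mode of a placed surface in the non-sequential trace."""

    REFRACT = "refract"            # Snell + Fresnel split
    REFRACT_NO_R = "refract_no_r"  # anti-reflecting: transmits all non-TIR energy
    MIRROR = "mirror"              # ideal reflector
    ABSORB = "absorb"              # terminates rays, energy booked
    SCATTER = "scatter"            # frosted: diffuse transmit + reflect
    IRIS = "iris"                  # plane stop: hole passes, annulus absorbs
    DETECTOR = "detector"          # retina: records hit, terminates


@dataclass(frozen=True)
class AsphericProfile:
    """Rotationally symmetric even-asphere profile.

    Parameters
    ----------
    radius :
        Radius of curvature in mm; ``np.inf`` yields a plane.
    conic :
        Conic constant k (0 sphere, -1 paraboloid, < -1 hyperboloid).
    coeffs :
        Mapping even power -> coefficient, e.g. ``{2: a2, 4: a4}`` with
        units mm^(1-power).  Empty for pure conics.
    aperture_radius :
        Outer radial extent of the usable surface patch, mm.
    inner_aperture_radius :
        Inner radius of an annular aperture (0 for a full disc).
    """

    radius: float
    conic: float = 0.0
    coeffs: dict[int, float] = field(default_factory=dict)
    aperture_radius: float = np.inf
    inner_aperture_radius: float = 0.0

    def __post_init__(self):
        for p in self.coeffs:
            if p < 2 or p % 2:
                raise ValueError(f"polynomial powers must be even and >= 2, got {p}")

    @property
    def curvature(self) -> float:
        return 0.0 if np.isinf(self.radius) else 1.0 / self.radius

    @property
    def is_plane(self) -> bool:
        return self.curvature == 0.0 and not self.coeffs

    @property
    def max_conic_radius(self) -> float:
        """Largest r at which the conic square root stays real."""
        c, k = self.curvature, self.conic
        if c == 0.0 or (1.0 + k) <= 0.0:
            return np.inf
        return 1.0 / (abs(c) * np.sqrt(1.0 + k))

    # -- sag and slope ---------------------------------------------------

    def sag(self, r):
        """Axial sag z(r) in mm.  Raises on points outside the conic domain."""
        r = np.asarray(r, dtype=float)
        arg = 1.0 - (1.0 + self.conic) * self.curvature**2 * r**2
        if np.any(arg < -INTERSECT_TOL):
            raise ValueError("r outside the conic domain of the profile")
        arg = np.maximum(arg, 0.0)
        z = self.curvature * r**2 / (1.0 + np.sqrt(arg))
        for p, a in self.coeffs.items():
            z = z + a * r**p
        return z if z.ndim else float(z)

    def sag_slope(self, r):
        """dz/dr, analytic.  Diverges at the conic-domain rim (r -> R/sqrt(1+k))."""
        r = np.asarray(r, dtype=float)
        arg = np.maximum(1.0 - (1.0 + self.conic) * self.curvature**2 * r**2, 0.0)
        with np.errstate(divide="ignore"):
            s = self.curvature * r / np.sqrt(arg)
        for p, a in self.coeffs.items():
            s = s + p * a * r ** (p - 1)
        return s if s.ndim else float(s)

    def in_aperture(self, r):
        return (r <= self.aperture_radius + 1e-12) & (r >= self.inner_aperture_radius - 1e-12)


@dataclass(frozen=True)
class PlacedSurface:
    """An aspheric profile placed on the optical axis.

    ``z_vertex`` is measured from the anterior corneal vertex; ``decenter_x``
    shifts the profile along the nasal(-x)/temporal(+x) axis.  ``n_front`` /
    ``n_back`` are the refractive indices on the -z and +z sides.
    """

    name: str
    profile: AsphericProfile
    z_vertex: float
    behavior: Behavior
    n_front: float = 1.0
    n_back: float = 1.0
    decenter_x: float = 0.0


@dataclass(frozen=True)
class CylinderSurface:
    """Axis-aligned cylinder barrel (the IOL optic edge).

    ``n_front`` is the index inside the barrel (the IOL material) and
    ``n_back`` the index outside (aqueous/vitreous).
    """

    name: str
    radius: float
    z_min: float
    z_max: float
    behavior: Behavior
    n_front: float = 1.0
    n_back: float = 1.0


# ---------------------------------------------------------------------------
# Vectorised intersection
# ---------------------------------------------------------------------------

def _conic_roots(profile: AsphericProfile, z0, dx, pos, dirn):
    """Both parametric roots of the ray/conic-quadric intersection.

    The conic surface satisfies  c (x^2+y^2) + c (1+k) w^2 - 2 w = 0 with
    w = z - z0 (local, decentred coordinates).  Returns (t1, t2) arrays with
    NaN where no real root exists.  A plane returns its single root twice.
    """
    x = pos[:, 0] - dx
    y = pos[:, 1]
    w = pos[:, 2] - z0
    dxr, dyr, dzr = dirn[:, 0], dirn[:, 1], dirn[:, 2]
    c, k = profile.curvature, profile.conic

    if c == 0.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(dzr != 0.0, -w / dzr, np.nan)
        return t, t.copy()

    A = c * (dxr**2 + dyr**2 + (1.0 + k) * dzr**2)
    B = 2.0 * c * (x * dxr + y * dyr + (1.0 + k) * w * dzr) - 2.0 * dzr
    C = c * (x**2 + y**2 + (1.0 + k) * w**2) - 2.0 * w

    t1 = np.full_like(A, np.nan)
    t2 = np.full_like(A, np.nan)
    lin = np.abs(A) < 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        tl = -C / B
    t1[lin] = tl[lin]
    t2[lin] = tl[lin]

    disc = B**2 - 4.0 * A * C
    q = ~lin & (disc >= 0.0)
    sq = np.sqrt(np.where(q, disc, 0.0))
    # numerically stable quadratic roots
    sgnB = np.where(B >= 0.0, 1.0, -1.0)
    qq = -0.5 * (B + sgnB * sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        ra = qq / A
        rb = C / qq
    t1[q] = np.minimum(ra, rb)[q]
    t2[q] = np.maximum(ra, rb)[q]
    return t1, t2


def _sag_residual(profile, z0, dx, pos, dirn, t):
    """f(t) = z(t) - z0 - sag(r(t)); NaN outside the conic domain."""
    p = pos + t[:, None] * dirn
    x = p[:, 0] - dx
    r2 = x**2 + p[:, 1] ** 2
    c, k = profile.curvature, profile.conic
    arg = 1.0 - (1.0 + k) * c**2 * r2
    ok = arg >= 0.0
    arg = np.maximum(arg, 0.0)
    sag = c * r2 / (1.0 + np.sqrt(arg))
    for pw, a in profile.coeffs.items():
        sag = sag + a * r2 ** (pw // 2)
    f = (p[:, 2] - z0) - sag
    f[~ok] = np.nan
    return f, np.sqrt(r2)


def intersect_surface(surface: PlacedSurface, pos: np.ndarray, dirn: np.ndarray,
                      eps: float = LAUNCH_EPS):
    """Nearest forward intersection of rays with a placed asphere.

    Returns ``(t, valid, clipped)``: ``t`` travel distances (NaN = miss),
    ``valid`` marks hits on the surface patch inside the aperture annulus,
    ``clipped`` marks rays that pierce the sag branch but outside the
    aperture (the non-sequential engine decides what those mean).
    """
    prof = surface.profile
    z0, dx = surface.z_vertex, surface.decenter_x
    n = len(pos)
    t1, t2 = _conic_roots(prof, z0, dx, pos, dirn)

    best_t = np.full(n, np.nan)
    best_r = np.full(n, np.nan)
    for t0 in (t1, t2):
        t = t0.copy()
        bad = ~np.isfinite(t) | (t <= eps)
        t[bad] = np.nan
        if prof.coeffs:
            # Newton-polish only seeds that could land inside the patch: the
            # polynomial perturbs the conic by well under 1 mm there, so a
            # conic seed far outside the aperture cannot be pulled back in
            _, r_seed = _sag_residual(prof, z0, dx, pos, dirn,
                                      np.where(np.isfinite(t), t, 0.0))
            far = np.isfinite(t) & (r_seed > prof.aperture_radius + 1.0)
            t[far] = np.nan
            t = _newton_refine(prof, z0, dx, pos, dirn, t)
            bad = ~np.isfinite(t) | (t <= eps)
            t[bad] = np.nan
        f, r = _sag_residual(prof, z0, dx, pos, dirn, t)
        on_branch = np.isfinite(f) & (np.abs(f) < 1e-6)
        cand = np.isfinite(t) & on_branch
        take = cand & (~np.isfinite(best_t) | (t < best_t))
        best_t[take] = t[take]
        best_r[take] = r[take]

    hit = np.isfinite(best_t)
    in_ap = np.zeros(n, dtype=bool)
    in_ap[hit] = prof.in_aperture(best_r[hit])
    valid = hit & in_ap
    clipped = hit & ~in_ap
    return best_t, valid, clipped


def _newton_refine(profile, z0, dx, pos, dirn, t):
    """Newton-polish conic-seeded roots on the full asphere residual.

    Iterates on the shrinking subset of unconverged rays only.
    """
    t = t.copy()
    idx = np.flatnonzero(np.isfinite(t))
    for _ in range(MAX_NEWTON_ITER):
        if idx.size == 0:
            break
        ts = t[idx]
        ps, ds = pos[idx], dirn[idx]
        f, r = _sag_residual(profile, z0, dx, ps, ds, ts)
        slope = profile.sag_slope(np.where(np.isfinite(r), r, 0.0))
        p = ps + ts[:, None] * ds
        x = p[:, 0] - dx
        with np.errstate(invalid="ignore", divide="ignore"):
            inv_r = np.where(r > 1e-12, 1.0 / r, 0.0)
            # df/dt = dz - slope * d(r)/dt
            drdt = (x * ds[:, 0] + p[:, 1] * ds[:, 1]) * inv_r
            dfdt = ds[:, 2] - slope * drdt
            step = f / dfdt
        bad = ~np.isfinite(step)
        step = np.where(bad, 0.0, step)
        t[idx] = ts - step
        keep = ~(np.abs(f) < INTERSECT_TOL) & ~bad & np.isfinite(t[idx])
        idx = idx[keep]
    f, _ = _sag_residual(profile, z0, dx, pos, dirn, t)
    t[~(np.abs(f) < 1e-6)] = np.nan
    return t


def intersect_cylinder(surface: CylinderSurface, pos: np.ndarray, dirn: np.ndarray,
                       eps: float = LAUNCH_EPS):
    """Nearest forward intersection with the barrel x^2+y^2 = rho^2, z-clipped."""
    x, y = pos[:, 0], pos[:, 1]
    dx, dy = dirn[:, 0], dirn[:, 1]
    A = dx**2 + dy**2
    B = 2.0 * (x * dx + y * dy)
    C = x**2 + y**2 - surface.radius**2
    disc = B**2 - 4.0 * A * C
    n = len(pos)
    best = np.full(n, np.nan)
    ok = (disc >= 0.0) & (A > 1e-16)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    for sgn in (-1.0, 1.0):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (-B + sgn * sq) / (2.0 * A)
        z = pos[:, 2] + t * dirn[:, 2]
        good = ok & (t > eps) & (z >= surface.z_min) & (z <= surface.z_max)
        take = good & (~np.isfinite(best) | (t < best))
        best[take] = t[take]
    valid = np.isfinite(best)
    return best, valid, np.zeros(n, dtype=bool)


def surface_normal(surface, points: np.ndarray) -> np.ndarray:
    """Unit normals at points on a surface, oriented toward -z (asphere) or
    radially outward (cylinder); the engine flips them against the ray."""
    if isinstance(surface, CylinderSurface):
        n = np.zeros_like(points)
        r = np.hypot(points[:, 0], points[:, 1])
        r = np.where(r > 1e-15, r, 1.0)
        n[:, 0] = points[:, 0] / r
        n[:, 1] = points[:, 1] / r
        return n
    prof = surface.profile
    x = points[:, 0] - surface.decenter_x
    y = points[:, 1]
    r = np.hypot(x, y)
    slope = prof.sag_slope(np.minimum(r, prof.max_conic_radius * (1 - 1e-12)))
    n = np.empty_like(points)
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_r = np.where(r > 1e-12, 1.0 / r, 0.0)
    n[:, 0] = slope * x * inv_r
    n[:, 1] = slope * y * inv_r
    n[:, 2] = -1.0
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    return n
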