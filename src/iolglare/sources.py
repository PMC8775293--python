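"""Collimated extended-source ray bundles at oblique incidence.

The glare source is a collimated pencil from an extended disc source of
6 mm diameter, incident from the temporal side (+x) at 50-90 degrees from
the optical axis, aimed by default at the centre of the (nasally
decentred) pupil opening.  The disc is perpendicular to the propagation
direction; total bundle energy is normalised to 1.

The default layout is a deterministic sunflower (Fibonacci) grid so that
specular experiment results carry no Monte-Carlo noise; seeded uniform
sampling is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eye import PUPIL_DECENTER, Z_PUPIL

#: default distance from the aim point back to the launch disc, mm
LAUNCH_DISTANCE = 30.0

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class SourceSpec:
    """Extended collimated disc source.

    incidence_angle is measured from the optical axis, temporal side;
    propagation direction is ``(-sin a, 0, cos a)`` (temporal to nasal).
    """

    incidence_angle: float                 # degrees, 0 <= a <= 90
    disc_diameter: float = 6.0             # mm
    ray_count: int = 1_000_000
    layout: str = "sunflower"              # or "random"
    seed: int = 0
    aim_point: tuple = (PUPIL_DECENTER, 0.0, Z_PUPIL)

    def direction(self) -> np.ndarray:
        a = np.radians(self.incidence_angle)
        return np.array([-np.sin(a), 0.0, np.cos(a)])


def disc_points(n: int, radius: float, layout: str = "sunflower",
                seed: int = 0) -> np.ndarray:
    """2-D points filling a disc: deterministic sunflower grid or uniform random."""
    if layout == "sunflower":
        i = np.arange(n, dtype=float)
        r = radius * np.sqrt((i + 0.5) / n)
        th = i * _GOLDEN_ANGLE
        return np.column_stack([r * np.cos(th), r * np.sin(th)])
    if layout == "random":
        rng = np.random.default_rng(seed)
        r = radius * np.sqrt(rng.random(n))
        th = 2.0 * np.pi * rng.random(n)
        return np.column_stack([r * np.cos(th), r * np.sin(th)])
    raise ValueError(f"unknown layout {layout!r}")


def make_bundle(spec: SourceSpec):
    """Build launch positions, directions and energies for a source spec.

    Returns ``(pos, dirn, energy)`` with ``pos`` of shape (n, 3), every
    direction equal to ``spec.direction()``, and energies summing to 1.
    """
    if not (0.0 <= spec.incidence_angle <= 90.0):
        raise ValueError("incidence angle must be in [0, 90] degrees")
    if spec.ray_count < 1:
        raise ValueError("ray_count must be >= 1")
    d = spec.direction()
    # orthonormal disc frame perpendicular to propagation
    e1 = np.array([d[2], 0.0, -d[0]])      # in the x-z plane
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    pts = disc_points(spec.ray_count, spec.disc_diameter / 2.0,
                      spec.layout, spec.seed)
    center = np.asarray(spec.aim_point, dtype=float) - LAUNCH_DISTANCE * d
    pos = center + pts[:, 0:1] * e1 + pts[:, 1:2] * e2
    dirn = np.tile(d, (spec.ray_count, 1))
    energy = np.full(spec.ray_count, 1.0 / spec.ray_count)
    return pos, dirn, energy


def visual_axis_bundle(ray_count: int = 3000, diameter: float = 1.5):
    """Narrow collimated bundle along the visual axis (5 degrees nasal).

    The fixation direction is tilted 5 degrees nasally in object space, so
    the chief ray travels with direction ``(+sin 5, 0, cos 5)`` through the
    pupil centre and lands on the temporal retina - this bundle's retinal
    centroid defines the foveal position.
    """
    a = np.radians(5.0)
    d = np.array([np.sin(a), 0.0, np.cos(a)])
    e1 = np.array([d[2], 0.0, -d[0]])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    pts = disc_points(ray_count, diameter / 2.0)
    center = np.array([PUPIL_DECENTER, 0.0, Z_PUPIL]) - LAUNCH_DISTANCE * d
    pos = center + pts[:, 0:1] * e1 + pts[:, 1:2] * e2
    dirn = np.tile(d, (ray_count, 1))
    energy = np.full(ray_count, 1.0 / ray_count)
    return pos, dirn, energy


def chief_ray_pupil_crossing(model, angle: float, offset: float):
    """Pupil-plane x of the chief ray launched with transverse offset ``offset``.

    The chief ray starts on the source axis shifted by ``offset`` along the
    in-plane disc basis vector, refracts through both corneal surfaces and
    is propagated to the pupil plane.  Returns None when the ray misses the
    cornea or is totally internally reflected.
    """
    from .engine import refract as _refract
    from .geometry import intersect_surface, surface_normal

    a = np.radians(angle)
    d = np.array([-np.sin(a), 0.0, np.cos(a)])
    e1 = np.array([d[2], 0.0, -d[0]])
    pos = (np.array([PUPIL_DECENTER, 0.0, Z_PUPIL]) + offset * e1
           - LAUNCH_DISTANCE * d)[None, :]
    dirn = d[None, :]
    for name in ("cornea_front", "cornea_back"):
        srf = model[name]
        t, valid, _ = intersect_surface(srf, pos, dirn)
        if not valid[0]:
            return None
        pos = pos + t[:, None] * dirn
        nrm = surface_normal(srf, pos)
        n_inc = np.where((dirn * nrm).sum(1)[:, None] > 0, -nrm, nrm)
        dirn, tir = _refract(dirn, n_inc, srf.n_front, srf.n_back)
        if tir[0]:
            return None
    s = (Z_PUPIL - pos[0, 2]) / dirn[0, 2]
    return float(pos[0, 0] + s * dirn[0, 0])


def aim_through_pupil(model, angle: float) -> tuple:
    """Aim point whose refracted chief ray crosses the pupil centre.

    At oblique incidence, corneal refraction displaces a beam aimed at the
    in-air pupil position temporally by several mm, leaving the pupil
    under-illuminated; this calibration (deterministic bisection on the
    transverse launch offset) restores the protocol of tracing the pencil
    *through* the pupil.  Returns an ``aim_point`` for :class:`SourceSpec`.
    """
    target = PUPIL_DECENTER
    lo, hi = -4.0, 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        x = chief_ray_pupil_crossing(model, angle, mid)
        if x is None or x > target:
            hi = mid
        else:
            lo = mid
    s = 0.5 * (lo + hi)
    a = np.radians(angle)
    d = np.array([-np.sin(a), 0.0, np.cos(a)])
    e1 = np.array([d[2], 0.0, -d[0]])
    aim = np.array([PUPIL_DECENTER, 0.0, Z_PUPIL]) + s * e1
    return tuple(aim)


def pupil_coverage_fraction(spec: SourceSpec, samples: int = 20000) -> float:
    """Fraction of the pupil opening covered by the projected source disc.

    Projects the collimated beam footprint onto the pupil plane and
    reports the covered fraction of the 4.5 mm (decentred) opening; a
    value < 1 means the source under-fills the pupil at this angle.
    """
    from .eye import PUPIL_RADIUS

    d = spec.direction()
    if d[2] <= 0:
        return 0.0
    rng = np.random.default_rng(12345)
    r = PUPIL_RADIUS * np.sqrt(rng.random(samples))
    th = 2.0 * np.pi * rng.random(samples)
    px = PUPIL_DECENTER + r * np.cos(th)
    py = r * np.sin(th)
    # distance of each pupil point from the beam axis (through aim point)
    aim = np.asarray(spec.aim_point)
    rel = np.column_stack([px, py, np.full(samples, Z_PUPIL)]) - aim
    along = rel @ d
    perp = rel - along[:, None] * d
    covered = np.linalg.norm(perp, axis=1) <= spec.disc_diameter / 2.0
    return float(covered.mean())
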