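"""Non-sequential ray propagation with deterministic Fresnel splitting.

Every ray iteratively intersects the *nearest* forward object of the model
(no prescribed surface order), and the object's behaviour is applied:

* ``refract``     - vector Snell refraction; the Fresnel-reflected fraction
  is spawned as a child ray (deterministic splitting, no Russian roulette),
  so specular maps are Monte-Carlo-noise free.
* ``refract_no_r`` - idealised anti-reflecting interface: all refractable
  energy transmits; energy that would undergo TIR is absorbed.
* ``mirror``      - ideal reflector.
* ``absorb``      - terminates the ray; energy booked per object.
* ``scatter``     - frosted finish: the transmitted and internally
  reflected fractions are each distributed over K diffuse child rays
  (cosine-weighted "Lambertian" hemisphere by default, uniform "isotropic"
  optional).
* ``iris``        - plane stop: transmits inside the decentred pupil hole,
  absorbs on the annulus.
* ``detector``    - the retina: records position/energy/path class.

The model is an open assembly of bounded objects: a ray that crosses
outside a surface's aperture continues unaffected, and a ray with no
forward intersection leaves the model (booked "blocked" if it never met
an object, "escaped" otherwise).

Path tagging uses bit flags (pupil passage, optic contact, edge
transmission, edge reflection) from which the retinal hit classes are
derived: ``interspace`` (never touched optic or edge) > ``edge_reflected``
> ``edge_transmitted`` > ``direct``.

Energy audit: emitted = retina + absorbed + escaped/blocked + cutoff,
enforced to 1e-9 relative on every trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    Behavior,
    CylinderSurface,
    LAUNCH_EPS,
    intersect_cylinder,
    intersect_surface,
    surface_normal,
)
from .eye import EyeModel, PUPIL_DECENTER, PUPIL_RADIUS

# path-tag bit flags
TAG_PUPIL = 1       # passed the pupil hole
TAG_OPTIC = 2       # interacted with iol_front or iol_back
TAG_EDGE_T = 4      # transmitted through the optic edge
TAG_EDGE_R = 8      # reflected at the optic edge (internal or external)

#: retinal hit classes, in tag-precedence order
CLASSES = ("interspace", "edge_reflected", "edge_transmitted", "direct", "other")
CLASS_INDEX = {name: i for i, name in enumerate(CLASSES)}


def classify(flags: np.ndarray) -> np.ndarray:
    """Map tag bit-flags to class indices (see :data:`CLASSES`)."""
    cls = np.full(flags.shape, CLASS_INDEX["direct"], dtype=np.int8)
    cls[(flags & TAG_EDGE_T) > 0] = CLASS_INDEX["edge_transmitted"]
    cls[(flags & TAG_EDGE_R) > 0] = CLASS_INDEX["edge_reflected"]
    cls[(flags & (TAG_OPTIC | TAG_EDGE_T | TAG_EDGE_R)) == 0] = CLASS_INDEX["interspace"]
    return cls


@dataclass
class TracePolicy:
    """Termination and splitting policy of the non-sequential trace."""

    energy_cutoff_frac: float = 1e-4   # of the launch energy of a primary ray
    max_generation: int = 8            # secondary-branch depth (reflections/scatter)
    max_events: int = 50               # interactions per ray, guards loops
    scatter_children: int = 8          # K diffuse children per frosted portion
    scatter_model: str = "lambertian"  # or "isotropic"
    seed: int = 0                      # RNG for diffuse scattering only


@dataclass
class TraceLedger:
    """Energy audit of one trace."""

    emitted: float = 0.0
    retina: dict = field(default_factory=dict)       # class name -> energy
    absorbed: dict = field(default_factory=dict)     # object name -> energy
    escaped: float = 0.0
    blocked: float = 0.0
    cutoff: float = 0.0
    warnings: dict = field(default_factory=dict)

    @property
    def retina_total(self) -> float:
        return float(sum(self.retina.values()))

    @property
    def balance(self) -> float:
        """Relative energy imbalance; must stay below 1e-9."""
        sinks = (self.retina_total + sum(self.absorbed.values())
                 + self.escaped + self.blocked + self.cutoff)
        return abs(self.emitted - sinks) / max(self.emitted, 1e-300)

    def check(self):
        if self.balance > 1e-9:
            raise RuntimeError(f"energy ledger imbalance {self.balance:.3e}")


@dataclass
class RetinalHits:
    """Recorded retina detector events."""

    points: np.ndarray      # (n, 3) positions on the retinal sphere, mm
    energy: np.ndarray      # (n,)
    cls: np.ndarray         # (n,) int8 class index into CLASSES
    flags: np.ndarray | None = None   # (n,) raw path-tag bits, diagnostics

    def select(self, class_name: str | None):
        if class_name is None:
            return np.ones(len(self.energy), dtype=bool)
        if class_name == "edge":
            return ((self.cls == CLASS_INDEX["edge_transmitted"])
                    | (self.cls == CLASS_INDEX["edge_reflected"]))
        return self.cls == CLASS_INDEX[class_name]


# ---------------------------------------------------------------------------
# elementary optics
# ---------------------------------------------------------------------------

def refract(direction: np.ndarray, normal: np.ndarray, n1, n2):
    """Vector Snell refraction.

    ``normal`` must oppose the ray (``direction . normal < 0``).  Returns
    ``(t_dir, tir)``; ``t_dir`` rows are NaN where total internal reflection
    occurs.  Works on single vectors or (n, 3) stacks.
    """
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    n = np.atleast_2d(np.asarray(normal, dtype=float))
    eta = (np.asarray(n1, dtype=float) / np.asarray(n2, dtype=float)).reshape(-1)
    cosi = -np.sum(d * n, axis=1)
    sin2t = eta**2 * (1.0 - cosi**2)
    tir = sin2t > 1.0
    cost = np.sqrt(np.maximum(1.0 - sin2t, 0.0))
    t = eta[:, None] * d + (eta * cosi - cost)[:, None] * n
    t[tir] = np.nan
    if np.ndim(direction) == 1:
        return (t[0], bool(tir[0]))
    return t, tir


def reflect(direction: np.ndarray, normal: np.ndarray):
    d = np.atleast_2d(direction)
    n = np.atleast_2d(normal)
    r = d - 2.0 * np.sum(d * n, axis=1)[:, None] * n
    return r[0] if np.ndim(direction) == 1 else r


def fresnel_unpolarized(theta1, n1, n2):
    """Unpolarised Fresnel power reflectance; 1 under TIR.

    ``theta1`` is the incidence angle in radians (array ok).
    """
    th = np.asarray(theta1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    cosi = np.cos(th)
    sin2t = (n1 / n2) ** 2 * np.sin(th) ** 2
    tir = sin2t > 1.0
    cost = np.sqrt(np.maximum(1.0 - sin2t, 0.0))
    rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
    rp = (n2 * cosi - n1 * cost) / (n2 * cosi + n1 * cost)
    R = 0.5 * (rs**2 + rp**2)
    R = np.where(tir, 1.0, R)
    return float(R) if R.ndim == 0 else R


def _fresnel_from_cos(cosi, cost, n1, n2, tir):
    rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
    rp = (n2 * cosi - n1 * cost) / (n2 * cosi + n1 * cost)
    return np.where(tir, 1.0, 0.5 * (rs**2 + rp**2))


def scatter_hemisphere(normal: np.ndarray, rng: np.random.Generator,
                       n: int = 1, model: str = "lambertian") -> np.ndarray:
    """Sample diffuse directions in the hemisphere about ``normal``.

    ``lambertian`` is cosine-weighted (radiance independent of view angle);
    ``isotropic`` is uniform in solid angle.
    """
    normal = np.atleast_2d(np.asarray(normal, dtype=float))
    if len(normal) == 1:
        normal = np.repeat(normal, n, axis=0)
    m = len(normal)
    u = rng.random(m)
    phi = 2.0 * np.pi * rng.random(m)
    if model == "lambertian":
        sin_t = np.sqrt(u)
        cos_t = np.sqrt(1.0 - u)
    elif model == "isotropic":
        cos_t = u
        sin_t = np.sqrt(1.0 - u**2)
    else:
        raise ValueError(f"unknown scatter model {model!r}")
    # local frame about each normal
    a = np.where(np.abs(normal[:, 2:3]) < 0.9,
                 np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
    t1 = np.cross(normal, a)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(normal, t1)
    d = (cos_t[:, None] * normal
         + (sin_t * np.cos(phi))[:, None] * t1
         + (sin_t * np.sin(phi))[:, None] * t2)
    return d


# ---------------------------------------------------------------------------
# batch containers
# ---------------------------------------------------------------------------

class _Batch:
    """Plain struct-of-arrays for a cohort of in-flight rays."""

    __slots__ = ("pos", "dirn", "energy", "gen", "events", "flags", "entered")

    def __init__(self, pos, dirn, energy, gen, events, flags, entered):
        self.pos = pos
        self.dirn = dirn
        self.energy = energy
        self.gen = gen
        self.events = events
        self.flags = flags
        self.entered = entered

    def __len__(self):
        return len(self.energy)

    def take(self, mask):
        return _Batch(self.pos[mask], self.dirn[mask], self.energy[mask],
                      self.gen[mask], self.events[mask], self.flags[mask],
                      self.entered[mask])


def _intersect_all(model: EyeModel, pos, dirn):
    """Nearest object per ray.  Returns (t, obj_idx).

    Out-of-aperture intersections with the analytic surface extensions are
    plain misses (virtual geometry): surfaces exist only on their aperture
    patches and rays passing outside an aperture continue unaffected, as in
    a non-sequential assembly of bounded objects.
    """
    n = len(pos)
    best_t = np.full(n, np.inf)
    best_i = np.full(n, -1, dtype=np.int32)
    for i, s in enumerate(model.surfaces):
        if isinstance(s, CylinderSurface):
            t, valid, _ = intersect_cylinder(s, pos, dirn)
        else:
            t, valid, _ = intersect_surface(s, pos, dirn)
        t = np.where(valid & np.isfinite(t), t, np.inf)
        take = t < best_t
        best_t[take] = t[take]
        best_i[take] = i
    best_i[~np.isfinite(best_t)] = -1
    return best_t, best_i


def trace(model: EyeModel, pos, dirn, energy,
          policy: TracePolicy | None = None):
    """Non-sequential trace of a collimated/arbitrary ray bundle.

    Parameters
    ----------
    pos, dirn, energy :
        Launch positions (n,3) mm, unit directions (n,3), weights (n,).
    policy :
        :class:`TracePolicy`; default policy if None.

    Returns
    -------
    (RetinalHits, TraceLedger)
    """
    if policy is None:
        policy = TracePolicy()
    rng = np.random.default_rng(policy.seed)
    pos = np.array(pos, dtype=float)
    dirn = np.array(dirn, dtype=float)
    dirn /= np.linalg.norm(dirn, axis=1, keepdims=True)
    energy = np.array(energy, dtype=float)
    n0 = len(energy)
    cutoff = policy.energy_cutoff_frac * energy.max()

    ledger = TraceLedger(emitted=float(energy.sum()))
    hit_pts, hit_en, hit_cls, hit_flags = [], [], [], []

    batch = _Batch(pos, dirn, energy,
                   np.zeros(n0, dtype=np.int16), np.zeros(n0, dtype=np.int16),
                   np.zeros(n0, dtype=np.int16), np.zeros(n0, dtype=bool))
    stack = [batch]

    def book_absorb(name, amount):
        ledger.absorbed[name] = ledger.absorbed.get(name, 0.0) + float(amount)

    while stack:
        b = stack.pop()
        if len(b) == 0:
            continue
        t, obj = _intersect_all(model, b.pos, b.dirn)

        # no forward intersection with any object: the ray leaves the model
        # volume (rays that never met an object are booked separately)
        lost = obj < 0
        if lost.any():
            e = b.energy[lost]
            air = ~b.entered[lost]
            ledger.blocked += float(e[air].sum())
            ledger.escaped += float(e[~air].sum())

        live = obj >= 0
        if not live.any():
            continue

        bl = b.take(live)
        tl = t[live]
        ol = obj[live]
        pts = bl.pos + tl[:, None] * bl.dirn

        for i in np.unique(ol):
            s = model.surfaces[i]
            m = ol == i
            sub = bl.take(m)
            p = pts[m]
            sub.pos = p
            sub.entered = np.ones(len(sub), dtype=bool)
            sub.events = sub.events + 1

            if s.behavior is Behavior.DETECTOR:
                hit_pts.append(p)
                hit_en.append(sub.energy)
                hit_cls.append(classify(sub.flags.astype(np.int32)))
                hit_flags.append(sub.flags.copy())
                continue
            if s.behavior is Behavior.ABSORB:
                book_absorb(s.name, sub.energy.sum())
                continue
            if s.behavior is Behavior.IRIS:
                dhole = np.hypot(p[:, 0] - PUPIL_DECENTER, p[:, 1])
                inside = dhole <= PUPIL_RADIUS
                book_absorb("iris", sub.energy[~inside].sum())
                sub = sub.take(inside)
                sub.flags = sub.flags | TAG_PUPIL
                sub.pos = sub.pos + LAUNCH_EPS * sub.dirn
                stack.append(_limit(sub, policy, ledger))
                continue

            # geometric normal, oriented against the incident ray
            nvec = surface_normal(s, p)
            d_dot_n = np.sum(sub.dirn * nvec, axis=1)
            n_inc = np.where(d_dot_n[:, None] > 0, -nvec, nvec)
            # indices: reference normal points anterior (asphere) / outward
            # (cylinder); d.n < 0 means the ray comes from that side
            if isinstance(s, CylinderSurface):
                n_ref_side, n_far_side = s.n_back, s.n_front  # outside, inside
            else:
                n_ref_side, n_far_side = s.n_front, s.n_back
            from_ref = d_dot_n < 0
            n1 = np.where(from_ref, n_ref_side, n_far_side)
            n2 = np.where(from_ref, n_far_side, n_ref_side)

            is_edge = s.name == "iol_edge"
            optic_tag = TAG_OPTIC if s.name in ("iol_front", "iol_back") else 0

            if s.behavior is Behavior.MIRROR:
                sub.dirn = reflect(sub.dirn, n_inc)
                sub.flags = sub.flags | (TAG_EDGE_R if is_edge else optic_tag)
                stack.append(_limit(sub, policy, ledger))
                continue

            # refraction quantities shared by the remaining behaviours
            cosi = -np.sum(sub.dirn * n_inc, axis=1)
            eta = n1 / n2
            sin2t = eta**2 * (1.0 - cosi**2)
            tir = sin2t > 1.0
            cost = np.sqrt(np.maximum(1.0 - sin2t, 0.0))
            tdir = eta[:, None] * sub.dirn + (eta * cosi - cost)[:, None] * n_inc
            R = _fresnel_from_cos(cosi, cost, n1, n2, tir)

            if s.behavior is Behavior.REFRACT:
                # transmitted continuation
                tr = sub.take(~tir)
                tr.dirn = tdir[~tir]
                tr.energy = tr.energy * (1.0 - R[~tir])
                tr.flags = tr.flags | (TAG_EDGE_T if is_edge else optic_tag)
                stack.append(_limit(tr, policy, ledger))
                # reflected branch (specular child, or full energy under TIR)
                rf = sub.take(np.ones(len(sub), dtype=bool))
                rf.dirn = reflect(sub.dirn, n_inc)
                rf.energy = sub.energy * R
                rf.gen = rf.gen + 1
                rf.flags = rf.flags | (TAG_EDGE_R if is_edge else optic_tag)
                stack.append(_limit(rf, policy, ledger, cutoff))
            elif s.behavior is Behavior.REFRACT_NO_R:
                # idealised AR finish: everything refractable transmits,
                # TIR-condition energy is absorbed (never reflected)
                book_absorb(s.name, sub.energy[tir].sum())
                tr = sub.take(~tir)
                tr.dirn = tdir[~tir]
                tr.flags = tr.flags | (TAG_EDGE_T if is_edge else optic_tag)
                stack.append(_limit(tr, policy, ledger))
            elif s.behavior is Behavior.SCATTER:
                K = policy.scatter_children
                # transmitted portion -> diffuse about the far-side normal
                for portion, base_n, tag in (
                        ((1.0 - R), -n_inc, TAG_EDGE_T),
                        (R, n_inc, TAG_EDGE_R)):
                    e_child = sub.energy * portion / K
                    keep = e_child > 0.0
                    if not keep.any():
                        continue
                    src = sub.take(keep)
                    nrm = base_n[keep]
                    rep_pos = np.repeat(src.pos, K, axis=0)
                    rep_nrm = np.repeat(nrm, K, axis=0)
                    d = scatter_hemisphere(rep_nrm, rng, model=policy.scatter_model)
                    child = _Batch(
                        rep_pos + LAUNCH_EPS * d, d,
                        np.repeat(e_child[keep], K),
                        np.repeat(src.gen + 1, K),
                        np.repeat(src.events, K),
                        np.repeat(src.flags | tag, K),
                        np.ones(len(src) * K, dtype=bool))
                    stack.append(_limit(child, policy, ledger, cutoff))
            else:  # pragma: no cover - exhaustive over behaviours
                raise AssertionError(s.behavior)

    if hit_pts:
        points = np.concatenate(hit_pts)
        en = np.concatenate(hit_en)
        cls = np.concatenate(hit_cls)
        flags = np.concatenate(hit_flags)
    else:
        points = np.empty((0, 3))
        en = np.empty(0)
        cls = np.empty(0, dtype=np.int8)
        flags = np.empty(0, dtype=np.int16)
    for ci, cname in enumerate(CLASSES):
        e = float(en[cls == ci].sum())
        if e:
            ledger.retina[cname] = e
    ledger.check()
    return RetinalHits(points, en, cls, flags), ledger


def _limit(batch: _Batch, policy: TracePolicy, ledger: TraceLedger,
           cutoff: float | None = None) -> _Batch:
    """Apply energy / generation / event caps, booking removed energy."""
    ok = batch.events < policy.max_events
    ok &= batch.gen <= policy.max_generation
    if cutoff is not None:
        ok &= batch.energy >= cutoff
    ledger.cutoff += float(batch.energy[~ok].sum())
    return batch.take(ok)
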