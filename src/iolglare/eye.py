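"""Pseudophakic Liou-Brennan-style model eye with a parameterisable IOL.

The model is a fixed surface prescription (anterior corneal vertex at z=0,
light travels in +z):

====  =======================  ==========  ======  ==============
 #    surface                  radius mm   conic   axial pos mm
====  =======================  ==========  ======  ==============
 1    cornea front              7.77       -0.18    0.00
 2    cornea back               6.40       -0.60    0.50
 3    iris stop (plane)         inf        --       3.66
 4    IOL front (sphere)        13.86      0        4.29
 5    IOL back (even asphere)  -11.66      -1.5     5.26
 6    retina (half-sphere)     -12         0       23.95
====  =======================  ==========  ======  ==============

Media: air 1.0 | cornea 1.376 | aqueous 1.336 | IOL 1.458 | vitreous 1.336.
The 4.5 mm pupil is decentred 0.5 mm nasally (nasal = -x, temporal = +x).
The IOL optic (diameter 6 or 7 mm) is bounded by a cylindrical edge whose
height equals the geometric rim gap between the two optic surfaces
(~0.29 mm for the 6 mm optic); the edge's optical behaviour is selected by
:class:`EdgeMode`.  In ``thin`` mode both optic surfaces are extended
radially until they meet in a knife edge and no edge barrel exists.

The annular channel between the iris margin and the IOL edge (the
iris-IOL "interspace") is deliberately open: rays there travel
ballistically in index-1.336 medium, which is the stray-light path that
produces the far-peripheral photic pattern.  Haptics are not modelled.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .geometry import (
    AsphericProfile,
    Behavior,
    CylinderSurface,
    PlacedSurface,
)

# refractive indices
N_AIR = 1.0
N_CORNEA = 1.376
N_AQUEOUS = 1.336
N_IOL = 1.458
N_VITREOUS = 1.336

# axial layout, mm (thickness column: 0.5, 3.16, 0.63, 0.97, 18.69)
CORNEA_THICKNESS = 0.5
Z_CORNEA_BACK = 0.5
Z_PUPIL = 0.5 + 3.16            # 3.66
Z_IOL_FRONT = Z_PUPIL + 0.63    # 4.29
Z_IOL_BACK = Z_IOL_FRONT + 0.97  # 5.26
AXIAL_LENGTH = Z_IOL_BACK + 18.69  # 23.95
RETINA_RADIUS = 12.0
Z_RETINA_CENTER = AXIAL_LENGTH - RETINA_RADIUS  # 11.95

PUPIL_RADIUS = 2.25
PUPIL_DECENTER = -0.5           # nasal = -x
IRIS_OUTER_RADIUS = 7.0         # Table row 3 stop housed in the 14 mm corneal zone
CORNEA_APERTURE_RADIUS = 7.0    # 14 mm optical diameter


class EdgeMode(str, Enum):
    """Optical finish of the IOL optic edge."""

    STANDARD = "standard"            # bare polished dielectric barrel
    ABSORBING = "absorbing"
    REFLECTING = "reflecting"        # ideal mirror
    ANTI_REFLECTING = "anti_reflecting"
    FROSTED = "frosted"              # diffuse (Lambertian by default)
    THIN = "thin"                    # 0 mm edge: knife-edge optic, no barrel


_EDGE_BEHAVIOR = {
    EdgeMode.STANDARD: Behavior.REFRACT,
    EdgeMode.ABSORBING: Behavior.ABSORB,
    EdgeMode.REFLECTING: Behavior.MIRROR,
    EdgeMode.ANTI_REFLECTING: Behavior.REFRACT_NO_R,
    EdgeMode.FROSTED: Behavior.SCATTER,
}

# optic surface profiles (shared by both diameters)
IOL_FRONT_RADIUS = 13.86
IOL_BACK_RADIUS = -11.66
IOL_BACK_CONIC = -1.5
IOL_BACK_COEFFS = {2: -6.34e-3, 4: 1.15e-3, 6: -3.86e-7, 8: -2.47e-8}


def _front_profile(aperture: float) -> AsphericProfile:
    return AsphericProfile(IOL_FRONT_RADIUS, 0.0, {}, aperture_radius=aperture)


def _back_profile(aperture: float) -> AsphericProfile:
    return AsphericProfile(IOL_BACK_RADIUS, IOL_BACK_CONIC, dict(IOL_BACK_COEFFS),
                           aperture_radius=aperture)


def rim_gap(optic_radius: float) -> float:
    """Axial gap between front and back optic surfaces at the optic radius, mm."""
    zf = Z_IOL_FRONT + _front_profile(np.inf).sag(optic_radius)
    zb = Z_IOL_BACK + _back_profile(np.inf).sag(optic_radius)
    return zb - zf


def knife_edge_radius() -> float:
    """Radius at which the extended optic surfaces meet (thin-edge optic), mm."""
    return brentq(rim_gap, 3.0, 6.0, xtol=1e-12)


@dataclass
class EyeModel:
    """Assembled non-sequential object list plus bookkeeping metadata."""

    surfaces: list            # PlacedSurface | CylinderSurface, front-to-back
    optic_diameter: float
    edge_mode: EdgeMode
    edge_height: float        # geometric rim gap (0 for thin)
    optic_radius: float       # aperture of the optic surfaces actually used
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str):
        for s in self.surfaces:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self):
        return [s.name for s in self.surfaces]

    def summary(self) -> str:
        """Human-readable surface table."""
        buf = io.StringIO()
        buf.write(f"Pseudophakic eye model: {self.optic_diameter:g} mm optic, "
                  f"edge mode '{self.edge_mode.value}'\n")
        buf.write(f"{'surface':<14}{'R [mm]':>10}{'conic':>8}{'z [mm]':>9}"
                  f"{'aperture [mm]':>15}  behavior\n")
        for s in self.surfaces:
            if isinstance(s, CylinderSurface):
                buf.write(f"{s.name:<14}{'barrel':>10}{'-':>8}{s.z_min:>9.3f}"
                          f"{2 * s.radius:>15.3f}  {s.behavior.value}"
                          f" (height {s.z_max - s.z_min:.4f} mm)\n")
            else:
                p = s.profile
                R = "inf" if np.isinf(p.radius) else f"{p.radius:.2f}"
                ap = 2 * p.aperture_radius if np.isfinite(p.aperture_radius) else np.nan
                buf.write(f"{s.name:<14}{R:>10}{p.conic:>8.2f}{s.z_vertex:>9.3f}"
                          f"{ap:>15.3f}  {s.behavior.value}\n")
        return buf.getvalue()


def media_index(region: str) -> float:
    """Refractive index of a named ocular region."""
    table = {"air": N_AIR, "cornea": N_CORNEA, "aqueous": N_AQUEOUS,
             "iol": N_IOL, "vitreous": N_VITREOUS}
    try:
        return table[region.lower()]
    except KeyError:
        raise ValueError(f"unknown region {region!r}; one of {sorted(table)}") from None


def build_model(optic_diameter: float = 6.0,
                edge_mode: EdgeMode | str = EdgeMode.STANDARD) -> EyeModel:
    """Assemble the pseudophakic eye with the requested IOL variant.

    Parameters
    ----------
    optic_diameter :
        IOL optic diameter in mm; 6 and 7 are the studied designs (other
        positive values are accepted but flagged in ``meta['non_standard']``).
    edge_mode :
        One of :class:`EdgeMode` (or its string value).
    """
    edge_mode = EdgeMode(edge_mode)
    if optic_diameter <= 0:
        raise ValueError("optic_diameter must be positive")
    rho = optic_diameter / 2.0

    surfaces: list = [
        PlacedSurface("cornea_front",
                      AsphericProfile(7.77, -0.18, {}, CORNEA_APERTURE_RADIUS),
                      0.0, Behavior.REFRACT, n_front=N_AIR, n_back=N_CORNEA),
        PlacedSurface("cornea_back",
                      AsphericProfile(6.40, -0.60, {}, CORNEA_APERTURE_RADIUS),
                      Z_CORNEA_BACK, Behavior.REFRACT,
                      n_front=N_CORNEA, n_back=N_AQUEOUS),
        PlacedSurface("iris",
                      AsphericProfile(np.inf, 0.0, {}, IRIS_OUTER_RADIUS),
                      Z_PUPIL, Behavior.IRIS,
                      n_front=N_AQUEOUS, n_back=N_AQUEOUS),
    ]

    if edge_mode is EdgeMode.THIN:
        r_knife = knife_edge_radius()
        edge_height = 0.0
        optic_radius = r_knife
        surfaces += [
            PlacedSurface("iol_front", _front_profile(r_knife), Z_IOL_FRONT,
                          Behavior.REFRACT, n_front=N_AQUEOUS, n_back=N_IOL),
            PlacedSurface("iol_back", _back_profile(r_knife), Z_IOL_BACK,
                          Behavior.REFRACT, n_front=N_IOL, n_back=N_VITREOUS),
        ]
    else:
        edge_height = rim_gap(rho)
        if edge_height <= 0:
            raise ValueError(
                f"IOL surfaces interpenetrate at optic radius {rho} mm")
        optic_radius = rho
        z_front_rim = Z_IOL_FRONT + _front_profile(np.inf).sag(rho)
        surfaces += [
            PlacedSurface("iol_front", _front_profile(rho), Z_IOL_FRONT,
                          Behavior.REFRACT, n_front=N_AQUEOUS, n_back=N_IOL),
            CylinderSurface("iol_edge", rho, z_front_rim, z_front_rim + edge_height,
                            _EDGE_BEHAVIOR[edge_mode],
                            n_front=N_IOL, n_back=N_AQUEOUS),
            PlacedSurface("iol_back", _back_profile(rho), Z_IOL_BACK,
                          Behavior.REFRACT, n_front=N_IOL, n_back=N_VITREOUS),
        ]

    surfaces.append(
        PlacedSurface("retina",
                      AsphericProfile(-RETINA_RADIUS, 0.0, {}, RETINA_RADIUS),
                      AXIAL_LENGTH, Behavior.DETECTOR,
                      n_front=N_VITREOUS, n_back=N_VITREOUS))

    meta = {
        "non_standard": optic_diameter not in (6.0, 7.0),
        "axial_length": AXIAL_LENGTH,
        "rim_gap": edge_height,
    }
    return EyeModel(surfaces, optic_diameter, edge_mode, edge_height,
                    optic_radius, meta)
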