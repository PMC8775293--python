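"""Retinal irradiance maps, fovea localisation and foveal-ROI metrics.

Hits on the spherical retina are projected with an azimuthal-equidistant
projection about the posterior pole: a hit at angular distance ``gamma``
from the pole maps to radius ``R * gamma`` (arc length, mm) along its
azimuth.  Map axes are nasal(-)/temporal(+) x and inferior(-)/superior(+)
y, in mm of retinal arc.  Maps carry one energy layer per path class
(direct, interspace, edge_transmitted, edge_reflected, other); layers are
disjoint and their total equals the ledger's retinal energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import CLASSES, CLASS_INDEX, RetinalHits
from .eye import AXIAL_LENGTH, RETINA_RADIUS, Z_RETINA_CENTER, EyeModel
from .sources import visual_axis_bundle

DEFAULT_BIN_SIZE = 0.05   # mm of retinal arc
DEFAULT_ROI_RADIUS = 0.75  # mm; ~1.5 mm anatomical foveal diameter


def project_hits(points: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant (u, v) arc coordinates of retinal hit points."""
    if len(points) == 0:
        return np.empty((0, 2))
    rel = points - np.array([0.0, 0.0, Z_RETINA_CENTER])
    rho = np.linalg.norm(rel, axis=1)
    cosg = np.clip(rel[:, 2] / rho, -1.0, 1.0)
    gamma = np.arccos(cosg)
    s = RETINA_RADIUS * gamma
    rxy = np.hypot(rel[:, 0], rel[:, 1])
    with np.errstate(invalid="ignore"):
        scale = np.where(rxy > 1e-12, s / np.where(rxy > 1e-12, rxy, 1.0), 0.0)
    return np.column_stack([rel[:, 0] * scale, rel[:, 1] * scale])


@dataclass
class FovealROI:
    """Circular foveal region of interest on the projected map."""

    center: tuple      # (u, v) mm
    radius: float = DEFAULT_ROI_RADIUS

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")


@dataclass
class RetinaIrradianceMap:
    """Binned retinal energy, one layer per path class."""

    layers: np.ndarray        # (n_classes, nx, ny)
    u_edges: np.ndarray
    v_edges: np.ndarray
    bin_size: float
    meta: dict = field(default_factory=dict)

    def layer(self, class_name: str | None) -> np.ndarray:
        if class_name is None:
            return self.layers.sum(axis=0)
        if class_name == "edge":
            return (self.layers[CLASS_INDEX["edge_transmitted"]]
                    + self.layers[CLASS_INDEX["edge_reflected"]])
        return self.layers[CLASS_INDEX[class_name]]

    @property
    def total_energy(self) -> float:
        return float(self.layers.sum())

    def to_text(self, class_name: str | None = None) -> str:
        """Delimited numeric grid with a '#'-comment metadata header."""
        g = self.layer(class_name)
        head = [f"# retinal irradiance map layer={class_name or 'total'}",
                f"# bin_size_mm={self.bin_size}",
                f"# u_min={self.u_edges[0]:.6f} u_max={self.u_edges[-1]:.6f}",
                f"# v_min={self.v_edges[0]:.6f} v_max={self.v_edges[-1]:.6f}"]
        for k, v in sorted(self.meta.items()):
            head.append(f"# {k}={v}")
        body = "\n".join(" ".join(f"{x:.8e}" for x in row) for row in g)
        return "\n".join(head) + "\n" + body + "\n"

    def render(self, path, class_name: str | None = None, log_scale: bool = True,
               roi: "FovealROI | None" = None, optic_disc: tuple | None = (-4.0, 0.0)):
        """Save a PNG rendering of one layer (or the total).

        The optional optic-disc overlay is cosmetic only (default nasal).
        """
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        g = self.layer(class_name).T
        ext = [self.u_edges[0], self.u_edges[-1], self.v_edges[0], self.v_edges[-1]]
        fig, ax = plt.subplots(figsize=(6, 5.5))
        show = np.log10(g + g[g > 0].min() * 1e-3) if (log_scale and (g > 0).any()) else g
        im = ax.imshow(show, origin="lower", extent=ext, cmap="inferno", aspect="equal")
        fig.colorbar(im, ax=ax, label="log10 energy / bin" if log_scale else "energy / bin")
        if roi is not None:
            ax.add_patch(plt.Circle(roi.center, roi.radius, fill=False,
                                    color="red", ls="--", lw=1.2))
        if optic_disc is not None:
            ax.add_patch(plt.Circle(optic_disc, 0.9, fill=False, color="white", lw=1.0))
        ax.set_xlabel("nasal  <-  u [mm arc]  ->  temporal")
        ax.set_ylabel("inferior  <-  v [mm arc]  ->  superior")
        ax.set_title(f"layer: {class_name or 'total'}")
        fig.tight_layout()
        fig.savefig(path, dpi=130)
        plt.close(fig)


def bin_hits(hits: RetinalHits, bin_size: float = DEFAULT_BIN_SIZE,
             extent: float | None = None, meta: dict | None = None) -> RetinaIrradianceMap:
    """Conservatively bin retinal hits into a per-class map.

    ``extent`` is the half-width of the map in mm of arc; the default covers
    the full hemisphere (R * pi/2).  Binning loses no energy: edge bins
    absorb out-of-range coordinates (there are none with the default extent).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if extent is None:
        extent = RETINA_RADIUS * np.pi / 2.0 + bin_size
    # odd bin count with a bin centred on 0: the meridional plane (v = 0,
    # where deterministic sources put many hits) lies at a bin centre, so
    # mirroring v -> -v maps bins onto bins exactly
    nbin = 2 * int(np.ceil(extent / bin_size)) + 1
    edges = (np.arange(nbin + 1) - nbin / 2) * bin_size
    uv = project_hits(hits.points)
    layers = np.zeros((len(CLASSES), nbin, nbin))
    for ci in range(len(CLASSES)):
        m = hits.cls == ci
        if not m.any():
            continue
        iu = np.clip(np.searchsorted(edges, uv[m, 0], side="right") - 1, 0, nbin - 1)
        iv = np.clip(np.searchsorted(edges, uv[m, 1], side="right") - 1, 0, nbin - 1)
        np.add.at(layers[ci], (iu, iv), hits.energy[m])
    return RetinaIrradianceMap(layers, edges, edges, bin_size, dict(meta or {}))


def roi_energy(map_or_hits, roi: FovealROI, class_name: str | None = None):
    """Energy sum and peak bin value of a layer restricted to the ROI disc.

    Accepts a :class:`RetinaIrradianceMap` (bin-resolved peak) or raw
    :class:`RetinalHits` (exact energy, peak = max single-hit energy).
    """
    cu, cv = roi.center
    if isinstance(map_or_hits, RetinalHits):
        hits = map_or_hits
        sel = hits.select(class_name)
        uv = project_hits(hits.points)
        inside = sel & ((uv[:, 0] - cu) ** 2 + (uv[:, 1] - cv) ** 2 <= roi.radius**2)
        e = hits.energy[inside]
        return float(e.sum()), float(e.max()) if len(e) else 0.0
    m = map_or_hits
    g = m.layer(class_name)
    uc = 0.5 * (m.u_edges[:-1] + m.u_edges[1:])
    vc = 0.5 * (m.v_edges[:-1] + m.v_edges[1:])
    U, V = np.meshgrid(uc, vc, indexing="ij")
    inside = (U - cu) ** 2 + (V - cv) ** 2 <= roi.radius**2
    vals = g[inside]
    if vals.size == 0:
        return 0.0, 0.0
    return float(vals.sum()), float(vals.max())


def locate_fovea(model: EyeModel, ray_count: int = 3000) -> float:
    """Signed transverse arc offset of the fovea from the posterior pole, mm.

    Traces the narrow visual-axis bundle (collimated, 5 degrees nasal in
    object space, chief ray through the pupil centre) and returns the
    energy-weighted centroid of its retinal hits along the nasal-temporal
    axis; positive = temporal.
    """
    from .engine import trace

    pos, dirn, energy = visual_axis_bundle(ray_count=ray_count)
    hits, ledger = trace(model, pos, dirn, energy)
    if len(hits.energy) == 0 or hits.energy.sum() <= 0:
        raise RuntimeError("visual-axis bundle produced no retinal hits")
    uv = project_hits(hits.points)
    w = hits.energy / hits.energy.sum()
    return float((uv[:, 0] * w).sum())
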