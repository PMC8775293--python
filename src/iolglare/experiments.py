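"""Glare experiments: angle sweeps, critical-angle searches, edge comparison.

These reproduce the study protocol: a collimated 6 mm disc source is swept
from 50 to 90 degrees (temporal) in 5-degree steps; at each angle the
retinal energy of each path class inside the foveal region of interest is
recorded.  A "critical angle" is the incidence angle that maximises the
foveal-ROI energy of an edge-related path class, found by the coarse sweep
followed by deterministic grid-zoom refinement to 0.05 degrees.  The
"onset angle" of the iris-IOL interspace pattern is the smallest grid
angle whose interspace-class retinal energy exceeds a declared floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import CLASSES, TracePolicy, trace
from .eye import EdgeMode, EyeModel, build_model
from .retina import DEFAULT_ROI_RADIUS, FovealROI, bin_hits, locate_fovea, roi_energy
from .sources import SourceSpec, aim_through_pupil, make_bundle

ONSET_ENERGY_FLOOR = 1e-6   # fraction of emitted energy


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    rays_per_angle: int = 100_000
    angle_start: float = 50.0
    angle_stop: float = 90.0
    angle_step: float = 5.0
    refine_tolerance: float = 0.05    # degrees
    roi_radius: float = DEFAULT_ROI_RADIUS
    disc_diameter: float = 6.0
    layout: str = "sunflower"
    aim: str = "pupil"                # "pupil": chief ray crosses the pupil
    #                                   centre after corneal refraction;
    #                                   "air": aim at the pupil in a straight
    #                                   line, ignoring refraction
    seed: int = 0
    bin_size: float = 0.05
    scatter_children: int = 8
    scatter_model: str = "lambertian"
    onset_floor: float = ONSET_ENERGY_FLOOR

    def __post_init__(self):
        if self.angle_step <= 0:
            raise ValueError("angle_step must be positive")
        if self.angle_start >= self.angle_stop:
            raise ValueError("angle_start must be below angle_stop")
        if self.refine_tolerance >= self.angle_step:
            raise ValueError("refine_tolerance must be below angle_step")

    def grid(self) -> np.ndarray:
        n = int(round((self.angle_stop - self.angle_start) / self.angle_step))
        return self.angle_start + self.angle_step * np.arange(n + 1)

    def policy(self) -> TracePolicy:
        return TracePolicy(seed=self.seed,
                           scatter_children=self.scatter_children,
                           scatter_model=self.scatter_model)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class ExperimentResult:
    """Per-angle metrics table plus located angles."""

    table: pd.DataFrame
    fovea_offset: float
    roi: FovealROI
    critical_angle: float | None = None
    critical_value: float | None = None
    onset_angle: float | None = None
    meta: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"fovea offset: {self.fovea_offset:+.3f} mm (temporal positive)"]
        if self.critical_angle is not None:
            lines.append(f"critical angle: {self.critical_angle:.1f} deg "
                         f"(ROI energy {self.critical_value:.3e})")
        if self.onset_angle is not None:
            lines.append(f"interspace onset angle: {self.onset_angle:g} deg")
        elif "onset_searched" in self.meta:
            lines.append("interspace onset: none in range")
        with pd.option_context("display.width", 120):
            lines.append(self.table.to_string(index=False,
                                              float_format=lambda x: f"{x:.4e}"))
        return "\n".join(lines)


def _trace_angle(model: EyeModel, config: RunConfig, angle: float):
    kwargs = {}
    if config.aim == "pupil":
        kwargs["aim_point"] = aim_through_pupil(model, angle)
    elif config.aim != "air":
        raise ValueError(f"unknown aim mode {config.aim!r}")
    spec = SourceSpec(incidence_angle=angle,
                      disc_diameter=config.disc_diameter,
                      ray_count=config.rays_per_angle,
                      layout=config.layout, seed=config.seed, **kwargs)
    pos, dirn, energy = make_bundle(spec)
    return trace(model, pos, dirn, energy, config.policy())


def angle_metrics(model: EyeModel, config: RunConfig, angle: float,
                  roi: FovealROI, map_dir=None) -> dict:
    """Trace one angle and compute per-class ROI and total retinal metrics.

    With ``map_dir`` set, the angle's binned irradiance map is archived
    there as a delimited numeric grid.
    """
    hits, ledger = _trace_angle(model, config, angle)
    row = {"angle": angle, "retina_energy": ledger.retina_total}
    for cname in CLASSES:
        row[f"retina_{cname}"] = ledger.retina.get(cname, 0.0)
        e, pk = roi_energy(hits, roi, cname)
        row[f"roi_{cname}"] = e
        row[f"roi_peak_{cname}"] = pk
    e, pk = roi_energy(hits, roi, "edge")
    row["roi_edge"] = e
    if map_dir is not None:
        import pathlib

        m = bin_hits(hits, config.bin_size,
                     meta={"angle": angle, "edge_mode": model.edge_mode.value,
                           "optic_diameter": model.optic_diameter})
        path = pathlib.Path(map_dir)
        path.mkdir(parents=True, exist_ok=True)
        fname = f"map_{model.edge_mode.value}_{angle:g}deg.txt"
        (path / fname).write_text(m.to_text())
        row["map_file"] = str(path / fname)
    return row


def foveal_roi(model: EyeModel, config: RunConfig | None = None) -> FovealROI:
    config = config or RunConfig()
    return FovealROI((locate_fovea(model), 0.0), config.roi_radius)


def angle_sweep(config: RunConfig, optic_diameter: float = 6.0,
                edge_mode: EdgeMode | str = EdgeMode.STANDARD,
                model: EyeModel | None = None,
                map_dir=None) -> ExperimentResult:
    """Trace every grid angle and tabulate per-class foveal-ROI metrics;
    with ``map_dir`` each angle's irradiance map is archived as a grid."""
    model = model or build_model(optic_diameter, edge_mode)
    fov = locate_fovea(model)
    roi = FovealROI((fov, 0.0), config.roi_radius)
    rows = [angle_metrics(model, config, a, roi, map_dir=map_dir)
            for a in config.grid()]
    table = pd.DataFrame(rows)
    return ExperimentResult(table, fov, roi,
                            meta={"optic_diameter": model.optic_diameter,
                                  "edge_mode": model.edge_mode.value,
                                  "config": config.to_dict()})


def _objective_column(tag_class: str) -> str:
    if tag_class not in CLASSES and tag_class != "edge":
        raise ValueError(f"unknown tag class {tag_class!r}")
    return f"roi_{tag_class}"


def find_critical_angle(config: RunConfig, optic_diameter: float = 6.0,
                        edge_mode: EdgeMode | str = EdgeMode.STANDARD,
                        objective_tag_class: str = "edge",
                        sweep: ExperimentResult | None = None) -> ExperimentResult:
    """Locate the incidence angle maximising foveal-ROI energy of a tag class.

    Coarse 5-degree sweep (reused if ``sweep`` is given) followed by
    deterministic golden-section refinement within one coarse step of the
    grid maximum, down to ``config.refine_tolerance``.  Returns the sweep
    result with ``critical_angle`` filled in.

    If the objective class deposits no energy in the foveal ROI at any
    coarse angle, the ROI is dilated (radius doubled, up to 16x) until the
    objective becomes non-empty somewhere; the dilation factor used is
    recorded in ``meta['roi_dilation']``.  A class empty even at 16x yields
    ``critical_angle = None`` ("no photic effect reaches the fovea" -
    expected for absorbing and thin edges).
    """
    from .retina import project_hits

    model = build_model(optic_diameter, edge_mode)
    if sweep is None:
        sweep = angle_sweep(config, model=model)
    col = _objective_column(objective_tag_class)
    base_roi = sweep.roi
    cu, cv = base_roi.center

    # one trace per angle; the projected objective-class hits are cached so
    # ROI dilation and refinement re-queries cost nothing extra
    cache: dict = {}

    def data(angle):
        key = round(float(angle), 4)
        if key not in cache:
            hits, _ = _trace_angle(model, config, angle)
            sel = hits.select(objective_tag_class)
            cache[key] = (project_hits(hits.points[sel]), hits.energy[sel])
        return cache[key]

    def roi_value(angle, radius):
        uv, en = data(angle)
        if len(en) == 0:
            return 0.0
        inside = (uv[:, 0] - cu) ** 2 + (uv[:, 1] - cv) ** 2 <= radius**2
        return float(en[inside].sum())

    grid = config.grid()
    # the precomputed sweep already holds base-radius objective values
    base_vals = sweep.table[col].to_numpy()
    dilation, roi = 1, base_roi
    vals = base_vals
    while vals.max() <= 0.0 and dilation < 32:
        dilation *= 2
        roi = FovealROI(base_roi.center, base_roi.radius * dilation)
        vals = np.array([roi_value(a, roi.radius) for a in grid])
    if vals.max() <= 0.0:
        return replace(sweep, critical_angle=None, critical_value=None,
                       meta={**sweep.meta, "objective": objective_tag_class,
                             "roi_dilation": None})

    # golden-section refinement inside +-1 coarse step of the grid maximum
    best = float(grid[int(np.argmax(vals))])
    lo = max(config.angle_start, best - config.angle_step)
    hi = min(config.angle_stop, best + config.angle_step)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc, fd = roi_value(c, roi.radius), roi_value(d, roi.radius)
    while hi - lo > config.refine_tolerance:
        if fc >= fd:
            hi, d, fd = d, c, fc
            c = hi - invphi * (hi - lo)
            fc = roi_value(c, roi.radius)
        else:
            lo, c, fc = c, d, fd
            d = lo + invphi * (hi - lo)
            fd = roi_value(d, roi.radius)
    candidates = [(roi_value(a, roi.radius), a)
                  for a in (0.5 * (lo + hi), best)]
    critical_value, critical_angle = max(candidates)
    critical_angle = round(critical_angle / config.refine_tolerance) \
        * config.refine_tolerance
    return replace(sweep, critical_angle=float(critical_angle),
                   critical_value=critical_value, roi=roi,
                   meta={**sweep.meta, "objective": objective_tag_class,
                         "roi_dilation": dilation})


def find_onset_angle(config: RunConfig, optic_diameter: float = 6.0,
                     tag_class: str = "interspace",
                     sweep: ExperimentResult | None = None,
                     edge_mode: EdgeMode | str = EdgeMode.STANDARD) -> ExperimentResult:
    """Smallest grid angle whose tag-class retinal energy exceeds the floor.

    The floor is ``config.onset_floor`` as a fraction of emitted energy
    (the bundle emits unit energy).  Returns the sweep with
    ``onset_angle`` set (None = never observed on the grid).
    """
    if sweep is None:
        sweep = angle_sweep(config, optic_diameter, edge_mode)
    col = f"retina_{tag_class}"
    above = sweep.table[sweep.table[col] > config.onset_floor]
    onset = float(above["angle"].iloc[0]) if len(above) else None
    return replace(sweep, onset_angle=onset,
                   meta={**sweep.meta, "onset_searched": tag_class})


def edge_comparison(config: RunConfig, optic_diameter: float, angle: float):
    """Run all six edge designs at one fixed incidence angle.

    Returns ``(summary_table, maps, checks)`` where ``maps`` maps edge-mode
    name to a :class:`RetinaIrradianceMap` and ``checks`` reports the
    definitional relations between designs:

    * absorbing and thin edges: zero edge-class retinal energy;
    * anti-reflecting: zero edge_reflected energy;
    * fully reflecting: zero edge_transmitted energy;
    * frosted: lower map-wide peak edge-layer bin irradiance than standard
      (the same light spread over a larger retinal area);
    * the interspace layer is identical across edge modes (deterministic
      sources), since those rays never meet the optic or its edge.
    """
    rows, maps, interspace_layers = [], {}, {}
    roi = None
    for mode in EdgeMode:
        model = build_model(optic_diameter, mode)
        if roi is None:
            roi = foveal_roi(model, config)
        hits, ledger = _trace_angle(model, config, angle)
        m = bin_hits(hits, config.bin_size,
                     meta={"angle": angle, "edge_mode": mode.value,
                           "optic_diameter": optic_diameter})
        maps[mode.value] = m
        interspace_layers[mode.value] = m.layer("interspace")
        row = {"edge_mode": mode.value,
               "retina_energy": ledger.retina_total}
        for cname in CLASSES:
            row[f"retina_{cname}"] = ledger.retina.get(cname, 0.0)
            e, _pk = roi_energy(hits, roi, cname)
            row[f"roi_{cname}"] = e
        _e, row["roi_peak_edge"] = roi_energy(m, roi, "edge")
        row["roi_edge"] = roi_energy(hits, roi, "edge")[0]
        row["retina_edge"] = (ledger.retina.get("edge_transmitted", 0.0)
                              + ledger.retina.get("edge_reflected", 0.0))
        row["map_peak_edge"] = float(m.layer("edge").max())
        rows.append(row)
    table = pd.DataFrame(rows).set_index("edge_mode")

    ref = interspace_layers[EdgeMode.STANDARD.value]
    checks = {
        "absorbing_no_edge_energy":
            bool(table.loc["absorbing", ["retina_edge_transmitted",
                                         "retina_edge_reflected"]].sum() == 0.0),
        "thin_no_edge_energy":
            bool(table.loc["thin", ["retina_edge_transmitted",
                                    "retina_edge_reflected"]].sum() == 0.0),
        "anti_reflecting_no_edge_reflection":
            bool(table.loc["anti_reflecting", "retina_edge_reflected"] == 0.0),
        "reflecting_no_edge_transmission":
            bool(table.loc["reflecting", "retina_edge_transmitted"] == 0.0),
        "frosted_lower_peak":
            bool(table.loc["frosted", "map_peak_edge"]
                 < table.loc["standard", "map_peak_edge"]),
        "interspace_invariant": all(
            np.array_equal(ref, interspace_layers[m.value])
            for m in (EdgeMode.ABSORBING, EdgeMode.REFLECTING,
                      EdgeMode.ANTI_REFLECTING, EdgeMode.FROSTED)),
    }
    return table, maps, checks
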