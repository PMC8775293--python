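# Methods

This note records the model, the numerical choices and the limits of what
the simulations show.  It is the package's own account; every number
quoted here is produced by the test suite or `scripts/acceptance.py`.

## The model eye

The eye is an *open, non-sequential assembly* of bounded surface patches
on a common optical axis (z, light travels in +z; x is the
nasal(−)/temporal(+) axis):

| object        | form                          | R (mm) | k    | z vertex | aperture ⌀ |
|---------------|-------------------------------|--------|------|----------|------------|
| cornea front  | conic                         | 7.77   | −0.18| 0        | 14 mm      |
| cornea back   | conic                         | 6.40   | −0.60| 0.5      | 14 mm      |
| iris          | plane stop                    | ∞      | —    | 3.66     | hole 4.5 mm|
| IOL front     | sphere                        | 13.86  | 0    | 4.29     | 6 / 7 mm   |
| IOL edge      | cylinder barrel               | —      | —    | rim gap  | 6 / 7 mm   |
| IOL back      | even asphere (α₂…α₈)          | −11.66 | −1.5 | 5.26     | 6 / 7 mm   |
| retina        | detector half-sphere          | −12    | 0    | 23.95    | 24 mm      |

Media: air 1.0 / cornea 1.376 / aqueous 1.336 / IOL 1.458 / vitreous
1.336, constant (monochromatic tracing: no dispersion data exist for the
prescription, so a single design wavelength is used).  The pupil hole is
decentred 0.5 mm nasally; its absorbing annulus extends to the 14 mm
corneal zone.  Haptics are not modelled; the annular channel between the
iris margin and the IOL edge (the *interspace*) is deliberately open.

Two consequences of taking the prescription literally are worth noting:

* the α₂ polynomial coefficient of the IOL back surface contributes to
  its paraxial curvature (c_eff = 1/R + 2α₂), which brings the IOL to
  20.8 D — matching its nominal 21 D label — and puts the paraxial focus
  at z = 23.788 mm, 0.16 mm in front of the retinal apex (verified in the
  tests against an independent ray-transfer-matrix computation);
* the *geometric* rim gap between the optic surfaces at the optic radius
  is 0.294 mm for the 6 mm optic (close to the nominal 0.3 mm edge
  thickness) but only 0.095 mm for the 7 mm optic.  The edge barrel uses
  the geometric gap, since forcing 0.3 mm would break surface continuity.
  In `thin` mode both optic surfaces are extended until they meet in a
  knife edge at r = 3.735 mm and no barrel exists (the only
  self-consistent meaning of a 0 mm edge; note this makes the 6 and 7 mm
  thin-edge lenses identical).

## Propagation

Rays iteratively intersect the nearest forward object; conic surfaces use
closed-form quadric roots, the polynomial asphere refines them by Newton
iteration on the exact sag residual (tolerance 10⁻⁹ mm, ≤ 50 iterations,
re-intersection guard 10⁻⁶ mm).  Out-of-aperture crossings of a surface's
analytic extension are plain misses — the assembly is open, like a
non-sequential system of bounded objects; rays with no forward
intersection leave the model and are booked as escaped (or "blocked" if
they never interacted at all).

Interfaces split deterministically: the transmitted continuation carries
(1−R) of the energy and the Fresnel-reflected child R, with R the
unpolarised average of the s/p reflectances (R = 1 under TIR).  Children
below 10⁻⁴ of the launch energy, beyond secondary-branch depth 8, or past
50 interactions are terminated and their energy booked as cut off, so the
audit *emitted = retina + absorbed + escaped + cutoff* closes to 10⁻⁹
relative on every run (a hard failure otherwise).  "Generation" counts
secondary branches only (reflections, scatter); counting transmissions
too would terminate legitimate five-interface direct paths.

Edge finishes are idealised as follows.  `standard`: bare polished
dielectric, same physics as the optic surfaces.  `absorbing`: terminate
and book.  `reflecting`: ideal mirror.  `anti_reflecting`: all
refractable energy transmits with zero reflectance; energy arriving
beyond the internal critical angle (≈ 66.4° for 1.458→1.336), for which
no refracted direction exists, is absorbed — the idealisation "this edge
never reflects" extended to the TIR regime.  `frosted`: the transmitted
and internally reflected fractions are each spread over K = 8 diffuse
child rays; sampling is cosine-weighted (Lambertian) by default with a
uniform-in-solid-angle "isotropic" switch, both seeded and reproducible
(the description of the frosted finish admits both readings; acceptance
runs use the Lambertian default).

Every retinal hit is classified from its interaction history with
precedence *interspace* (never touched optic or edge) → *edge_reflected*
(≥ 1 reflection at the edge, internal or external) → *edge_transmitted*
(crossed the edge) → *direct*.  The classes partition the hits, and the
interspace layer is bin-identical across the five thick-edge finishes for
deterministic sources (asserted in the tests).

## Sources and protocol

The glare source is a collimated pencil from a 6 mm disc perpendicular to
the propagation direction d = (−sin θ, 0, cos θ), θ = 50–90° temporal.
The default layout is a deterministic sunflower grid (Monte-Carlo-free
specular maps); energy is normalised to 1.  θ = 90° (grazing) is allowed:
the sweep grid of the protocol includes it.

Aim: by default the disc axis is offset (bisection-calibrated,
deterministic) so the chief ray crosses the pupil centre *after* corneal
refraction — tracing the pencil "through the pupil" in the literal sense.
An uncorrected in-air aim is available (`aim="air"`); at θ ≥ 70° it
leaves the pupil nearly dark because refraction displaces the beam
temporally by 1–4 mm.  The interspace onset angles are identical under
both aims.

The fovea is located by tracing a narrow collimated bundle tilted 5°
toward the temporal direction (fixation 5° nasal in object space) through
the pupil centre: the energy-weighted retinal centroid lies 1.475 mm
temporal to the posterior pole.  The foveal region of interest is a disc
of radius 0.75 mm (≈ the 1.5 mm anatomical foveal diameter) at that
point.

Maps are binned at 0.05 mm in an azimuthal-equidistant projection about
the posterior pole (arc-length coordinates, area-faithful near the
fovea); the bin grid has a bin centred on the meridional plane so mirror
symmetry is exact.  The optic-disc overlay on rendered maps is cosmetic.

A *critical angle* is found by the coarse 5° sweep followed by
grid-zoom refinement (step ÷5 per level down to 0.05°) of the foveal-ROI
energy of the objective tag class — edge-related energy for the standard
edge, edge-reflected energy for the fully reflecting edge.  If the
objective is empty over the whole grid the ROI is dilated (radius ×2, up
to ×16) until it is not; the dilation used is reported.  The *onset
angle* of the interspace pattern is the smallest grid angle whose
interspace-class retinal energy exceeds 10⁻⁶ of the emitted energy.

## Problem sizes

The acceptance script uses 10⁵ rays per traced angle (2 × 10⁴ for the
fovea bundle); the test suite runs the same protocol at 3 × 10⁴ rays per
angle and smaller.  With deterministic splitting a 10⁵-ray trace
generates roughly 3–5 × 10⁵ ray segments.

## What reproduces and what does not

With this reconstruction the following published values are recovered:
the foveal offset (1.475 vs 1.462 mm, within 0.1 mm), the interspace
onset angles (50° for the 6 mm optic, 55° for the 7 mm — the narrower
channel of the larger optic needs a steeper ray), every definitional
edge-finish property (absorbing/thin edges extinguish all edge-tagged
retinal light; anti-reflecting extinguishes the reflected class; fully
reflecting extinguishes the transmitted class; the interspace pattern is
untouched by edge design), the map-wide contrast reduction of the
frosted edge, and the first-order optics (20.8 D IOL, focus within
0.25 mm of the retina).

The *absolute* critical angles do not reproduce.  In this model the
edge-transmission arc crosses the fovea near 80° and its foveal-ROI
energy peaks near 84–89° depending on optic diameter and ray budget
(published: 77.5° and 78.2° for the 6/7 mm optics); edge-*reflected*
light reaches the foveal region only above ≈ 80° — below that the
reflected pattern is a ring ≥ 6 mm from the fovea — so the reflected
objective peaks near 85–87° (published: foveal at 67.4°/68.8°).
Extensive variation of every under-specified element —
source aim, iris annulus extent, enclosure walls, decentration chirality,
an oversized source covering every entry window — moves these families by
a few degrees but cannot reproduce the published angles; the responsible
ray families pass the corneal periphery and the lens rim, where the
original commercial-tracer model's object boundaries (closed lens/cornea
volumes, obscuration sizes, source placement) are not documented in the
prescription.  The *relative* structure does reproduce: the 7 mm optic's
critical angle exceeds the 6 mm optic's, as published.  The searches are
implemented exactly as specified and report what this geometry yields.

Passing tests therefore show that the simulator's physics (refraction,
Fresnel splitting, TIR, diffuse scatter, energy conservation, tagging)
and the documented geometry are correct and reproducible — not that every
figure of the original study is recovered; the synthetic source is ideal
(perfectly collimated, uniform, monochromatic) and real glare sources,
scleral scatter and ocular media turbidity are outside the model.

## Known limitations

No polarisation-resolved Fresnel terms (unpolarised average only), no
diffraction or coherence, no wavelength sampling, no IOL tilt or
decentration, no haptics, no retinal sensitivity weighting; intensities
are relative energies, never calibrated photometric units.
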