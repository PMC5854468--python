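# Methods

## Orientation-energy model

The model treats a membrane-bound cytoskeletal filament as an elastic beam
of two protofilaments, idealized as a solid cylindrical rod of cross-section
radius r = 2.5 nm, so the flexural rigidity is B = E·I with I = πr⁴/4.
Bound along direction θ on a surface with principal curvatures (κ₁, κ₂),
the filament's contact line has the normal curvature κₙ(θ) = κ₁cos²θ +
κ₂sin²θ. Curvatures are signed: negative means the surface curves toward
the filament side (the inner leaflet of a cylindrical cell is (0, −1/R)).
The curvature the filament adopts when conforming is c = −κₙ, so a
direction with positive κₙ (curving away, as across a neck/saddle) is
penalized more strongly than a flat one — this is what makes saddle necks
the most orienting geometry in the alignment-energy map.

Four terms, per filament of length L, in kT at 300 K:

| term | form | notes |
|---|---|---|
| beam bending | ½ B L (c − κ₀)² | κ₀ = 10 μm⁻¹ (preferred curvature from the ~200 nm bound diameter) |
| adhesion | −ε L/δ | ε = 10 kT per monomer, δ = 5 nm rise; θ-independent when fully bound |
| membrane | k_b a²L/(2w³) + σ a²L/(2w) | groove of amplitude a, width w = 20 nm beneath the filament |
| pressure | P·(a w L/2) | volume displaced by the groove against turgor |

The groove bows the contact line longitudinally, adding 8a/L² of curvature
(circular-arc sagitta relation); the Helfrich term uses the curvature scale
a/w² of a Gaussian-profile indentation integrated over the footprint L·w,
and the displaced volume uses a parabolic cross-section shape factor of ½.
These ansatz choices set prefactors, not the physics: at the default turgor
of 1 MPa the linear pressure term dominates any bending relief, the optimal
amplitude is 0, and the landscape reduces exactly to the rigid-membrane
closed form ΔE(θ) = ½BL[(κ₀−|κₙ(θ)|)² − (κ₀−1/R)²], which the tests verify
to 10⁻³ kT. At zero pressure under a floppy membrane the quadratic is
minimized where the filament reaches κ₀ — it deforms the membrane instead
of sensing it (the liposome regime).

Defaults: E = 2 GPa (actin-like), L = 200 nm (~40 monomers, a mid-range
in-vivo filament), membrane bending modulus 20 kT, tension 0, turgor 1 MPa
(Gram-positive scale; 0 for liposomes), cell radius 0.45 μm. Temperature is
fixed at 300 K for the Pa→kT conversion.

Numerics: ΔE(θ) is evaluated on a 1° grid over [0°, 90°] (the landscape is
symmetric about both 0° and 90° on any quadric surface); at each θ the
energy is minimized over the groove amplitude with bounded Brent search,
tolerance well below 10⁻⁶ kT, and the a = 0 boundary is checked explicitly
because the pressure term is linear. The amplitude search bound defaults to
max(10r, 1.25·κ₀L²/8) so the fully conforming optimum is always interior
rather than clipped. Sensitivity sweeps are per-axis: each swept value
rebuilds the profile (on the cylinder of the swept radius where the radius
itself is the axis) and records the argmin, the well depth ΔE(0°), and
whether it exceeds 1 kT.

## Trajectory statistics

Line fits use the first principal axis of the position cloud (orthogonal
least squares); r² is the explained-variance fraction along the axis, the
line angle is axial (mod 180°), and displacement is end-to-end along the
fitted line. Tracks shorter than 5 frames are not fit (the tracker's
linking minimum).

MSD fits use the time-averaged MSD per lag. The filament model
MSD = 4Dt + (Vt)² and its localization-noise variant + 4σ² are linear in
(D, V², σ²) and are fitted by non-negative least squares — exact under the
non-negativity constraints, with no convergence failures. The power-law
variant C·tᵅ + 4σ² uses bounded nonlinear least squares. The filament
variant fits the first 80% of lags; the single-molecule variants fit lags
up to half the track length. In all cases lags are capped at 100: the time
average at lag k pools only n − k displacements, so on very long tracks the
largest lags carry almost no information and would otherwise dominate the
log-log regression (the cap never binds for typical 20–120-frame tracks).
α and its r² come from a straight-line fit of log MSD vs log t on the same
lags.

Filters are strict lower bounds (R² > 0.9, displacement > 0.2 μm, velocity
> 10⁻⁹ μm/s, log-log R² > 0.6); the single-molecule policy instead bounds
track length to [10, 120] frames with log-log R² > 0.95 and velocity >
5×10⁻⁵ nm/s. Both are exposed as named policies and fully overridable.
Attrition is reported per predicate.

Angles are axial throughout. Differences are folded to [0°, 90°] by the
two-step transform (add 180° if negative, reflect about 90° if above);
σ₉₀ is the RMS deviation from 90°, which for uniformly random orientations
converges to 90/√3 ≈ 51.96°. Pairwise statistics use distances between
mean track positions, require 3 neighbors within 5 μm (out-of-cell guard),
bin to a 3 μm maximum (about one cell length) in 0.5 μm bins — the bin
width is our choice — and report the mean dot product cos(θᵢ−θⱼ) per bin
(no absolute value; the fold applies only to Δθ) plus the median Δθ for
pairs within 1 μm. The nearest midline station for angle-to-midline uses
Euclidean distance from the mean track position, ties to the lower index.

## Contour geometry

Sidewall curvature is the signed circumcircle curvature of three successive
vertices (positive = convex outward on the CCW-normalized contour),
boxcar-smoothed over a two-pixel arc-length window (pixel size 0.065 μm by
default) with wrap-around. The pill mesh places stations along the
principal axis of the vertex cloud and clips the perpendicular chord to the
polygon at each; chord midpoints (lightly smoothed) form the midline, and
the cell width is the maximum chord. This station-chord construction
replaces a Voronoi-skeleton midline: it is exact for rectangles and
spherocylinders and robust on the near-convex shapes the generator
produces; strongly bent cells would need a true skeleton. Contours with
principal-axis aspect ratio ≤ 1.1 are flagged round — no midline, width
from the maximum inscribed circle.

The principal-curvature ratio divides the mean flank sidewall curvature by
κ₂ = 1/(width/2). Flank = vertices excluding max(10% of the length,
width/2) at each end; the width/2 widening removes exactly the
spherocylinder cap, whose curvature would otherwise leak into the "flat"
flank mean. Track-local queries instead average the 3 nearest contour
points on each side of the cell.

Tangent correlation uses directed edge angles atan2(Δy, Δx), so
G(l) = ⟨cos(θᵢ₊ₗ − θᵢ)⟩ equals cos(l/r) on a circle exactly; a
slope-arctangent (mod-180°) convention would flip the cosine past a quarter
turn and is equivalent only at small separations. Vertex separation is
converted to arc length via the mean edge length. Doubling times fit a line
to (t, ln area) and return ln 2/slope; slopes ≤ 10⁻¹² (constant series at
float precision) are flagged non-growing.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
images: no photophysics, no detection noise model, no segmentation error.
Passing tests therefore validate the estimators and the energy model, not
robustness to raw-microscopy artifacts.

- **random_field** — the null model: straight segments of displacement
  1 μm at 25 nm/s (41 frames at 1 s), centers uniform on a 100 × 100 μm
  area, angles uniform on [0°, 180°). Each track carries a recorded
  orthogonal-regression R² of 0.95 as metadata rather than noise calibrated
  to produce it: the angle statistics under test are independent of
  positional noise, and the recorded value lets the tracks pass the same
  filters as real data.
- **circumferential** — tracks at 90° to a rod midline with axial von Mises
  noise (one concentration parameter κ; angle = 90° + ν/2 with ν ~ VM(0, κ)
  on the doubled circle), speeds and lengths configurable.
- **ballistic / diffusive / isotropic** — straight drift, 2-D random walks
  (step sd √(2DΔt) per axis), optional Gaussian localization noise; the MSD
  oracles (MSD = (Vt)² exactly; ensemble MSD → 4Dt) pin the fit code.
- **contours** — spherocylinder (two flanks + semicircular caps), circle,
  and bulged sphere: a body circle externally tangent to a smaller bulge
  circle, joined by concave fillet arcs of radius `neck_depth` tangent to
  both, so neck vertices carry curvature of opposite sign (−1/neck_depth)
  to the convex body — the saddle-neck geometry of a sphere-to-rod
  transition. Optional radial vertex jitter; every generator is
  deterministic given its seed.

Defaults (1000+ null tracks, 128-vertex contours, 0.9 μm rod width, 1 μm
sphere radius) match the study conditions where stated and a realistic
microscopy scale otherwise.

## Known limitations

- The pill-mesh midline assumes near-convex cells; curved or branched
  morphologies need a skeleton-based midline.
- Adhesion does not scale with contact fraction at nonzero groove
  amplitude (fully bound filament assumed), and the membrane ansatz is a
  scaling form, not a solved membrane shape; both matter only in the
  low-pressure regime, where the conforming limit is still exact.
- ΔE is reported per filament of the stated length; length is a sweep axis
  for per-length questions.
- Single-trajectory MSD estimates of D scatter substantially (expected
  Monte-Carlo behavior); ensemble questions should pool tracks.
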