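# Methods

## The geometric model

A honeycomb-like capsule surface is idealised as a planar Voronoi
tessellation of its pore centres: pore *i* occupies the region
V(Pᵢ) = {x : ‖x − Pᵢ‖ ≤ ‖x − Pⱼ‖ ∀ j ≠ i}, and the wall separating pores
*i* and *j* lies on the perpendicular bisector of PᵢPⱼ. Two consequences
are testable on images: (1) every wall segment is perpendicular to the
segment joining the two pore centres it separates (the dual Delaunay edge) —
the acute intersection angle is exactly 90° for an ideal tessellation; and
(2) the wall network computed from the pore centres should overlay a
correctly traced wall network.

### Construction

`build_voronoi` implements the defining construction directly: each cell is
the intersection of the bounding box with the half-planes
{q : ‖q − Pᵢ‖ ≤ ‖q − Pⱼ‖}, clipped by Sutherland–Hodgman against one
bisector at a time, nearest sites first. Once every cell vertex is nearer
to the site than half the distance to the next candidate site, no remaining
bisector can cut the cell and clipping stops, which keeps the O(n²) method
comfortable for the few hundred sites a micrograph yields. This is the
reference implementation precisely because it is the definition; the test
suite checks it against two independent routes — a brute-force raster
labelling of grid points by nearest site (`nearest_site_raster_oracle`) and
`scipy.spatial`'s divide-and-conquer Voronoi/Delaunay.

All cells are clipped to a bounding box (tight box around the sites padded
by 10% of each span, by default), which makes areas and edge lists finite
and well defined; cell areas then sum exactly to the box area. Voronoi
edges are identified from cell-polygon sides whose midpoint is equidistant
(within 10⁻⁶ of the box diagonal) to the two nearest sites; edges shorter
than 10⁻⁹ of the box diagonal (degenerate, e.g. from near-cocircular sites)
are dropped. Coordinates are plain Cartesian; image-derived coordinates map
row r to y = −r so printed screen-style listings and image measurements
share one convention.

### Angle statistics

All intersection angles are folded acute into [0°, 90°] — the convention of
ImageJ-style angle tools, and the reason an observed mean below 90° measures
tracing error. For observed (hand-traced) wall segments the dual edge is
chosen as the two sites nearest the wall's midpoint; for points in the
plane the two nearest sites are Voronoi neighbours except where the pair's
shared edge was clipped away by the bounding box, in which case the segment
is skipped and counted. Under Gaussian angular error with sd σ the folded
acute angle has mean 90° − σ√(2/π) (folded-normal), giving a closed-form
check for the jitter simulation: σ = 6° → 85.21°.

The relative error of an observed mean angle against theory is
(90 − mean)/90 × 100, reported to one decimal.

### Congruence

`tessellation_congruence` samples points densely along both edge sets and
reports the mean and maximum symmetric point-to-nearest-edge distance plus
the fraction of observed edge length within a tolerance of the computed
diagram. Self-comparison gives (0, 0, 1.0); the mean distance grows
monotonically with vertex jitter.

## Image measurements

The segmentation chain mirrors standard micrograph practice: optional edge
emphasis (3×3 Sobel gradient magnitude rescaled to [0, 1]), Gaussian
smoothing (default 1.5 px), then global thresholding (Otsu's between-class
variance criterion over a 256-bin histogram, or a fixed level). Edge
emphasis precedes smoothing. For area-fraction work the edge-emphasis step
is off by default — it converts regions to outlines and is useful only for
boundary-based measurements on low-contrast images. Area fractions are
pixel counts; the foreground/background pair sums to exactly 100%.

Quantities the micrographs only show visually are operationalised as:

- **Pore diameter** — twice the maximum of the Euclidean distance transform
  inside each pore (background component of the wall mask), i.e. the
  maximal inscribed-circle diameter, with a half-pixel boundary correction
  (EDT is centre-to-centre). Equals the wall-to-wall chord on circular
  pores and is robust on polygonal ones. Pores clipped by the image border
  are excluded — their inscribed circle is truncated.
- **Pore depth** — in a vertical-section profile, the vertical extent of
  each wall spine above the dense layer top (first row with > 50%
  foreground), matching the reported protrusion lengths.
- **Layer thickness** — foreground run length along radial rays cast from
  the centre of an annular layer mask (36 rays by default, 0.25-px
  stepping); rays crossing a gap in a broken annulus are skipped with a
  warning, reducing n.
- **Cell major axis** — the longer of the axis-aligned bounding-box height
  and width per connected component, in µm. Touching cells merge and are
  measured as one cluster; no watershed splitting is applied, matching the
  cluster-as-unit convention of the surface micrographs.

All distances scale exactly with the nm-per-pixel calibration.

## Synthetic data: what it emulates and what it does not

No micrographs are distributed with the source study, so every pipeline
stage is exercised on synthetic samples that carry their own ground truth
(true sites, noise-free mask, realized per-structure values). Defaults are
the reported study conditions:

| parameter | default | provenance |
|---|---|---|
| pore diameter | 95.0 nm, per-pore SD 22.05 nm | printed 95.0 ± 4.41 (SE, n = 25); SD = SE·√n |
| pore depth | 166.3 nm, per-spine SD 29.55 nm | printed 166.3 ± 5.91 (SE, n = 25); SD = SE·√n |
| wall thickness | 20 nm | not printed; chosen from the apparent wall:pore proportion in the section images |
| dense capsule layer | 48.2 nm | printed 48.2 ± 2.82 |
| cell wall | 27.9 nm | printed 27.9 ± 1.97 (SE, n = 25) |
| cell diameter | 1.26 µm, SD 0.236 µm | printed 1.26 ± 0.236 (SD, n = 40) |
| biofilm cell area | 45.3% | printed cell:cavity ratio 45.3:54.7 |
| calibration | 2.0 nm/px (20 nm/px for cell fields) | a 95 nm pore spans ~48 px |

Printed SEs describe the mean of n measurements; the generator needs
per-object spread, hence the SE·√n conversion.

**Pore centres** sit on a triangular lattice with constant
pore-diameter + wall-thickness (115 nm), each node jittered isotropically.
The default jitter sd is the printed SE of the gap measurements (4.41 nm):
the pores are described as equally spaced, so positional disorder at the
measurement-uncertainty scale is the appropriate prior — and markedly
larger jitter is geometrically inconsistent with the stated pore size,
because cell irregularity inflates inscribed diameters well above
spacing − wall. Because nearest-neighbour spacing is a minimum over ~6
neighbours, jitter shrinks realized spacings below the lattice constant (an
extreme-value effect); the generator rescales the pattern about its
centroid so the realized interior mean nearest-neighbour spacing equals the
nominal constant. A hardcore (minimum-separation uniform) process is
available for robustness tests.

**Horizontal capsule sections** rasterise the Voronoi edges of the true
sites to the nominal wall thickness (distance-transform thresholding, so
realized thickness stays within a pixel of nominal), bright walls on dark
cavities, then Gaussian blur and additive Gaussian noise. They are exact
Voronoi tessellations of their true sites by construction. **Vertical
sections** are comb profiles: wall spines of Gaussian-drawn depth rising
from the dense capsule layer over the cell-wall band. **Biofilm sections**
place non-overlapping discs by drawing candidate centres from the free
region (distance transform), shrinking radii as space tightens, until the
ground-truth cell fraction is within 0.5 points of target. **Cell fields**
draw the full sample of diameters first and then place every cell (largest
first), so packing failures cannot bias the realized size distribution;
shading is flat-topped with a bright limb, as in secondary-electron images
of spheres. **Spectra** are sums of Gaussian bands on a flat baseline on a
descending wavenumber grid.

Passing recovery tests on these samples demonstrates that the measurement
chain returns the generating parameters under blur, noise, and
thresholding. It does not demonstrate robustness to electron-optical
artifacts the generator omits: charging and shading gradients, focus
drift, section compression and knife marks, projection distortion of
curved surfaces (noted but uncorrected in the source analysis), or
correlated texture noise. Real-micrograph numbers (the observed 83.7° mean
angle, the FT-IR reductions on actual colonies) depend on unavailable
images and are represented here only by their procedures and by synthetic
stand-ins.

## Statistics

Summaries use the sample SD (n − 1) and SE = SD/√n. The significance test
is the two-tailed Student's t-test assuming equal variance; p-values come
from the exact t cumulative distribution — at n = 3 per group the normal
approximation is badly anticonservative — with star labels ns (p ≥ 0.05),
\* (< 0.05), \*\* (< 0.01), \*\*\* (< 0.001). Zero pooled variance with
equal means returns t = 0, p = 1; with unequal means it is a degenerate
input and raises.

FT-IR band areas are trapezoidal integrals over the standard evaluation
windows (O–H/N–H 3200–3600, amide I+II 1500–1700, C–O 1000–1150, C–H
reference 2800–3000 cm⁻¹) and are expressed as ratios a/d, b/d, c/d
against the copper-insensitive C–H band. Transmittance input is converted
to absorbance (−log₁₀ T) before integration by default (band-area
comparison is conventionally absorbance-based; a flag integrates raw).
The default baseline joins the window-edge values (`linear_endpoints`);
`none` integrates the raw signal and is what flat-baseline synthetic tests
use. Percent reduction of a treated ratio against control is
(1 − treated/control) × 100; both raw-area and ratio-based comparisons are
possible since the reduction operates on whichever pair is supplied.

The diffusion barrier time t₉₀ = 1.03·L²/De (time for a solute at depth L
in a biofilm to reach 90% of bulk concentration under Fickian diffusion)
is provided as a direct formula with positivity checks.

## Numerical choices and scales

- Coincident-site rejection: pairwise distance ≤ 10⁻⁹ × bbox diagonal.
- Edge-to-site-pair assignment tolerance: 10⁻⁶ × bbox diagonal; zero-length
  edge cutoff 10⁻⁹ × bbox diagonal.
- Perpendicularity holds to < 10⁻⁶ degrees on all tested seed sets; the
  bisector property (equal endpoint distances) to 10⁻⁹ relative.
- Recovery tests and the acceptance script use: 2000 × 2000 nm horizontal
  sections (~250 interior pores), 100–150 vertical spines, 36 radial rays,
  512² px biofilm sections, and 40-cell fields — sizes chosen so sampling
  error is small against the printed uncertainties while a full run stays
  in seconds on one CPU.
- Determinism: every generator takes an explicit seed; identical seeds give
  bit-identical outputs. Pipeline reports contain no timestamp (the
  resolved-config sidecar does), so a seeded run is byte-reproducible.

## Known limitations

- The half-plane construction is O(n²) with small constants; it is meant
  for micrograph-scale n (≤ a few thousand sites), not point-cloud scale.
- Pore-site inference uses component centroids; pores clipped by the image
  border yield shifted centroids and are the main error source near frame
  edges.
- The wall→Delaunay assignment rule (two nearest sites to the wall
  midpoint) is a stated operationalisation — the original hand measurement
  protocol did not specify one.
- The unit of the bundled P1–P22 coordinates is the original image's pixel
  grid and is treated as dimensionless.
- No 3-D geometry: vertical and horizontal sections are modelled as
  independent 2-D problems; no correction for the projection distortion of
  spherical surfaces.
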