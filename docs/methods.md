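# Methods

## The measurement model

The method treats a leaf-off tree crown as a radial structure around a
fixed center **C** (the trunk fork): branches diverge from **C** and
grow predominantly *along* their own direction. Under that model the
growth signal is purely radial, so describing the crown in
center-relative spherical coordinates (r, θ, φ) turns branch elongation
into a change of r at a fixed (θ, φ) — a quantity that survives
discretization into angular cells and simple image differencing.

Three consequences shape the implementation:

- **Furthest point per cell.** Within an angular cell, the branch end
  is the furthest return from **C**; everything behind it (branch body,
  inner scaffold) is irrelevant to growth. Each cell stores the maximum
  radial distance after a per-cell percentile trim.
- **Intersection mask.** Differencing is defined only where both epochs
  saw something; cells populated in one epoch only are excluded rather
  than imputed.
- **Equal-area merging.** The solid angle of a Δθ × Δφ cell scales with
  cos φ, so zenith-ward rows are merged azimuthally
  (`m = round(1/cos φ_mid)` members per merged element, the last group
  absorbing any remainder) before statistics are taken, so that every
  element has comparable support. Note the spherical-quadrilateral area
  itself scales with r²·cos φ; only the cos φ factor is relevant to the
  *angular* reshaping, which is what the merge implements.

### Coordinate conventions

θ = atan2(X, Y) mod 360° (zero along +Y, increasing toward +X) resolves
the quadrant ambiguity of the single-argument arctan(X/Y) form while
agreeing with it in the first quadrant. φ = arcsin(Z/r) is an elevation
angle measured *from the horizontal plane* through **C** (0° at the
horizon, 90° at the vertical), despite often being called "zenithal" in
this context; its working range 0–90° covers the crown above the fork.
Points below the plane (trunk, low scaffold) are discarded by default
(`below_center="discard"`), or clamped to φ = 0 with
`"keep_clamped"`; both paths report how many points they touched.
Points coinciding with **C** have undefined angles and are dropped with
a count. Angles cross every API in degrees.

### Angular grids

Azimuth increments must divide 360° exactly so columns wrap cleanly.
Elevation increments may leave a *partial top band* at the zenith
(e.g. 20° → rows at 0–20, …, 60–80, 80–90°): the standard resolution
sweep {0.5, 1, 2, 3, 5, 7.5, 10, 15, 20}° requires this, and the top
band's merge factor uses its true center elevation. φ = 90° maps into
the top row; θ wraps at 360°.

### Per-cell outlier trimming

The trim keeps distances at or below the cell's p-th percentile
(default p = 99, exposed everywhere). Rationale: isolated long returns
in a cell are almost always SLAM ghosts or mid-air noise, while the
true branch end is supported by a cluster of near-tip returns; p = 99
removes roughly the single most extreme return per hundred without
biasing well-populated tips. The percentile of a non-empty set is at
least its minimum, so a cell never trims itself empty; p = 100 disables
the filter. Trimming is per cell, not global — a distance that is an
outlier in one direction is normal in another.

The vectorized implementation sorts points by (cell, r) and reads the
retained maximum directly at the percentile rank: for sorted values the
largest value not exceeding the linearly interpolated percentile is
`v[floor((p/100)(n−1))]`. The test suite checks this against an
explicit-loop reference implementation cell-for-cell.

### Growth statistics

Per tree: mean and SD of the cell differences (later − earlier;
positive = growth) over the intersection mask. Per orchard, the
per-tree-first convention: μ = ME = mean of per-tree means, MAE = mean
of their absolute values, σ = SD across trees of the per-tree means
(sample, n−1, by default; population optional — a single-tree orchard
has σ undefined (NaN) under the sample convention). A pooled per-cell
variant of ME/MAE is available (`pooled=True`) for sensitivity
analysis. Orchard statistics are computed on merged images by default,
matching the workflow order (reshape, then compare); unmerged images
remain available for diagnostics. The density view of an orchard is a
Gaussian KDE over per-tree means; when all means coincide the KDE is
undefined and a flagged unit point mass is returned instead.

## The synthetic orchard generator

Real HHLS campaigns come without per-branch ground truth, so the
generator exists to make every claim testable: it produces two-epoch
clouds whose true per-branch elongations are known exactly.

**What it emulates.** A mature leaf-off chestnut-like crown scanned by
a handheld SLAM unit: trunk fork ~1.3 m up; ~60 terminal branch systems
per tree spread over all azimuths and 5–65° elevation; branch reach
0.5–1.5 m from the fork; surface density ~3200 points/m²; range noise
SD 0.02 m (the middle of a 0.01–0.03 m scanner accuracy band);
per-branch seasonal elongation uniform on 0–0.5 m; tree-to-tree vigor
variation (per-tree elongation scale uniform on 0.4–1.6, emulating
orchards whose trees range from barely growing to vigorous); a trunk
section below the fork so the below-center policy sees realistic input.
A 64-tree orchard on an 8 m planting grid is the default campaign
scale. Everything is driven by one seed; equal specs give identical
clouds.

**Branch geometry: conical shoot systems.** Each branch is modelled as
a narrow cone (half-angle 1.5°) around its radial axis, sampled on the
outer `shoot_length` = 0.4 m — the terminal shoot with its side twigs,
which is what the laser sees and what fans out self-similarly with
distance from the center. Two deliberate choices here, made because the
obvious alternatives break the measurement model in ways real crowns do
not:

- *No inner scaffold sampling.* In a real crown, inner wood is never
  the furthest return in any direction — outer twigs overtop it. A
  sparse simulation that samples branch surfaces all the way to the
  center populates cells across the whole sky with short, epoch-static
  distances, a structure no real crown produces, and biases the mean
  difference low.
- *Cones, not constant-radius cylinders.* A thin cylinder's angular
  footprint shrinks with radius (atan(R/r)), so a cell boundary slicing
  a shoot's footprint sees only its inner portion; that cell's maximum
  is pinned at R/tan(δ) and does not advance under elongation,
  producing a systematic underestimate of several centimeters at 3–5°
  resolutions. The cone's footprint is radius-independent, so the whole
  visible structure — and every cell's maximum — slides radially with
  the tip, which is exactly the radial-growth geometry the method
  assumes of real branch systems.

**Noise: along-beam, not isotropic.** The 0.01–0.03 m accuracy of
handheld SLAM scanners is dominated by range and registration error
along the line of sight; per-point angular precision is millimetric at
crown distances, and what large transverse drift exists is spatially
smooth (it displaces whole branch regions coherently rather than
scattering points). The generator therefore applies Gaussian range
noise (SD 0.02 m) along the radial direction from the tree center — the
operator scans the crown from outside, so the beam is approximately
anti-radial at the branch surface — plus a small transverse jitter
(SD 0.005 m) for beam divergence and residual drift. Fully isotropic
per-point noise at 0.02 m would scatter returns angularly far more than
a real denoised cloud does and, like the cylinder geometry, pins
off-axis cell maxima at epoch-static values.

**What it does not emulate.** Occlusion, beam divergence footprints and
intensity, non-radial branch curvature, sub-branching topology,
foliage, wind deformation, and spatially correlated SLAM drift. Passing
tests on this generator therefore show that the pipeline measures
radial growth correctly when the radial-structure model holds and the
input is a denoised per-tree cloud; they do not show robustness to
heavily occluded crowns, mis-placed centers, or strongly non-radial
growth, all of which degrade the real method too.

## Numerical choices

- Empty cells are represented by an explicit mask (CSV sentinel `NA`),
  never zero — zero is a legal distance.
- r = 0 points are excluded with a logged count rather than an error
  (measure-zero degeneracy).
- φ = 90° is clamped into the top row; θ = 360° wraps to column 0.
- Merged images are rectangular arrays with per-row lengths; trailing
  padding is structurally unmasked and never written.
- Sample SD (ddof = 1) is the default everywhere a convention is
  needed; both per-tree `sd_growth` and orchard σ honor it.
- LAS is written at 1 mm coordinate scale — an order of magnitude below
  scanner accuracy — and LAZ is not supported.
- The CLI validation gate defaults to |ME| ≤ 0.03 m, the upper edge of
  the scanner accuracy band.

## Problem sizes

The test suite and the acceptance script run on 64-tree orchards
(~6 × 10⁵ points per epoch in total) at the full resolution sweep;
those sizes were chosen as the smallest that exercise the campaign
geometry faithfully, and keep a complete run to about a minute on one
CPU. Scaling to larger orchards is linear in points and trees.

## Known limitations

- The center **C** must be supplied per tree in the cloud's frame; the
  method's output is sensitive to its placement, and no automatic fork
  detection is attempted.
- Growth of branches that leave their angular cell sideways (strongly
  non-radial growth) is attributed to neighboring cells and partially
  lost; the model measures radial extension only.
- Cells populated in only one epoch carry no growth information and are
  dropped; heavily occluded or sparsely scanned crowns lose coverage
  accordingly (the per-image population counts are logged for
  diagnosis).
- ME/MAE/σ follow the per-tree-first reading; a per-cell pooled
  convention gives slightly different MAE on heterogeneous orchards and
  is available behind a flag.
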