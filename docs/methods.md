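# Methods

This note documents the models, parameter choices and numerics behind
`xpcilung`, in the order the pipeline runs them.

## Phantom

**Geometry.** The phantom is spheres-on-a-binary-tree inside a soft-tissue
body cylinder: a trachea descending along the vertical (rotation) axis
bifurcates for `depth` generations (default 5, radii shrinking by 0.85 per
generation from a 50 µm root), and spherical alveoli (default 21, the
number measured in the emulated study) attach near terminal branch tips
with diameters uniform on 100–150 µm — the immature-mouse alveolar range
the phantom emulates.  Bone rib arcs (torus segments) sit near the body
surface.  This is deliberately minimal anatomy: every structure has an
analytic volume, surface area and diameter, so each downstream stage can
be scored against ground truth.  Real alveolar anatomy differs in ways
that matter for interpretation: alveolar sacs share walls, open into their
ducts, and have non-spherical shapes and wall-thickness distributions that
the phantom does not model.  Passing tests here demonstrates that the
*measurement chain* is unbiased on resolvable, separable objects; it says
nothing about wall-sharing anatomy.

**Detachment choice.** Alveoli are placed detached from their parent branch, and rejection
sampling enforces clearances everywhere: 65 µm between any two air lumina
(branch/alveolus or alveolus/alveolus) and 80 µm between lung air and the
ribs or the body wall.  These are fringe-driven: edge enhancement paints a
dark ring one to two detector pixels wide around every interface, and
structures closer than two ring widths would have their rings merge into a
single thresholded component (neighbouring alveoli would fuse; lung air
would chain through rib rings to the outside air and be discarded with
it).
Real alveoli communicate with their duct; the gap is what makes
"one planted sphere = one labeled component" a well-defined ground truth
through the blurred reconstruction, which the per-object recovery tests
require.  Airway radii stop at ~26 µm (two detector pixels) because
thinner tubes are not resolvable at the 13 µm detector pitch and would
fragment into debris that contaminates per-object statistics.

**Steering.** Branch directions are drawn from a polar-angle range
(30–55°) at random azimuths; candidates are resampled (seeded, bounded)
until the branch stays inside the volume and body cylinder and clear of
the rib arcs, preferring endpoints that leave room for the remaining
subtree.  A placement pass that cannot seat all alveoli restarts its draws
(up to six times), and a tree whose shape leaves no room triggers a full
geometry re-draw from a derived seed (bounded); only then does generation
fail, reporting the count it managed.

**Rasterization.** Voxels take the material of the structure covering
their center (body, then ribs, tree lumina, alveoli), at 4 µm pitch on a
256³ grid (1.024 mm cube) by default — small enough that the full chain
runs in minutes, large enough that alveoli span 25–38 phantom voxels.

**Materials.** δ and β at 18 keV for air, water-equivalent soft tissue
and cortical-bone-like mineral are package constants (`materials.py`,
values derived from electron densities and standard mass-attenuation
figures), scaled δ ∝ E⁻², β ∝ E⁻⁴ elsewhere in the 8–72.5 keV band.  The
real animal's tissue composition is unknown; these are documented,
swappable stand-ins, and all downstream claims are about relative
contrast, not absolute gray values.

## Forward model

Ideal parallel monochromatic plane wave (synchrotron-like); no source
blur, no polychromaticity, no detector PSF beyond pixel binning.  Per
projection angle the δ+iβ volume is rotated about the vertical axis
(bilinear interpolation) and summed along rays; μ and ϕ follow the
prefactors above.  The exit wave exp(−μ/2 + iϕ) is propagated with the
Fresnel transfer function exp(−iπλz(u²+v²)) on a grid padded 2× with edge
replication (wrap-around suppression).  The propagation pitch is enforced
(not assumed) to be ≤ detector_pitch/2 and ≤ √(λz)/4 ≈ 2.27 µm at 18 keV
and 1.2 m — a quarter of the first Fresnel-zone width — by integer
upsampling of the projected maps; violating it raises an error naming the
bound.  The linearized weak-object propagator implements the Fourier-domain
relation above and agrees with the exact propagator to RMS < 1% of contrast
on weak smooth objects (tested); the exact propagator is the default and
the oracle.  The half-plane-edge fringe position is additionally checked
against the Fresnel-integral closed form (scipy's C/S functions).

Detector: area-weighted binning from the propagation grid to the 13 µm
pixel pitch, centered so the rotation axis lands on the (n−1)/2 detector
column; then Poisson noise at 10⁴ photons/pixel (flat-field level).  The
flat field is the mean of 20 no-object frames — the standard practice that
keeps flat noise from imprinting rings.  Photon count ≤ 0 disables noise
with a warning.  Default angle count is 1296 over 180° (the emulated
experiment); the packaged study configuration uses 240, which the angular
convergence of FBP makes visually indistinguishable at this grid size and
keeps a full run near ten minutes.

## Reconstruction

Projections are divided by the flat field, clamped at a small positive
floor, and −ln-transformed (attenuation convention: absorbing structures
positive, fringes superimposed as local over/undershoots).  No phase
retrieval — the edge-enhanced intensity itself is reconstructed, as is
conventional for in-line holotomography without a Paganin-type step;
consequently gray values are attenuation-like but carry a fringe term, and
only relative contrast is meaningful.  FBP: discrete band-limited ramp
kernel (spatial-domain definition, avoiding the DC bias of sampling |f|),
optional Hann apodization, cutoff at Nyquist; linear-interpolation
backprojection scaled by π/N; rotation center fixed at the (n−1)/2 column
(the simulation guarantees a centered axis, so no center search exists).
The implementation is validated against an analytic disk (2%), an impulse
localization test, and skimage's radon/iradon pair as an independent route.

## Segmentation

Air reconstructs dark.  The automatic threshold is the bottom of the
histogram valley on a percentile-clipped range (extreme fringe values
would otherwise crush the modes into a few bins), after moving-average
smoothing of width bins/64.  Two peak-pairing policies exist: the two
highest peaks (the generic contract), and a "dark" mode — dominant peak
paired with the highest darker peak — which the pipeline uses because a
bone mode can outrank the small air mode in these volumes.  Otsu's
criterion is the logged fallback for unimodal histograms and for dips
shallower than 5% of the smaller peak (noise, not a valley); when both
modes were detected but the dip is shallow, the pipeline thresholds at
air-peak + 0.4 x (tissue-peak − air-peak) instead.  The deep valley
threshold is deliberate: a milder (midpoint) threshold thickens the
fringe-ring network around every interface until the lung air percolates
through it to the border air and is removed with it.  The diameter
shrinkage the deep threshold would otherwise cause is corrected by hole
filling (next paragraph), leaving a residual mean equivalent-diameter bias
of about half a detector pixel.

Fresnel fringes oscillate *inside* air lumina, so a bare threshold yields
hollow shells.  The airway stage therefore removes border-connected
components (the air around the body) and then fills enclosed holes —
air spaces are solid cavities; the filling restores their volume.  The
bronchial tree is grown by seeded region growing *on the filled airway
mask* (predicate: mask membership, i.e. a binary gray volume at threshold
0.5), which keeps thin branches connected where the raw gray predicate
fragments them.  Region growing itself is the maximal connected set
containing the seed whose voxels satisfy the intensity predicate —
set-valued, order-independent, verified against an exhaustive BFS flood
fill.  The stopping rule is the intensity predicate alone; no leak
heuristics.  Connectivity defaults to 26 and is configurable.

Ribs: voxels ≥ a high threshold, with one binary opening pass (removes
the one-voxel fringe shells around air cavities that also reach bone-like
values) and small-component removal.  The pipeline's automatic bone
threshold is tissue-peak + 0.35 × (99.9th percentile − tissue-peak); a
config value overrides it.  Manual steps of the original workflow (airway
gray threshold, seed voxel) are explicit config/CLI parameters; the
pipeline's automatic seed maps a point 60% down the trachea into the
reconstruction and refines to the darkest voxel in a 5³ window.

## Morphometry

Per component: volume = voxel count × pitch³; equivalent diameter
(6V/π)^(1/3); 3D Feret calipers over surface-voxel centers + one pitch
voxel-extent correction (a single voxel has diameter = pitch), d_max exact
over pairwise distances (convex-hull pre-reduction above 400 surface
points), d_min as the minimal projected width over a 3° orientation
hemisphere; the ratio d_max/d_min as a spheroidicity index.  Components
below a configurable volume floor (default 1.5×10⁵ µm³, i.e. equivalent
diameter ≈ 66 µm) are excluded as sub-resolution debris — below the
planted 100 µm minimum and above the speckle scale.

Surface area: marching cubes at level 0.5 on the binary grid after
Gaussian smoothing (σ = 0.5 voxel), which suppresses the voxelization
staircase with negligible erosion — important because a stronger smoothing
also erases genuine noise-roughening of reconstructed surfaces and pushes
the measured area below the isoperimetric bound of the measured volume.
For well-resolved components (≥ 16 voxels across) three volume-preserving
Taubin passes on the mesh remove the residual voxel-scale ripple, making
the estimate converge monotonically to the analytic area as the pitch
shrinks; for coarser components the passes are skipped, where their
erosion would exceed the ripple they remove.  Voxel-face counting is the
fallback for degenerate components and the exact reference for cubes.

## Meshing and I/O

Iso-surfaces by marching cubes with a one-voxel constant pad so closed
components yield watertight meshes; vertices in world µm.  Export to
STL/PLY/OBJ via trimesh; STL is unitless by format, so units live in the
run manifest.  Plane clipping keeps the half-space the normal points into,
splitting crossing faces, cut left open (the cut-away rendering use case).
Volumes travel as multi-page TIFF (float32 gray, uint32 labels) with JSON
sidecars carrying pitch, provenance and label legends; configs are YAML;
every `run_all` writes a manifest sufficient to re-execute each stage.

## Determinism and problem sizes

All randomness flows from `numpy.random.default_rng` seeded per stage from
one base seed; identical config + seed reproduces every artifact
bit-identically (tested).  The packaged study run is 256³ phantom voxels
at 4 µm, 240 projections onto 78×78 detector pixels at 13 µm, ~10 minutes
on one CPU; the test suite also uses a 80³ / 90-projection miniature for
the stage-level checks.  The slanted-edge resolution measurement uses a
tilted (3°) tissue bar at 2 µm simulation pitch, 200 noise-free
projections, quarter-pixel ESF binning, and reports the FWHM of the LSF
main lobe; with propagation fringes at 1.2 m the measured FWHM (~8 µm)
sits below the 13 µm pixel pitch — fringe sharpening, an expected feature
of edge-enhanced reconstructions.

## What per-voxel overlap can and cannot show

Dice overlap of the airway and rib masks against planted truth saturates
around 0.75–0.85 under these fully coherent conditions: the masks are one
fringe-ring wide of the true boundary (airways) or rim-dominated (bone),
which is a property of the contrast mechanism, not a segmentation bug.
The quantities the pipeline exists for — per-alveolus diameters and
areas — are insensitive to this: hole filling and the volume-based
equivalent diameter keep the mean diameter error near half a detector
pixel.  A partially coherent source or a phase-retrieval step would trade
fringe amplitude for overlap fidelity; both are out of scope here.

## Known limitations

* No partial coherence, polychromaticity, cone-beam geometry, detector
  PSF, ring/center artifacts — the simulation isolates the Fresnel
  mechanism itself.
* No phase retrieval; gray values are qualitative.
* The phantom's separability (detached alveoli) idealizes real acinar
  anatomy; recovery metrics do not transfer to wall-sharing structures.
* Diameter recovery at the 13 µm detector pitch carries a residual bias
  of a fraction of a pixel from the fringe-distorted edge profile; the
  tests bound the mean absolute error at two reconstruction pitches.
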