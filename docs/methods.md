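# Methods

`spinereg` implements a marker-based 3D/2D rigid registration pipeline for
spine imaging — aligning vertebrae segmented from a baseline CT-like volume
to a pair of intraoperative fluoroscopy-like views — together with a
procedural phantom that generates every input the pipeline needs, and a
target-registration-error (TRE) harness that measures it.  This note
describes the model, the numerical choices, and what the synthetic
experiments do and do not show.

## Coordinates, poses, cameras

All 3D quantities live in one patient-aligned frame in millimetres:
x left–right, y caudo-cranial, z fronto-dorsal (depth of a prone patient).
A rigid pose is `q = (tx, ty, tz, ωx, ωy, ωz)` — translations in mm,
rotations in degrees applied extrinsically in the order x→y→z about an
explicit rotation center.  Per-vertebra poses rotate about the
vertebral-body center; the coarse global pose rotates about the volume
center.  Keeping the center explicit keeps translation magnitudes
comparable across vertebrae and makes the TRE axis decomposition
meaningful.

The C-arm is an ideal cone-beam camera: point source, flat detector
orthogonal to the central ray, square pixels, pixel-center 0-based
coordinates.  Angulation is a rotation of the whole camera about the
patient's longitudinal (y) axis; 0° is anterior–posterior.  The mobile
C-arm's intrinsics are not published for this problem, so the defaults —
SDD 1000 mm, 256² detector at 1.0 mm pitch for the scaled-down phantom —
are configuration, not claims.  The detector–skin distance factor
(200/300 mm) is realized by shifting the source–object distance, i.e. by
its magnification effect, the only geometric consequence available in this
model.

## The phantom

A stylized spine: per vertebra an ellipsoidal body, a posterior ring
(torus), two pedicle struts and a spinous knob, stacked along y with
low-intensity disc gaps, inside an elliptic-cylinder soft-tissue torso
(bone ≈ 0.03 /mm, tissue ≈ 0.005 /mm).  Shapes are voxelized with a
one-voxel anti-aliased edge so line integrals and image gradients are well
behaved.  Stylization is deliberate: the registration machinery needs
structured gradients, not anatomy, and analytic shapes give exact landmark
ground truth (body center and left-pedicle center — the two TRE points,
both on a pedicle-screw trajectory).

Default scale: 96³ voxels at (1.0, 0.67, 1.0) mm — 0.67 mm slice spacing as
in a thin-slice baseline protocol — holding five labelled vertebrae
(~13 mm pitch).  This is roughly a factor 2–3 smaller than life; it keeps a
full simulate→register→evaluate replicate around 20 s on one CPU so that
20-replicate experiments fit desk-scale runtimes.  Problem sizes quoted by
the test suite (96³ volume, 256² detectors, 20 seeds/replicates) are this
package's chosen study conditions.

Intraoperative change is modelled per vertebra as an independent uniform
rigid perturbation, by default up to ±5° about x and ±2 mm along z — the
inter-vertebral motion the per-vertebra registration is designed to absorb.
Perturbations are applied at projection time (the rays are inverse-mapped
per vertebra), never by resampling the volume, so there are no resampling
artifacts and the rigid model is exact.  When a vertebra is "lifted out" of
the background volume for separate projection, the hole left behind is
filled with soft tissue; filling it with vacuum would imprint bone-shaped
edges at the *unperturbed* outlines and measurably bias the similarity
optimum (~0.3 mm in early experiments).

Skin markers are radiopaque spheres (r = 3 mm, µ = 0.5 /mm) scattered on
the dorsal skin surface within a 150×150 mm frame centered over the
centered vertebra, rejection-sampled to ≥2 diameters separation, count
5–9 (8 by default).  The surface is convex — 25 mm sagittal drop toward the
lateral frame edges, plus ±2 mm relief — like a prone back.  This curvature
is load-bearing: markers on a *plane parallel to the inter-view baseline*
make the relative angulation mathematically unobservable from two views
(rotating the second camera can be compensated by sliding the
reconstructed points within the plane).

Fluoroscopy simulation composes per-vertebra DRRs (each under its true
pose), the soft-tissue background, and analytic marker footprints, all in
the line-integral domain, then applies Poisson-like noise (variance
`gain·I`, gain 0.003), Gaussian detector noise (σ 0.03 ≈ 3% of a typical
bone path), and an affine intensity change (scale 1.3, offset 0.1) that
forces the similarity's scale factor `s` to do real work.  The noise level
was set so that registration error is dominated by view geometry rather
than by the optimizer's convergence floor — the regime the angulation
experiment is about.  The second view's realized angulation is jittered
(±2° uniform) around its nominal value, as a hand-positioned C-arm would
be; view 1 defines the reference frame and is taken as exact.

What the phantom does **not** emulate: real bone texture and anatomy,
pathology (lesions, fractures), scatter, beam hardening, detector blur,
soft-tissue deformation, and marker-skin motion.  Passing tests therefore
demonstrate the *algorithmic* properties (conditioning, convergence,
trends), not clinical accuracy on humans.

## DRR formation

Ray-driven line integrals with trilinear interpolation at a fixed step
(default half the smallest voxel; one full voxel at half-resolution search
stages), restricted to the detector region of interest and to the bounding
box of the projected structure.  Sample positions are snapped to a global
grid along each ray (anchored at the source) so that a decomposition of one
volume into masks + background integrates to exactly the sum of its parts.
The central-pixel integral of a homogeneous sphere matches the analytic
chord length 2rµ to <0.1% at 0.25 mm steps.  The inner loop is a numba
kernel (~35× the scipy `map_coordinates` fallback, which remains as the
no-numba path).

## Similarity

The measure compares vertical and horizontal central-difference derivatives
(replicate borders) of fluoro and DRR after removing an intensity scale s:

    S = Σ_ij A_v/(A_v + I_diffV²) + A_h/(A_h + I_diffH²),
    I_diffV = dI_fl/di − s·dI_DRR/di   (I_diffH likewise in j)

Each per-pixel term has the 1/(1+x²) form and lies in (0, 1], so
S ≤ 2·N_ROI with equality exactly when the scaled gradients agree.  Three
quantities the formulation leaves open are fixed as follows:

* **s** — re-estimated per evaluation by the least-squares closed form
  `s = Σ∇I_fl·∇I_DRR / Σ|∇I_DRR|²` over the ROI (both directions pooled);
  an all-zero DRR gradient returns s = 1 with a degeneracy flag.
* **A_v, A_h** — default to the squared median absolute fluoro gradient on
  the ROI; tying the soft threshold to the data keeps the normalization
  meaningful across noise levels.  Any positive constants may be supplied.
* **ROI** — per-vertebra matching uses the projected bounding box of the
  vertebra's mask dilated by 5 px (plus the translational search margin
  during optimization).  Detected marker footprints are cut out of the
  support: a sphere marker's gradients are not explainable by a vertebra
  DRR and otherwise bias the optimum when they overlap the spine.

Images are compared in the line-integral (log-like) domain; the affine
detector response of the simulation plus the explicit s factor model the
fluoro/DRR intensity mismatch.

## Marker detection and relative pose

Detection: the image is flattened by subtracting a wide Gaussian
background, then LoG blob detection over the expected radius range,
greedy non-maximum suppression at one marker diameter, and subpixel
refinement — intensity-weighted centroid followed by a least-squares fit of
the analytic sphere-radiograph profile `b + a·√(R²−d²)`.  On simulated
views the fit reaches ~0.02 px median centroid error, which is what makes
sub-0.1° angulation recovery possible.

Correspondence: every cross-view detection pair is scored by the
closest-approach distance of its back-projected rays under the nominal
geometries; the assignment minimizing total residual (Hungarian algorithm)
is the match.  Fewer than five detections in either view is an error.

Relative pose: initialized by a few alternating rounds of {triangulate the
matched rays; Umeyama-align the per-view closest-point sets; move the
view-2 camera} — the alternation alone contracts only linearly, so it is
finished by a Levenberg–Marquardt refinement under pixel reprojection
error.  Two statistical facts shape the refinement: (i) with only ~9
markers, a free-point bundle adjustment (33 parameters vs 36 measurements)
overfits noise badly; (ii) the markers' rigid 3D constellation is known —
they are hybrid optically-tracked markers, so their model exists outside
the images — and aligning that *rigid* model (6 alignment + 6 camera
parameters) restores the redundancy and conditions the angulation well
even for shallow marker relief.  The baseline magnitude between the views
is unobservable from image correspondences (a camera translation along the
baseline rescales the scene consistently); a weak Tikhonov term pins that
flat direction at its nominal initialization.  The initialization requires
the nominal angulation to be coarsely right (the config-declared pair;
tested up to several degrees of jitter), mirroring the clinical fact that
the C-arm's approximate angle is known without being calibrated.

## Two-stage registration

* **Stage 1 (coarse, one view):** the centered vertebra and its cranial
  neighbour are matched *simultaneously* with a single shared pose (about
  the volume center) against view 1 at half detector resolution.  Matching
  two vertebrae at once anchors the cranio-caudal position (a single
  vertebra can latch onto the wrong level).  Translation is parametrized in
  the camera basis with the component along the viewing ray clamped to
  ±2 mm: one view cannot observe its own depth, and letting it drift pushed
  stage-2 starts outside their search bounds.
* **Stage 2 (per vertebra, two views):** each vertebra is registered
  separately, maximizing the unweighted sum S₁+S₂ over both views (the
  view-2 geometry is view 1 composed with the estimated relative pose),
  multi-resolution: half detector resolution, then full, the second level
  starting from the first's optimum with a 0.3× step size.

Both stages use the package's CMA-ES (rank-µ + rank-one updates, cumulative
step-size adaptation, Hansen's default strategy parameters; λ = 8 at n = 6).
Defaults: σ₀ = 2 mm / 2° per coordinate, bounds ±10 mm / ±10° about the
stage-1 pose, 400 evaluations for stage 1 and 300 + 300 for stage 2, early
stop at 1e-3 relative best-objective stagnation over 20 generations.
Bounds are enforced by evaluating the clipped candidate plus a quadratic
out-of-bounds penalty, so returned solutions are always feasible.  A result
is flagged "converged" when the run stopped on stagnation or its normalized
step size contracted below 0.8 — a statement about the search settling, not
a guarantee of correctness (a wrong-level lock-in can converge; ground
truth exposes those in simulation, outlier statistics flag them in
practice).  Vertebrae whose posed bounding box does not project fully onto
both detectors are skipped with a recorded capture failure and no pose;
sacral vertebrae are excluded by default.

## Evaluation

TRE is the Euclidean distance between a landmark mapped by the estimated
vs. the true pose; it is computed at the body center and at the left
pedicle, with the signed per-axis decomposition (z = dorsal) and the
rotational-error indicator TRE(pedicle) − TRE(body).  Cohort summaries use
medians, linear-interpolation quartiles, and Tukey fences (Q1 − 1.5·IQR,
Q3 + 1.5·IQR); outliers are exactly the values outside the fences.  Axis
errors are reported both as signed medians and medians of absolute values,
clearly labelled.  Inferential statistics (rank tests, regressions) are out
of scope; the harness emits raw per-stratum values any stats package can
consume.

The RAD sweep runs the full simulate→register→evaluate loop per angulation
stratum (opposed pairs: ±20°→40, ±28°→56, ±30°→60, ±32°→64, ±45°→90) per
replicate, with fresh phantoms, markers, perturbations and noise each time.
Acceptance-scale sweeps register only the centered vertebra per replicate;
per-vertebra independence makes this unbiased for per-vertebra TRE while
cutting runtime five-fold.  Two qualitative anchors are expected and
tested: the median TRE decreases from RAD 40° to RAD 90° (wider view
separation conditions the depth axis better), and at RAD 40° the |z|
component dominates |x| and |y| (a near-AP pair constrains depth worst).
Absolute accuracies measured on real spines depend on the specimen and the
acquisition and are not reproduced here — only the trends are.

## Known limitations

* Stylized anatomy; no deformation, scatter, or detector physics beyond
  Gaussian/Poisson-like noise.
* The relative-pose step needs the rigid marker constellation; without it
  (pure two-view estimation) shallow marker relief degrades angulation
  accuracy by an order of magnitude.
* Wrong-level lock-in is possible when a stage-2 search starts ≥ half a
  vertebra pitch off in y without stage-1 anchoring.
* The convergence flag measures search contraction, not correctness.
* DICOM reading supports plain axial series with uniform slice spacing.
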