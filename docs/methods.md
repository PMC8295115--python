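# Methods

## Problem

During pulmonary-vein isolation a cryo-balloon catheter is navigated under
biplane X-ray fluoroscopy. The only reliably localizable part of the device
is its radio-opaque marker — a small, very dark band on the catheter shaft —
and the shaft itself, a dark tube a few millimeters wide. `cryoloc`
implements the full chain from raw 2D frames to a 3D device pose:

1. **Annotation** (semiautomatic): one manual click per run is grown into
   training masks for the whole run.
2. **Segmentation**: two U-nets predict per-pixel soft masks of the marker
   and of the shaft centerline.
3. **Post-processing**: soft masks become a sub-pixel seed point and a
   spline centerline.
4. **3D reconstruction**: seeds and centerlines from the two views are
   combined by epipolar geometry into the 3D marker position and the unit
   catheter-direction vector, onto which a 28 mm balloon model is aligned.

No clinical frames are distributable, so all quantitative statements are
made on a synthetic phantom with exact ground truth; see *Phantom* below
for what this does and does not demonstrate.

## Projection model

Each C-arm view is an ideal point-source/flat-detector camera. The world
frame is right-handed, origin at the isocenter, z head-ward. The primary
angle rotates the source-detector axis about z (LAO positive, RAO
negative), the secondary angle about the resulting lateral axis. Pixels
are (u = column, v = row), 0-based, centers on integers; the isocenter
projects exactly onto the detector center pixel.

Defaults: source-isocenter distance 800 mm, source-detector distance
1200 mm, detector 512 x 512 px. The pixel spacing, 0.56/1.52 ≈ 0.368
mm/px, is back-derived from the clinical pixel-to-millimeter conversion
(1.52 px = 0.56 mm); the scanner's true spacing and distances are not
published, so these are stated model choices, not calibrations.

Triangulation uses the midpoint of the common perpendicular of the two
back-projected rays. Half the perpendicular's length is reported as the
residual — a natural quality metric that is zero exactly when the rays
intersect. This midpoint coincides with the least-squares point minimizing
the summed squared distances to both rays (the test suite checks this
equivalence against an explicit normal-equations solve).

## Phantom

The phantom renders additive darkness on an 8-bit canvas: a ~200-level
background with smooth low-frequency shading, a dark anti-aliased tube
along the projected shaft curve (physical radius 1.75 mm), a darker
elliptical marker (semi-axes 0.8/0.8/0.5 mm, chosen so the projected
marker area of ~20 px respects the 10 x 10 annotation ROI), dark blob and
vessel-like clutter, an occasional large contrast-agent-like cloud, and
Gaussian noise (default sigma 2). The shaft extends 45 mm proximally from
the marker and 8 mm distally (the tip stub entering the balloon). Marker
positions are uniform in a box about the isocenter; shaft directions are
uniform on the sphere excluding a 10 degree cone around each view's
central ray, so biplane reconstruction is well posed by construction (a
flag re-enables degenerate scenes for negative tests). Within a run the
marker drifts by at most 2 px/frame in every view while clutter and
background stay fixed, which is what makes template tracking meaningful.

There is no physical attenuation, no scatter, no ECG-gated motion, and the
background texture is far simpler than real anatomy. Passing the phantom
tests therefore demonstrates the *algorithmic* correctness of the chain —
tracking, graph extraction, training dynamics, projective geometry — not
clinical-grade robustness to contrast injections or overlapping devices.

## Annotation

**Marker.** The click is grown to a 10 x 10 template. The per-run
segmentation threshold is the midpoint between the darkest template pixel
and the median of a surrounding 30 x 30 annulus — a concrete, seed-only
rule standing in for per-run manual calibration. Tracking uses local-sums
normalized cross-correlation (zero-mean, unit-variance per window; ties
break toward smallest row, then column). Frames whose segmented area falls
outside [2, 60] px or whose centroid jumps more than 5 px are flagged and
excluded; an NCC peak below 0.5 freezes the ROI and flags the frame, and
three consecutive losses truncate the run.

**Shaft.** The frame is inverted, equalized with *contrast-limited
adaptive* histogram equalization (CLAHE, 64 px tiles, clip 0.02), and
ridge-enhanced with multiscale Frangi vesselness at scales (7, 9) px,
matched to the ~7 px projected tube radius. Two numerical findings drove
these choices: scales well below the tube radius respond to the tube's
*edges* (the equalized tube interior is a plateau), displacing the
skeleton by half the tube width; and global equalization lets smooth
background shading erase the tube contrast locally (annotation success on
200 clean frames: 89% global vs 100% adaptive). The response is
Otsu-binarized (1024 bins over the nonzero responses), closed with a 3 x 3
square, specks under 8 px are dropped, and the result is skeletonized.

Skeleton pixels inside a 50 x 50 ROI around the seed become an 8-connected
graph with weights 1/sqrt(2); nearby connected components (gaps up to
12 px, e.g. where the marker locally suppresses vesselness) are merged
through straight distance-weighted bridge edges, then the component
nearest the seed is kept. Shortest paths between all end-node pairs are
computed by Dijkstra's algorithm (ties broken by lexicographically
smallest node sequence, making extraction fully deterministic); candidates
must pass within 10 px of the seed — measured point-to-segment against
the path polyline, so a bridge spanning the marker gap counts — and have
an end-to-end chord orientation inside the operator's interval (±30
degrees around the expected shaft angle during annotation, fully open at
inference). The longest candidate wins; ties prefer smaller seed distance,
then lexicographic end-node order. The path is fit with a cubic smoothing
spline parameterized by chord length (assumed point noise 0.5 px) and
resampled at 1 px arc spacing; rasterized at 3 px thickness it is the
shaft-net training target (1 px targets make per-pixel losses vanishingly
sparse).

## Segmentation networks

Both networks share one encoder-decoder architecture: per level two 3 x 3
convolutions + ReLU, 2 x 2 maxpool down, 2 x 2 stride-2 transposed
convolutions up with skip concatenations, dropout 0.5 at the bottleneck,
and a residual connection feeding the input image into the 1 x 1 output
stage before the sigmoid. The marker net sees the grayscale frame (1
channel); the shaft net additionally receives a marker mask (2 channels) —
either predicted or annotated. Training uses per-pixel binary
cross-entropy (optionally class-weighted; a soft-Dice alternative is
available) with Adam at learning rate 1e-3. Clinical-protocol defaults: 50
epochs, batch 8 (marker) / 4 (shaft), 512 px frames.

The entire network — im2col convolutions, pooling, transposed
convolutions, backpropagation, Adam — is implemented on numpy in float32.
This keeps the package dependency-light and training bit-deterministic
under a seed; a desk-scale configuration (128 px frames, depth 3, 8 base
filters, ~120k parameters) trains in a few minutes per net on one CPU.
Gradients are verified against directional finite differences in the test
suite.

Desk-scale experiments in the tests and the acceptance script use 15
epochs (marker, class weight 5) and 12 epochs (shaft, class weight 10) on
~200 training frames at 128 px — sizes chosen so the full suite runs
comfortably on a single CPU while still exercising real learning. The
class weights counter the extreme foreground imbalance (a ~20 px marker in
16384 px); localization is read off the *relative* response (threshold at
20% of the per-image maximum), so calibrated probabilities are not needed.

## Post-processing

The marker soft mask is binarized at 20% of its maximum; the largest
connected component is filled and its image-moment centroid
(m10/m00, m01/m00) is the seed point. Multiple detections keep the largest
component deterministically (unique device identification is out of
scope, as in clinical practice to date). An empty thresholded mask yields
a typed absent result, never an exception — non-detections are data for
the detection-rate statistics. The shaft soft mask is binarized at 1.5% of
its maximum and runs through the same skeleton-graph-spline machinery as
annotation (orientation interval fully open, no bridging — the network
output is already gapless).

## 3D reconstruction

Seeds from the two views are back-projected and triangulated. Each view's
centerline is reduced to a total-least-squares line (principal axis
through the centroid); its sign points away from the seed, i.e. along the
visible shaft. Embedding the 2D direction into the detector plane and
crossing it with the source ray through the line centroid gives the unit
normal of the plane containing the source and the image line; the
catheter direction is the cross-product of the two plane normals — the
intersection of the two planes. Using the source ray through the *line
centroid* rather than the central projection vector matters: the central
approximation is exact only for lines through the detector center and
costs ~1e-2 rad on off-center lines, while the exact form recovers
noiseless directions to 1e-6 rad. The sign of the 3D direction is chosen
so its projections agree with the 2D tip-ward line directions in both
views. Orthonormals within 1 degree of parallel raise a degeneracy error
rather than returning a wild estimate (the method assumes a essentially
straight shaft and well-separated views). Quality is reported as the
triangulation residual and the per-view back-projection error of the
reconstructed marker.

The balloon model (ellipsoid semi-axes 14/14/12 mm, shaft with tip,
marker offset -20 mm along the shaft axis) is placed with its marker at
the reconstructed position and its axis along the direction; roll about
the axis is unobservable and fixed to 0. Overlay rendering and OBJ mesh
export are diagnostic conveniences.

## Numerical choices and degenerate inputs

- Rays are normalized on construction; triangulation refuses ray pairs
  within 1e-6 rad of parallel and carries the angle in the error.
- All randomness flows through `numpy.random.Generator` seeded from
  explicit integers; scene, view, and frame indices enter the seed so a
  dataset is reproducible file-by-file.
- Graph extraction is deterministic including ties (lexicographic node
  ordering everywhere).
- Spline fitting collapses duplicate consecutive points first and refuses
  paths shorter than 4 distinct points.
- Constant images yield zero ridge response; empty binarizations yield
  empty skeletons with a warning; empty soft masks yield absent results.

## Limitations

- Phantom realism, as above; detection rates measured here do not predict
  clinical rates.
- The shaft is modeled as straight for direction recovery; strongly
  angulated catheters violate the cross-product construction.
- Vesselness scales are matched to the rendered tube width; other imaging
  scales require adjusting `scales_px`.
- Training at the 512 px clinical protocol size is supported but slow on
  CPU; the numpy backend is not meant for GPU-scale training.
- No temporal smoothing across frames and no multi-device disambiguation.
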