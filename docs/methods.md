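# Methods

## Imaging model

The rig is a single monochrome pinhole camera viewing a plant on a
rotation stage. A "view" is a bundle of three single-channel frames taken
through red/green/blue band-pass filters under white light, optionally
plus one green-filter frame under 365 nm UV excitation. Between two
consecutive views the stage rotates by a small angle θ about the vertical
axis; at working radius R this displaces the scene relative to the camera
by ≈ R·θ horizontally, which is the rectified-stereo regime the
reconstruction assumes. The package therefore models the two-view
geometry as a pure horizontal baseline b: a surface point at depth Z
moves by the disparity d = f·k_u·b/Z pixels between views, and no
rotation compensation or rectification is applied. This is accurate for
step sizes of a few degrees and degrades as θ grows — which is precisely
the trend the angle-step study quantifies.

Reprojection uses the 4×4 perspective matrix with rows
(1, 0, 0, −u₀), (0, −1, 0, v₀), (0, 0, s·f·k_u, 0), (0, 0, 0, 1) applied
to [u, v, 1/d, 1]ᵀ. Because the last row pins the homogeneous scale to 1,
the closed form is X = u − u₀, Y = v₀ − v (world Y points up; image v
points down), Z = s·f·k_u/d. Only k_u enters the depth row, so cameras
with non-square pixels get an asymmetric treatment of Y; the reference
rig has square pixels (k_u = k_v) and the point is moot. The
dimensionless calibration factor s (default 0.02) absorbs the unknown
baseline scale: recovered depth is proportional to true depth with factor
s/b, and absolute metric depth is not claimed. An optional `world_scale`
multiplies the final coordinates when a metric calibration exists.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `f` | 8 mm | objective focal length |
| `ku`, `kv` | 1/0.00345 px/mm | reciprocal pixel pitch (3.45 µm pixels) |
| `u0`, `v0` | 720, 540 px | principal point (1440×1080 sensor) |
| `s` | 0.02 | calibrated reprojection scale |
| `upsample_factor` | 5 | bicubic upsampling before detection (1080×1440 → 5400×7200) |
| `match_ratio` | 0.6 | Lowe ratio-test cutoff (kept iff best/second ≤ ratio) |
| `ann_kdtree_indexes`, `ann_trees` | 1, 5 | nearest-neighbour index configuration |
| `max_vertical_drift` | 20 px (native) | vertical-drift gate on matches; scaled by the upsampling factor |
| `disease_threshold` | 110 counts | UV-green fluorescence threshold; values ≥ τ kept |
| `channel_for_matching` | `exg` | channel used for detection/matching |

## Design choices

**ExG is kept signed.** ExG = 2G − R − B ranges over ±2·(2^bits − 1) and
is stored as float without clipping; only `normalize_for_detection`
(affine min–max to 8-bit, constant images to zero) produces detector
input. This preserves contrast ordering and makes the quantisation an
explicit, testable step.

**Disparity is the horizontal displacement magnitude.** The turntable
rotates about a vertical axis, so apparent motion is horizontal; vertical
displacement beyond `max_vertical_drift` marks a gross mismatch and the
pair is discarded (as are zero-disparity pairs, which carry no depth).
No RANSAC runs by default — the drift gate suffices on well-textured
input — but an affine-consistency RANSAC is available (`use_ransac`).

**Matching backends.** The default matcher answers 2-nearest-neighbour
descriptor queries from a k-d tree; an exhaustive `brute` mode exists and
the two are asserted equal in tests, so the index is never trusted blind.
The ratio comparison is inclusive (`≤`) at the boundary.

**Upsampled coordinates are rescaled to native pixels** (u, v and d all
divided by the factor) before reprojection, so Z = s·f·k_u/d means the
same thing at every upsampling setting and s keeps one calibration.

**Densification.** The reported clouds with one point per plant pixel
come from interpolating the sparse matched depths over the image plane:
linear (barycentric) inside the convex hull of samples, nearest-sample
outside, over the plant mask (ExG > 0 by default). With fewer than three
samples the linear method falls back to nearest with a warning.

**Disease registration is the identity in pixel space.** UV and
white-light frames share camera and pose; a resolution mismatch is
bridged by nearest-neighbour mask resizing to preserve binarity. The
threshold keeps values exactly equal to τ (only signals *smaller than*
110 counts are removed). Leaf veins also fluoresce and are not
suppressed; τ is the single exposed control. Coverage is computed over
the mapped surface points, and both raw counts are serialized alongside
the fraction.

## The synthetic scene generator

`make_scene` builds a rosette of elliptical leaves with a smooth random
depth field (600–1000 mm) blended into a far background plane (1400 mm),
band-limited speckle texture, and channel weights that make ExG ≈ +120
counts on the leaf and −20 counts on the background. A fluorescence patch
covering an exact requested fraction of the leaf area (default 4%) emits
200 counts in the UV-green frame over a 20-count autofluorescence floor.
`render_views` renders the pair under the small-angle translation model
with a z-buffered, row-supersampled forward splat (occlusions at leaf
borders resolve to the nearer surface; disocclusion holes take the
nearest rendered sample), adds per-view glare and Gaussian sensor noise
(σ = 0.5 counts), and returns per-pixel ground-truth depth and disparity.
All randomness flows from one seed; identical seeds give identical scenes
and renders.

The glare field — band-limited noise fixed in the *image* frame and added
equally to all three channels — emulates view-dependent specular sheen.
Single channels see it as clutter that does not co-move with the surface,
while ExG cancels it exactly as common mode. This is what makes the
channel study reproduce the ExG advantage on synthetic data; on real
foliage the advantage additionally draws on saturation and spectral
effects the generator does not model. Other omissions: no true rotation
(so the generator cannot probe rotation-model error itself, only feature
decorrelation with baseline), no demosaicing/flat-field artefacts, no
fluorescing veins, no self-occlusion between overlapping leaves beyond
the z-buffer, and Lambertian-flat shading. Passing tests therefore
demonstrate the pipeline's internal consistency and its behaviour under
the stated image-formation model, not performance on real plants.

## Numerical notes

- Bicubic upsampling uses the pixel-center convention and clips overshoot
  back to the bit-depth range before re-quantising.
- Keypoints carry subpixel positions; intensity lookup at a source pixel
  is nearest-neighbour.
- Degenerate inputs: constant images yield zero keypoints (not an error);
  empty match sets or all-zero disparities abort reconstruction with a
  diagnostic rather than emitting an empty cloud; an empty cloud makes
  coverage undefined (error).
- Z-buffer ties in the renderer resolve to the first sample in scan
  order; at 4× row supersampling the geometric splat error is ≤ 1/8 px.

## Problem sizes

Tests and the acceptance script run the generator at 0.12–0.17 MP for
unit-level checks, 0.39 MP (540×720, the default `SceneParams`) for
fixtures, and ~1 MP (864×1152) for the full round-trip fidelity check —
sizes at which SIFT statistics are stable while the whole suite stays
quick on a laptop. The round trip at ~1 MP typically yields ~10⁴
keypoints per view and ~10⁴ ratio-test matches, with ≥ 99% of matches
within 2 px of the true correspondence and Spearman ρ ≈ 0.96 between
recovered and true depth.

## Known limitations

- Two views only; no multi-view fusion over the full 360° sweep, no
  bundle adjustment, no meshing.
- The small-angle translation model biases depth at larger steps; use
  1–2° steps (or supply externally rectified pairs).
- Coverage is a per-point fraction of the reconstructed surface, not a
  physical area: it inherits the view's foreshortening.
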