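# Methods

`organotrack` turns 4D two-channel fluorescence movies of a growing
organoid into a "digital organoid": drift-corrected crops, per-frame
segmentations of organoid / lumen / epithelium / nuclei / cells, a
lineage tree with divisions and cytokinesis-failure merges, per-entity
features in physical units, surface meshes, and a viewer data bundle.
This note records the models, the defaults that matter, and the design
choices made where the problem was genuinely open.

## Conventions

Axis order is `(z, y, x)`, boxes are 0-based and half-open, and all
physical quantities are in μm, μm³ and minutes. Voxel grids are
anisotropic; the reference grid uses a 2 μm z-step and 1 μm lateral
pixels, typical of light-sheet recordings of cysts. Lateral pixel size
is never defaulted in movie configs — calibration must be supplied.

## Synthetic organoid generator

The generator (`organotrack.synthetic`) is first-class, tested code: it
defines the study conditions under which every downstream claim is
measured. It emulates a cyst growing from one cell:

- **Geometry.** The organoid is a sphere of radius
  `R(t) = initial_radius + growth_rate·t` (defaults 6 μm + 0.5 μm/frame)
  around a concentric lumen of radius `R − shell_thickness` (shell
  9 μm). The lumen is empty while `R < 2·nucleus_radius`, mirroring the
  single-cell stage of a real cyst and exercising the NaN
  apical-distance path.
- **Cells** are angular sectors: each cell is a unit direction on the
  shell, relaxed toward an equal-spacing equilibrium by capped pairwise
  repulsion each frame. Ground-truth cell labels are the
  nearest-direction partition of the epithelium, the shell analogue of a
  geodesic nearest-nucleus partition.
- **Nuclei** are spheres (radius 3.5 μm) at mid-shell height, clipped to
  the epithelium; contested voxels go to the nearest center. Over the
  two frames before mitosis the nucleus migrates toward the apical
  (lumen) side by up to `interkinetic_amplitude` (3 μm) — interkinetic
  nuclear migration, which makes the distance-to-membrane features
  dynamic and assertable.
- **Divisions.** Each track draws a cycle length from
  N(9, 0.5²) frames (its own seeded stream, so perturbing one track
  never changes another). Mitosis happens at the apical surface: the two
  daughters appear at the parent's apical position separated along a
  random tangent, end their birth frame at about touching distance
  (two nucleus radii), and migrate back to mid-shell over two frames.
  With 40 frames at 10 min/frame the reference condition grows 1 → 16
  cells, i.e. four division rounds in ~6.5 h of simulated time per
  round.
- **Cytokinesis failure.** A merge event `(track, start_frame,
  duration)` marks the two daughters of the named division as conjoined:
  they stay distinct, normally spaced nuclei until, `duration` frames
  later, they are replaced by a single fused label of doubled nuclear
  volume (radius ×2^⅓) that later divides into two again. In the
  lineage tree this is an in-degree-2 node — the signature used to
  study binucleation in organoids.
- **Channels.** The nuclei channel renders each nucleus as a flat-top
  blob, `A·exp(−½ (d²/σ²)²)` with the half-maximum at the ground-truth
  radius — a filled chromatin body with a steep edge, not a point
  source. Contributions combine by maximum, because nuclei are mutually
  exclusive volumes: summing would create a bridge brighter than either
  nucleus between close sisters, which real images never show. The
  membrane channel lights the basal surface, the apical (lumen) surface
  and cell-cell interfaces. Amplitude 3000 counts over a background of
  100, written as 16-bit TIFF.
- **Degradation** is separate and opt-in: Gaussian blur (default σ =
  (2, 1, 1) μm, axially elongated like a detection PSF), then Poisson
  shot noise and Gaussian read noise (50 counts). The clean movie with
  exact ground truth is always available, so tests can separate
  algorithmic error from noise.

What the generator does **not** emulate: crypt budding and any
non-spherical morphogenesis, pseudostratification (one nucleus per cell
sector), photobleaching, depth-dependent scattering, cell death and
extrusion, and multi-organoid fields of view. Passing tests therefore
show that the pipeline's logic is correct under realistic geometry and
noise — not that the classical backend matches trained networks on real
light-sheet data.

## Cropping and drift correction

Per-frame minimal boxes come from Otsu thresholding of the σ=1-smoothed
frame, keeping the largest 26-connected component, padded by 5 voxels.
Drift is estimated per consecutive pair as the integer shift maximizing
FFT cross-correlation, bounded by a search radius (default 10 voxels)
and accumulated; frames that hit the bound are flagged in the crop
manifest rather than failing, and the manifest (JSON) is the manual
correction surface. Drift is integer-voxel only — no interpolation — so
label volumes cropped with the same manifest stay voxel-exact. The
global crop box is the union of drift-aligned per-frame boxes, making
cropping idempotent.

## Preprocessing

The PSF is measured from bead stacks: local maxima above a threshold,
separated by more than twice the crop half-width, background-subtracted
(median of crop faces), center-aligned and averaged to a unit-sum,
odd-extent kernel. Richardson–Lucy deconvolution is the standard
multiplicative update with reflective padding by the PSF half-width and
a flat-field renormalization (deconvolving a volume of ones) so that
total intensity is conserved at the edges; a delta kernel
short-circuits convolution, making the delta-PSF identity exact rather
than merely close. Default 30 iterations; the iteration count is not
calibrated against any external deconvolution engine. Denoising is a
pluggable interface (`none`, `median`, `gaussian`, or a registered
plugin); training a self-supervised denoiser is out of scope, and the
pipeline runs equally with preprocessing skipped.

## Segmentation

The reference backend is classical and deterministic; learned backends
can be registered and must satisfy the same bundle invariants, enforced
by a validator on every frame of every run:

lumen ⊆ organoid; epithelium = organoid ∖ lumen voxelwise; every cell
and nucleus voxel inside the epithelium; cell labels ⊇ nucleus labels;
and cell voxels + unassigned = epithelium voxels exactly.

- **Organoid**: largest bright 26-connected component of the smoothed
  frame (Otsu), holes filled per z-slice then in 3D. When a membrane
  channel exists, masks are driven by the *sum* of nuclei and membrane
  channels, so cell interiors are not mistaken for cavities.
- **Lumen**: the low-intensity component (below half the median
  intensity inside the organoid) that contains the organoid's deepest
  interior point (EDT maximum). On cysts this coincides with the
  largest dark cavity; at the single-cell stage no dark component
  contains the deepest point and the empty lumen is returned instead of
  a spurious cytoplasm pocket. An empty lumen is a valid result.
- **Nuclei**: seeded watershed of the inverted smoothed nuclei channel.
  Seeds are tracked-spot voxels labeled with their track labels (so
  segmentation labels and track labels coincide); seeds landing just
  outside the epithelium are snapped to the nearest epithelium voxel
  within twice the spot radius, farther strays are an error naming the
  spot ids. Growth is confined to above-background voxels inside the
  epithelium, where "background" is a half-maximum rule — halfway from
  the epithelium's median to its 99.5th-percentile intensity — which
  tracks the apparent nuclear boundary far more robustly than a global
  histogram split when nuclei fill a small fraction of the frame. A
  small distance-from-seed bias (3 % of the image contrast per μm) is
  added to the landscape so the flat plateau between two touching blobs
  splits at the inter-seed midplane deterministically instead of by
  flooding-order accident; wherever a real intensity valley exists the
  bias is negligible. Ties break toward the smaller label.
- **Cells**: seeded watershed constrained to the epithelium (geodesic,
  so labels cannot leak across the lumen), markers = nuclei labels,
  landscape = smoothed membrane channel when available, flat otherwise.
  Epithelium components without a nucleus stay 0 and are reported.

On the clean reference condition the median per-nucleus volume error of
this backend vs ground truth is ~12 %.

## Tracking

Nuclei on consecutive frames are linked by maximum voxel overlap, with
the implicit rules stated explicitly:

- a child links to its maximum-overlap parent if the overlap is ≥
  `f_min` (0.1) of the child's volume; smaller overlaps are
  appearances;
- parents keep at most two children (binary division), ranked by
  overlap; excess children become appearances plus over-division hints;
- a child gains a second parent — a merge — only when both parents
  overlap it by ≥ `f_merge` (0.3) of their own volumes **and** the
  child's volume is ≥ 0.7 of the parents' combined volume. The volume
  gate encodes that a genuine fusion conserves nuclear volume; without
  it, touching sisters whose watershed split wobbles between frames are
  misread as fusions.

All thresholds are configurable; ties break toward smaller labels, so
linking is deterministic and equal to an exhaustive brute-force
assignment under the same caps (property-tested on random fixtures).
Trees are the union of chosen links over all frame pairs, with node
centroids/volumes from the segmentation. Curation hints flag volume
jumps above 40 % on non-division, non-merge edges (division halving and
merge doubling are exempt), orphan appearances, merges and
over-divisions. Trees round-trip through a TrackMate/Mastodon-style
MaMuT.xml dialect with calibrated positions (1e-9 μm print precision);
the track label and nuclear volume ride along as spot attributes.

`compare_trees` matches nodes greedily per frame by nearest centroid
within a radius (default: twice the median nucleus radius implied by
the truth volumes) and reports node/edge/division/merge recall and
precision; an event node counts as recovered iff its match has the same
event. These are this package's own standard metrics.

## Features

Volumes are voxel count × voxel volume, exactly; centroids are physical.
`dist_basal` is the Euclidean distance from the nucleus centroid to the
nearest voxel outside the organoid, `dist_apical` to the nearest lumen
voxel (NaN when no lumen); distances use centroids, not surfaces, as the
single well-defined point per nucleus. On analytic shells both agree
with the closed forms R−d and d−r within one voxel diagonal — the
half-voxel centroid quantization and the half-voxel surface placement
are the irreducible discretization terms. Neighbors are cells sharing at
least 5 face-adjacent voxel pairs (suppressing single-voxel watershed
artifacts); the relation is symmetric by construction. Generation
numbering starts at 1 at the recording root and increments at each
division; through a merge the larger parent generation is inherited.
Compound per-frame features include nuclei count, nuclei density per μm³
of epithelium, mean cell and nucleus volumes and their dimensionless
ratio (invariant under uniform spacing rescales).

## Fixed-sample registration and backtracking

Fixation shrinks and tilts the sample, so fixed-space maps to live-space
through a similarity transform `p_live = s·R·p_fixed + t`. Moments give
the initial translation (foreground centroids), scale (RMS radii) and —
only when the foreground is clearly anisotropic — rotation (principal
axes, sign-disambiguated toward a proper rotation); near-spherical
foregrounds start at identity and are flagged low-confidence. A Powell
search over (rotation vector, log scale, translation) then maximizes the
NCC of the resampled pair. The contract is nucleus-level, not
voxel-level: on the reference condition a known transform (s = 0.9, 10°,
5 μm shifts) is recovered to ~0.3 % scale, ~0.1° and ~0.1 voxel, far
inside what nearest-centroid marker assignment needs. Markers are
accepted as pre-segmented label volumes; each marker centroid is mapped
to live space and assigned to the nearest last-frame nucleus centroid
(ties to the smaller label, flagged; beyond twice the median nucleus
radius, unassigned). Backtracking is the ancestral closure through the
tree, taking both parents at merges; it is idempotent and monotone.

## Meshes and the viewer bundle

Each label is meshed by marching cubes at the 0.5 isolevel of its
binary mask after padding by one background voxel (surfaces always
close, including at volume borders), vertices scaled to physical μm.
Optional Taubin smoothing is approximately volume-preserving; default
off. Mesh-enclosed volume converges to the voxel volume as labels grow
(≈3 % at radius 4 voxels, ≈0.2 % at 16). The viewer bundle is a plain
directory — `tree.json` (nodes with parent/child ids and numeric
features), one OBJ per label per frame with an index, and a color-map
manifest with per-feature min/max so nodes and meshes can be colored
independently from the same key — validated by cross-reference checks
that run in every pipeline. The web front-end itself is out of scope;
the bundle format is the contract.

## Orchestration

Stages run in dependency order (simulate? → crop → preprocess? →
segment → track → features → export). Each stage directory carries a
provenance JSON (stage config hash, content hash of inputs, output
list); a stage re-runs when any of those change or anything upstream
re-ran, so identical config + seed reproduce byte-identical
features.csv and tree.xml, and an immediate second run executes zero
stages. `--strict` turns a hash mismatch into an error.

## Problem sizes and determinism

The reference condition (40 frames of 48×72×72 voxels, 1 → 16 cells) was
chosen as the smallest simulation that exercises four division rounds,
interkinetic migration, lumen emergence and merge events; the full
pipeline runs in well under a minute on one CPU at this size, and all
randomness flows from a single integer seed through per-track seeded
streams.

## Known limitations

- The classical segmentation backend assumes one roughly convex
  organoid per frame; budded morphologies and multi-organoid fields
  need a learned backend behind the same interface.
- Overlap linking needs consecutive-frame nucleus displacements below
  about one nucleus diameter; gap closing across more than one frame is
  not implemented.
- The merge rule's volume gate assumes nuclear volume is roughly
  conserved through fusion; partial fusions would need curation via the
  emitted hints.
- Lumen detection keys on a dark cavity at the deepest interior point;
  multiple disjoint lumina are collapsed to one.
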