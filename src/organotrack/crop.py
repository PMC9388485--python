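"""Per-timepoint bounding boxes, 3D drift estimation, and fixed-size crops.

One organoid per movie is assumed. Each frame gets a minimal bounding box
around the largest above-threshold connected component; integer-voxel
drift between consecutive frames is estimated by cross-correlation and
accumulated; the union of the drift-aligned minimal boxes gives one global
box, and cropping extracts that box (shifted per frame) so all output
frames share a shape with the object held still.

Drift is integer-voxel only: no interpolation means label volumes cropped
with the same manifest stay voxel-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_otsu

from .core import BoundingBox3D, ImageVolume, LabelVolume, Movie, box_union

__all__ = [
    "CropManifest",
    "detect_object_box",
    "estimate_drift",
    "build_crop_manifest",
    "crop_movie",
    "crop_volume",
]

DEFAULT_MARGIN = 5
DEFAULT_SEARCH_RADIUS = 10


@dataclass
class CropManifest:
    """Everything needed to reproduce (or hand-edit) a crop.

    ``offsets[t]`` is the cumulative integer drift of frame ``t`` relative
    to frame 0; ``global_box`` is expressed in frame-0 coordinates and is
    shifted by ``offsets[t]`` before slicing frame ``t``. Frames whose
    estimated shift hit the search-radius bound are listed in ``flagged``
    and should be reviewed by editing the manifest.
    """

    boxes: list[BoundingBox3D]
    global_box: BoundingBox3D
    offsets: list[tuple[int, int, int]]
    margin: int = DEFAULT_MARGIN
    flagged: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "margin": self.margin,
            "boxes": [{"lo": b.lo, "hi": b.hi} for b in self.boxes],
            "global_box": {"lo": self.global_box.lo, "hi": self.global_box.hi},
            "offsets": [list(o) for o in self.offsets],
            "flagged": self.flagged,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CropManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            boxes=[BoundingBox3D(tuple(b["lo"]), tuple(b["hi"])) for b in d["boxes"]],
            global_box=BoundingBox3D(tuple(d["global_box"]["lo"]), tuple(d["global_box"]["hi"])),
            offsets=[tuple(int(v) for v in o) for o in d["offsets"]],
            margin=int(d["margin"]),
            flagged=[int(v) for v in d.get("flagged", [])],
        )


def _foreground(data: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    smooth = ndimage.gaussian_filter(data.astype(np.float64), sigma=sigma)
    if smooth.max() <= smooth.min():
        return np.zeros(data.shape, dtype=bool)
    thr = threshold_otsu(smooth)
    return smooth > thr


def detect_object_box(
    frame: ImageVolume,
    margin: int = DEFAULT_MARGIN,
    sigma: float = 1.0,
) -> BoundingBox3D:
    """Minimal box around the largest above-threshold 26-connected component.

    The frame is smoothed (Gaussian, σ in voxels), thresholded with Otsu's
    method, and the largest 26-connected component kept; the box is padded
    by ``margin`` voxels and clipped to the grid.
    """
    fg = _foreground(frame.data, sigma=sigma)
    if not fg.any():
        raise ValueError("no object found: empty foreground after thresholding")
    lab, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    sizes = np.bincount(lab.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1
    idx = np.nonzero(lab == keep)
    lo = tuple(max(0, int(i.min()) - margin) for i in idx)
    hi = tuple(min(s, int(i.max()) + 1 + margin) for i, s in zip(idx, frame.data.shape))
    return BoundingBox3D(lo, hi)


def _best_shift(a: np.ndarray, b: np.ndarray, radius: int) -> tuple[tuple[int, int, int], bool]:
    """Integer shift s (|s|<=radius per axis) maximizing correlation of
    ``b`` shifted by s against ``a``; ties broken lexicographically smallest.
    Returns (shift, hit_bound)."""
    a = a.astype(np.float64) - a.mean()
    b = b.astype(np.float64) - b.mean()
    corr = signal.fftconvolve(a, b[::-1, ::-1, ::-1], mode="same")
    center = tuple(s // 2 for s in corr.shape)
    sl = tuple(
        slice(max(0, c - radius), min(n, c + radius + 1))
        for c, n in zip(center, corr.shape)
    )
    window = corr[sl]
    # deterministic argmax: first maximum in C order => lexicographically
    # smallest shift among ties
    flat = int(np.argmax(window))
    idx = np.unravel_index(flat, window.shape)
    shift = tuple(int(i + s.start - c) for i, s, c in zip(idx, sl, center))
    hit = any(abs(v) >= radius for v in shift)
    return shift, hit  # type: ignore[return-value]


def estimate_drift(
    movie: Movie,
    channel: str | None = None,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
) -> tuple[list[tuple[int, int, int]], list[int]]:
    """Cumulative integer drift offsets per frame, offset[0] = (0,0,0).

    offset[t] - offset[t-1] is the integer shift maximizing the
    cross-correlation of frame t against frame t-1, bounded by
    ``search_radius`` per axis. Frames at the bound are flagged (not fatal):
    they need manual review via the manifest.
    """
    if movie.n_frames < 2:
        raise ValueError("drift estimation needs at least 2 frames")
    channel = channel or movie.channels[0]
    offsets = [(0, 0, 0)]
    flagged: list[int] = []
    for t in range(1, movie.n_frames):
        shift, hit = _best_shift(
            movie.frames[t][channel].data, movie.frames[t - 1][channel].data, search_radius
        )
        if hit:
            flagged.append(t)
        prev = offsets[-1]
        offsets.append(tuple(p + s for p, s in zip(prev, shift)))
    return offsets, flagged


def build_crop_manifest(
    movie: Movie,
    channel: str | None = None,
    margin: int = DEFAULT_MARGIN,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
) -> CropManifest:
    """Detect per-frame boxes and drift, and derive the global crop box.

    The global box is the union of the per-frame minimal boxes after
    removing each frame's drift, so that the cropped movie holds the object
    still while covering it at every timepoint.
    """
    channel = channel or movie.channels[0]
    if movie.n_frames >= 2:
        offsets, flagged = estimate_drift(movie, channel, search_radius)
    else:
        offsets, flagged = [(0, 0, 0)], []
    boxes = [
        detect_object_box(movie.frames[t][channel], margin=margin)
        for t in range(movie.n_frames)
    ]
    aligned = [b.shift(tuple(-o for o in off)) for b, off in zip(boxes, offsets)]
    return CropManifest(
        boxes=boxes, global_box=box_union(aligned), offsets=offsets,
        margin=margin, flagged=flagged,
    )


def crop_volume(vol: ImageVolume | LabelVolume, box: BoundingBox3D):
    """Extract ``box`` with zero fill where the box leaves the grid."""
    shape = vol.data.shape
    out = np.zeros(box.shape, dtype=vol.data.dtype)
    src = [slice(max(0, box.lo[a]), min(shape[a], box.hi[a])) for a in range(3)]
    if all(s.start < s.stop for s in src):
        dst = [slice(s.start - box.lo[a], s.stop - box.lo[a]) for a, s in enumerate(src)]
        out[tuple(dst)] = vol.data[tuple(src)]
    return vol.with_data(out)


def crop_movie(movie: Movie, manifest: CropManifest) -> Movie:
    """Crop every frame to the drift-shifted global box (zero-filled edges)."""
    if len(manifest.offsets) < movie.n_frames:
        raise ValueError("manifest does not cover all timepoints")
    frames: dict[int, dict[str, ImageVolume]] = {}
    for t in range(movie.n_frames):
        box = manifest.global_box.shift(manifest.offsets[t])
        frames[t] = {c: crop_volume(movie.frames[t][c], box) for c in movie.channels}
    return Movie(frames, dt=movie.dt)


def crop_labels(labels: list[LabelVolume], manifest: CropManifest) -> list[LabelVolume]:
    """Apply the same crop transformation to per-frame label volumes."""
    out = []
    for t, lv in enumerate(labels):
        box = manifest.global_box.shift(manifest.offsets[t])
        out.append(crop_volume(lv, box))
    return out
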