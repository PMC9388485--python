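"""Core domain types and image-stack I/O.

Conventions used throughout the package:

* axis order is ``(z, y, x)``, 0-based, with half-open bounding boxes;
* all physical quantities are in micrometres (μm, μm³) and minutes;
* intensity stacks are stored on disk as 16-bit unsigned multi-page TIFFs,
  one file per (timepoint, channel), label stacks likewise as 16-bit
  unsigned (sufficient for hundreds of instances).

Voxel grids are anisotropic: light-sheet recordings typically use a z-step
of 2 μm, several times the lateral pixel size, so every physical
measurement must go through :class:`VoxelSpacing`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile
import yaml

__all__ = [
    "VoxelSpacing",
    "ImageVolume",
    "LabelVolume",
    "BoundingBox3D",
    "Movie",
    "Spot",
    "load_movie",
    "save_movie",
    "load_stack",
    "save_stack",
    "clip_to_box",
    "box_union",
    "load_config",
    "MASK_KINDS",
    "LABEL_KINDS",
]

MASK_KINDS = frozenset({"organoid", "lumen", "epithelium"})
LABEL_KINDS = frozenset({"nuclei", "cells"}) | MASK_KINDS


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel size in μm per voxel, ``(dz, dy, dx)``."""

    dz: float
    dy: float
    dx: float

    def __post_init__(self) -> None:
        for name in ("dz", "dy", "dx"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"spacing {name}={v!r} must be finite and > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.dz, self.dy, self.dx], dtype=float)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³ (dz·dy·dx, exact)."""
        return self.dz * self.dy * self.dx


def _check_3d(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D (z,y,x) array, got ndim={data.ndim}")
    return data


@dataclass
class ImageVolume:
    """A single 3D intensity stack with physical calibration."""

    data: np.ndarray
    spacing: VoxelSpacing
    timepoint: int = 0
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = _check_3d(self.data)
        if self.timepoint < 0:
            raise ValueError("timepoint must be >= 0")
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.all(np.isfinite(self.data)):
                raise ValueError("intensities must be finite")
            if self.data.size and self.data.min() < 0:
                raise ValueError("intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def physical_extent(self) -> np.ndarray:
        """Physical size of the grid in μm per axis."""
        return np.array(self.shape) * self.spacing.as_array()

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=data)


@dataclass
class LabelVolume:
    """A 3D integer instance map; 0 is background.

    ``kind`` distinguishes instance maps (``nuclei``, ``cells``) from the
    binary tissue masks (``organoid``, ``lumen``, ``epithelium``), which may
    only contain labels {0, 1}.
    """

    data: np.ndarray
    spacing: VoxelSpacing
    timepoint: int = 0
    kind: str = "nuclei"

    def __post_init__(self) -> None:
        self.data = _check_3d(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be an integer array")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.kind not in LABEL_KINDS:
            raise ValueError(f"kind must be one of {sorted(LABEL_KINDS)}")
        if self.kind in MASK_KINDS and self.data.size and self.data.max() > 1:
            raise ValueError(f"{self.kind} mask must be binary (labels in {{0,1}})")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        out = np.unique(self.data)
        return out[out > 0]

    def with_data(self, data: np.ndarray) -> "LabelVolume":
        return replace(self, data=data)


@dataclass(frozen=True)
class BoundingBox3D:
    """Axis-aligned box, ``lo`` inclusive, ``hi`` exclusive, voxel indices."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.lo)
        hi = tuple(int(v) for v in self.hi)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if any(a >= b for a, b in zip(lo, hi)):
            raise ValueError(f"degenerate box: lo={lo} must be < hi={hi} componentwise")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]

    def shift(self, offset: Sequence[int]) -> "BoundingBox3D":
        return BoundingBox3D(
            tuple(l + int(o) for l, o in zip(self.lo, offset)),
            tuple(h + int(o) for h, o in zip(self.hi, offset)),
        )

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]


def box_union(boxes: Iterable[BoundingBox3D]) -> BoundingBox3D:
    """Smallest box containing every input box."""
    boxes = list(boxes)
    if not boxes:
        raise ValueError("box_union of an empty list")
    lo = tuple(min(b.lo[a] for b in boxes) for a in range(3))
    hi = tuple(max(b.hi[a] for b in boxes) for a in range(3))
    return BoundingBox3D(lo, hi)


def clip_to_box(vol: ImageVolume | LabelVolume, box: BoundingBox3D):
    """Crop a volume to ``box`` (clipped to the grid).

    Voxel (0,0,0) of the output corresponds to voxel ``box.lo`` of the input.
    Raises if the box does not intersect the volume extent.
    """
    shape = vol.data.shape
    lo = [max(0, box.lo[a]) for a in range(3)]
    hi = [min(shape[a], box.hi[a]) for a in range(3)]
    if any(l >= h for l, h in zip(lo, hi)):
        raise ValueError(f"box {box.lo}-{box.hi} does not intersect volume of shape {shape}")
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    return vol.with_data(vol.data[sl].copy())


@dataclass
class Movie:
    """Ordered timepoints → {channel → ImageVolume}, shared spacing."""

    frames: dict[int, dict[str, ImageVolume]]
    dt: float  # minutes between frames

    def __post_init__(self) -> None:
        ts = sorted(self.frames)
        if ts != list(range(len(ts))):
            raise ValueError(f"gap in timepoints: got {ts}, expected consecutive from 0")
        if not ts:
            raise ValueError("movie has no frames")
        chans = sorted(self.frames[0])
        for t in ts:
            if sorted(self.frames[t]) != chans:
                raise ValueError(f"timepoint {t} has channels {sorted(self.frames[t])}, expected {chans}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def channels(self) -> list[str]:
        return sorted(self.frames[0])

    @property
    def spacing(self) -> VoxelSpacing:
        return next(iter(self.frames[0].values())).spacing

    def frame(self, t: int, channel: str) -> ImageVolume:
        return self.frames[t][channel]


@dataclass(frozen=True)
class Spot:
    """A tracked nucleus marker: a sphere drawn at a tracked position.

    Positions are physical (μm), as produced by trackers working on
    calibrated images; ``track_label`` is stable along a track and doubles
    as the segmentation label id.
    """

    id: int
    timepoint: int
    position: tuple[float, float, float]  # (z, y, x) μm
    radius: float
    track_label: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("spot radius must be > 0")

    def voxel(self, spacing: VoxelSpacing, shape: Sequence[int]) -> tuple[int, int, int]:
        """Voxel index of the spot: floor(position/spacing), clamped to the grid."""
        idx = np.floor(np.asarray(self.position) / spacing.as_array()).astype(int)
        idx = np.clip(idx, 0, np.asarray(shape) - 1)
        return tuple(int(v) for v in idx)


# ---------------------------------------------------------------------------
# disk I/O


def save_stack(path: str | Path, data: np.ndarray) -> None:
    """Write a 3D stack as a multi-page uint16 TIFF (lossless for uint16)."""
    data = _check_3d(np.asarray(data))
    if np.issubdtype(data.dtype, np.floating):
        data = np.clip(np.rint(data), 0, np.iinfo(np.uint16).max)
    data = data.astype(np.uint16)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def load_stack(path: str | Path) -> np.ndarray:
    data = tifffile.imread(str(path))
    return _check_3d(data)


def _pattern_regex(path_pattern: str) -> re.Pattern:
    """Regex matching filenames produced by ``path_pattern.format(t=..., channel=...)``."""
    out = []
    for piece in re.split(r"(\{t[^}]*\}|\{channel[^}]*\})", Path(path_pattern).name):
        if piece.startswith("{t"):
            out.append(r"(?P<t>\d+)")
        elif piece.startswith("{channel"):
            out.append(r"(?P<channel>[^/]+?)")
        else:
            out.append(re.escape(piece))
    return re.compile("^" + "".join(out) + "$")


def discover_timepoints(path_pattern: str) -> tuple[list[int], list[str]]:
    """Scan the directory of ``path_pattern`` for matching (t, channel) files."""
    directory = Path(path_pattern).parent
    rx = _pattern_regex(path_pattern)
    ts: set[int] = set()
    channels: set[str] = set()
    if directory.is_dir():
        for p in directory.iterdir():
            m = rx.match(p.name)
            if m:
                ts.add(int(m.group("t")))
                channels.add(m.groupdict().get("channel") or "")
    return sorted(ts), sorted(channels)


def load_movie(
    path_pattern: str,
    spacing: VoxelSpacing,
    dt: float,
    channels: Sequence[str] | None = None,
) -> Movie:
    """Load a movie from per-(timepoint, channel) TIFFs.

    ``path_pattern`` is a templated path with ``{t}`` and ``{channel}``
    fields, e.g. ``"movie/t{t:04d}_{channel}.tif"``. Timepoints must be
    consecutive starting at 0; a missing intermediate timepoint is an error.
    """
    ts, found_channels = discover_timepoints(path_pattern)
    if channels is None:
        channels = [c for c in found_channels if c]
        if not channels:
            channels = [""]
    if not ts:
        raise FileNotFoundError(f"no files matched pattern {path_pattern!r}")
    if ts != list(range(len(ts))):
        missing = sorted(set(range(max(ts) + 1)) - set(ts))
        raise ValueError(f"gap in timepoints: missing {missing}")
    frames: dict[int, dict[str, ImageVolume]] = {}
    for t in ts:
        frames[t] = {}
        shape = None
        for c in channels:
            p = path_pattern.format(t=t, channel=c)
            if not Path(p).exists():
                raise FileNotFoundError(f"missing file for timepoint {t}, channel {c!r}: {p}")
            data = load_stack(p)
            if shape is None:
                shape = data.shape
            elif data.shape != shape:
                raise ValueError(f"shape mismatch at timepoint {t}: channel {c!r} has {data.shape}, expected {shape}")
            frames[t][c] = ImageVolume(data, spacing, timepoint=t, channel=c)
    return Movie(frames, dt=dt)


def save_movie(movie: Movie, path_pattern: str) -> list[Path]:
    """Write every (timepoint, channel) stack of a movie; returns paths written."""
    written = []
    for t in range(movie.n_frames):
        for c in movie.channels:
            p = Path(path_pattern.format(t=t, channel=c))
            save_stack(p, movie.frames[t][c].data)
            written.append(p)
    return written


def load_config(path: str | Path) -> dict:
    """Read the structured movie config (keys: dz, dy, dx, dt_min, channels).

    The lateral pixel size is deliberately never defaulted: calibration must
    always be supplied explicitly.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    missing = [k for k in ("dz", "dy", "dx", "dt_min") if k not in cfg]
    if missing:
        raise KeyError(f"movie config is missing required keys: {missing}")
    return cfg
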