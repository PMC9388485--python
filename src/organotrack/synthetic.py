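"""Ground-truthed synthetic organoid movies.

The generator emulates the phenomenology of an intestinal organoid growing
from a single cell into a cyst of a few tens of cells: a spherical
epithelial monolayer around an expanding lumen, cells modeled as angular
sectors on the shell, nuclei as spheres at mid-shell height that migrate
apically (toward the lumen) just before mitosis, binary divisions on a
per-cell cycle clock, and optional cytokinesis-failure events in which two
sister nuclei re-fuse into a single binucleated label that later divides
again into two.

Two fluorescence channels are rendered: a nuclei channel (Gaussian blobs at
nucleus centers, the histone-marker analogue) and a membrane channel
(bright basal/apical surfaces and cell-cell interfaces). Optics and noise
are applied by :func:`degrade` (blur first, then Poisson and Gaussian
noise), so a clean movie with exact ground truth is always available.

Everything is deterministic given ``SimConfig.seed``: random draws use
per-track seeded streams, so injecting an event into one track does not
perturb the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import ndimage

from .core import ImageVolume, LabelVolume, Movie, Spot, VoxelSpacing

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_movie",
    "inject_cytokinesis_failure",
    "degrade",
    "DEFAULT_NOISE",
    "DEFAULT_PSF_SIGMA",
]

#: noise level used by the "noisy" study condition: additive Gaussian read
#: noise of 50 counts plus Poisson shot noise (on a ~3000-count signal this
#: gives a realistic but clearly visible degradation).
DEFAULT_NOISE = (50.0, 1.0)  # (gaussian_sd counts, poisson_scale)

#: optical blur used by the "noisy" study condition, μm (σz, σy, σx); the
#: axial σ is twice the lateral one, as for a detection PSF elongated along z.
DEFAULT_PSF_SIGMA = (2.0, 1.0, 1.0)

_BACKGROUND = 100.0
_AMPLITUDE = 3000.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated recording.

    Defaults describe the reference condition used throughout the test
    suite: growth from one cell to ~16 cells over 40 frames at 10-minute
    intervals on a (2, 1, 1) μm anisotropic grid, clean images (noise and
    blur are opt-in via :data:`DEFAULT_NOISE` / :data:`DEFAULT_PSF_SIGMA`).
    """

    seed: int = 0
    n_frames: int = 40
    dt: float = 10.0  # minutes, as in the recordings this emulates
    spacing: VoxelSpacing = VoxelSpacing(2.0, 1.0, 1.0)
    shape: tuple[int, int, int] = (48, 72, 72)  # voxels (z, y, x)
    initial_radius: float = 6.0  # μm organoid radius at t=0 (single cell)
    organoid_growth_rate: float = 0.5  # μm per frame
    shell_thickness: float = 9.0  # μm epithelial layer thickness
    cell_cycle_mean: float = 9.0  # frames
    cell_cycle_sd: float = 0.5  # frames
    interkinetic_amplitude: float = 3.0  # μm apical migration before division
    nucleus_radius: float = 3.5  # μm
    merge_events: tuple[tuple[int, int, int], ...] = ()  # (track_label, start_frame, duration)
    noise_gaussian_sd: float = 0.0
    noise_poisson_scale: float = 0.0
    psf_sigma: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.cell_cycle_mean <= 2:
            raise ValueError("cell cycle mean must be > 2 frames")
        if self.shell_thickness < 2 * self.nucleus_radius:
            raise ValueError(
                f"shell too thin to contain nucleus_radius: thickness {self.shell_thickness} "
                f"< 2 x {self.nucleus_radius}"
            )
        for ev in self.merge_events:
            if len(ev) != 3 or ev[2] < 1:
                raise ValueError(f"merge event must be (track_label, start_frame, duration>=1), got {ev}")


@dataclass
class GroundTruth:
    """Everything the simulator knows: tree, spots, labels, masks, config."""

    tree: nx.DiGraph  # nodes (t, label); attrs centroid_um, volume_um3
    spots: list[Spot]
    nuclei_labels: list[LabelVolume]
    cell_labels: list[LabelVolume]
    masks: dict[str, list[LabelVolume]]  # organoid / lumen / epithelium
    config: SimConfig


# ---------------------------------------------------------------------------
# lineage bookkeeping


@dataclass
class _Cell:
    label: int
    u: np.ndarray  # unit direction on the shell
    birth: int
    t_div: int | None  # frame at which daughters appear; None = never in-movie
    radius_scale: float = 1.0  # 2^(1/3) for fused (binucleated) cells
    conjoined_with: int | None = None  # sibling label of a failed cytokinesis
    fuse_at: int | None = None


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _cycle_length(cfg: SimConfig, label: int) -> int:
    rng = np.random.default_rng([cfg.seed % (2**31), 1000 + label])
    L = int(round(rng.normal(cfg.cell_cycle_mean, cfg.cell_cycle_sd)))
    return max(3, L)


def _division_tangent(cfg: SimConfig, label: int, u: np.ndarray) -> np.ndarray:
    rng = np.random.default_rng([cfg.seed % (2**31), 7000 + label])
    v = rng.normal(size=3)
    t = v - np.dot(v, u) * u
    if np.linalg.norm(t) < 1e-8:  # pathological draw: pick any perpendicular
        t = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(t) < 1e-8:
            t = np.cross(u, [0.0, 1.0, 0.0])
    return _unit(t)


def _relax(
    cells: list[_Cell], pin_delta: float, iters: int = 8, k: float = 0.01, cap: float = 0.012
) -> None:
    """Repel cell directions toward an equal-spacing equilibrium on the sphere.

    Per-step displacement is capped so that freshly divided (nearly
    coincident) siblings separate gradually rather than explosively.
    """
    if len(cells) < 2:
        return
    us = np.stack([c.u for c in cells])
    for _ in range(iters):
        diff = us[:, None, :] - us[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(d, np.inf)
        f = (diff / (d**3)[..., None]).sum(axis=1)
        step = k * f
        mag = np.linalg.norm(step, axis=-1, keepdims=True)
        scale = np.minimum(1.0, cap / np.maximum(mag, 1e-12))
        us = us + step * scale
        us /= np.linalg.norm(us, axis=-1, keepdims=True)
    for c, u in zip(cells, us):
        c.u = u
    # conjoined pairs stay pinned side by side until they fuse
    done = set()
    by_label = {c.label: c for c in cells}
    for c in cells:
        if c.conjoined_with is None or c.label in done:
            continue
        sib = by_label.get(c.conjoined_with)
        if sib is None:
            continue
        m = _unit(c.u + sib.u)
        axis = c.u - sib.u
        n = np.linalg.norm(axis)
        axis = axis / n if n > 1e-9 else _division_tangent(_CFG_SENTINEL, c.label, m)
        c.u = _unit(m + pin_delta * axis)
        sib.u = _unit(m - pin_delta * axis)
        done.update({c.label, sib.label})


_CFG_SENTINEL = SimConfig()  # only used for a deterministic fallback tangent


# ---------------------------------------------------------------------------
# geometry helpers


def _radii(cfg: SimConfig, t: int) -> tuple[float, float]:
    """(organoid radius R, lumen radius r_l) at frame t; r_l = 0 means no lumen."""
    R = cfg.initial_radius + cfg.organoid_growth_rate * t
    r_l = max(0.0, R - cfg.shell_thickness)
    if R < 2 * cfg.nucleus_radius:  # single-cell stage: no cavity yet
        r_l = 0.0
    return R, r_l


def _nucleus_radial(cfg: SimConfig, t: int, cell: _Cell) -> float:
    """Radial position of a nucleus center, including interkinetic migration."""
    R, r_l = _radii(cfg, t)
    r_n = cfg.nucleus_radius * cell.radius_scale
    lo = r_l + r_n if r_l > 0 else 0.0
    hi = max(R - r_n - 0.25, 0.0)
    rm = float(np.clip(R - cfg.shell_thickness / 2.0, lo, max(lo, hi)))
    apical = max(lo, rm - cfg.interkinetic_amplitude)
    if cell.t_div is not None and cell.conjoined_with is None:
        steps_left = cell.t_div - t
        if steps_left in (1, 2):  # apical migration over the 2 pre-division frames
            progress = 1.0 if steps_left == 1 else 0.5
            return rm + progress * (apical - rm)
    age = t - cell.birth
    if cell.birth > 0 and age in (0, 1):
        # mitosis happens apically: daughters are born at the apical side
        # and migrate back to mid-shell over their first two frames
        progress = 1.0 / 3.0 if age == 0 else 2.0 / 3.0
        return apical + progress * (rm - apical)
    return rm


def _coordinate_grid(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """(absolute voxel-center coordinates in μm (3,z,y,x), grid center (3,))."""
    sp = cfg.spacing.as_array()
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(cfg.shape, sp)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"))
    center = np.array(cfg.shape) * sp / 2.0
    return grid, center


# ---------------------------------------------------------------------------
# rendering


def _render_frame(
    cfg: SimConfig,
    t: int,
    cells: list[_Cell],
    grid: np.ndarray,
    center: np.ndarray,
) -> dict:
    R, r_l = _radii(cfg, t)
    rel = grid - center[:, None, None, None]
    rho = np.sqrt((rel**2).sum(axis=0))
    organoid = rho <= R
    lumen = (rho <= r_l) & organoid if r_l > 0 else np.zeros_like(organoid)
    epi = organoid & ~lumen

    epi_idx = np.nonzero(epi)
    pts = rel[:, epi_idx[0], epi_idx[1], epi_idx[2]].T  # (N, 3)
    n_vox = pts.shape[0]

    labels = np.array([c.label for c in cells])
    us = np.stack([c.u for c in cells])

    # cells: angular nearest-direction partition of the shell
    norms = np.linalg.norm(pts, axis=1, keepdims=True)
    vhat = np.divide(pts, norms, out=np.zeros_like(pts), where=norms > 1e-9)
    dots = vhat @ us.T  # (N, n_cells)
    cell_assign = labels[np.argmax(dots, axis=1)]
    cell_vol = np.zeros(cfg.shape, dtype=np.uint16)
    cell_vol[epi_idx] = cell_assign

    # nuclei: spheres at nucleus centers, clipped to the epithelium;
    # contested voxels go to the nearest center (ties to the smaller label,
    # guaranteed by argmin returning the first minimum over sorted labels)
    order = np.argsort(labels)
    centers = np.stack([_nucleus_radial(cfg, t, c) * c.u for c in cells])[order]
    radii = np.array([cfg.nucleus_radius * c.radius_scale for c in cells])[order]
    slabels = labels[order]
    d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=-1)  # (N, n)
    inside = d <= radii[None, :]
    d_masked = np.where(inside, d, np.inf)
    best = np.argmin(d_masked, axis=1)
    has = inside.any(axis=1)
    nuc_assign = np.where(has, slabels[best], 0)
    nuc_vol = np.zeros(cfg.shape, dtype=np.uint16)
    nuc_vol[epi_idx] = nuc_assign.astype(np.uint16)

    # nuclei channel: flat-top blobs at nucleus centers — a filled chromatin
    # body with a steep edge, its half-maximum at the ground-truth radius.
    # Contributions combine by maximum, not sum: nuclei are mutually
    # exclusive volumes, so two adjacent nuclei never produce a bridge
    # brighter than either nucleus.
    blob = np.zeros(cfg.shape, dtype=np.float64)
    sp = cfg.spacing.as_array()
    for c_center, r_n in zip(centers, radii):
        sigma = r_n / (2.0 * math.log(2.0)) ** 0.25  # half-max at d = r_n
        abs_c = c_center + center
        lo = np.maximum(0, np.floor((abs_c - 2.5 * r_n) / sp - 0.5)).astype(int)
        hi = np.minimum(cfg.shape, np.ceil((abs_c + 2.5 * r_n) / sp + 0.5)).astype(int)
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        sub = grid[(slice(None),) + sl] - abs_c[:, None, None, None]
        d2 = (sub**2).sum(axis=0)
        np.maximum(blob[sl], _AMPLITUDE * np.exp(-0.5 * (d2 / sigma**2) ** 2), out=blob[sl])
    nuc_img = _BACKGROUND + blob

    # membrane channel: basal surface + apical surface + cell-cell interfaces
    boundary = organoid & ~ndimage.binary_erosion(organoid)
    if lumen.any():
        boundary |= epi & ndimage.binary_dilation(lumen)
    for ax in range(3):
        a = cell_vol
        b = np.roll(cell_vol, 1, axis=ax)
        iface = (a != b) & (a > 0) & (b > 0)
        iface[tuple(slice(0, 1) if i == ax else slice(None) for i in range(3))] = False
        boundary |= iface
        boundary |= np.roll(iface, -1, axis=ax)
    mem_img = np.full(cfg.shape, _BACKGROUND, dtype=np.float64)
    mem_img[boundary] += _AMPLITUDE
    mem_img = ndimage.gaussian_filter(mem_img, sigma=0.7)

    return {
        "organoid": organoid,
        "lumen": lumen,
        "epithelium": epi,
        "cells": cell_vol,
        "nuclei": nuc_vol,
        "nuclei_img": nuc_img,
        "membrane_img": mem_img,
        "centers_abs": {int(l): c + center for l, c in zip(slabels, centers)},
        "radii": {int(l): float(r) for l, r in zip(slabels, radii)},
    }


# ---------------------------------------------------------------------------
# main entry points


def simulate_movie(config: SimConfig) -> tuple[Movie, GroundTruth]:
    """Simulate one two-channel movie with full ground truth.

    Deterministic given ``config.seed``. Divisions place the two daughters
    at the parent's position split along a random tangent, so that each
    daughter overlaps its parent's nucleus on the next frame (the property
    overlap-based linking relies on). A merge event listed in
    ``config.merge_events`` re-fuses the two daughters of the named track's
    division at ``start_frame`` after ``duration`` frames into a single
    label of ~doubled nuclear volume, which later divides into two again.
    """
    cfg = config
    grid, center = _coordinate_grid(cfg)
    R_final, _ = _radii(cfg, cfg.n_frames - 1)
    if np.any(R_final + 1 > np.array(cfg.shape) * cfg.spacing.as_array() / 2.0):
        raise ValueError("grid too small for the final organoid radius; enlarge shape")

    merge_by_parent = {}
    for label, start, duration in cfg.merge_events:
        merge_by_parent[int(label)] = (int(start), int(duration))

    rng0 = np.random.default_rng([cfg.seed % (2**31), 999])
    root = _Cell(label=1, u=_unit(rng0.normal(size=3)), birth=0, t_div=None)
    root.t_div = _cycle_length(cfg, root.label)
    cells: list[_Cell] = [root]
    next_label = 2

    tree = nx.DiGraph()
    spots: list[Spot] = []
    nuclei_labels: list[LabelVolume] = []
    cell_labels: list[LabelVolume] = []
    masks: dict[str, list[LabelVolume]] = {"organoid": [], "lumen": [], "epithelium": []}
    frames: dict[int, dict[str, ImageVolume]] = {}
    pending_edges: list[tuple[tuple[int, int], tuple[int, int]]] = []
    spot_id = 0
    voxvol = cfg.spacing.voxel_volume

    for t in range(cfg.n_frames):
        R_t, _ = _radii(cfg, t)
        # conjoined sisters stay distinct, normally spaced nuclei (about
        # touching distance) until their envelopes fuse
        r_rad = max(R_t - cfg.shell_thickness / 2.0, 1.0)
        pin_delta = float(np.arcsin(min(1.0, cfg.nucleus_radius / r_rad)))
        _relax(cells, pin_delta)
        fr = _render_frame(cfg, t, cells, grid, center)
        for kind in ("organoid", "lumen", "epithelium"):
            masks[kind].append(
                LabelVolume(fr[kind].astype(np.uint16), cfg.spacing, timepoint=t, kind=kind)
            )
        nuclei_labels.append(LabelVolume(fr["nuclei"], cfg.spacing, timepoint=t, kind="nuclei"))
        cell_labels.append(LabelVolume(fr["cells"], cfg.spacing, timepoint=t, kind="cells"))
        frames[t] = {
            "nuclei": ImageVolume(
                np.clip(np.rint(fr["nuclei_img"]), 0, 65535).astype(np.uint16),
                cfg.spacing, timepoint=t, channel="nuclei",
            ),
            "membrane": ImageVolume(
                np.clip(np.rint(fr["membrane_img"]), 0, 65535).astype(np.uint16),
                cfg.spacing, timepoint=t, channel="membrane",
            ),
        }
        for c in cells:
            node = (t, c.label)
            count = int((fr["nuclei"] == c.label).sum())
            if count == 0:
                raise RuntimeError(f"ground-truth nucleus of track {c.label} empty at frame {t}")
            tree.add_node(
                node,
                centroid_um=tuple(float(v) for v in fr["centers_abs"][c.label]),
                volume_um3=count * voxvol,
            )
            spots.append(
                Spot(
                    id=spot_id,
                    timepoint=t,
                    position=tuple(float(v) for v in fr["centers_abs"][c.label]),
                    radius=fr["radii"][c.label],
                    track_label=c.label,
                )
            )
            spot_id += 1
            if t > 0 and (t - 1, c.label) in tree:
                tree.add_edge((t - 1, c.label), node)

        # transition to frame t+1
        if t == cfg.n_frames - 1:
            break
        new_cells: list[_Cell] = []
        by_label = {c.label: c for c in cells}
        fused_done = set()
        for c in cells:
            if c.label in fused_done:
                continue
            if c.fuse_at is not None and c.fuse_at == t + 1:
                sib = by_label[c.conjoined_with]  # type: ignore[index]
                fused = _Cell(
                    label=next_label,
                    u=_unit(c.u + sib.u),
                    birth=t + 1,
                    t_div=None,
                    radius_scale=2.0 ** (1.0 / 3.0),
                )
                fused.t_div = t + 1 + _cycle_length(cfg, fused.label)
                if fused.t_div >= cfg.n_frames:
                    fused.t_div = None
                next_label += 1
                pending_edges.append(((t, c.label), (t + 1, fused.label)))
                pending_edges.append(((t, sib.label), (t + 1, fused.label)))
                new_cells.append(fused)
                fused_done.update({c.label, sib.label})
            elif c.t_div is not None and c.t_div == t + 1 and c.conjoined_with is None:
                tangent = _division_tangent(cfg, c.label, c.u)
                R_next, _ = _radii(cfg, t + 1)
                # sisters end their birth frame at about touching distance
                # (2 nucleus radii): the repulsive relaxation adds roughly
                # one more radius of separation before the frame is rendered
                r_birth = max(
                    R_next - cfg.shell_thickness / 2.0 - 2.0 * cfg.interkinetic_amplitude / 3.0,
                    1e-3,
                )
                delta = 0.8 * cfg.nucleus_radius / r_birth
                d1 = _Cell(label=next_label, u=_unit(c.u + delta * tangent), birth=t + 1, t_div=None)
                d2 = _Cell(label=next_label + 1, u=_unit(c.u - delta * tangent), birth=t + 1, t_div=None)
                next_label += 2
                for d in (d1, d2):
                    d.t_div = d.birth + _cycle_length(cfg, d.label)
                    if d.t_div >= cfg.n_frames:
                        d.t_div = None
                if c.label in merge_by_parent and merge_by_parent[c.label][0] == t + 1:
                    duration = merge_by_parent[c.label][1]
                    d1.conjoined_with, d2.conjoined_with = d2.label, d1.label
                    d1.fuse_at = d2.fuse_at = min(t + 1 + duration, cfg.n_frames - 1)
                    d1.t_div = d2.t_div = None
                pending_edges.append(((t, c.label), (t + 1, d1.label)))
                pending_edges.append(((t, c.label), (t + 1, d2.label)))
                new_cells.extend([d1, d2])
            else:
                new_cells.append(c)
        cells = new_cells

    for a, b in pending_edges:
        if a in tree and b in tree:
            tree.add_edge(a, b)

    movie = Movie(frames, dt=cfg.dt)
    if cfg.psf_sigma is not None or cfg.noise_gaussian_sd > 0 or cfg.noise_poisson_scale > 0:
        movie = degrade(
            movie,
            noise=(cfg.noise_gaussian_sd, cfg.noise_poisson_scale),
            psf_sigma=cfg.psf_sigma,
            seed=cfg.seed,
        )
    gt = GroundTruth(
        tree=tree,
        spots=spots,
        nuclei_labels=nuclei_labels,
        cell_labels=cell_labels,
        masks=masks,
        config=cfg,
    )
    return movie, gt


def inject_cytokinesis_failure(
    gt: GroundTruth, event: tuple[int, int, int]
) -> tuple[Movie, GroundTruth]:
    """Re-simulate with a cytokinesis failure added to one division.

    ``event`` is ``(track_label, start_frame, duration)``: the named track
    must divide at ``start_frame`` (daughters appearing on that frame); its
    two daughters then re-fuse into one binucleated label ``duration``
    frames later. Per-track random streams make the rest of the simulation
    identical to the original.
    """
    label, start, duration = (int(v) for v in event)
    node = (start - 1, label)
    if node not in gt.tree or gt.tree.out_degree(node) != 2:
        raise ValueError(f"track {label} does not divide at frame {start}")
    cfg = replace(gt.config, merge_events=gt.config.merge_events + ((label, start, duration),))
    return simulate_movie(cfg)


def degrade(
    movie: Movie,
    noise: tuple[float, float] = (0.0, 0.0),
    psf_sigma: tuple[float, float, float] | None = None,
    seed: int = 0,
) -> Movie:
    """Blur (optional Gaussian PSF, μm), then add Poisson and Gaussian noise.

    Deterministic given ``seed``. Intensities are clipped to the valid
    range; integer inputs come back as the same integer dtype, float inputs
    stay float (so a noiseless, blur-free call is the identity).
    """
    gaussian_sd, poisson_scale = noise
    if gaussian_sd < 0 or poisson_scale < 0:
        raise ValueError("noise parameters must be >= 0")
    rng = np.random.default_rng([int(seed) % (2**31), 4242])
    sp = movie.spacing.as_array()
    out: dict[int, dict[str, ImageVolume]] = {}
    for t in range(movie.n_frames):
        out[t] = {}
        for c in movie.channels:
            vol = movie.frames[t][c]
            data = vol.data.astype(np.float64)
            if psf_sigma is not None:
                data = ndimage.gaussian_filter(data, sigma=np.asarray(psf_sigma) / sp)
            if poisson_scale > 0:
                data = rng.poisson(np.maximum(data, 0) / poisson_scale) * poisson_scale
            if gaussian_sd > 0:
                data = data + rng.normal(0.0, gaussian_sd, size=data.shape)
            if np.issubdtype(vol.data.dtype, np.integer):
                info = np.iinfo(vol.data.dtype)
                data = np.clip(np.rint(data), info.min, info.max).astype(vol.data.dtype)
            else:
                data = np.maximum(data, 0.0)
            out[t][c] = ImageVolume(data, vol.spacing, timepoint=t, channel=c)
    return Movie(out, dt=movie.dt)
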