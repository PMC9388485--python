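"""Registration of a post-fixation stack onto the last live frame, marker
transfer, and backtracking of marked cells through the lineage tree.

Fixation flattens and shrinks the sample, so fixed-space coordinates map
to live-space coordinates through a similarity transform
``p_live = s·R·p_fixed + t`` (rotation R, isotropic scale s, translation
t, all in physical μm). The estimate is initialized from intensity
moments (foreground centroids for translation, RMS radii for scale,
principal axes for rotation when they are well-conditioned) and refined
by a local search maximizing the normalized cross-correlation of the
resampled fixed stack against the live frame. Overlap after registration
need not be voxel-perfect: the operative contract is nucleus-level — each
marker must land on the right nucleus, which nearest-centroid assignment
then backtracks through the tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation
from skimage.filters import threshold_otsu

from .core import ImageVolume, LabelVolume
from .features import neighbor_counts, contact_areas

__all__ = [
    "SimilarityTransform",
    "estimate_similarity",
    "apply_similarity",
    "transfer_markers",
    "backtrack",
    "neighbor_history",
]


@dataclass
class SimilarityTransform:
    """p_live = scale · rotation @ p_fixed + translation, coordinates (z,y,x) μm."""

    rotation: np.ndarray  # 3x3, orthonormal, det +1
    scale: float
    translation: np.ndarray  # (z, y, x) μm
    correlation: float = np.nan  # NCC of the registered pair
    low_confidence: bool = False  # near-spherical foreground: rotation ill-posed

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation must be 3x3 orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must have det +1")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map fixed-space points (N,3) μm into live space."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * pts @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        s = 1.0 / self.scale
        return SimilarityTransform(
            rotation=Rinv, scale=s, translation=-s * Rinv @ self.translation,
            correlation=self.correlation, low_confidence=self.low_confidence,
        )


def _foreground_moments(vol: ImageVolume) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """(centroid μm, RMS radius μm, principal axes, eigenvalues) of the foreground."""
    data = vol.data.astype(np.float64)
    thr = threshold_otsu(data) if data.max() > data.min() else 0.0
    mask = data > thr
    if not mask.any():
        raise ValueError("empty foreground")
    w = data * mask
    sp = vol.spacing.as_array()
    idx = np.argwhere(mask)
    pts = (idx + 0.5) * sp
    weights = w[mask]
    centroid = np.average(pts, axis=0, weights=weights)
    rel = pts - centroid
    cov = (rel * weights[:, None]).T @ rel / weights.sum()
    evals, evecs = np.linalg.eigh(cov)
    rms = float(np.sqrt(np.trace(cov)))
    return centroid, rms, evecs, evals


def apply_similarity(vol: ImageVolume, transform: SimilarityTransform, order: int = 1) -> ImageVolume:
    """Resample a fixed-space volume into live space on the same grid.

    output(v_live) = fixed(T⁻¹(p_live)); linear interpolation by default.
    """
    sp = vol.spacing.as_array()
    inv = transform.inverse()
    # voxel index -> physical center: p = (i + 0.5) * sp
    A_phys = inv.scale * inv.rotation
    M = (A_phys * sp[None, :]) / sp[:, None]  # voxel-to-voxel linear part
    offset = (inv.translation + A_phys @ (0.5 * sp) ) / sp - 0.5
    out = ndimage.affine_transform(
        vol.data.astype(np.float64), M, offset=offset, order=order, mode="constant", cval=0.0
    )
    return vol.with_data(np.maximum(out, 0.0))


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def estimate_similarity(
    fixed: ImageVolume,
    live_last: ImageVolume,
    refine: bool = True,
    axis_ratio_tol: float = 1.15,
) -> SimilarityTransform:
    """Estimate the similarity transform mapping the fixed stack onto the live frame.

    Moments give the initial translation and scale; the principal-axes
    rotation is only used when the foreground is clearly anisotropic
    (largest/smallest RMS axis ratio above ``axis_ratio_tol``), otherwise
    the identity initializes the rotation and the result is flagged
    low-confidence. A Powell search over (rotation vector, log scale,
    translation) then maximizes the NCC of the resampled pair.
    """
    c_f, rms_f, axes_f, ev_f = _foreground_moments(fixed)
    c_l, rms_l, axes_l, ev_l = _foreground_moments(live_last)
    s0 = rms_l / rms_f
    low_confidence = False
    ratio = np.sqrt(max(ev_f.max(), 1e-12) / max(ev_f.min(), 1e-12))
    if ratio >= axis_ratio_tol:
        R0 = axes_l @ axes_f.T
        # principal axes are sign-ambiguous; take the nearest proper rotation
        if np.linalg.det(R0) < 0:
            axes_l2 = axes_l.copy()
            axes_l2[:, 0] *= -1
            R0 = axes_l2 @ axes_f.T
        rot0 = Rotation.from_matrix(R0).as_rotvec()
        # a large moments rotation on noisy axes is less trustworthy than
        # starting at identity; keep it only when modest
        if np.linalg.norm(rot0) > np.deg2rad(45):
            rot0 = np.zeros(3)
            low_confidence = True
    else:
        rot0 = np.zeros(3)
        low_confidence = True

    def build(params: np.ndarray) -> SimilarityTransform:
        rvec, logs, trans = params[:3], params[3], params[4:]
        R = Rotation.from_rotvec(rvec).as_matrix()
        s = float(np.exp(logs))
        return SimilarityTransform(rotation=R, scale=s, translation=np.asarray(trans))

    def translation_for(R: np.ndarray, s: float) -> np.ndarray:
        return c_l - s * R @ c_f

    t0 = translation_for(Rotation.from_rotvec(rot0).as_matrix(), s0)
    x0 = np.concatenate([rot0, [np.log(s0)], t0])
    live = live_last.data.astype(np.float64)

    def objective(x: np.ndarray) -> float:
        tf = build(x)
        resampled = apply_similarity(fixed, tf).data
        return -_ncc(resampled, live)

    if refine:
        res = optimize.minimize(
            objective, x0, method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-5, "maxfev": 2500},
        )
        x = res.x
    else:
        x = x0
    tf = build(x)
    tf.correlation = -objective(x)
    tf.low_confidence = low_confidence
    return tf


def transfer_markers(
    marker_mask: LabelVolume,
    transform: SimilarityTransform,
    live_nuclei: LabelVolume,
    max_assign_dist: float | None = None,
) -> pd.DataFrame:
    """Assign fixed-space marker labels to last-frame nuclei.

    Each marker centroid is mapped into live space and assigned to the
    nearest nucleus centroid; ties go to the smaller nucleus label (and
    are flagged), assignments beyond ``max_assign_dist`` (default: twice
    the median nucleus radius) come back unassigned.
    """
    from .track import node_attributes_from_labels

    markers = node_attributes_from_labels(marker_mask)
    nuclei = node_attributes_from_labels(live_nuclei)
    if not nuclei:
        raise ValueError("live nuclei volume is empty")
    nuc_labels = sorted(nuclei)
    nuc_pos = np.array([nuclei[l]["centroid_um"] for l in nuc_labels])
    if max_assign_dist is None:
        radii = [(3 * nuclei[l]["volume_um3"] / (4 * np.pi)) ** (1 / 3) for l in nuc_labels]
        max_assign_dist = 2.0 * float(np.median(radii))
    rows = []
    for mid in sorted(markers):
        p = transform.apply(np.asarray(markers[mid]["centroid_um"]))[0]
        d = np.linalg.norm(nuc_pos - p, axis=1)
        best = float(d.min())
        winners = [nuc_labels[i] for i in np.flatnonzero(np.isclose(d, best))]
        rows.append(
            {
                "marker": mid,
                "nucleus_label": min(winners) if best <= max_assign_dist else -1,
                "distance_um": best,
                "assigned": best <= max_assign_dist,
                "tie": len(winners) > 1,
            }
        )
    return pd.DataFrame(rows)


def backtrack(
    tree: nx.DiGraph,
    nodes: set[tuple[int, int]],
    feature_table: pd.DataFrame | None = None,
    feature: str = "volume_um3",
) -> tuple[set[tuple[int, int]], pd.DataFrame | None]:
    """Ancestral closure of a set of nodes, plus a per-generation comparison.

    The closure follows in-edges and passes through merge nodes along both
    parent branches. When a feature table with ``generation`` is supplied,
    the comparison table lists, per generation, the feature's mean over
    backtracked nodes and over all other nuclei.
    """
    missing = [n for n in nodes if n not in tree]
    if missing:
        raise KeyError(f"nodes not in tree: {missing}")
    closure: set[tuple[int, int]] = set()
    for n in nodes:
        closure.add(n)
        closure |= nx.ancestors(tree, n)
    if feature_table is None:
        return closure, None
    ft = feature_table[feature_table.entity == "nucleus"].copy()
    keys = set(zip(ft.timepoint.astype(int), ft.label.astype(int)))
    ft["backtracked"] = [
        (int(t), int(l)) in closure for t, l in zip(ft.timepoint, ft.label)
    ]
    if "generation" not in ft.columns:
        raise ValueError("feature table lacks a 'generation' column (run tree_features)")
    comp = (
        ft.groupby(["generation", "backtracked"])[feature]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return closure, comp


def neighbor_history(
    cells_per_frame: list[LabelVolume],
    target_track: int,
    min_contact_voxels: int = 5,
) -> tuple[dict[int, set[int]], dict[str, float]]:
    """Per-timepoint neighbor sets of one track, with an exchange summary.

    An exchange event is a label entering or leaving the neighbor set
    between consecutive frames in which the target exists. The summary
    reports the mean per-frame neighbor count, the number of distinct
    neighbors ever seen, and the exchange-event count.
    """
    sets: dict[int, set[int]] = {}
    for lv in cells_per_frame:
        if not (lv.data == target_track).any():
            continue
        contact = contact_areas(lv)
        nbrs = {
            (b if a == target_track else a)
            for (a, b), n in contact.items()
            if n >= min_contact_voxels and target_track in (a, b)
        }
        sets[lv.timepoint] = nbrs
    if not sets:
        raise ValueError(f"track {target_track} not present in any frame")
    ts = sorted(sets)
    exchanges = 0
    for prev, nxt in zip(ts, ts[1:]):
        if nxt == prev + 1:
            exchanges += len(sets[prev] ^ sets[nxt])
    summary = {
        "mean_neighbors": float(np.mean([len(sets[t]) for t in ts])),
        "distinct_neighbors": float(len(set().union(*sets.values()))),
        "exchange_events": float(exchanges),
    }
    return sets, summary
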