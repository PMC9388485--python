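"""Per-entity and compound morphometric features in a tidy table.

One row per (timepoint, label, entity); entities are nuclei, cells and
the three tissue masks. Geometric features are in physical units (μm,
μm³); the apical/basal distances are Euclidean distances from the nucleus
centroid to the lumen surface and to the outside of the organoid mask
respectively (NaN apical distance when there is no lumen yet, the
single-cell cyst stage). Per-frame compound rows aggregate counts,
densities and the cell:nucleus volume ratio, the quantity that settles to
a steady state as a cyst matures.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ImageVolume, LabelVolume, Movie
from .segment import SegmentationBundle

__all__ = [
    "region_features",
    "membrane_distances",
    "neighbor_counts",
    "tree_features",
    "compound_features",
    "extract_features",
]

MIN_CONTACT_VOXELS = 5  # suppresses single-voxel watershed contacts


def _label_rows(
    lv: LabelVolume, entity: str, images: dict[str, np.ndarray]
) -> list[dict]:
    data = lv.data
    ids = np.unique(data)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return []
    sp = lv.spacing.as_array()
    voxvol = lv.spacing.voxel_volume
    ones = np.ones_like(data, dtype=np.float64)
    counts = ndimage.sum_labels(ones, data, ids)
    centroids = ndimage.center_of_mass(ones, data, ids)
    rows = []
    for lid, n, cen in zip(ids, counts, centroids):
        row = {
            "timepoint": lv.timepoint,
            "label": int(lid),
            "entity": entity,
            "volume_um3": float(n) * voxvol,
            "centroid_z_um": float((cen[0] + 0.5) * sp[0]),
            "centroid_y_um": float((cen[1] + 0.5) * sp[1]),
            "centroid_x_um": float((cen[2] + 0.5) * sp[2]),
        }
        rows.append(row)
    for ch, img in images.items():
        sums = ndimage.sum_labels(img.astype(np.float64), data, ids)
        for row, s, n in zip(rows, sums, counts):
            row[f"total_intensity_{ch}"] = float(s)
            row[f"mean_intensity_{ch}"] = float(s) / float(n)
    return rows


def region_features(bundle: SegmentationBundle, movie: Movie | None = None) -> pd.DataFrame:
    """Volumes, physical centroids and per-channel intensities for one frame.

    Nuclei labels missing from the cells volume are still reported (their
    rows simply have no cell counterpart) with a warning.
    """
    t = bundle.timepoint
    images = (
        {c: movie.frames[t][c].data for c in movie.channels} if movie is not None else {}
    )
    rows: list[dict] = []
    rows += _label_rows(bundle.nuclei, "nucleus", images)
    rows += _label_rows(bundle.cells, "cell", images)
    for kind in ("organoid", "lumen", "epithelium"):
        rows += _label_rows(getattr(bundle, kind), kind, images)
    df = pd.DataFrame(rows)
    if not df.empty:
        nuc = set(df.loc[df.entity == "nucleus", "label"])
        cells = set(df.loc[df.entity == "cell", "label"])
        if nuc - cells:
            warnings.warn(f"nucleus labels without a cell: {sorted(nuc - cells)}", stacklevel=2)
    return df


def membrane_distances(bundle: SegmentationBundle, table: pd.DataFrame) -> pd.DataFrame:
    """Attach dist_basal / dist_apical (μm) to the nucleus rows of one frame.

    dist_basal: distance from the nucleus centroid to the nearest voxel
    outside the organoid. dist_apical: distance to the nearest lumen
    voxel; NaN when the lumen is empty. Centroids outside the organoid are
    warned about but still measured.
    """
    org = bundle.organoid.data.astype(bool)
    if not org.any():
        raise ValueError("organoid mask is empty")
    sp = bundle.spacing.as_array()
    basal_edt = ndimage.distance_transform_edt(org, sampling=sp)
    lumen = bundle.lumen.data.astype(bool)
    apical_edt = (
        ndimage.distance_transform_edt(~lumen, sampling=sp) if lumen.any() else None
    )
    table = table.copy()
    mask = (table.entity == "nucleus") & (table.timepoint == bundle.timepoint)
    basal, apical = [], []
    for _, row in table.loc[mask].iterrows():
        vox = tuple(
            int(np.clip(np.floor(row[f"centroid_{ax}_um"] / s), 0, n - 1))
            for ax, s, n in zip("zyx", sp, org.shape)
        )
        if not org[vox]:
            warnings.warn(
                f"nucleus {int(row.label)} centroid outside the organoid at t={bundle.timepoint}",
                stacklevel=2,
            )
        basal.append(float(basal_edt[vox]))
        apical.append(float(apical_edt[vox]) if apical_edt is not None else np.nan)
    table.loc[mask, "dist_basal_um"] = basal
    table.loc[mask, "dist_apical_um"] = apical
    return table


def neighbor_counts(
    cells: LabelVolume, min_contact_voxels: int = MIN_CONTACT_VOXELS
) -> dict[int, int]:
    """Number of neighbors per cell: labels sharing ≥ min_contact_voxels
    face-adjacent (6-connectivity) voxel pairs."""
    contact = contact_areas(cells)
    counts: dict[int, int] = {int(l): 0 for l in cells.labels()}
    for (a, b), n in contact.items():
        if n >= min_contact_voxels:
            counts[a] += 1
            counts[b] += 1
    return counts


def contact_areas(cells: LabelVolume) -> dict[tuple[int, int], int]:
    """Face-adjacent voxel-pair counts for every touching label pair (a<b)."""
    data = cells.data
    contact: dict[tuple[int, int], int] = {}
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        a = data[tuple(sl_a)].ravel()
        b = data[tuple(sl_b)].ravel()
        m = (a != b) & (a > 0) & (b > 0)
        if not m.any():
            continue
        pair = np.stack([np.minimum(a[m], b[m]), np.maximum(a[m], b[m])])
        uniq, cnt = np.unique(pair, axis=1, return_counts=True)
        for (x, y), n in zip(uniq.T, cnt):
            key = (int(x), int(y))
            contact[key] = contact.get(key, 0) + int(n)
    return contact


def tree_features(tree: nx.DiGraph) -> pd.DataFrame:
    """Per-node lineage features: distance to parent, generation, cycle phase.

    Generation starts at 1 at the recording root and increments after each
    division; through a merge the larger parent generation is inherited.
    ``cycle_phase_frames`` counts frames since the node's track began
    (birth at a division, a merge, or the recording start);
    ``cycle_length_frames`` is filled on completed cycles (division to
    division) with the track's total cycle length.
    """
    rows = []
    generation: dict[tuple[int, int], int] = {}
    phase: dict[tuple[int, int], int] = {}
    for node in nx.topological_sort(tree):
        preds = list(tree.predecessors(node))
        if not preds:
            generation[node] = 1
            phase[node] = 0
        else:
            gens = []
            for p in preds:
                g = generation[p]
                if tree.out_degree(p) >= 2:  # born at a division
                    g += 1
                gens.append(g)
            generation[node] = max(gens)
            born = len(preds) >= 2 or any(tree.out_degree(p) >= 2 for p in preds)
            phase[node] = 0 if born else phase[preds[0]] + 1
    for node in tree.nodes:
        preds = list(tree.predecessors(node))
        if preds:
            c = np.asarray(tree.nodes[node]["centroid_um"])
            dists = [np.linalg.norm(c - np.asarray(tree.nodes[p]["centroid_um"])) for p in preds]
            dist_to_parent = float(min(dists))
        else:
            dist_to_parent = np.nan
        divides_here = tree.out_degree(node) >= 2
        rows.append(
            {
                "timepoint": node[0],
                "label": node[1],
                "entity": "nucleus",
                "dist_to_parent_um": dist_to_parent,
                "generation": generation[node],
                "cycle_phase_frames": phase[node],
                "cycle_length_frames": phase[node] + 1 if divides_here else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compound_features(table: pd.DataFrame) -> pd.DataFrame:
    """Per-frame compound rows from the per-entity table.

    nuclei_density is nuclei per μm³ of epithelium; the cell:nucleus
    volume ratio is dimensionless and therefore invariant under a uniform
    rescaling of the voxel spacing.
    """
    rows = []
    for t, grp in table.groupby("timepoint"):
        nuc = grp[grp.entity == "nucleus"]
        cell = grp[grp.entity == "cell"]
        epi = grp[grp.entity == "epithelium"]
        if nuc.empty or cell.empty:
            raise ValueError(f"timepoint {t}: nucleus and cell rows are required")
        epi_vol = float(epi.volume_um3.sum())
        if epi_vol <= 0:
            raise ValueError(f"timepoint {t}: zero epithelium volume")
        mean_nuc = float(nuc.volume_um3.mean())
        mean_cell = float(cell.volume_um3.mean())
        rows.append(
            {
                "timepoint": t,
                "nuclei_count": int(len(nuc)),
                "nuclei_density_per_um3": len(nuc) / epi_vol,
                "mean_cell_volume_um3": mean_cell,
                "mean_nucleus_volume_um3": mean_nuc,
                "cell_nucleus_volume_ratio": mean_cell / mean_nuc,
                "epithelium_volume_um3": epi_vol,
            }
        )
    return pd.DataFrame(rows)


def extract_features(
    bundles: Sequence[SegmentationBundle],
    movie: Movie | None = None,
    tree: nx.DiGraph | None = None,
    min_contact_voxels: int = MIN_CONTACT_VOXELS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full feature table for a movie: (per-entity rows, per-frame compound rows)."""
    per_frame = []
    for bundle in bundles:
        df = region_features(bundle, movie)
        if df.empty:
            continue
        df = membrane_distances(bundle, df)
        nn = neighbor_counts(bundle.cells, min_contact_voxels)
        mask = df.entity == "cell"
        df.loc[mask, "n_neighbors"] = [nn.get(int(l), 0) for l in df.loc[mask, "label"]]
        per_frame.append(df)
    table = pd.concat(per_frame, ignore_index=True) if per_frame else pd.DataFrame()
    if tree is not None and not table.empty:
        tf = tree_features(tree)
        table = table.merge(tf, on=["timepoint", "label", "entity"], how="left")
    compound = compound_features(table) if not table.empty else pd.DataFrame()
    return table, compound
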