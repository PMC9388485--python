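"""Lineage-tree assembly by maximum-overlap linking of nuclei labels.

Nuclei labels on frame t+1 are connected to their parents on frame t by
the label with the maximum voxel overlap. Made explicit as rules:

* a child links to its maximum-overlap parent if the overlap is at least
  ``f_min`` of the child's volume (smaller overlaps are appearances);
* a parent keeps at most two children — binary division — ranked by
  overlap; excess children are cut loose as appearances and flagged as
  over-division curation hints;
* a child additionally links to its second-best parent when BOTH parents
  overlap it by at least ``f_merge`` of their own volumes AND the child's
  volume is consistent with a fusion (at least ``merge_volume_min`` of
  the two parents' combined volume) — a merge, the lineage signature of
  cytokinesis failure (two sister nuclei re-fusing into one binucleated
  label). The volume condition keeps transiently touching sisters from
  being mistaken for a fusion.

Volume jumps along non-division, non-merge edges are emitted as curation
hints: they mark positions where tracks should be merged or split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .core import LabelVolume
from .segment import SegmentationBundle

__all__ = [
    "LinkParams",
    "LinkTable",
    "CurationHint",
    "link_frames",
    "assemble_tree",
    "curation_hints",
    "compare_trees",
    "node_attributes_from_labels",
]


@dataclass(frozen=True)
class LinkParams:
    """Linking thresholds (all fractions of a volume, dimensionless)."""

    f_min: float = 0.1  # min overlap as a fraction of the child volume
    f_merge: float = 0.3  # overlap needed from BOTH parents, fraction of parent volume
    merge_volume_min: float = 0.7  # child volume vs sum of parent volumes, for merges


@dataclass
class LinkTable:
    """All candidate links between one frame pair, with the chosen subset."""

    timepoint: int  # parent frame t (children live at t+1)
    candidates: list[tuple[int, int, int]]  # (parent, child, overlap voxels)
    chosen: set[tuple[int, int]] = field(default_factory=set)
    parent_volumes: dict[int, int] = field(default_factory=dict)
    child_volumes: dict[int, int] = field(default_factory=dict)
    over_division_children: list[int] = field(default_factory=list)

    def overlap(self, parent: int, child: int) -> int:
        for p, c, o in self.candidates:
            if p == parent and c == child:
                return o
        return 0


def link_frames(
    labels_t: LabelVolume, labels_t1: LabelVolume, params: LinkParams = LinkParams()
) -> LinkTable:
    """Choose parent→child links between two consecutive nuclei label volumes."""
    a, b = labels_t.data, labels_t1.data
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    parent_volumes = {int(l): int(n) for l, n in zip(*np.unique(a[a > 0], return_counts=True))}
    child_volumes = {int(l): int(n) for l, n in zip(*np.unique(b[b > 0], return_counts=True))}
    both = (a > 0) & (b > 0)
    pairs, counts = np.unique(
        np.stack([a[both].astype(np.int64), b[both].astype(np.int64)]), axis=1, return_counts=True
    ) if both.any() else (np.zeros((2, 0), dtype=np.int64), np.zeros(0, dtype=np.int64))
    candidates = sorted(
        (int(p), int(c), int(o)) for (p, c), o in zip(pairs.T, counts)
    )
    table = LinkTable(
        timepoint=labels_t.timepoint,
        candidates=candidates,
        parent_volumes=parent_volumes,
        child_volumes=child_volumes,
    )

    by_child: dict[int, list[tuple[int, int]]] = {}
    for p, c, o in candidates:
        by_child.setdefault(c, []).append((p, o))

    chosen: set[tuple[int, int]] = set()
    for c, plist in by_child.items():
        # best parent: max overlap, ties to the smaller label id
        plist = sorted(plist, key=lambda po: (-po[1], po[0]))
        p1, o1 = plist[0]
        if o1 < params.f_min * table.child_volumes[c]:
            continue
        chosen.add((p1, c))
        if len(plist) > 1:
            p2, o2 = plist[1]
            if (
                o2 >= params.f_merge * table.parent_volumes[p2]
                and o1 >= params.f_merge * table.parent_volumes[p1]
                and table.child_volumes[c]
                >= params.merge_volume_min
                * (table.parent_volumes[p1] + table.parent_volumes[p2])
            ):
                chosen.add((p2, c))  # merge: the child keeps both parents

    # cap parents at two children, keeping the two largest overlaps
    by_parent: dict[int, list[tuple[int, int]]] = {}
    for p, c in chosen:
        by_parent.setdefault(p, []).append((c, table.overlap(p, c)))
    for p, clist in by_parent.items():
        if len(clist) <= 2:
            continue
        clist = sorted(clist, key=lambda co: (-co[1], co[0]))
        for c, _ in clist[2:]:
            chosen.discard((p, c))
            still_linked = any((q, c) in chosen for q in table.parent_volumes)
            if not still_linked:
                table.over_division_children.append(c)

    table.chosen = chosen
    return table


def node_attributes_from_labels(labels: LabelVolume) -> dict[int, dict]:
    """Per-label physical centroid (μm, grid coordinates) and volume (μm³)."""
    data = labels.data
    ids = np.unique(data)
    ids = ids[ids > 0]
    sp = labels.spacing.as_array()
    voxvol = labels.spacing.voxel_volume
    out = {}
    if len(ids):
        from scipy import ndimage

        centroids = ndimage.center_of_mass(np.ones_like(data), data, ids)
        counts = ndimage.sum_labels(np.ones_like(data), data, ids)
        for lid, cen, n in zip(ids, centroids, counts):
            out[int(lid)] = {
                "centroid_um": tuple(float((ci + 0.5) * si) for ci, si in zip(cen, sp)),
                "volume_um3": float(n) * voxvol,
            }
    return out


def assemble_tree(
    link_tables: Sequence[LinkTable],
    bundles: Sequence[SegmentationBundle] | Sequence[LabelVolume],
) -> nx.DiGraph:
    """Union of chosen links over all frame pairs, with node attributes.

    ``bundles`` supplies the per-frame nuclei label volumes (either
    SegmentationBundles or bare LabelVolumes) for centroids/volumes.
    Nodes at t>0 without a parent are flagged ``orphan``; children cut by
    the binary-division cap are recorded as over-division hints on the
    graph.
    """
    nuclei = [b.nuclei if isinstance(b, SegmentationBundle) else b for b in bundles]
    if len(link_tables) != len(nuclei) - 1:
        raise ValueError(
            f"need one link table per consecutive pair: {len(link_tables)} tables "
            f"for {len(nuclei)} frames"
        )
    tree = nx.DiGraph()
    for t, lv in enumerate(nuclei):
        attrs = node_attributes_from_labels(lv)
        for label, a in attrs.items():
            tree.add_node((t, label), **a)
    for t, table in enumerate(link_tables):
        frame_labels = set(np.unique(nuclei[t].data)) - {0}
        if set(table.parent_volumes) - frame_labels:
            raise ValueError(f"link table at t={t} references labels absent from its bundle")
        for p, c in sorted(table.chosen):
            voxvol = nuclei[t].spacing.voxel_volume
            tree.add_edge(
                (t, p), (t + 1, c),
                overlap_voxels=table.overlap(p, c),
                overlap_fraction=table.overlap(p, c) / max(table.child_volumes[c], 1),
            )
    over_division = [
        (t + 1, c) for t, table in enumerate(link_tables) for c in table.over_division_children
    ]
    for node in tree.nodes:
        t, _ = node
        tree.nodes[node]["orphan"] = t > 0 and tree.in_degree(node) == 0
    tree.graph["over_division"] = over_division
    return tree


@dataclass(frozen=True)
class CurationHint:
    """A place where a human should look at the tree."""

    node: tuple[int, int]
    kind: str  # volume_jump | over_division | orphan_appearance | merge_detected
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("hint magnitude must be >= 0")


def curation_hints(tree: nx.DiGraph, jump_fraction: float = 0.4) -> list[CurationHint]:
    """Volume-jump, orphan, merge and over-division hints for curation.

    A volume jump is flagged on an edge where the child's nuclear volume
    changes by more than ``jump_fraction`` of the parent's — except on
    division and merge edges, where volume halving/doubling is the
    expected biology.
    """
    hints: list[CurationHint] = []
    for u, v in tree.edges:
        if tree.out_degree(u) >= 2 or tree.in_degree(v) >= 2:
            continue
        vu = tree.nodes[u].get("volume_um3")
        vv = tree.nodes[v].get("volume_um3")
        if vu is None or vv is None or vu <= 0:
            continue
        ratio = abs(vv - vu) / vu
        if ratio > jump_fraction:
            hints.append(CurationHint(node=v, kind="volume_jump", magnitude=ratio))
    for node in tree.nodes:
        if tree.nodes[node].get("orphan"):
            hints.append(CurationHint(node=node, kind="orphan_appearance"))
        if tree.in_degree(node) >= 2:
            hints.append(CurationHint(node=node, kind="merge_detected"))
    for node in tree.graph.get("over_division", []):
        hints.append(CurationHint(node=node, kind="over_division"))
    return sorted(hints, key=lambda h: (h.node, h.kind))


def _match_nodes(
    predicted: nx.DiGraph, truth: nx.DiGraph, match_radius: float
) -> dict[tuple[int, int], tuple[int, int]]:
    """Greedy per-frame nearest-centroid matching within match_radius."""
    match: dict[tuple[int, int], tuple[int, int]] = {}
    frames = sorted({t for t, _ in predicted.nodes} | {t for t, _ in truth.nodes})
    for t in frames:
        pn = [n for n in predicted.nodes if n[0] == t]
        tn = [n for n in truth.nodes if n[0] == t]
        if not pn or not tn:
            continue
        pc = np.array([predicted.nodes[n]["centroid_um"] for n in pn])
        tc = np.array([truth.nodes[n]["centroid_um"] for n in tn])
        d = np.linalg.norm(pc[:, None, :] - tc[None, :, :], axis=-1)
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        used_p: set[int] = set()
        used_t: set[int] = set()
        for i, j in order:
            if d[i, j] > match_radius:
                break
            if i in used_p or j in used_t:
                continue
            match[pn[i]] = tn[j]
            used_p.add(int(i))
            used_t.add(int(j))
    return match


def compare_trees(
    predicted: nx.DiGraph, truth: nx.DiGraph, match_radius: float | None = None
) -> dict[str, float]:
    """Node/edge/division/merge recall and precision of a predicted tree.

    Nodes are matched greedily per frame by nearest centroid within
    ``match_radius`` (default: twice the median nucleus radius implied by
    the truth volumes). An edge counts as correct iff both endpoints are
    matched and the corresponding edge exists in the other tree; a
    division (out-degree ≥ 2) or merge (in-degree ≥ 2) node counts as
    recovered iff its match has the same event.
    """
    if predicted.number_of_nodes() == 0 or truth.number_of_nodes() == 0:
        raise ValueError("compare_trees needs nonempty trees")
    if match_radius is None:
        vols = [truth.nodes[n].get("volume_um3", 0.0) for n in truth.nodes]
        r = np.median([(3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0) for v in vols])
        match_radius = 2.0 * float(r)
    match = _match_nodes(predicted, truth, match_radius)
    inv = {v: k for k, v in match.items()}

    node_recall = len(match) / truth.number_of_nodes()
    node_precision = len(match) / predicted.number_of_nodes()

    def edge_ok(u, v, src, dst, m):
        return u in m and v in m and dst.has_edge(m[u], m[v])

    t_edges = truth.number_of_edges()
    p_edges = predicted.number_of_edges()
    correct_t = sum(edge_ok(u, v, truth, predicted, inv) for u, v in truth.edges)
    correct_p = sum(edge_ok(u, v, predicted, truth, match) for u, v in predicted.edges)

    def event_scores(degree_fn_t, degree_fn_p):
        t_nodes = [n for n in truth.nodes if degree_fn_t(n) >= 2]
        p_nodes = [n for n in predicted.nodes if degree_fn_p(n) >= 2]
        rec = (
            sum(1 for n in t_nodes if n in inv and degree_fn_p(inv[n]) >= 2) / len(t_nodes)
            if t_nodes else 1.0
        )
        prec = (
            sum(1 for n in p_nodes if n in match and degree_fn_t(match[n]) >= 2) / len(p_nodes)
            if p_nodes else 1.0
        )
        return rec, prec

    div_rec, div_prec = event_scores(truth.out_degree, predicted.out_degree)
    mrg_rec, mrg_prec = event_scores(truth.in_degree, predicted.in_degree)

    return {
        "node_recall": node_recall,
        "node_precision": node_precision,
        "edge_recall": correct_t / t_edges if t_edges else 1.0,
        "edge_precision": correct_p / p_edges if p_edges else 1.0,
        "division_recall": div_rec,
        "division_precision": div_prec,
        "merge_recall": mrg_rec,
        "merge_precision": mrg_prec,
    }
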