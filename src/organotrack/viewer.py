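"""Digital-organoid viewer input bundle: linked tree + meshes + features.

The bundle is a plain directory a front-end can consume:

* ``tree.json`` — one record per lineage node (id, timepoint, label,
  parent/child ids, numeric features);
* ``meshes/t{t:04d}/{kind}_{label}.obj`` — one OBJ per label per frame,
  indexed by ``meshes/index.json``;
* ``manifest.json`` — the color-map manifest: per-feature min/max so any
  numeric feature can color nodes and meshes consistently.

Every mesh's (timepoint, label) must exist in the tree; the validator
enforces the cross-references and is run by every pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import trimesh

from .meshes import LabelMesh

__all__ = ["export_viewer_bundle", "validate_viewer_bundle", "BundleValidationError"]


class BundleValidationError(ValueError):
    """The viewer bundle's cross-references are inconsistent."""


def _node_id(t: int, label: int) -> str:
    return f"t{t:04d}_l{label}"


def export_viewer_bundle(
    tree: nx.DiGraph,
    meshes_per_frame: Mapping[int, Mapping[str, Sequence[LabelMesh]]],
    features: pd.DataFrame | None,
    out_dir: str | Path,
) -> Path:
    """Write the bundle directory; returns its path after validation.

    ``meshes_per_frame`` maps timepoint → {kind → meshes}, e.g. nuclei and
    cell meshes of each frame. Numeric feature columns of the nucleus rows
    are attached to the matching tree nodes.
    """
    out = Path(out_dir)
    (out / "meshes").mkdir(parents=True, exist_ok=True)

    feat_by_node: dict[tuple[int, int], dict[str, float]] = {}
    feature_names: set[str] = set()
    if features is not None and not features.empty:
        nuc = features[features.entity == "nucleus"]
        numeric = [
            c for c in nuc.columns
            if c not in ("timepoint", "label", "entity") and pd.api.types.is_numeric_dtype(nuc[c])
        ]
        feature_names.update(numeric)
        for _, row in nuc.iterrows():
            feat_by_node[(int(row.timepoint), int(row.label))] = {
                c: (None if pd.isna(row[c]) else float(row[c])) for c in numeric
            }

    nodes = []
    for node in sorted(tree.nodes):
        t, label = node
        rec = {
            "id": _node_id(t, label),
            "timepoint": t,
            "label": label,
            "parents": [_node_id(*p) for p in sorted(tree.predecessors(node))],
            "children": [_node_id(*c) for c in sorted(tree.successors(node))],
            "features": feat_by_node.get((t, label), {}),
        }
        if "volume_um3" in tree.nodes[node]:
            rec["features"].setdefault("volume_um3", float(tree.nodes[node]["volume_um3"]))
            feature_names.add("volume_um3")
        nodes.append(rec)
    (out / "tree.json").write_text(json.dumps({"nodes": nodes}, indent=1))

    index: dict[str, dict] = {}
    for t, kinds in sorted(meshes_per_frame.items()):
        frame_dir = out / "meshes" / f"t{t:04d}"
        frame_dir.mkdir(parents=True, exist_ok=True)
        for kind, meshes in sorted(kinds.items()):
            for m in meshes:
                name = f"{kind}_{m.label}.obj"
                m.mesh.export(frame_dir / name)
                index[f"t{t:04d}/{name}"] = {"timepoint": t, "label": m.label, "kind": kind}
    (out / "meshes" / "index.json").write_text(json.dumps(index, indent=1))

    ranges: dict[str, dict[str, float]] = {}
    for name in sorted(feature_names):
        vals = [
            rec["features"][name]
            for rec in nodes
            if rec["features"].get(name) is not None
        ]
        if vals:
            ranges[name] = {"min": float(np.min(vals)), "max": float(np.max(vals))}
    (out / "manifest.json").write_text(
        json.dumps({"color_keys": ranges, "n_nodes": len(nodes)}, indent=1)
    )
    validate_viewer_bundle(out)
    return out


def validate_viewer_bundle(bundle_dir: str | Path) -> dict:
    """Cross-reference check; raises BundleValidationError naming offenders."""
    bundle = Path(bundle_dir)
    try:
        tree = json.loads((bundle / "tree.json").read_text())
        index = json.loads((bundle / "meshes" / "index.json").read_text())
        manifest = json.loads((bundle / "manifest.json").read_text())
    except FileNotFoundError as e:
        raise BundleValidationError(f"bundle incomplete: {e}") from e
    node_keys = {(rec["timepoint"], rec["label"]) for rec in tree["nodes"]}
    node_ids = {rec["id"] for rec in tree["nodes"]}
    orphans = [
        rel for rel, meta in index.items()
        if (meta["timepoint"], meta["label"]) not in node_keys
    ]
    if orphans:
        raise BundleValidationError(f"meshes with (t,label) absent from tree: {orphans}")
    missing_files = [rel for rel in index if not (bundle / "meshes" / rel).exists()]
    if missing_files:
        raise BundleValidationError(f"indexed mesh files missing on disk: {missing_files}")
    dangling = [
        rec["id"] for rec in tree["nodes"]
        if any(p not in node_ids for p in rec["parents"] + rec["children"])
    ]
    if dangling:
        raise BundleValidationError(f"tree records referencing unknown node ids: {dangling}")
    return {
        "n_nodes": len(node_keys),
        "n_meshes": len(index),
        "color_keys": sorted(manifest.get("color_keys", {})),
    }
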