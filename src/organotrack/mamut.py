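"""MaMuT.xml reader/writer (TrackMate/Mastodon-compatible dialect).

The file stores calibrated spots grouped by frame under
``Model/AllSpots/SpotsInFrame`` and directed edges grouped into tracks
under ``Model/AllTracks/Track``. Lineage-tree nodes ``(timepoint, label)``
map 1:1 onto spots; the track label and the nuclear volume ride along as
extra spot attributes (``TRACK_LABEL``, ``NUCLEUS_VOLUME``) so a
write→read round-trip reproduces the graph and all node attributes, with
positions preserved to better than 1e-6 μm. Merge nodes (in-degree 2) are
plain extra edges and survive the round-trip.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from lxml import etree

from .core import Spot

__all__ = ["write_mamut_xml", "read_mamut_xml"]

_FMT = "{:.9f}"


def write_mamut_xml(
    tree: nx.DiGraph, spots: Sequence[Spot] | None, path: str | Path
) -> None:
    """Write a lineage tree (+ optional spot radii) as MaMuT.xml.

    ``spots`` supplies per-(timepoint, track_label) radii; nodes without a
    matching spot get a radius derived from their nuclear volume.
    """
    radius_by_node: dict[tuple[int, int], float] = {}
    for s in spots or []:
        radius_by_node[(s.timepoint, s.track_label)] = s.radius

    nodes = sorted(tree.nodes)
    spot_ids = {node: i for i, node in enumerate(nodes)}

    root = etree.Element("TrackMate", version="7.10.2")
    model = etree.SubElement(root, "Model", spatialunits="um", timeunits="frame")
    allspots = etree.SubElement(model, "AllSpots", nspots=str(len(nodes)))
    frames = sorted({t for t, _ in nodes})
    for t in frames:
        sif = etree.SubElement(allspots, "SpotsInFrame", frame=str(t))
        for node in (n for n in nodes if n[0] == t):
            _, label = node
            cz, cy, cx = tree.nodes[node]["centroid_um"]
            volume = float(tree.nodes[node].get("volume_um3", 0.0))
            radius = radius_by_node.get(
                node, (3.0 * max(volume, 1e-9) / (4.0 * math.pi)) ** (1.0 / 3.0)
            )
            etree.SubElement(
                sif, "Spot",
                ID=str(spot_ids[node]),
                name=f"L{label}",
                FRAME=str(t),
                POSITION_X=_FMT.format(cx),
                POSITION_Y=_FMT.format(cy),
                POSITION_Z=_FMT.format(cz),
                RADIUS=_FMT.format(radius),
                QUALITY="1.0",
                TRACK_LABEL=str(label),
                NUCLEUS_VOLUME=_FMT.format(volume),
            )
    alltracks = etree.SubElement(model, "AllTracks")
    components = sorted(nx.weakly_connected_components(tree), key=lambda c: min(c))
    filtered = []
    for track_id, comp in enumerate(components):
        edges = [(u, v) for u, v in tree.edges if u in comp]
        if not edges:
            continue
        trk = etree.SubElement(
            alltracks, "Track", TRACK_ID=str(track_id), name=f"Track_{track_id}",
            NUMBER_SPOTS=str(len(comp)), NUMBER_EDGES=str(len(edges)),
        )
        filtered.append(track_id)
        for u, v in sorted(edges):
            etree.SubElement(
                trk, "Edge",
                SPOT_SOURCE_ID=str(spot_ids[u]),
                SPOT_TARGET_ID=str(spot_ids[v]),
            )
    ftracks = etree.SubElement(model, "FilteredTracks")
    for track_id in filtered:
        etree.SubElement(ftracks, "TrackID", TRACK_ID=str(track_id))
    etree.SubElement(root, "Settings")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def read_mamut_xml(path: str | Path) -> tuple[nx.DiGraph, list[Spot]]:
    """Read a MaMuT.xml file back into a lineage tree and spot list.

    Raises on malformed XML and on edges referencing nonexistent spot ids.
    """
    try:
        doc = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise ValueError(f"malformed MaMuT XML: {e}") from e
    model = doc.find("Model")
    if model is None:
        raise ValueError("malformed MaMuT XML: no <Model> element")
    tree = nx.DiGraph()
    spots: list[Spot] = []
    node_by_id: dict[int, tuple[int, int]] = {}
    for spot_el in model.iter("Spot"):
        sid = int(spot_el.get("ID"))
        t = int(spot_el.get("FRAME"))
        label_attr = spot_el.get("TRACK_LABEL")
        label = int(label_attr) if label_attr is not None else sid
        pos = (
            float(spot_el.get("POSITION_Z")),
            float(spot_el.get("POSITION_Y")),
            float(spot_el.get("POSITION_X")),
        )
        radius = float(spot_el.get("RADIUS"))
        node = (t, label)
        node_by_id[sid] = node
        volume = float(spot_el.get("NUCLEUS_VOLUME", "0"))
        tree.add_node(node, centroid_um=pos, volume_um3=volume)
        spots.append(Spot(id=sid, timepoint=t, position=pos, radius=radius, track_label=label))
    for edge_el in model.iter("Edge"):
        src = int(edge_el.get("SPOT_SOURCE_ID"))
        dst = int(edge_el.get("SPOT_TARGET_ID"))
        if src not in node_by_id or dst not in node_by_id:
            raise ValueError(f"edge references nonexistent spot id: {src}->{dst}")
        tree.add_edge(node_by_id[src], node_by_id[dst])
    return tree, spots
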