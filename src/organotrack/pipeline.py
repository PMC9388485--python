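"""Staleness-aware pipeline orchestrator.

Stages run in dependency order::

    simulate? -> crop -> preprocess? -> segment -> track -> features -> export

Each stage directory carries a ``provenance.json`` recording the stage
config, a content hash of its inputs, and its outputs. A stage is skipped
when its provenance matches (same config, same input hashes, outputs
present) and nothing upstream re-ran; otherwise it re-runs, and so does
everything downstream. With ``strict=True`` a hash mismatch is an error
instead of a re-run.

Identical config + seed therefore give byte-identical artifacts
(features.csv, tree.xml), and an immediate second run executes zero
stages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import crop as crop_mod
from . import features as feat_mod
from . import meshes as mesh_mod
from . import preprocess as pre_mod
from . import segment as seg_mod
from . import track as track_mod
from .core import ImageVolume, LabelVolume, Movie, Spot, VoxelSpacing, load_movie, save_stack, load_stack
from .mamut import read_mamut_xml, write_mamut_xml
from .synthetic import SimConfig, simulate_movie
from .viewer import export_viewer_bundle

__all__ = ["run_pipeline", "STAGES", "PipelineError"]

STAGES = ["simulate", "crop", "preprocess", "segment", "track", "features", "export"]


class PipelineError(RuntimeError):
    pass


def _hash_files(paths: Sequence[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _stage_dir(out_dir: Path, stage: str) -> Path:
    d = out_dir / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _artifacts(d: Path) -> list[Path]:
    return [p for p in sorted(d.rglob("*")) if p.is_file() and p.name != "provenance.json"]


def _up_to_date(d: Path, config_hash: str, input_hash: str) -> bool:
    prov = d / "provenance.json"
    if not prov.exists():
        return False
    rec = json.loads(prov.read_text())
    if rec.get("config_hash") != config_hash or rec.get("input_hash") != input_hash:
        return False
    return all((d / rel).exists() for rel in rec.get("outputs", []))


def _write_provenance(d: Path, stage: str, config_hash: str, input_hash: str) -> None:
    outputs = [str(p.relative_to(d)) for p in _artifacts(d)]
    (d / "provenance.json").write_text(
        json.dumps(
            {
                "stage": stage,
                "config_hash": config_hash,
                "input_hash": input_hash,
                "outputs": outputs,
            },
            indent=1,
        )
    )


def _spacing(cfg: dict) -> VoxelSpacing:
    return VoxelSpacing(cfg["dz"], cfg["dy"], cfg["dx"])


def _load_labels(d: Path, prefix: str, kind: str, spacing: VoxelSpacing) -> list[LabelVolume]:
    out = []
    t = 0
    while (d / f"{prefix}_t{t:04d}.tif").exists():
        out.append(
            LabelVolume(load_stack(d / f"{prefix}_t{t:04d}.tif").astype(np.uint16), spacing, t, kind=kind)
        )
        t += 1
    return out


def run_pipeline(
    config: dict,
    out_dir: str | Path,
    stages: Sequence[str] | None = None,
    strict: bool = False,
) -> list[str]:
    """Run (a subset of) the pipeline; returns the stages actually executed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    requested = list(stages) if stages is not None else [
        s for s in STAGES
        if not (s == "simulate" and "simulate" not in config)
        and not (s == "preprocess" and not config.get("preprocess", {}).get("enabled", False))
    ]
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    requested = [s for s in STAGES if s in requested]

    executed: list[str] = []
    upstream_ran = False

    def maybe_run(stage: str, inputs: list[Path], stage_cfg: dict, fn: Callable[[Path], None]) -> None:
        nonlocal upstream_ran
        d = _stage_dir(out_dir, stage)
        ch = _hash_config(stage_cfg)
        ih = _hash_files(inputs)
        fresh = _up_to_date(d, ch, ih)
        if fresh and not upstream_ran:
            return
        if strict and (d / "provenance.json").exists() and not fresh:
            raise PipelineError(f"stage {stage}: recorded hashes do not match current inputs (--strict)")
        for p in _artifacts(d):
            p.unlink()
        fn(d)
        _write_provenance(d, stage, ch, ih)
        executed.append(stage)
        upstream_ran = True

    movie_cfg = config.get("movie", {})
    dt = float(movie_cfg.get("dt_min", config.get("simulate", {}).get("dt", 10.0)))

    # ---- simulate -------------------------------------------------------
    if "simulate" in requested:
        sim_cfg = dict(config.get("simulate", {}))
        sim_cfg.setdefault("seed", config.get("seed", 0))

        def do_simulate(d: Path) -> None:
            kwargs = dict(sim_cfg)
            if "spacing" in kwargs and not isinstance(kwargs["spacing"], VoxelSpacing):
                kwargs["spacing"] = VoxelSpacing(*kwargs["spacing"])
            if "shape" in kwargs:
                kwargs["shape"] = tuple(kwargs["shape"])
            if "merge_events" in kwargs:
                kwargs["merge_events"] = tuple(tuple(e) for e in kwargs["merge_events"])
            cfg = SimConfig(**kwargs)
            movie, gt = simulate_movie(cfg)
            for t in range(movie.n_frames):
                for c in movie.channels:
                    save_stack(d / f"t{t:04d}_{c}.tif", movie.frames[t][c].data)
                save_stack(d / f"gt_nuclei_t{t:04d}.tif", gt.nuclei_labels[t].data)
                save_stack(d / f"gt_cells_t{t:04d}.tif", gt.cell_labels[t].data)
            write_mamut_xml(gt.tree, gt.spots, d / "spots.xml")
            sp = cfg.spacing
            (d / "manifest.json").write_text(
                json.dumps(
                    {"seed": cfg.seed, "config": {**sim_cfg, "spacing": [sp.dz, sp.dy, sp.dx]}},
                    indent=1, default=str,
                )
            )

        maybe_run("simulate", [], sim_cfg, do_simulate)

    # where the raw movie comes from (resolved lazily so that a subset run
    # like `track` alone fails on its own missing upstream, not on this)
    raw_pattern: str | None = None
    spacing: VoxelSpacing | None = None
    spots_path: Path | None = None
    if (out_dir / "simulate" / "manifest.json").exists() or "simulate" in requested:
        raw_dir = out_dir / "simulate"
        raw_pattern = str(raw_dir / "t{t:04d}_{channel}.tif")
        manifest = json.loads((raw_dir / "manifest.json").read_text())
        spacing = VoxelSpacing(*manifest["config"]["spacing"])
        spots_path = raw_dir / "spots.xml"
    elif movie_cfg:
        raw_pattern = movie_cfg["pattern"]
        spacing = _spacing(movie_cfg)
        spots_path = Path(movie_cfg["spots"]) if "spots" in movie_cfg else None

    def raw_inputs() -> list[Path]:
        if raw_pattern is None:
            raise PipelineError("config must name an input movie or include a simulate stage")
        d = Path(raw_pattern).parent
        if not d.exists():
            raise PipelineError("missing upstream artifact: no raw movie (run simulate or point to one)")
        files = [p for p in sorted(d.iterdir()) if p.suffix in (".tif", ".xml")]
        return files

    # ---- crop -----------------------------------------------------------
    if "crop" in requested:
        crop_cfg = dict(config.get("crop", {}))

        def do_crop(d: Path) -> None:
            movie = load_movie(raw_pattern, spacing, dt)
            manifest = crop_mod.build_crop_manifest(
                movie,
                channel=crop_cfg.get("channel"),
                margin=int(crop_cfg.get("margin", crop_mod.DEFAULT_MARGIN)),
                search_radius=int(crop_cfg.get("search_radius", crop_mod.DEFAULT_SEARCH_RADIUS)),
            )
            cropped = crop_mod.crop_movie(movie, manifest)
            for t in range(cropped.n_frames):
                for c in cropped.channels:
                    save_stack(d / f"t{t:04d}_{c}.tif", cropped.frames[t][c].data)
            manifest.to_json(d / "crop_manifest.json")
            if spots_path is not None and spots_path.exists():
                tree, spots = read_mamut_xml(spots_path)
                sp = spacing.as_array()
                shifted_spots = []
                remap = {}
                for s in spots:
                    box = manifest.global_box.shift(manifest.offsets[s.timepoint])
                    newpos = tuple(float(p - l * si) for p, l, si in zip(s.position, box.lo, sp))
                    shifted_spots.append(
                        Spot(s.id, s.timepoint, newpos, s.radius, s.track_label)
                    )
                    remap[(s.timepoint, s.track_label)] = newpos
                for node in tree.nodes:
                    if node in remap:
                        tree.nodes[node]["centroid_um"] = remap[node]
                write_mamut_xml(tree, shifted_spots, d / "spots.xml")

        maybe_run("crop", raw_inputs(), crop_cfg, do_crop)

    crop_dir = out_dir / "crop"

    def cropped_inputs() -> list[Path]:
        if not (crop_dir / "provenance.json").exists():
            raise PipelineError("missing upstream artifact: crop has not run")
        return _artifacts(crop_dir)

    # ---- preprocess (optional) -----------------------------------------
    pre_enabled = config.get("preprocess", {}).get("enabled", False) or "preprocess" in requested
    segment_src = crop_dir
    if "preprocess" in requested:
        pre_cfg = dict(config.get("preprocess", {}))

        def do_pre(d: Path) -> None:
            movie = load_movie(str(crop_dir / "t{t:04d}_{channel}.tif"), spacing, dt)
            psf = None
            if pre_cfg.get("psf_sigma"):
                psf = pre_mod.gaussian_psf(tuple(pre_cfg["psf_sigma"]), spacing)
            backend = pre_cfg.get("denoise", "none")
            iters = int(pre_cfg.get("iterations", 30))
            for t in range(movie.n_frames):
                for c in movie.channels:
                    vol = movie.frames[t][c]
                    vol = pre_mod.denoise(vol, backend=backend)
                    if psf is not None:
                        vol = pre_mod.richardson_lucy(vol, psf, iterations=iters)
                    save_stack(d / f"t{t:04d}_{c}.tif", vol.data)
            (d / "preprocess.json").write_text(json.dumps(pre_cfg, indent=1, default=str))

        maybe_run("preprocess", cropped_inputs(), pre_cfg, do_pre)
        segment_src = out_dir / "preprocess"

    # ---- segment --------------------------------------------------------
    if "segment" in requested:
        seg_cfg = dict(config.get("segment", {}))

        def seg_inputs() -> list[Path]:
            if not (segment_src / "provenance.json").exists():
                raise PipelineError(
                    f"missing upstream artifact: stage '{segment_src.name}' has not run"
                )
            files = _artifacts(segment_src)
            if segment_src != crop_dir and (crop_dir / "spots.xml").exists():
                files = files + [crop_dir / "spots.xml"]
            return files

        def do_segment(d: Path) -> None:
            movie = load_movie(str(segment_src / "t{t:04d}_{channel}.tif"), spacing, dt)
            _, spots = read_mamut_xml(crop_dir / "spots.xml")
            backend = seg_cfg.get("backend", "classical")
            report = {}
            for t in range(movie.n_frames):
                frame = movie.frames[t].get("nuclei", movie.frames[t][movie.channels[0]])
                membrane = movie.frames[t].get("membrane")
                bundle = seg_mod.segment_frame(
                    frame, [s for s in spots if s.timepoint == t],
                    membrane_channel=membrane, backend=backend,
                )
                for kind in ("organoid", "lumen", "epithelium", "nuclei", "cells"):
                    save_stack(d / f"{kind}_t{t:04d}.tif", getattr(bundle, kind).data)
                report[str(t)] = {
                    "n_nuclei": int(len(bundle.nuclei.labels())),
                    "unassigned_voxels": bundle.unassigned_voxels,
                    "invariants_ok": True,
                }
            (d / "bundle_report.json").write_text(json.dumps(report, indent=1))

        maybe_run("segment", seg_inputs(), seg_cfg, do_segment)

    seg_dir = out_dir / "segment"

    def seg_outputs() -> list[Path]:
        if not (seg_dir / "provenance.json").exists():
            raise PipelineError("missing upstream artifact: segment has not run")
        return _artifacts(seg_dir)

    def load_bundles() -> list[seg_mod.SegmentationBundle]:
        report = json.loads((seg_dir / "bundle_report.json").read_text())
        nuclei = _load_labels(seg_dir, "nuclei", "nuclei", spacing)
        cells = _load_labels(seg_dir, "cells", "cells", spacing)
        bundles = []
        for t in range(len(nuclei)):
            bundles.append(
                seg_mod.SegmentationBundle(
                    organoid=LabelVolume(load_stack(seg_dir / f"organoid_t{t:04d}.tif").astype(np.uint16), spacing, t, "organoid"),
                    lumen=LabelVolume(load_stack(seg_dir / f"lumen_t{t:04d}.tif").astype(np.uint16), spacing, t, "lumen"),
                    epithelium=LabelVolume(load_stack(seg_dir / f"epithelium_t{t:04d}.tif").astype(np.uint16), spacing, t, "epithelium"),
                    nuclei=nuclei[t],
                    cells=cells[t],
                    unassigned_voxels=int(report[str(t)]["unassigned_voxels"]),
                    timepoint=t,
                )
            )
        return bundles

    # ---- track ----------------------------------------------------------
    if "track" in requested:
        trk_cfg = dict(config.get("track", {}))

        def do_track(d: Path) -> None:
            nuclei = _load_labels(seg_dir, "nuclei", "nuclei", spacing)
            params = track_mod.LinkParams(
                f_min=float(trk_cfg.get("f_min", 0.1)),
                f_merge=float(trk_cfg.get("f_merge", 0.3)),
            )
            tables = [
                track_mod.link_frames(nuclei[t], nuclei[t + 1], params)
                for t in range(len(nuclei) - 1)
            ]
            tree = track_mod.assemble_tree(tables, nuclei)
            write_mamut_xml(tree, None, d / "tree.xml")
            hints = track_mod.curation_hints(tree, float(trk_cfg.get("jump_fraction", 0.4)))
            pd.DataFrame(
                [{"timepoint": h.node[0], "label": h.node[1], "kind": h.kind, "magnitude": h.magnitude} for h in hints]
            ).to_csv(d / "hints.csv", index=False)

        maybe_run("track", seg_outputs(), trk_cfg, do_track)

    track_dir = out_dir / "track"

    # ---- features -------------------------------------------------------
    if "features" in requested:
        ft_cfg = dict(config.get("features", {}))

        def ft_inputs() -> list[Path]:
            if not (track_dir / "provenance.json").exists():
                raise PipelineError("missing upstream artifact: track has not run")
            return seg_outputs() + _artifacts(track_dir)

        def do_features(d: Path) -> None:
            bundles = load_bundles()
            movie = load_movie(str(segment_src / "t{t:04d}_{channel}.tif"), spacing, dt)
            tree, _ = read_mamut_xml(track_dir / "tree.xml")
            table, compound = feat_mod.extract_features(
                bundles, movie, tree,
                min_contact_voxels=int(ft_cfg.get("min_contact_voxels", feat_mod.MIN_CONTACT_VOXELS)),
            )
            table.to_csv(d / "features.csv", index=False)
            compound.to_csv(d / "compound.csv", index=False)
            (d / "units.json").write_text(
                json.dumps(
                    {
                        "volume_um3": "cubic micrometre",
                        "centroid_*_um": "micrometre, (z,y,x) grid coordinates",
                        "dist_apical_um": "micrometre; NaN when no lumen",
                        "dist_basal_um": "micrometre",
                        "dist_to_parent_um": "micrometre",
                        "cycle_phase_frames": f"frames of {dt} min",
                    },
                    indent=1,
                )
            )

        maybe_run("features", ft_inputs(), ft_cfg, do_features)

    # ---- export ---------------------------------------------------------
    if "export" in requested:
        ex_cfg = dict(config.get("export", {}))

        def ex_inputs() -> list[Path]:
            feat_dir = out_dir / "features"
            for dep in (track_dir, feat_dir):
                if not (dep / "provenance.json").exists():
                    raise PipelineError(f"missing upstream artifact: {dep.name} has not run")
            return seg_outputs() + _artifacts(track_dir) + _artifacts(feat_dir)

        def do_export(d: Path) -> None:
            tree, _ = read_mamut_xml(track_dir / "tree.xml")
            table = pd.read_csv(out_dir / "features" / "features.csv")
            nuclei = _load_labels(seg_dir, "nuclei", "nuclei", spacing)
            cells = _load_labels(seg_dir, "cells", "cells", spacing)
            iters = int(ex_cfg.get("smoothing_iters", 0))
            meshes = {
                t: {
                    "nuclei": mesh_mod.extract_meshes(nuclei[t], iters),
                    "cells": mesh_mod.extract_meshes(cells[t], iters),
                }
                for t in range(len(nuclei))
            }
            export_viewer_bundle(tree, meshes, table, d / "viewer")

        maybe_run("export", ex_inputs(), ex_cfg, do_export)

    return executed

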