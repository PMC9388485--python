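"""Shared fixtures: synthetic movies and pipeline runs reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from organotrack.core import ImageVolume, LabelVolume, VoxelSpacing
from organotrack.segment import segment_frame
from organotrack.synthetic import SimConfig, simulate_movie
from organotrack.track import assemble_tree, link_frames


@pytest.fixture(scope="session")
def iso_spacing() -> VoxelSpacing:
    return VoxelSpacing(1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def aniso_spacing() -> VoxelSpacing:
    return VoxelSpacing(2.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def small_sim():
    """A short clean recording: one division, 10 frames."""
    cfg = SimConfig(seed=1, n_frames=10)
    movie, gt = simulate_movie(cfg)
    return cfg, movie, gt


@pytest.fixture(scope="session")
def default_sim():
    """The reference study condition: 1 -> 16 cells over 40 clean frames."""
    cfg = SimConfig(seed=1)
    movie, gt = simulate_movie(cfg)
    return cfg, movie, gt


def segment_movie(cfg, movie, gt):
    return [
        segment_frame(
            movie.frames[t]["nuclei"],
            [s for s in gt.spots if s.timepoint == t],
            membrane_channel=movie.frames[t]["membrane"],
        )
        for t in range(cfg.n_frames)
    ]


@pytest.fixture(scope="session")
def default_segmentation(default_sim):
    cfg, movie, gt = default_sim
    return segment_movie(cfg, movie, gt)


@pytest.fixture(scope="session")
def default_tree(default_segmentation):
    nuclei = [b.nuclei for b in default_segmentation]
    tables = [link_frames(nuclei[t], nuclei[t + 1]) for t in range(len(nuclei) - 1)]
    return assemble_tree(tables, nuclei)


def make_ball(shape, center, radius, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Boolean ball on a voxel-center grid in physical coordinates."""
    sp = np.asarray(spacing, dtype=float)
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, sp)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    c = np.asarray(center, dtype=float)
    return (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= radius**2


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at the reference study condition, with timing."""
    import time

    from organotrack.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("default_run")
    t0 = time.perf_counter()
    run_pipeline({"seed": 1, "simulate": {}}, out)
    elapsed = time.perf_counter() - t0
    return out, elapsed
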