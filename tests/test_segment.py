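"""Multiscale segmentation: masks, seeded nuclei, cell partition, invariants."""

import numpy as np
import pytest

from organotrack.core import ImageVolume, LabelVolume, Spot, VoxelSpacing
from organotrack.segment import (
    BundleInvariantError,
    SegmentationBundle,
    register_backend,
    segment_cells,
    segment_frame,
    segment_lumen,
    segment_nuclei,
    segment_organoid,
    validate_bundle,
)
from tests.conftest import make_ball


SP = VoxelSpacing(1.0, 1.0, 1.0)
CENTER = (24.0, 24.0, 24.0)
SHAPE = (48, 48, 48)


def _shell_frame(outer=16.0, inner=8.0, amp=1000.0, bg=50.0):
    """Bright spherical shell with a dark cavity (cyst cross-section)."""
    outer_mask = make_ball(SHAPE, CENTER, outer)
    inner_mask = make_ball(SHAPE, CENTER, inner) if inner > 0 else np.zeros(SHAPE, bool)
    data = np.full(SHAPE, bg)
    data[outer_mask & ~inner_mask] = amp
    return ImageVolume(data, SP), outer_mask, inner_mask


class TestSegmentOrganoid:
    def test_solid_ball_recovered(self):
        frame, outer, _ = _shell_frame(inner=0.0)
        mask = segment_organoid(frame).data.astype(bool)
        overlap = (mask & outer).sum() / max(1, (mask | outer).sum())
        assert overlap >= 0.95

    def test_hollow_shell_cavity_is_filled(self):
        frame, outer, inner = _shell_frame()
        mask = segment_organoid(frame).data.astype(bool)
        assert (mask & inner).sum() / inner.sum() >= 0.95

    def test_larger_of_two_organoids_wins(self):
        data = np.full(SHAPE, 50.0)
        big = make_ball(SHAPE, (16, 16, 16), 10.0)
        small = make_ball(SHAPE, (38, 38, 38), 4.0)
        data[big] = 1000.0
        data[small] = 1000.0
        mask = segment_organoid(ImageVolume(data, SP)).data.astype(bool)
        assert (mask & big).sum() / big.sum() >= 0.9
        assert (mask & small).sum() == 0

    def test_flat_frame_is_error(self):
        with pytest.raises(ValueError, match="empty foreground"):
            segment_organoid(ImageVolume(np.zeros(SHAPE), SP))


class TestSegmentLumen:
    def test_dark_cavity_recovered(self):
        frame, outer, inner = _shell_frame()
        org = segment_organoid(frame)
        lumen = segment_lumen(frame, org).data.astype(bool)
        assert (lumen & inner).sum() / inner.sum() >= 0.90
        assert not (lumen & ~org.data.astype(bool)).any()

    def test_solid_ball_has_empty_lumen(self):
        frame, _, _ = _shell_frame(inner=0.0)
        org = segment_organoid(frame)
        assert segment_lumen(frame, org).data.sum() == 0

    def test_empty_organoid_mask_is_error(self):
        frame, _, _ = _shell_frame()
        empty = LabelVolume(np.zeros(SHAPE, dtype=np.uint16), SP, kind="organoid")
        with pytest.raises(ValueError, match="empty"):
            segment_lumen(frame, empty)


def _blob_frame(centers, radius=4.0, amp=1000.0, bg=50.0):
    data = np.full(SHAPE, bg)
    for c in centers:
        d2 = sum(
            ((np.arange(n) + 0.5).reshape([-1 if i == j else 1 for j in range(3)]) - c[i]) ** 2
            for i, n in enumerate(SHAPE)
        )
        sigma = radius / (2 * np.log(2)) ** 0.25
        data = np.maximum(data, bg + amp * np.exp(-0.5 * (d2 / sigma**2) ** 2))
    return ImageVolume(data, SP)


def _spots(centers, radius=4.0, t=0):
    return [
        Spot(id=i, timepoint=t, position=tuple(c), radius=radius, track_label=i + 1)
        for i, c in enumerate(centers)
    ]


class TestSegmentNuclei:
    def test_single_blob_recovers_ninety_percent(self):
        frame = _blob_frame([CENTER])
        epi = LabelVolume(np.ones(SHAPE, dtype=np.uint16), SP, kind="epithelium")
        labels = segment_nuclei(frame, _spots([CENTER]), epi)
        truth = make_ball(SHAPE, CENTER, 4.0)
        got = labels.data == 1
        assert (got & truth).sum() / truth.sum() >= 0.90

    def test_two_touching_blobs_partition_their_union(self):
        c1, c2 = (24.0, 24.0, 20.0), (24.0, 24.0, 28.0)
        frame = _blob_frame([c1, c2])
        epi = LabelVolume(np.ones(SHAPE, dtype=np.uint16), SP, kind="epithelium")
        labels = segment_nuclei(frame, _spots([c1, c2]), epi)
        assert set(labels.labels()) == {1, 2}
        s1 = Spot(0, 0, c1, 4.0, 1)
        s2 = Spot(1, 0, c2, 4.0, 2)
        assert labels.data[s1.voxel(SP, SHAPE)] == 1
        assert labels.data[s2.voxel(SP, SHAPE)] == 2
        # the two regions partition the above-background union: no third label,
        # and both cover a similar share of it
        v1, v2 = (labels.data == 1).sum(), (labels.data == 2).sum()
        assert abs(v1 - v2) / max(v1, v2) < 0.2

    def test_zero_spots_gives_empty_labels(self):
        frame = _blob_frame([CENTER])
        epi = LabelVolume(np.ones(SHAPE, dtype=np.uint16), SP, kind="epithelium")
        labels = segment_nuclei(frame, [], epi)
        assert labels.data.sum() == 0

    def test_two_spots_in_one_voxel_is_error(self):
        frame = _blob_frame([CENTER])
        epi = LabelVolume(np.ones(SHAPE, dtype=np.uint16), SP, kind="epithelium")
        spots = [Spot(0, 0, CENTER, 4.0, 1), Spot(1, 0, CENTER, 4.0, 2)]
        with pytest.raises(ValueError, match="same voxel"):
            segment_nuclei(frame, spots, epi)

    def test_spot_far_outside_epithelium_is_error_listing_ids(self):
        frame = _blob_frame([CENTER])
        epi_mask = make_ball(SHAPE, CENTER, 10.0)
        epi = LabelVolume(epi_mask.astype(np.uint16), SP, kind="epithelium")
        stray = [Spot(id=77, timepoint=0, position=(44.0, 44.0, 44.0), radius=2.0, track_label=1)]
        with pytest.raises(ValueError, match="77"):
            segment_nuclei(frame, stray, epi)

    def test_spot_slightly_outside_is_snapped_inside(self):
        frame = _blob_frame([CENTER])
        epi_mask = make_ball(SHAPE, CENTER, 10.0)
        epi = LabelVolume(epi_mask.astype(np.uint16), SP, kind="epithelium")
        near = [Spot(id=0, timepoint=0, position=(24.0, 24.0, 36.0), radius=4.0, track_label=5)]
        labels = segment_nuclei(frame, near, epi)
        assert 5 in labels.labels()


class TestSegmentCells:
    @staticmethod
    def _shell_with_nuclei(n):
        outer = make_ball(SHAPE, CENTER, 16.0)
        inner = make_ball(SHAPE, CENTER, 8.0)
        epi = LabelVolume((outer & ~inner).astype(np.uint16), SP, kind="epithelium")
        if n == 4:  # tetrahedral directions: equally spaced on the sphere
            dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
        elif n == 1:
            dirs = np.array([[0.0, 0.0, 1.0]])
        nuc = np.zeros(SHAPE, dtype=np.uint16)
        for i, d in enumerate(dirs):
            c = np.asarray(CENTER) + 12.0 * d
            ball = make_ball(SHAPE, c, 3.0) & epi.data.astype(bool) & (nuc == 0)
            nuc[ball] = i + 1
        return epi, LabelVolume(nuc, SP, kind="nuclei")

    def test_four_symmetric_nuclei_give_equal_cells(self):
        epi, nuc = self._shell_with_nuclei(4)
        cells, unassigned = segment_cells(epi, nuc)
        vols = [(cells.data == l).sum() for l in (1, 2, 3, 4)]
        assert unassigned == 0
        assert (max(vols) - min(vols)) / max(vols) <= 0.10

    def test_exact_voxel_conservation(self):
        epi, nuc = self._shell_with_nuclei(4)
        cells, unassigned = segment_cells(epi, nuc)
        assert int((cells.data > 0).sum()) + unassigned == int(epi.data.sum())

    def test_single_nucleus_claims_entire_epithelium(self):
        epi, nuc = self._shell_with_nuclei(1)
        cells, unassigned = segment_cells(epi, nuc)
        assert unassigned == 0
        assert int((cells.data == 1).sum()) == int(epi.data.sum())

    def test_component_without_nucleus_reported_unassigned(self):
        epi_mask = make_ball(SHAPE, (12, 12, 12), 6.0) | make_ball(SHAPE, (36, 36, 36), 6.0)
        epi = LabelVolume(epi_mask.astype(np.uint16), SP, kind="epithelium")
        nuc = np.zeros(SHAPE, dtype=np.uint16)
        nuc[make_ball(SHAPE, (12, 12, 12), 2.5)] = 1
        cells, unassigned = segment_cells(epi, LabelVolume(nuc, SP, kind="nuclei"))
        assert unassigned == int(make_ball(SHAPE, (36, 36, 36), 6.0).sum())


class TestSegmentFrame:
    def test_nuclei_count_matches_ground_truth(self, small_sim):
        cfg, movie, gt = small_sim
        t = cfg.n_frames - 1
        bundle = segment_frame(
            movie.frames[t]["nuclei"],
            [s for s in gt.spots if s.timepoint == t],
            membrane_channel=movie.frames[t]["membrane"],
        )
        assert len(bundle.nuclei.labels()) == len(gt.nuclei_labels[t].labels())

    def test_determinism_identical_label_volumes(self, small_sim):
        cfg, movie, gt = small_sim
        t = cfg.n_frames - 1
        args = (
            movie.frames[t]["nuclei"],
            [s for s in gt.spots if s.timepoint == t],
        )
        b1 = segment_frame(*args, membrane_channel=movie.frames[t]["membrane"])
        b2 = segment_frame(*args, membrane_channel=movie.frames[t]["membrane"])
        for kind in ("organoid", "lumen", "epithelium", "nuclei", "cells"):
            np.testing.assert_array_equal(getattr(b1, kind).data, getattr(b2, kind).data)

    def test_early_empty_lumen_frame_passes_invariants(self, small_sim):
        cfg, movie, gt = small_sim
        bundle = segment_frame(
            movie.frames[0]["nuclei"],
            [s for s in gt.spots if s.timepoint == 0],
            membrane_channel=movie.frames[0]["membrane"],
        )
        validate_bundle(bundle)  # must not raise
        assert bundle.lumen.data.sum() == 0

    def test_validator_rejects_cell_outside_epithelium(self, small_sim):
        cfg, movie, gt = small_sim
        t = cfg.n_frames - 1
        bundle = segment_frame(
            movie.frames[t]["nuclei"],
            [s for s in gt.spots if s.timepoint == t],
            membrane_channel=movie.frames[t]["membrane"],
        )
        bad_cells = bundle.cells.data.copy()
        outside = np.argwhere(~bundle.epithelium.data.astype(bool))[0]
        bad_cells[tuple(outside)] = 1
        bad = SegmentationBundle(
            organoid=bundle.organoid, lumen=bundle.lumen, epithelium=bundle.epithelium,
            nuclei=bundle.nuclei,
            cells=LabelVolume(bad_cells, bundle.spacing, t, "cells"),
            unassigned_voxels=bundle.unassigned_voxels, timepoint=t,
        )
        with pytest.raises(BundleInvariantError, match="outside the epithelium"):
            validate_bundle(bad)

    def test_plugin_backend_violating_invariants_is_hard_error(self, small_sim):
        cfg, movie, gt = small_sim

        def bad_backend(frame, spots, membrane_channel=None, intensity_for_masks=None):
            shape = frame.data.shape
            ones = np.ones(shape, dtype=np.uint16)
            zeros = np.zeros(shape, dtype=np.uint16)
            return SegmentationBundle(
                organoid=LabelVolume(ones, frame.spacing, frame.timepoint, "organoid"),
                lumen=LabelVolume(ones.copy(), frame.spacing, frame.timepoint, "lumen"),
                epithelium=LabelVolume(ones.copy(), frame.spacing, frame.timepoint, "epithelium"),
                nuclei=LabelVolume(zeros, frame.spacing, frame.timepoint, "nuclei"),
                cells=LabelVolume(zeros.copy(), frame.spacing, frame.timepoint, "cells"),
                timepoint=frame.timepoint,
            )

        register_backend("bad-test-backend", bad_backend)
        with pytest.raises(BundleInvariantError):
            segment_frame(movie.frames[0]["nuclei"], [], backend="bad-test-backend")

    def test_unknown_backend_is_error(self, small_sim):
        _, movie, _ = small_sim
        with pytest.raises(ValueError, match="classical"):
            segment_frame(movie.frames[0]["nuclei"], [], backend="rdcnet")


class TestVolumeAccuracy:
    def test_median_per_nucleus_volume_error_within_15_percent(self, default_sim, default_segmentation):
        cfg, movie, gt = default_sim
        errs = []
        for t in range(cfg.n_frames):
            pred = default_segmentation[t].nuclei.data
            truth = gt.nuclei_labels[t].data
            for l in gt.nuclei_labels[t].labels():
                tv = (truth == l).sum()
                errs.append(abs(int((pred == l).sum()) - int(tv)) / int(tv))
        assert float(np.median(errs)) <= 0.15
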