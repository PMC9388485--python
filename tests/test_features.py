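"""Morphometric features: volumes, distances, neighbors, lineage, compounds."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from organotrack.core import ImageVolume, LabelVolume, Movie, VoxelSpacing
from organotrack.features import (
    compound_features,
    extract_features,
    membrane_distances,
    neighbor_counts,
    region_features,
    tree_features,
)
from organotrack.segment import SegmentationBundle
from tests.conftest import make_ball

SHAPE = (48, 48, 48)
CENTER = (24.0, 24.0, 24.0)


def _bundle_from_masks(organoid, lumen, nuclei, cells, spacing, t=0):
    epi = organoid & ~lumen
    mk = lambda d, kind: LabelVolume(d.astype(np.uint16), spacing, t, kind)
    return SegmentationBundle(
        organoid=mk(organoid, "organoid"), lumen=mk(lumen, "lumen"),
        epithelium=mk(epi, "epithelium"), nuclei=mk(nuclei, "nuclei"),
        cells=mk(cells, "cells"), timepoint=t,
    )


def _shell_bundle(spacing=VoxelSpacing(1, 1, 1), nucleus_at=14.0, outer=20.0, inner=10.0,
                  shape=(48, 48, 48)):
    """Analytic spherical shell with one nucleus at a given centroid radius."""
    center = tuple(s * n / 2.0 for s, n in zip(spacing.as_array(), shape))
    organoid = make_ball(shape, center, outer, spacing.as_array())
    lumen = make_ball(shape, center, inner, spacing.as_array())
    nuc_center = np.asarray(center) + np.array([0.0, 0.0, nucleus_at])
    nuclei = make_ball(shape, nuc_center, 3.0, spacing.as_array()) & organoid & ~lumen
    cells = (organoid & ~lumen).astype(np.uint16)
    return _bundle_from_masks(organoid, lumen, nuclei.astype(np.uint16), cells, spacing)


class TestRegionFeatures:
    def test_volume_is_count_times_voxel_volume(self, aniso_spacing):
        ball = make_ball((24, 24, 24), (12, 12, 12), 5.0).astype(np.uint16)
        count = int(ball.sum())
        bundle = _bundle_from_masks(
            np.ones((24, 24, 24), bool), np.zeros((24, 24, 24), bool), ball, ball, aniso_spacing
        )
        df = region_features(bundle)
        vol = df.loc[df.entity == "nucleus", "volume_um3"].iloc[0]
        assert vol == count * 2.0  # dz*dy*dx = 2 μm³, exact arithmetic

    def test_uniform_intensity_means_and_totals(self, iso_spacing):
        ball = make_ball(SHAPE, CENTER, 5.0).astype(np.uint16)
        img = ImageVolume(np.where(ball, 7.0, 0.0), iso_spacing, 0, "a")
        movie = Movie({0: {"a": img}}, dt=1.0)
        bundle = _bundle_from_masks(
            np.ones(SHAPE, bool), np.zeros(SHAPE, bool), ball, ball, iso_spacing
        )
        df = region_features(bundle, movie)
        row = df[df.entity == "nucleus"].iloc[0]
        assert row["mean_intensity_a"] == pytest.approx(7.0)
        assert row["total_intensity_a"] == pytest.approx(7.0 * ball.sum())

    def test_centroid_of_symmetric_ball_within_half_voxel(self, iso_spacing):
        ball = make_ball(SHAPE, CENTER, 6.0).astype(np.uint16)
        bundle = _bundle_from_masks(
            np.ones(SHAPE, bool), np.zeros(SHAPE, bool), ball, ball, iso_spacing
        )
        df = region_features(bundle)
        row = df[df.entity == "nucleus"].iloc[0]
        got = np.array([row.centroid_z_um, row.centroid_y_um, row.centroid_x_um])
        assert np.abs(got - np.asarray(CENTER)).max() <= 0.5

    def test_nucleus_without_cell_warns_but_reports(self, iso_spacing):
        ball = make_ball(SHAPE, CENTER, 5.0).astype(np.uint16)
        bundle = _bundle_from_masks(
            np.ones(SHAPE, bool), np.zeros(SHAPE, bool), ball, np.zeros(SHAPE, np.uint16),
            iso_spacing,
        )
        bundle.unassigned_voxels = int(np.ones(SHAPE).sum())
        with pytest.warns(UserWarning, match="without a cell"):
            df = region_features(bundle)
        assert (df.entity == "nucleus").any()


class TestMembraneDistances:
    def test_analytic_shell_distances(self, aniso_spacing):
        # outer R=20 μm, lumen r=10 μm, nucleus centroid at radius 14 μm:
        # basal ~ 20-14 = 6 μm, apical ~ 14-10 = 4 μm, within a voxel diagonal
        bundle = _shell_bundle(aniso_spacing, shape=(24, 48, 48))
        df = membrane_distances(bundle, region_features(bundle))
        row = df[df.entity == "nucleus"].iloc[0]
        diag = float(np.linalg.norm(aniso_spacing.as_array()))
        assert abs(row.dist_basal_um - 6.0) <= diag
        assert abs(row.dist_apical_um - 4.0) <= diag

    def test_no_lumen_gives_nan_apical_finite_basal(self, iso_spacing):
        ball = make_ball(SHAPE, CENTER, 4.0).astype(np.uint16)
        organoid = make_ball(SHAPE, CENTER, 15.0)
        bundle = _bundle_from_masks(organoid, np.zeros(SHAPE, bool), ball, ball, iso_spacing)
        df = membrane_distances(bundle, region_features(bundle))
        row = df[df.entity == "nucleus"].iloc[0]
        assert np.isnan(row.dist_apical_um)
        assert np.isfinite(row.dist_basal_um) and row.dist_basal_um > 0

    def test_centroid_on_outer_surface_has_small_basal_distance(self, iso_spacing):
        organoid = make_ball(SHAPE, CENTER, 12.0)
        nuc = np.zeros(SHAPE, dtype=np.uint16)
        nuc[24, 24, 35] = 1  # on the surface
        bundle = _bundle_from_masks(organoid, np.zeros(SHAPE, bool), nuc, nuc, iso_spacing)
        df = membrane_distances(bundle, region_features(bundle))
        assert df[df.entity == "nucleus"].iloc[0].dist_basal_um <= 2.0


class TestNeighborCounts:
    @staticmethod
    def _two_half_shells(spacing=VoxelSpacing(1, 1, 1)):
        outer = make_ball(SHAPE, CENTER, 14.0)
        inner = make_ball(SHAPE, CENTER, 8.0)
        shell = outer & ~inner
        cells = np.zeros(SHAPE, dtype=np.uint16)
        cells[shell] = 1
        cells[shell & (np.arange(SHAPE[2])[None, None, :] >= 24)] = 2
        return LabelVolume(cells, spacing, kind="cells")

    def test_two_half_shells_have_one_neighbor_each(self):
        counts = neighbor_counts(self._two_half_shells())
        assert counts == {1: 1, 2: 1}

    def test_matches_exhaustive_voxel_pair_scan(self, rng):
        data = rng.integers(0, 5, size=(6, 10, 10)).astype(np.uint16)
        cells = LabelVolume(data, VoxelSpacing(1, 1, 1), kind="cells")
        # oracle: count face-adjacent pairs by explicit shifting per axis
        pair_counts = {}
        for ax in range(3):
            for idx in np.ndindex(*data.shape):
                jdx = list(idx)
                jdx[ax] += 1
                if jdx[ax] >= data.shape[ax]:
                    continue
                a, b = int(data[idx]), int(data[tuple(jdx)])
                if a > 0 and b > 0 and a != b:
                    key = (min(a, b), max(a, b))
                    pair_counts[key] = pair_counts.get(key, 0) + 1
        for threshold in (1, 5, 20):
            expected = {int(l): 0 for l in np.unique(data) if l > 0}
            for (a, b), n in pair_counts.items():
                if n >= threshold:
                    expected[a] += 1
                    expected[b] += 1
            assert neighbor_counts(cells, threshold) == expected

    def test_threshold_above_largest_interface_zeroes_all(self):
        counts = neighbor_counts(self._two_half_shells(), min_contact_voxels=10**6)
        assert set(counts.values()) == {0}

    def test_neighbor_relation_is_symmetric(self, small_sim):
        cfg, _, gt = small_sim
        from organotrack.features import contact_areas

        contact = contact_areas(gt.cell_labels[cfg.n_frames - 1])
        for (a, b) in contact:
            assert a < b  # stored once per unordered pair by construction


class TestTreeFeatures:
    def test_static_cell_has_zero_parent_distance(self):
        g = nx.DiGraph()
        for t in range(4):
            g.add_node((t, 1), centroid_um=(5.0, 5.0, 5.0), volume_um3=10.0)
            if t:
                g.add_edge((t - 1, 1), (t, 1))
        df = tree_features(g)
        moved = df[df.timepoint > 0]
        assert (moved.dist_to_parent_um == 0.0).all()

    def test_generation_starts_at_one_and_increments_at_divisions(self, small_sim):
        _, _, gt = small_sim
        df = tree_features(gt.tree).set_index(["timepoint", "label"])
        root = min(gt.tree.nodes)
        assert df.loc[root].generation == 1
        for n in gt.tree.nodes:
            if gt.tree.out_degree(n) >= 2:
                for child in gt.tree.successors(n):
                    assert df.loc[child].generation == df.loc[n].generation + 1

    def test_cycle_length_matches_simulator_schedule(self):
        from organotrack.synthetic import SimConfig, simulate_movie

        cfg = SimConfig(seed=3, n_frames=18, cell_cycle_mean=8, cell_cycle_sd=0)
        _, gt = simulate_movie(cfg)
        df = tree_features(gt.tree)
        lengths = df.cycle_length_frames.dropna().unique()
        assert list(lengths) == [8.0]


class TestCompoundFeatures:
    @staticmethod
    def _table(nuc_vols, cell_vols, epi_vol, t=0):
        rows = []
        for i, v in enumerate(nuc_vols):
            rows.append({"timepoint": t, "label": i + 1, "entity": "nucleus", "volume_um3": v})
        for i, v in enumerate(cell_vols):
            rows.append({"timepoint": t, "label": i + 1, "entity": "cell", "volume_um3": v})
        rows.append({"timepoint": t, "label": 1, "entity": "epithelium", "volume_um3": epi_vol})
        return pd.DataFrame(rows)

    def test_density_arithmetic(self):
        df = compound_features(self._table([100.0] * 8, [600.0] * 8, 4000.0))
        assert df.iloc[0].nuclei_density_per_um3 == pytest.approx(8 / 4000.0)

    def test_volume_ratio(self):
        df = compound_features(self._table([150.0] * 4, [600.0] * 4, 4000.0))
        assert df.iloc[0].cell_nucleus_volume_ratio == pytest.approx(4.0)

    def test_ratio_invariant_under_spacing_rescale(self, small_sim):
        cfg, movie, gt = small_sim
        t = cfg.n_frames - 1
        bundle1 = _bundle_from_masks(
            gt.masks["organoid"][t].data.astype(bool),
            gt.masks["lumen"][t].data.astype(bool),
            gt.nuclei_labels[t].data, gt.cell_labels[t].data, cfg.spacing, t,
        )
        doubled = VoxelSpacing(cfg.spacing.dz * 2, cfg.spacing.dy * 2, cfg.spacing.dx * 2)
        bundle2 = _bundle_from_masks(
            gt.masks["organoid"][t].data.astype(bool),
            gt.masks["lumen"][t].data.astype(bool),
            gt.nuclei_labels[t].data, gt.cell_labels[t].data, doubled, t,
        )
        r1 = compound_features(region_features(bundle1)).iloc[0].cell_nucleus_volume_ratio
        r2 = compound_features(region_features(bundle2)).iloc[0].cell_nucleus_volume_ratio
        assert r1 == pytest.approx(r2)

    def test_zero_epithelium_volume_is_error(self):
        with pytest.raises(ValueError, match="epithelium"):
            compound_features(self._table([1.0], [1.0], 0.0))


class TestExtractFeatures:
    def test_cell_volume_conservation_against_epithelium(self, small_sim):
        cfg, movie, gt = small_sim
        t = cfg.n_frames - 1
        bundle = _bundle_from_masks(
            gt.masks["organoid"][t].data.astype(bool),
            gt.masks["lumen"][t].data.astype(bool),
            gt.nuclei_labels[t].data, gt.cell_labels[t].data, cfg.spacing, t,
        )
        table, compound = extract_features([bundle], movie)
        cells = table[table.entity == "cell"].volume_um3.sum()
        epi = table[table.entity == "epithelium"].volume_um3.sum()
        assert cells == pytest.approx(epi)  # exact voxel arithmetic
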