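"""Buffer grids, patch labeling, and closed-form landscape metrics."""

import numpy as np
import pytest

from lcfusion.landmetrics import (
    buffer_metrics,
    circular_mask,
    class_metrics,
    label_patches,
    make_grid,
)

from conftest import make_map


def flood_fill_count(binary, connectivity=8):
    """Independent BFS patch counter."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    for i in range(binary.shape[0]):
        for j in range(binary.shape[1]):
            if binary[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < binary.shape[0] and 0 <= cc < binary.shape[1]
                                and binary[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count


class TestMakeGrid:
    def test_20km_extent_retains_16_tangent_buffers(self):
        grid = make_grid((0, 0, 20000, 20000), spacing=5000, radius=2500)
        assert grid.n == 16
        xs = sorted({c[0] for c in grid.centers})
        assert xs == [2500.0, 7500.0, 12500.0, 17500.0]

    def test_buffers_extending_beyond_extent_dropped(self):
        # 22 km extent: centers at 2.5..17.5 km fit; a 21-km-axis center does not exist,
        # but radius 4 km drops the 2.5 km rows/cols
        grid = make_grid((0, 0, 22000, 22000), spacing=5000, radius=4000)
        for x, y in grid.centers:
            assert x - 4000 >= 0 and x + 4000 <= 22000
            assert y - 4000 >= 0 and y + 4000 <= 22000

    def test_extent_smaller_than_buffer_errors(self):
        with pytest.raises(ValueError):
            make_grid((0, 0, 4000, 4000), spacing=5000, radius=2500)

    def test_doubling_spacing_roughly_quarters_centers(self):
        a = make_grid((0, 0, 40000, 40000), spacing=5000, radius=2500).n
        b = make_grid((0, 0, 40000, 40000), spacing=10000, radius=2500).n
        assert a == pytest.approx(4 * b, rel=0.5)


class TestLabelPatches:
    def test_square_patch_area_and_perimeter(self):
        values = np.ones((30, 30), dtype=np.int32)
        values[10:20, 10:20] = 5  # 10x10 cells of 10 m = 1 ha
        r = make_map(values, domain=frozenset({1, 5}))
        window = np.ones_like(values, dtype=bool)
        patches = label_patches(r, 5, window)
        assert patches.n_patches == 1
        assert patches.areas_m2[0] == pytest.approx(10_000.0)
        assert patches.perimeters_m[0] == pytest.approx(400.0)

    def test_diagonal_cells_8_vs_4_connectivity(self):
        values = np.ones((5, 5), dtype=np.int32)
        values[1, 1] = values[2, 2] = 5
        r = make_map(values, domain=frozenset({1, 5}))
        window = np.ones_like(values, dtype=bool)
        assert label_patches(r, 5, window, connectivity=8).n_patches == 1
        assert label_patches(r, 5, window, connectivity=4).n_patches == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_random_noise_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(5):
            values = rng.choice([1, 5], size=(40, 40), p=[0.6, 0.4]).astype(np.int32)
            r = make_map(values, domain=frozenset({1, 5}))
            window = np.ones_like(values, dtype=bool)
            got = label_patches(r, 5, window, connectivity=connectivity).n_patches
            assert got == flood_fill_count(values == 5, connectivity=connectivity)

    def test_mask_clips_patches(self):
        values = np.full((20, 20), 5, dtype=np.int32)
        r = make_map(values, domain=frozenset({5}))
        window = circular_mask(r, (100.0, 100.0), 50.0)
        patches = label_patches(r, 5, window)
        assert patches.areas_m2.sum() == pytest.approx(window.sum() * 100.0)


class TestClassMetrics:
    def _window_fixture(self, values):
        r = make_map(values, domain=frozenset({1, 2, 5}))
        center = (r.grid.ncols * 10 / 2, r.grid.nrows * 10 / 2)
        window = circular_mask(r, center, 250.0)
        return r, window, center

    def test_single_square_closed_form(self):
        # 1-ha square inside an r=250 m circular window
        values = np.ones((60, 60), dtype=np.int32)
        values[25:35, 25:35] = 5
        r, window, center = self._window_fixture(values)
        patches = label_patches(r, 5, window)
        rec = class_metrics(patches, window, r, 5, center=center)
        assert rec.mean_patch_area_ha == pytest.approx(1.0)
        assert rec.total_class_area_ha == pytest.approx(1.0)
        # ED = 400 m of edge over the discretized window area
        assert rec.edge_density_m_per_ha == pytest.approx(400.0 / rec.window_area_ha)
        # pixelated circle area close to pi r^2 = 19.63 ha
        assert rec.window_area_ha == pytest.approx(19.63, abs=0.4)
        assert rec.edge_density_m_per_ha == pytest.approx(20.37, abs=1.0)

    def test_pafrac_one_for_square_families(self):
        values = np.ones((80, 80), dtype=np.int32)
        for side, (r0, c0) in zip((3, 5, 9, 17), ((2, 2), (10, 10), (22, 22), (40, 40))):
            values[r0:r0 + side, c0:c0 + side] = 5
        r = make_map(values, domain=frozenset({1, 5}))
        window = np.ones_like(values, dtype=bool)
        patches = label_patches(r, 5, window)
        assert patches.n_patches == 4
        rec = class_metrics(patches, window, r, 5)
        assert rec.pafrac == pytest.approx(1.0, abs=0.02)

    def test_pafrac_in_unit_interval_for_random_patches(self, rng):
        values = rng.choice([1, 5], size=(60, 60), p=[0.7, 0.3]).astype(np.int32)
        r = make_map(values, domain=frozenset({1, 5}))
        window = np.ones_like(values, dtype=bool)
        patches = label_patches(r, 5, window)
        rec = class_metrics(patches, window, r, 5)
        if np.isfinite(rec.pafrac):
            assert 1.0 - 0.1 <= rec.pafrac <= 2.0 + 0.1

    def test_zero_class_cells(self):
        values = np.ones((30, 30), dtype=np.int32)
        r, window, center = self._window_fixture(values)
        patches = label_patches(r, 5, window)
        rec = class_metrics(patches, window, r, 5, center=center)
        assert rec.total_class_area_ha == 0.0
        assert np.isnan(rec.mean_patch_area_ha)
        assert np.isnan(rec.pafrac)

    def test_ed_invariant_to_nonclass_relabeling(self, rng):
        values = rng.choice([1, 2, 5], size=(40, 40)).astype(np.int32)
        r = make_map(values, domain=frozenset({1, 2, 5}))
        window = np.ones_like(values, dtype=bool)
        rec1 = class_metrics(label_patches(r, 5, window), window, r, 5)
        swapped = values.copy()
        swapped[values == 1] = 2
        swapped[values == 2] = 1
        r2 = make_map(swapped, domain=frozenset({1, 2, 5}))
        rec2 = class_metrics(label_patches(r2, 5, window), window, r2, 5)
        assert rec1.edge_density_m_per_ha == rec2.edge_density_m_per_ha

    def test_window_boundary_edges_excluded_by_default(self):
        # patch sliced through by the window: clipped boundary adds no edge
        values = np.full((40, 40), 5, dtype=np.int32)
        r = make_map(values, domain=frozenset({5}))
        window = circular_mask(r, (200.0, 200.0), 100.0)
        patches = label_patches(r, 5, window)
        rec = class_metrics(patches, window, r, 5)
        assert rec.edge_density_m_per_ha == 0.0
        rec_incl = class_metrics(patches, window, r, 5, include_window_boundary_edges=True)
        assert rec_incl.edge_density_m_per_ha > 0


class TestBufferMetrics:
    def test_total_area_conserved_across_tangent_buffers(self, rng):
        # CA over the full mosaic == sum over tangent buffers on the covered part
        values = rng.choice([1, 5], size=(100, 100), p=[0.5, 0.5]).astype(np.int32)
        r = make_map(values, cell=100.0, domain=frozenset({1, 5}))  # 10 km extent
        df = buffer_metrics(r, 5, spacing=5000.0, radius=2500.0)
        assert len(df) == 4
        covered = np.zeros_like(values, dtype=bool)
        for _, row in df.iterrows():
            covered |= circular_mask(r, (row.x, row.y), 2500.0)
        expected_ha = (values == 5)[covered].sum() * 100.0 * 100.0 / 1e4
        assert df.total_class_area_ha.sum() == pytest.approx(expected_ha)

    def test_one_row_per_buffer_with_missing_as_nan(self):
        values = np.ones((100, 100), dtype=np.int32)
        r = make_map(values, cell=100.0, domain=frozenset({1, 5}))
        df = buffer_metrics(r, 5, spacing=5000.0, radius=2500.0)
        assert len(df) == 4
        assert (df.total_class_area_ha == 0).all()
        assert df.pafrac.isna().all()
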