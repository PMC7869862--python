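import numpy as np
import pandas as pd
import pytest

from voxcyto.io_formats import LabelMap
from voxcyto.distances import (
    classify_population,
    classify_populations,
    shortest_distance,
    signed_distance_map,
    within_fraction,
)


def brute_force_signed_distance(mask: np.ndarray, voxel: tuple) -> np.ndarray:
    """Independent oracle: per voxel, min anisotropic Euclidean distance to
    the nearest opposite-phase voxel centre; negative inside the mask."""
    coords = np.indices(mask.shape).reshape(3, -1).T * np.array(voxel)
    fg = coords[mask.ravel()]
    bg = coords[~mask.ravel()]
    out = np.empty(mask.size)
    for i, (p, inside) in enumerate(zip(coords, mask.ravel())):
        other = bg if inside else fg
        d = np.sqrt(((other - p) ** 2).sum(axis=1)).min() if len(other) else np.inf
        out[i] = -d if inside else d
    return out.reshape(mask.shape)


def sphere_mask(shape, voxel, center_xyz, r):
    z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (
        ((z + 0.5) * voxel[0] - center_xyz[2]) ** 2
        + ((y + 0.5) * voxel[1] - center_xyz[1]) ** 2
        + ((x + 0.5) * voxel[2] - center_xyz[0]) ** 2
    )
    return d2 <= r * r


class TestSignedDistanceMap:
    def test_radial_geometry(self):
        voxel = (1.0, 1.0, 1.0)
        shape = (40, 40, 40)
        lm = LabelMap(sphere_mask(shape, voxel, (20, 20, 20), 10.0).astype(np.int32),
                      voxel, "glomeruli")
        dmap = signed_distance_map(lm)
        half_diag = np.linalg.norm(voxel) / 2
        probe_out = dmap[20, 20, 35]  # centre at 15 µm from sphere centre -> ~ +5
        assert probe_out == pytest.approx(5.0, abs=2 * half_diag)
        probe_in = dmap[20, 20, 24]  # centre at x=24.5, 4 µm from centre
        assert probe_in == pytest.approx(-6.0, abs=2 * half_diag)

    def test_empty_target_all_inf(self):
        lm = LabelMap(np.zeros((4, 4, 4), np.int32), (1, 1, 1), "glomeruli")
        with pytest.warns(UserWarning, match="empty target"):
            dmap = signed_distance_map(lm)
        assert np.all(np.isinf(dmap))

    @pytest.mark.parametrize("seed", range(8))
    def test_brute_force_oracle_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(6, 16, size=3))
        voxel = tuple(rng.choice([0.3, 0.5, 1.0, 2.0], size=3))
        mask = rng.random(shape) < 0.2
        if not mask.any():
            mask[tuple(s // 2 for s in shape)] = True
        lm = LabelMap(mask.astype(np.int32), voxel, "t")
        # slice-wise filling is part of the map contract; apply to oracle too
        from voxcyto.segmentation import fill_holes_by_slice

        filled = fill_holes_by_slice(mask)
        expected = brute_force_signed_distance(filled, voxel)
        got = signed_distance_map(lm)
        half_diag = np.linalg.norm(voxel) / 2
        assert np.max(np.abs(got - expected)) <= half_diag + 1e-9

    def test_translation_symmetry(self):
        voxel = (1.0, 0.5, 0.5)
        base = np.zeros((16, 24, 24), bool)
        base[4:8, 6:12, 6:12] = True
        shifted = np.roll(base, (3, 4, 5), axis=(0, 1, 2))  # pure translate, no wrap
        d0 = signed_distance_map(LabelMap(base.astype(np.int32), voxel, "t"))
        d1 = signed_distance_map(LabelMap(shifted.astype(np.int32), voxel, "t"))
        assert np.allclose(d1[3:, 4:, 5:], d0[:-3, :-4, :-5])

    def test_dilation_monotonicity(self):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(5)
        mask = rng.random((10, 14, 14)) < 0.1
        mask[5, 7, 7] = True
        voxel = (1.0, 0.5, 0.5)
        d0 = signed_distance_map(LabelMap(mask.astype(np.int32), voxel, "t"))
        dilated = ndi.binary_dilation(mask)
        d1 = signed_distance_map(LabelMap(dilated.astype(np.int32), voxel, "t"))
        assert np.all(d1 <= d0 + 1e-9)


class TestShortestDistance:
    def _setup(self, gap_um=15.0):
        voxel = (1.0, 0.5, 0.5)
        shape = (40, 120, 120)
        glom = sphere_mask(shape, voxel, (15, 30, 20), 10.0)
        cell_center = (15 + 10 + gap_um + 5.0, 30, 20)  # x offset by gap
        cell = sphere_mask(shape, voxel, cell_center, 5.0)
        targets = LabelMap(glom.astype(np.int32), voxel, "glomeruli")
        objects = LabelMap(cell.astype(np.int32), voxel, "cells")
        return objects, targets, voxel

    def test_analytic_sphere_gap(self):
        objects, targets, voxel = self._setup(gap_um=15.0)
        dmap = signed_distance_map(targets)
        res = shortest_distance(objects, dmap, targets)
        assert len(res) == 1
        assert res.iloc[0]["shortest_distance_um"] == pytest.approx(
            15.0, abs=np.linalg.norm(voxel)
        )
        assert res.iloc[0]["nearest_target_id"] == 1

    def test_contained_cell_negative(self):
        voxel = (1.0, 0.5, 0.5)
        shape = (40, 80, 80)
        glom = sphere_mask(shape, voxel, (20, 20, 20), 12.0)
        cell = sphere_mask(shape, voxel, (20, 20, 20), 4.0)
        dmap = signed_distance_map(LabelMap(glom.astype(np.int32), voxel, "g"))
        res = shortest_distance(
            LabelMap(cell.astype(np.int32), voxel, "c"), dmap,
            LabelMap(glom.astype(np.int32), voxel, "g"),
        )
        assert res.iloc[0]["shortest_distance_um"] < 0

    def test_no_targets_inf_marker(self):
        voxel = (1.0, 1.0, 1.0)
        cell = np.zeros((8, 8, 8), np.int32)
        cell[3:5, 3:5, 3:5] = 1
        empty = LabelMap(np.zeros((8, 8, 8), np.int32), voxel, "g")
        with pytest.warns(UserWarning):
            dmap = signed_distance_map(empty)
        res = shortest_distance(LabelMap(cell, voxel, "c"), dmap, empty)
        assert np.isinf(res.iloc[0]["shortest_distance_um"])
        assert pd.isna(res.iloc[0]["nearest_target_id"])

    def test_tie_prefers_smaller_target_id(self):
        voxel = (1.0, 1.0, 1.0)
        targets = np.zeros((3, 3, 9), np.int32)
        targets[1, 1, 0] = 1
        targets[1, 1, 8] = 2
        objects = np.zeros((3, 3, 9), np.int32)
        objects[1, 1, 4] = 1  # equidistant from both targets
        tlm = LabelMap(targets, voxel, "g")
        res = shortest_distance(LabelMap(objects, voxel, "c"),
                                signed_distance_map(tlm), tlm)
        assert res.iloc[0]["nearest_target_id"] == 1

    def test_geometry_mismatch(self):
        voxel = (1.0, 1.0, 1.0)
        a = LabelMap(np.zeros((4, 4, 4), np.int32), voxel, "a")
        b = LabelMap(np.ones((5, 5, 5), np.int32), voxel, "b")
        with pytest.raises(ValueError, match="geometry"):
            shortest_distance(a, np.zeros((4, 4, 4)), b)


class TestClassification:
    @pytest.mark.parametrize(
        "d,expected",
        [(-2.0, "within"), (0.0, "within"), (0.499, "within"),
         (0.5, "surrounding"), (10.0, "surrounding"), (20.0, "surrounding"),
         (20.001, "peripheral"), (25.0, "peripheral"), (np.inf, "peripheral")],
    )
    def test_boundaries(self, d, expected):
        assert classify_population(d) == expected

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(0)
        d = np.concatenate([rng.uniform(-5, 30, 200), [0.5, 20.0, np.inf]])
        vec = classify_populations(d)
        assert all(v == classify_population(x) for v, x in zip(vec, d))

    def test_partition_conservation(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(-10, 50, 500)
        labels = classify_populations(d)
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == 500

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            classify_population(1.0, thresholds_um=(2.0, 1.0))


class TestWithinFraction:
    def _df(self, distances):
        return pd.DataFrame({"object_id": range(1, len(distances) + 1),
                             "shortest_distance_um": distances})

    def test_counting(self):
        out = within_fraction(self._df([-1.0, 10.0, 10.0, 30.0]))
        assert out["n_gated"] == 3
        assert out["fraction_within"] == pytest.approx(1 / 3)

    def test_all_peripheral_undefined(self):
        out = within_fraction(self._df([25.0, 30.0, np.inf]))
        assert out["n_gated"] == 0
        assert out["fraction_within"] is None

    def test_gate_includes_endpoint(self):
        out = within_fraction(self._df([20.0]))
        assert out["n_gated"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            within_fraction(self._df([]))
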