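"""Regridding, coverage, tissue weights — checked against brute-force oracles."""

import numpy as np
import pytest

from mrsproc import (
    LabelImage,
    MRSVolume,
    PhantomSpec,
    SequenceMeta,
    build_csi_phantom,
    coverage_filter,
    coverage_fraction,
    fid_to_spectrum,
    regrid_to_csi,
    tissue_weights,
    weighted_average_spectrum,
)


def _csi(shape=(2, 2, 1), n=16, voxel=10.0):
    meta = SequenceMeta(127.74, 2000.0)
    aff = np.diag([voxel, voxel, voxel, 1.0])
    data = np.zeros(shape + (n,), dtype=complex)
    return MRSVolume(data, aff, meta)


from tests_helpers import brute_force_assignment  # noqa: E402


class TestRegrid:
    def test_identical_grids_map_to_themselves(self):
        csi = _csi(shape=(3, 3, 2))
        labels = LabelImage(np.ones((3, 3, 2), dtype=int), csi.affine.copy())
        assign = regrid_to_csi(labels, csi)
        expected = np.arange(18).reshape(3, 3, 2)
        np.testing.assert_array_equal(assign.flat_index, expected)

    def test_thousand_centres_inside_one_big_voxel(self):
        """1 mm label voxels tiling a 10 mm CSI voxel all map to it."""
        csi = _csi(shape=(2, 2, 1), voxel=10.0)
        aff = np.diag([1.0, 1.0, 1.0, 1.0])
        aff[:3, 3] = [-4.5, -4.5, -4.5]  # 10x10x10 grid centred on CSI voxel (0,0,0)
        labels = LabelImage(np.ones((10, 10, 10), dtype=int), aff)
        assign = regrid_to_csi(labels, csi)
        np.testing.assert_array_equal(assign.flat_index, 0)
        np.testing.assert_array_equal(assign.flat_index, brute_force_assignment(labels, csi))

    def test_grid_outside_fov_is_all_outside(self):
        csi = _csi()
        aff = np.eye(4)
        aff[:3, 3] = [1000.0, 1000.0, 1000.0]
        labels = LabelImage(np.ones((4, 4, 4), dtype=int), aff)
        assign = regrid_to_csi(labels, csi)
        np.testing.assert_array_equal(assign.flat_index, -1)

    def test_matches_brute_force_on_random_geometry(self):
        rng = np.random.default_rng(9)
        csi = _csi(shape=(3, 2, 2), voxel=8.0)
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        aff[:3, 3] = rng.uniform(-10, 10, size=3)
        labels = LabelImage(rng.integers(0, 3, size=(9, 8, 8)), aff)
        assign = regrid_to_csi(labels, csi)
        np.testing.assert_array_equal(assign.flat_index, brute_force_assignment(labels, csi))


class TestCoverage:
    def _setup(self, mask_data):
        csi = _csi(shape=(2, 2, 1), voxel=10.0)
        f = 10  # 1 mm labels
        aff = np.eye(4)
        aff[:3, 3] = [-4.5, -4.5, -4.5]
        labels = LabelImage(np.asarray(mask_data, dtype=int), aff)
        return csi, labels

    def test_full_mask_gives_fraction_one(self):
        csi, mask = self._setup(np.ones((20, 20, 10)))
        assign = regrid_to_csi(mask, csi)
        cov = coverage_fraction(assign, mask)
        covered = cov.denominator > 0
        assert np.all(cov.fraction[covered] == 1.0)

    def test_partial_count_oracle(self):
        """600 of 1000 high-res voxels in the mask gives fraction 0.6 exactly."""
        data = np.zeros((10, 10, 10), dtype=int)
        data.ravel()[:600] = 1
        csi, mask = self._setup(data)
        assign = regrid_to_csi(mask, csi)
        cov = coverage_fraction(assign, mask)
        assert cov.fraction[0, 0, 0] == 0.6
        assert cov.numerator[0, 0, 0] == 600
        assert cov.denominator[0, 0, 0] == 1000

    def test_uncovered_voxel_has_zero_fraction_and_denominator(self):
        csi, mask = self._setup(np.ones((10, 10, 10)))
        assign = regrid_to_csi(mask, csi)
        cov = coverage_fraction(assign, mask)
        assert cov.fraction[1, 1, 0] == 0.0
        assert cov.denominator[1, 1, 0] == 0

    def test_exact_equality_with_triple_loop_on_random_grids(self):
        """Coverage equals a brute-force count exactly on grids <= 20^3."""
        rng = np.random.default_rng(4)
        csi = _csi(shape=(3, 3, 1), voxel=10.0)
        aff = np.diag([1.7, 1.7, 1.7, 1.0])
        aff[:3, 3] = [-6.0, -5.0, -2.0]
        mask = LabelImage((rng.random((18, 19, 6)) < 0.5).astype(int), aff)
        assign = regrid_to_csi(mask, csi)
        cov = coverage_fraction(assign, mask)
        brute = brute_force_assignment(mask, csi)
        for v in np.ndindex(csi.grid_shape):
            flat = np.ravel_multi_index(v, csi.grid_shape)
            denom = int(np.sum(brute == flat))
            numer = int(np.sum((brute == flat) & (mask.data > 0)))
            assert cov.denominator[v] == denom
            assert cov.numerator[v] == numer
            assert cov.fraction[v] == (numer / denom if denom else 0.0)


class TestCoverageFilter:
    def test_strictly_greater_than_threshold(self):
        fractions = np.array([[[0.4]], [[0.5]], [[0.51]], [[1.0]]])
        from mrsproc.spatial import CoverageMap

        cov = CoverageMap(fractions, np.ones_like(fractions), np.ones_like(fractions))
        included = coverage_filter(cov, 0.5)
        assert included == {(2, 0, 0), (3, 0, 0)}

    def test_zero_threshold_keeps_any_positive_fraction(self):
        from mrsproc.spatial import CoverageMap

        fractions = np.array([[[0.0]], [[0.01]]])
        cov = CoverageMap(fractions, np.ones_like(fractions), np.ones_like(fractions))
        assert coverage_filter(cov, 0.0) == {(1, 0, 0)}

    def test_empty_map_gives_empty_set(self):
        from mrsproc.spatial import CoverageMap

        z = np.zeros((2, 2, 1))
        assert coverage_filter(CoverageMap(z, z, z)) == frozenset()


class TestTissueWeights:
    def test_hand_normalisation(self):
        """Raw overlaps 0.30 and 0.10 normalise to weights 0.75 and 0.25."""
        csi = _csi(shape=(2, 1, 1), voxel=10.0)
        data = np.zeros((20, 10, 10), dtype=int)
        data[:10].ravel()[:300] = 1   # voxel (0,0,0): 300/1000 in tissue
        data[10:].ravel()[:100] = 1   # voxel (1,0,0): 100/1000 in tissue
        aff = np.eye(4)
        aff[:3, 3] = [-4.5, -4.5, -4.5]
        labels = LabelImage(data, aff)
        assign = regrid_to_csi(labels, csi)
        w = tissue_weights(assign, labels, [1], [(0, 0, 0), (1, 0, 0)])
        assert w.weights[0, 0, 0] == pytest.approx(0.75, abs=1e-12)
        assert w.weights[1, 0, 0] == pytest.approx(0.25, abs=1e-12)

    def test_single_full_voxel_gets_weight_one(self):
        csi = _csi(shape=(2, 1, 1), voxel=10.0)
        data = np.zeros((20, 10, 10), dtype=int)
        data[:10] = 1
        aff = np.eye(4)
        aff[:3, 3] = [-4.5, -4.5, -4.5]
        labels = LabelImage(data, aff)
        assign = regrid_to_csi(labels, csi)
        w = tissue_weights(assign, labels, [1], [(0, 0, 0)])
        assert w.weights[0, 0, 0] == 1.0

    def test_absent_tissue_is_an_explicit_error(self):
        csi = _csi(shape=(2, 1, 1), voxel=10.0)
        labels = LabelImage(np.zeros((20, 10, 10), dtype=int), np.eye(4))
        assign = regrid_to_csi(labels, csi)
        with pytest.raises(ValueError, match="tissue absent"):
            tissue_weights(assign, labels, [1], [(0, 0, 0)])

    def test_weights_sum_to_one_on_random_phantoms(self):
        """Normalisation closes to 1 within 1e-12 across 20 phantom seeds."""
        for seed in range(20):
            spec = PhantomSpec(grid_shape=(4, 4, 1), n_points=64,
                               noise_sd=0.05, seed=seed)
            suppressed, _, truth = build_csi_phantom(spec)
            assign = regrid_to_csi(truth.labels, suppressed)
            cov = coverage_fraction(assign, truth.brain_mask)
            included = coverage_filter(cov)
            for tissue in ([1], [2]):
                w = tissue_weights(assign, truth.labels, tissue, included)
                assert abs(w.weights.sum() - 1.0) <= 1e-12

    def test_tissue_partition_conserves_coverage(self):
        """Per voxel, WM + dGM raw fractions add up to the brain fraction."""
        spec = PhantomSpec(grid_shape=(4, 4, 1), n_points=64, seed=2)
        suppressed, _, truth = build_csi_phantom(spec)
        assign = regrid_to_csi(truth.labels, suppressed)
        cov = coverage_fraction(assign, truth.brain_mask)
        wm = coverage_fraction(assign, truth.labels.binarize([1]))
        dgm = coverage_fraction(assign, truth.labels.binarize([2]))
        np.testing.assert_allclose(wm.fraction + dgm.fraction, cov.fraction, atol=1e-12)


class TestWeightedAverage:
    def test_weight_one_on_single_voxel_returns_that_spectrum(self, small_spectrum):
        spec, freq, axis, truth = small_spectrum
        from mrsproc.spatial import WeightMap

        w = np.zeros(spec.grid_shape)
        w[2, 3, 0] = 1.0
        wmap = WeightMap(w, frozenset({(2, 3, 0)}), (1,))
        avg = weighted_average_spectrum(freq, wmap)
        np.testing.assert_array_equal(avg.data[0, 0, 0], freq.data[2, 3, 0])
        np.testing.assert_allclose(avg.affine[:3, 3], freq.voxel_center_world((2, 3, 0)))

    def test_equal_weights_on_opposite_spectra_cancel(self, meta):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(32) + 1j * rng.standard_normal(32)
        data = np.stack([s, -s]).reshape(2, 1, 1, 32)
        vol = MRSVolume(data, np.diag([10.0, 10, 10, 1]), meta, domain_tag="frequency")
        from mrsproc.spatial import WeightMap

        w = WeightMap(np.full((2, 1, 1), 0.5), frozenset({(0, 0, 0), (1, 0, 0)}), (1,))
        avg = weighted_average_spectrum(vol, w)
        np.testing.assert_allclose(avg.data, 0.0, atol=1e-12)

    def test_tissue_amplitude_ratio_recovered(self):
        """WM at 2x dGM metabolite amplitude gives a 2x weighted-average NAA area."""
        from mrsproc import default_window, peak_area

        spec = PhantomSpec(grid_shape=(4, 4, 1), n_points=1024, seed=0)
        suppressed, _, truth = build_csi_phantom(spec)
        freq, axis = fid_to_spectrum(suppressed)
        assign = regrid_to_csi(truth.labels, freq)
        cov = coverage_fraction(assign, truth.brain_mask)
        included = coverage_filter(cov)
        areas = {}
        for name, label in (("WM", 1), ("dGM", 2)):
            w = tissue_weights(assign, truth.labels, [label], included)
            avg = weighted_average_spectrum(freq, w)
            areas[name] = peak_area(avg.data[0, 0, 0], axis, default_window("NAA"))
        assert areas["WM"] / areas["dGM"] == pytest.approx(2.0, rel=0.01)
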