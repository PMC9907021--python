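import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contourbench import (
    added_path_length,
    dice,
    extract_surface,
    surface_dice,
    surface_distance_stats,
    volume_cc,
)
from contourbench.metrics import Metric, UndefinedMetricError

from conftest import make_mask, random_blob_mask
import oracles


def _cube(shape, lo, hi, spacing=(1.0, 1.0, 1.0)):
    vox = np.zeros(shape, dtype=bool)
    vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return make_mask(vox, spacing)


class TestDice:
    def test_identity(self):
        m = _cube((5, 5, 5), (1, 1, 1), (4, 4, 4))
        assert float(dice(m, m)) == 1.0

    def test_disjoint(self):
        a = _cube((6, 6, 6), (0, 0, 0), (2, 2, 2))
        b = _cube((6, 6, 6), (4, 4, 4), (6, 6, 6))
        assert float(dice(a, b)) == 0.0

    def test_hand_counted_overlap(self):
        # |a|=4, |b|=2, |a∩b|=2 on a 1-slice 4x4 grid
        a = np.zeros((1, 4, 4), dtype=bool)
        a[0, 0, :4] = True
        b = np.zeros((1, 4, 4), dtype=bool)
        b[0, 0, 1:3] = True
        got = float(dice(make_mask(a), make_mask(b)))
        assert got == pytest.approx(2 * 2 / (4 + 2))

    def test_empty_conventions(self):
        empty = make_mask(np.zeros((3, 3, 3)))
        full = _cube((3, 3, 3), (0, 0, 0), (2, 2, 2))
        assert float(dice(empty, empty)) == 1.0
        assert float(dice(empty, full)) == 0.0

    def test_grid_mismatch_rejected(self):
        a = make_mask(np.ones((2, 2, 2)), spacing=(1, 1, 1))
        b = make_mask(np.ones((2, 2, 2)), spacing=(2, 1, 1))
        with pytest.raises(ValueError, match="grid mismatch"):
            dice(a, b)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = random_blob_mask(rng, shape=(8, 8, 8))
        b = random_blob_mask(rng, shape=(8, 8, 8))
        dab, dba = float(dice(a, b)), float(dice(b, a))
        assert dab == dba
        assert 0.0 <= dab <= 1.0


class TestSurfaceExtraction:
    def test_solid_cube_boundary(self):
        m = _cube((5, 5, 5), (1, 1, 1), (4, 4, 4))  # 3x3x3 cube
        assert extract_surface(m).n_elements == 26  # all but the center

    def test_single_voxel(self):
        m = _cube((3, 3, 3), (1, 1, 1), (2, 2, 2))
        s = extract_surface(m)
        assert s.n_elements == 1
        assert np.allclose(s.points[0], (1.0, 1.0, 1.0))

    def test_empty_mask(self):
        assert extract_surface(make_mask(np.zeros((3, 3, 3)))).is_empty()

    def test_grid_edge_counts_as_background(self):
        m = make_mask(np.ones((3, 3, 3)))
        # every voxel touches the grid edge except the center... center has
        # all 6 neighbors inside, so 26 boundary voxels
        assert extract_surface(m).n_elements == 26

    def test_element_area_isotropic_approximation(self):
        m = _cube((4, 4, 4), (1, 1, 1), (3, 3, 3), spacing=(3.0, 1.0, 2.0))
        s = extract_surface(m)
        assert s.element_area == pytest.approx(np.mean([3.0, 6.0, 2.0]))


class TestSurfaceDistances:
    def test_identity(self):
        m = _cube((5, 5, 5), (1, 1, 1), (4, 4, 4))
        msd, hd95 = surface_distance_stats(m, m)
        assert float(msd) == 0.0 and float(hd95) == 0.0

    def test_two_voxels_5mm_apart(self):
        a = _cube((11, 3, 3), (1, 1, 1), (2, 2, 2))
        b = _cube((11, 3, 3), (6, 1, 1), (7, 2, 2))
        msd, hd95 = surface_distance_stats(a, b)
        assert float(msd) == pytest.approx(5.0)
        assert float(hd95) == pytest.approx(5.0)

    def test_empty_mask_undefined(self):
        m = _cube((3, 3, 3), (0, 0, 0), (2, 2, 2))
        with pytest.raises(UndefinedMetricError):
            surface_distance_stats(m, make_mask(np.zeros((3, 3, 3))))


class TestSurfaceDice:
    def test_identity_any_tau(self):
        m = _cube((5, 5, 5), (1, 1, 1), (4, 4, 4))
        assert float(surface_dice(m, m, 0.0)) == 1.0

    def test_saturation_at_grid_diameter(self):
        rng = np.random.default_rng(5)
        a = random_blob_mask(rng, shape=(10, 10, 10))
        b = random_blob_mask(rng, shape=(10, 10, 10))
        diam = float(np.sqrt(3) * 10)
        assert float(surface_dice(a, b, diam)) == 1.0

    def test_shifted_cube_tau_zero_counts_coincident(self):
        a = _cube((14, 14, 14), (1, 1, 1), (11, 11, 11))  # 10^3 cube
        b = _cube((14, 14, 14), (2, 1, 1), (12, 11, 11))  # shifted 1 voxel
        got = float(surface_dice(a, b, 0.0))
        assert got == pytest.approx(oracles.oracle_surface_dice(a, b, 0.0))

    def test_negative_tau_rejected(self):
        m = _cube((3, 3, 3), (0, 0, 0), (2, 2, 2))
        with pytest.raises(ValueError):
            surface_dice(m, m, -1.0)

    def test_monotone_in_tau(self):
        rng = np.random.default_rng(11)
        a = random_blob_mask(rng, shape=(10, 10, 10))
        b = random_blob_mask(rng, shape=(10, 10, 10))
        vals = [float(surface_dice(a, b, t)) for t in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))


class TestAddedPathLength:
    def test_identity_zero(self):
        m = _cube((5, 8, 8), (1, 1, 1), (4, 6, 6))
        assert float(added_path_length(m, m, 0.0)) == 0.0

    def test_empty_test_full_reference_boundary(self):
        ref = _cube((3, 8, 8), (1, 1, 1), (2, 6, 6))  # one 5x5 slice
        empty = make_mask(np.zeros((3, 8, 8)))
        # 5x5 square: 25 - 9 interior = 16 boundary pixels at 1 mm
        assert float(added_path_length(ref, empty, 0.0)) == pytest.approx(16.0)

    def test_shifted_square_matches_oracle(self):
        ref = _cube((3, 10, 10), (1, 2, 2), (2, 8, 8))
        test = _cube((3, 10, 10), (1, 4, 2), (2, 10, 8))  # shifted 2 px
        got = float(added_path_length(ref, test, 0.0))
        assert got == pytest.approx(oracles.oracle_apl(ref, test, 0.0))

    def test_empty_reference_undefined(self):
        with pytest.raises(UndefinedMetricError):
            added_path_length(make_mask(np.zeros((3, 3, 3))),
                              make_mask(np.ones((3, 3, 3))), 0.0)


class TestVolume:
    def test_empty(self):
        assert float(volume_cc(make_mask(np.zeros((4, 4, 4))))) == 0.0

    def test_unit_conversion(self):
        m = _cube((10, 10, 10), (0, 0, 0), (10, 10, 10))
        assert float(volume_cc(m)) == pytest.approx(1.0)

    def test_anisotropic(self):
        m = _cube((10, 10, 10), (0, 0, 0), (10, 10, 10), spacing=(3.0, 1.0, 1.0))
        assert float(volume_cc(m)) == pytest.approx(3.0)


class TestOracleEquivalence:
    """All surface metrics must agree with explicit O(n^2) brute force."""

    @pytest.mark.parametrize("seed", range(50))
    def test_random_pair_matches_bruteforce(self, seed):
        rng = np.random.default_rng(1000 + seed)
        shape = tuple(rng.integers(6, 17, 3))
        spacing = tuple(rng.uniform(0.8, 3.0, 3).round(2))
        a = random_blob_mask(rng, shape=shape, spacing=spacing)
        b = random_blob_mask(rng, shape=shape, spacing=spacing)
        if a.is_empty() or b.is_empty():
            pytest.skip("degenerate draw")
        tau = float(rng.uniform(0.5, 4.0))

        msd, hd95 = surface_distance_stats(a, b)
        o_msd, o_hd95 = oracles.oracle_msd_hd95(a, b)
        assert float(msd) == pytest.approx(o_msd, abs=1e-9)
        assert float(hd95) == pytest.approx(o_hd95, abs=1e-9)
        assert float(surface_dice(a, b, tau)) == pytest.approx(
            oracles.oracle_surface_dice(a, b, tau), abs=1e-12
        )
        assert float(added_path_length(a, b, tau)) == pytest.approx(
            oracles.oracle_apl(a, b, tau), abs=1e-9
        )


class TestMetricProperties:
    def _pair(self, seed):
        rng = np.random.default_rng(seed)
        a = random_blob_mask(rng, shape=(10, 10, 10), spacing=(2.0, 1.0, 1.0))
        b = random_blob_mask(rng, shape=(10, 10, 10), spacing=(2.0, 1.0, 1.0))
        return a, b

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_symmetry(self, seed):
        a, b = self._pair(seed)
        assert float(dice(a, b)) == float(dice(b, a))
        assert float(surface_dice(a, b, 1.5)) == float(surface_dice(b, a, 1.5))
        ab = surface_distance_stats(a, b)
        ba = surface_distance_stats(b, a)
        assert float(ab[0]) == pytest.approx(float(ba[0]), abs=1e-12)
        assert float(ab[1]) == pytest.approx(float(ba[1]), abs=1e-12)

    @pytest.mark.parametrize("seed", [31, 32])
    def test_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        spacing = (2.0, 1.0, 1.0)
        small_a = random_blob_mask(rng, shape=(7, 7, 7), spacing=spacing)
        small_b = random_blob_mask(rng, shape=(7, 7, 7), spacing=spacing)

        def embed(small, offset):
            vox = np.zeros((14, 14, 14), dtype=bool)
            sl = tuple(slice(o, o + 7) for o in offset)
            vox[sl] = small.voxels
            return make_mask(vox, spacing)

        a, b = embed(small_a, (1, 1, 1)), embed(small_b, (1, 1, 1))
        at, bt = embed(small_a, (3, 2, 4)), embed(small_b, (3, 2, 4))
        assert float(dice(at, bt)) == float(dice(a, b))
        assert float(surface_dice(at, bt, 1.5)) == float(surface_dice(a, b, 1.5))
        msd, hd95 = surface_distance_stats(a, b)
        msdt, hd95t = surface_distance_stats(at, bt)
        assert float(msdt) == pytest.approx(float(msd), abs=1e-12)
        assert float(hd95t) == pytest.approx(float(hd95), abs=1e-12)

    @pytest.mark.parametrize("seed", [41, 42])
    def test_spacing_scale_behavior(self, seed):
        rng = np.random.default_rng(seed)
        a = random_blob_mask(rng, shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0))
        b = random_blob_mask(rng, shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0))
        a2 = make_mask(a.voxels, spacing=(2.0, 2.0, 2.0))
        b2 = make_mask(b.voxels, spacing=(2.0, 2.0, 2.0))
        msd, hd95 = surface_distance_stats(a, b)
        msd2, hd952 = surface_distance_stats(a2, b2)
        assert float(msd2) == pytest.approx(2 * float(msd))
        assert float(hd952) == pytest.approx(2 * float(hd95))
        assert float(dice(a2, b2)) == float(dice(a, b))
        assert float(surface_dice(a2, b2, 3.0)) == pytest.approx(
            float(surface_dice(a, b, 1.5))
        )
        assert float(added_path_length(a2, b2, 3.0)) == pytest.approx(
            2 * float(added_path_length(a, b, 1.5))
        )
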