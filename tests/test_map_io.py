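"""Map/structure-factor store: I/O, transforms, sharpening, interpolation."""

import struct

import numpy as np
import pytest

from embuild import map_io
from embuild.map_io import (
    DensityMap,
    MapFormatError,
    OutsideVolumeError,
    StructureFactorSet,
    apply_mask,
    apply_sharpening,
    interpolate,
    map_to_structure_factors,
    nyquist_d_min,
    read_mrc,
    structure_factors_to_map,
    write_mrc,
)


def write_raw_mrc(path, values_file_order, cell, mapc, mapr, maps, mode=2, nz_override=None):
    """Independent minimal MRC 2014 writer (test oracle, not the library).

    ``values_file_order`` is indexed [sections, rows, columns].
    """
    ns, nr, nc = values_file_order.shape
    nz = ns if nz_override is None else nz_override
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nc, nr, nz)  # NX NY NZ (file order)
    struct.pack_into("<i", header, 12, mode)
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nstart
    struct.pack_into("<3i", header, 28, nc, nr, nz)  # sampling MX MY MZ (file order)
    struct.pack_into("<3f", header, 40, *cell)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, mapc, mapr, maps)
    struct.pack_into("<i", header, 88, 1)  # ISPG volume
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0, 0])  # little-endian machine stamp
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(values_file_order.astype("<f4").tobytes())


class TestMrcIO:
    def test_write_read_round_trip(self, small_map, tmp_path):
        p = tmp_path / "m.mrc"
        write_mrc(small_map, str(p))
        back = read_mrc(str(p))
        assert back.shape == small_map.shape
        assert np.allclose(back.values, small_map.values, atol=1e-5)
        assert np.allclose(back.spacing, small_map.spacing, atol=1e-5)
        assert np.allclose(back.origin, small_map.origin, atol=1e-4)

    def test_axis_permutation_matches_canonical(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = rng.standard_normal((6, 5, 4))  # indexed [x, y, z]
        cell = (6.0, 5.0, 4.0)
        # canonical file: columns = x, rows = y, sections = z
        p1 = tmp_path / "xyz.mrc"
        write_raw_mrc(p1, np.transpose(vol, (2, 1, 0)), cell, 1, 2, 3)
        # permuted file: columns = z, rows = y, sections = x
        p2 = tmp_path / "zyx.mrc"
        write_raw_mrc(p2, np.transpose(vol, (0, 1, 2)), (cell[2], cell[1], cell[0]), 3, 2, 1)
        m1 = read_mrc(str(p1))
        m2 = read_mrc(str(p2))
        assert np.allclose(m1.values, vol, atol=1e-6)
        assert np.allclose(m2.values, m1.values, atol=1e-6)

    def test_image_mode_rejected(self, tmp_path):
        rng = np.random.default_rng(1)
        p = tmp_path / "img.mrc"
        write_raw_mrc(p, rng.standard_normal((1, 8, 8)), (8.0, 8.0, 1.0), 1, 2, 3)
        with pytest.raises(MapFormatError):
            read_mrc(str(p))

    def test_degenerate_grid_rejected(self):
        with pytest.raises(MapFormatError):
            DensityMap(np.zeros((4, 4)), np.ones(3))
        with pytest.raises(MapFormatError):
            DensityMap(np.zeros((4, 4, 4)), np.array([1.0, -1.0, 1.0]))


class TestStructureFactors:
    def test_constant_map_is_dc_only(self):
        m = DensityMap(np.full((8, 8, 8), 3.5), np.ones(3))
        sf = map_to_structure_factors(m, 4.0)
        nonzero = sf.amplitude > 1e-9
        assert np.sum(nonzero) == 1
        dc = sf.hkl[nonzero][0]
        assert tuple(dc) == (0, 0, 0)
        assert np.isclose(sf.amplitude[nonzero][0], 3.5 * 8**3)

    def test_retained_count_matches_enumeration(self):
        m = DensityMap(np.zeros((20, 20, 20)) + 1.0, np.full(3, 3.0))  # 60 A cell
        m.values[3, 4, 5] = 2.0
        d_min = 6.0
        sf = map_to_structure_factors(m, d_min)
        # brute-force count of integer triples with 1/d <= 1/d_min
        count = 0
        for h in range(-10, 10):
            for k in range(-10, 10):
                for l in range(-10, 10):
                    if (h / 60.0) ** 2 + (k / 60.0) ** 2 + (l / 60.0) ** 2 <= 1 / 36.0 + 1e-12:
                        count += 1
        assert len(sf.hkl) == count

    def test_band_limited_round_trip(self):
        # a map synthesised from low-order Fourier components only
        n = 16
        x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        vals = (
            1.0
            + np.cos(2 * np.pi * x / n)
            + 0.5 * np.sin(2 * np.pi * (y + z) / n)
        )
        m = DensityMap(vals, np.ones(3))
        sf = map_to_structure_factors(m, nyquist_d_min(m))
        back = structure_factors_to_map(sf, m.shape)
        rms = np.sqrt(np.mean((back.values - m.values) ** 2))
        assert rms / np.sqrt(np.mean(m.values**2)) < 1e-6

    def test_below_nyquist_rejected(self, small_map):
        with pytest.raises(ValueError, match="Nyquist"):
            map_to_structure_factors(small_map, 1.0)

    def test_truncation_monotonicity(self, small_map):
        counts = [
            len(map_to_structure_factors(small_map, d).hkl) for d in (2.4, 3.0, 4.0, 6.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_truncated_map_variance_never_grows(self, small_map):
        sf = map_to_structure_factors(small_map, 4.0)
        smoothed = structure_factors_to_map(sf, small_map.shape)
        assert smoothed.values.var() <= small_map.values.var() + 1e-12

    def test_out_of_grid_index_rejected(self):
        sf = StructureFactorSet(
            hkl=np.array([[7, 0, 0]]),
            amplitude=np.array([1.0]),
            phase=np.array([0.0]),
            cell=np.array([8.0, 8.0, 8.0]),
            d_min=2.0,
            grid_shape=(8, 8, 8),
        )
        with pytest.raises(ValueError, match="outside grid"):
            structure_factors_to_map(sf, (8, 8, 8))


class TestSharpening:
    def test_zero_b_is_identity(self, small_map):
        sf = map_to_structure_factors(small_map, 3.0)
        out = apply_sharpening(sf, 0.0)
        assert np.array_equal(out.amplitude, sf.amplitude)
        assert np.array_equal(out.phase, sf.phase)

    def test_inverse_pair(self, small_map):
        sf = map_to_structure_factors(small_map, 3.0)
        out = apply_sharpening(apply_sharpening(sf, 40.0), -40.0)
        assert np.allclose(out.amplitude, sf.amplitude, rtol=1e-12)

    def test_additive_in_b(self, small_map):
        sf = map_to_structure_factors(small_map, 3.0)
        a = apply_sharpening(apply_sharpening(sf, 17.0), 11.0)
        b = apply_sharpening(sf, 28.0)
        assert np.allclose(a.amplitude, b.amplitude, rtol=1e-12)

    def test_single_reflection_ratio(self):
        # one reflection at d = 2 A (h=2 on a 4 A cell edge), B = -40
        sf = StructureFactorSet(
            hkl=np.array([[2, 0, 0]]),
            amplitude=np.array([5.0]),
            phase=np.array([1.0]),
            cell=np.array([4.0, 100.0, 100.0]),
            d_min=2.0,
            grid_shape=(8, 100, 100),
        )
        out = apply_sharpening(sf, -40.0)
        assert np.isclose(out.amplitude[0] / 5.0, np.exp(40.0 / 16.0), rtol=1e-12)


def brute_trilinear(values, spacing, origin, pos):
    c = (pos - origin) / spacing
    base = np.floor(c).astype(int)
    base = np.minimum(base, np.array(values.shape) - 2)
    base = np.maximum(base, 0)
    f = c - base
    out = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[0] if dx else 1 - f[0])
                    * (f[1] if dy else 1 - f[1])
                    * (f[2] if dz else 1 - f[2])
                )
                out += w * values[base[0] + dx, base[1] + dy, base[2] + dz]
    return out


class TestInterpolation:
    def test_node_value(self, small_map):
        pos = small_map.origin + np.array([3, 4, 5]) * small_map.spacing
        assert np.isclose(interpolate(small_map, pos), small_map.values[3, 4, 5])

    def test_midpoint_mean(self):
        vals = np.zeros((4, 4, 4))
        vals[1, 1, 1] = 2.0
        vals[2, 1, 1] = 4.0
        m = DensityMap(vals, np.ones(3))
        assert np.isclose(interpolate(m, np.array([1.5, 1.0, 1.0])), 3.0)

    def test_against_brute_force(self, small_map):
        rng = np.random.default_rng(5)
        hi = small_map.origin + (np.array(small_map.shape) - 1) * small_map.spacing
        pts = rng.uniform(small_map.origin, hi, size=(1000, 3))
        got = interpolate(small_map, pts)
        want = [
            brute_trilinear(small_map.values, small_map.spacing, small_map.origin, p)
            for p in pts
        ]
        assert np.allclose(got, want, atol=1e-12)

    def test_outside_raises(self, small_map):
        with pytest.raises(OutsideVolumeError):
            interpolate(small_map, small_map.origin - 1.0)


class TestSharpeningProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        b1=st.floats(min_value=-80, max_value=80),
        b2=st.floats(min_value=-80, max_value=80),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_multiplicative_in_b(self, b1, b2):
        """apply(B1) then apply(B2) equals apply(B1+B2) for any B."""
        sf = StructureFactorSet(
            hkl=np.array([[1, 0, 0], [2, 1, 0], [0, 3, 2]]),
            amplitude=np.array([2.0, 5.0, 0.7]),
            phase=np.array([0.1, 1.0, 2.0]),
            cell=np.array([20.0, 20.0, 20.0]),
            d_min=4.0,
            grid_shape=(10, 10, 10),
        )
        a = apply_sharpening(apply_sharpening(sf, b1), b2)
        b = apply_sharpening(sf, b1 + b2)
        assert np.allclose(a.amplitude, b.amplitude, rtol=1e-10, atol=1e-300)


class TestMask:
    def test_mask_above_threshold_is_identity(self, small_map):
        mask = small_map.copy(values=np.ones(small_map.shape))
        out = apply_mask(small_map, mask, 0.5)
        assert np.array_equal(out.values, small_map.values)

    def test_mask_below_threshold_zeroes(self, small_map):
        mask = small_map.copy(values=np.zeros(small_map.shape))
        out = apply_mask(small_map, mask, 0.5)
        assert np.all(out.values == 0)

    def test_random_binary_mask_oracle(self, small_map):
        rng = np.random.default_rng(2)
        bits = rng.integers(0, 2, small_map.shape).astype(float)
        mask = small_map.copy(values=bits)
        out = apply_mask(small_map, mask, 0.5)
        assert np.array_equal(out.values, small_map.values * bits)

    def test_geometry_mismatch(self, small_map):
        other = DensityMap(np.zeros((4, 4, 4)), np.ones(3))
        with pytest.raises(ValueError):
            apply_mask(small_map, other, 0.5)
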