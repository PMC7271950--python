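"""Placement scoring modes and seed searches."""

import numpy as np
import pytest

from embuild.map_io import DensityMap
from embuild.reference_targets import TargetTemplate, sphere_offsets
from embuild.search import (
    SENTINEL,
    ScoredPlacement,
    SeedSearchSettings,
    correlation_score,
    fast_seed_search,
    fourier_seed_search,
    llk_score,
    node_scores_fourier,
    refine_placement,
    rotation_set,
    score_placements,
)


@pytest.fixture()
def toy_template():
    offsets = sphere_offsets(2.5, 1.0)
    rng = np.random.default_rng(3)
    mean = rng.uniform(0.5, 3.0, len(offsets))
    var = rng.uniform(0.2, 1.5, len(offsets))
    return TargetTemplate(
        offsets=offsets, mean=mean, variance=var, radius=2.5, centre_role="CA", resolution=3.0
    )


class TestRotationSet:
    def test_orthonormal_and_deterministic(self):
        rots = rotation_set(288)
        assert rots.shape == (288, 3, 3)
        assert np.allclose(np.einsum("nij,nik->njk", rots, rots), np.eye(3)[None], atol=1e-9)
        assert np.allclose(np.linalg.det(rots), 1.0)
        assert np.array_equal(rots, rotation_set(288))


class TestLlkScore:
    def test_uniform_map_matching_means_scores_zero(self, toy_template):
        tpl = toy_template
        tpl.mean = np.full_like(tpl.mean, 1.7)
        m = DensityMap(np.full((16, 16, 16), 1.7), np.ones(3))
        s = llk_score(m, tpl, np.array([8.0, 8.0, 8.0]), np.eye(3))
        assert np.isclose(s, 0.0, atol=1e-12)

    def test_doubling_variance_halves_magnitude(self, small_map, toy_template):
        pos = small_map.origin + small_map.cell / 2
        s1 = llk_score(small_map, toy_template, pos, np.eye(3))
        doubled = TargetTemplate(
            offsets=toy_template.offsets,
            mean=toy_template.mean,
            variance=2 * toy_template.variance,
            radius=toy_template.radius,
            centre_role="CA",
            resolution=3.0,
        )
        s2 = llk_score(small_map, doubled, pos, np.eye(3))
        assert np.isclose(s2, s1 / 2, rtol=1e-12)

    def test_against_direct_sum_oracle(self, small_map, toy_template):
        from embuild.map_io import interpolate

        rng = np.random.default_rng(9)
        rots = rotation_set(100)
        lo = small_map.origin + 3.0
        hi = small_map.origin + small_map.cell - 4.5
        pts = rng.uniform(lo, hi, (100, 3))
        got = score_placements(small_map, toy_template, pts, rots, "llk")
        for i in range(100):
            total = 0.0
            for off, mu, var in zip(
                toy_template.offsets, toy_template.mean, toy_template.variance
            ):
                rho = interpolate(small_map, pts[i] + rots[i] @ off)
                total -= (rho - mu) ** 2 / (2 * var)
            assert np.isclose(got[i], total, atol=1e-10)

    def test_out_of_volume_sentinel(self, small_map, toy_template):
        s = llk_score(small_map, toy_template, small_map.origin, np.eye(3))
        assert s == SENTINEL


class TestCorrelationScore:
    def test_affine_invariance(self, small_map, toy_template):
        pos = small_map.origin + small_map.cell / 2
        base = correlation_score(small_map, toy_template, pos, np.eye(3))
        for a, b in ((3.7, 12.0), (0.2, -5.0)):
            m2 = small_map.copy(values=a * small_map.values + b)
            s = correlation_score(m2, toy_template, pos, np.eye(3))
            assert abs(s - base) < 1e-9 * abs(base)

    def test_llk_lacks_invariance(self, small_map, toy_template):
        pos = small_map.origin + small_map.cell / 2
        base = llk_score(small_map, toy_template, pos, np.eye(3))
        m2 = small_map.copy(values=3.7 * small_map.values + 12.0)
        assert abs(llk_score(m2, toy_template, pos, np.eye(3)) - base) > 1e-3 * abs(base)

    def test_affine_match_scores_zero(self, toy_template):
        """A map equal to the means up to an affine transform is a perfect
        fit."""
        tpl = toy_template
        tpl.mean = np.full_like(tpl.mean, 0.0)
        tpl.mean[:10] = 2.0  # two distinct levels
        m = DensityMap(np.full((16, 16, 16), 5.0), np.ones(3))
        # make the map reproduce the mean pattern around the centre (affine:
        # rho = 2*mu + 1)
        centre = np.array([8.0, 8.0, 8.0])
        idx = np.rint(centre + tpl.offsets).astype(int)
        m.values[tuple(idx.T)] = 2.0 * tpl.mean + 1.0
        s = correlation_score(m, tpl, centre, np.eye(3))
        # offsets are integral here so interpolation is exact
        assert s > -1e-9

    def test_closed_form_matches_normal_equations(self, small_map, toy_template):
        from embuild.map_io import interpolate
        from embuild.search import _correlation_from_samples, _sample

        pos = small_map.origin + small_map.cell / 2
        rho = _sample(small_map, toy_template, pos, np.eye(3))[0]
        w = 1.0 / toy_template.variance
        A = np.stack([rho * np.sqrt(w), np.sqrt(w)], axis=1)
        y = toy_template.mean * np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = np.sum((A @ coef - y) ** 2)
        got = correlation_score(small_map, toy_template, pos, np.eye(3))
        assert np.isclose(got, -0.5 * resid, rtol=1e-9)

    def test_degenerate_fit_sentinel(self, toy_template):
        m = DensityMap(np.full((12, 12, 12), 4.0), np.ones(3))
        s = correlation_score(m, toy_template, np.array([6.0, 6.0, 6.0]), np.eye(3))
        assert s == SENTINEL


class TestFastSeedSearch:
    def test_finds_helix_ca(self, helix30):
        _, _, dmap, cas = helix30
        seeds = fast_seed_search(dmap, SeedSearchSettings(n_seeds=10), resolution=3.0)
        assert len(seeds) >= 1
        dists = [np.min(np.linalg.norm(cas - s.position, axis=1)) for s in seeds]
        assert min(dists) < 1.5

    def test_affine_invariant_ranking(self, helix30):
        _, _, dmap, _ = helix30
        seeds = fast_seed_search(dmap, SeedSearchSettings(n_seeds=8), resolution=3.0)
        m2 = dmap.copy(values=5.0 * dmap.values - 2.0)
        seeds2 = fast_seed_search(m2, SeedSearchSettings(n_seeds=8), resolution=3.0)
        assert len(seeds) == len(seeds2)
        for a, b in zip(seeds, seeds2):
            assert np.allclose(a.position, b.position)
            assert np.allclose(a.orientation, b.orientation)
            assert np.isclose(a.score, b.score, atol=1e-9)

    def test_noise_scores_below_helix(self, helix30):
        _, _, dmap, _ = helix30
        helix_seeds = fast_seed_search(dmap, SeedSearchSettings(n_seeds=5), resolution=3.0)
        rng = np.random.default_rng(11)
        noise = DensityMap(rng.standard_normal(dmap.shape), dmap.spacing, dmap.origin)
        noise_seeds = fast_seed_search(noise, SeedSearchSettings(n_seeds=5), resolution=3.0)
        assert max(s.score for s in noise_seeds) < min(s.score for s in helix_seeds)

    def test_constant_map_empty(self):
        m = DensityMap(np.full((20, 20, 20), 1.0), np.ones(3))
        assert fast_seed_search(m, SeedSearchSettings(n_seeds=5)) == []


class TestFourierSeedSearch:
    def test_node_scores_equal_direct(self, small_map, toy_template):
        m = DensityMap(small_map.values[:10, :10, :10].copy(), np.ones(3))
        for rot in rotation_set(3):
            fft_scores = node_scores_fourier(m, toy_template, rot)
            nodes = np.argwhere(np.ones(m.shape, dtype=bool))
            pos = m.origin + nodes * m.spacing
            direct = score_placements(m, toy_template, pos, rot, "llk").reshape(m.shape)
            valid = fft_scores > SENTINEL / 2
            assert np.array_equal(valid, direct > SENTINEL / 2)
            assert np.max(np.abs(fft_scores[valid] - direct[valid])) < 1e-6

    def test_top_seed_near_helix_ca(self, helix30, ca_target):
        _, _, dmap, cas = helix30
        seeds = fourier_seed_search(dmap, ca_target, SeedSearchSettings(n_seeds=5, n_rotations=48))
        assert len(seeds) >= 1
        d = np.min(np.linalg.norm(cas - seeds[0].position, axis=1))
        assert d < 1.5

    def test_not_scale_invariant(self, helix30, ca_target):
        _, _, dmap, _ = helix30
        rot = rotation_set(1)[0]
        s1 = node_scores_fourier(dmap, ca_target, rot)
        m2 = dmap.copy(values=5.0 * dmap.values - 2.0)
        s2 = node_scores_fourier(m2, ca_target, rot)
        valid = s1 > SENTINEL / 2
        assert not np.allclose(s1[valid], s2[valid], rtol=1e-3)

    def test_constant_map_empty(self, toy_template):
        m = DensityMap(np.zeros((16, 16, 16)), np.ones(3))
        assert fourier_seed_search(m, toy_template, SeedSearchSettings(n_seeds=3)) == []


class TestRefinePlacement:
    def test_never_worsens_and_deterministic(self, helix30, ca_target):
        _, _, dmap, cas = helix30
        p = ScoredPlacement(cas[10] + 0.8, np.eye(3), 0.0, "llk")
        r1 = refine_placement(dmap, ca_target, p, "llk")
        r2 = refine_placement(dmap, ca_target, p, "llk")
        start = llk_score(dmap, ca_target, p.position, p.orientation)
        assert r1.score >= start
        assert np.array_equal(r1.position, r2.position)
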