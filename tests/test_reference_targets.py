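"""Residue frames and likelihood target construction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from embuild.geometry import CollinearBackboneError, ideal_cb_position, residue_frame
from embuild.map_io import DensityMap, interpolate
from embuild.reference_targets import (
    ReferenceData,
    build_ca_target,
    build_cb_targets,
    simulate_reference,
    sphere_offsets,
)
from embuild.synthetic import SyntheticSpec, make_map, make_model


@pytest.fixture()
def triad():
    n = np.array([1.2, 0.3, -0.5])
    ca = np.array([2.5, 1.0, 0.1])
    c = np.array([3.6, 0.2, 1.0])
    return n, ca, c


class TestResidueFrame:
    def test_orthonormal_right_handed(self, triad):
        f = residue_frame(*triad, "CA")
        assert np.allclose(f.axes.T @ f.axes, np.eye(3), atol=1e-9)
        assert np.isclose(np.linalg.det(f.axes), 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equivariance_under_rotation(self, triad, seed):
        R = Rotation.random(random_state=seed).as_matrix()
        t = np.array([4.0, -2.0, 7.0])
        f0 = residue_frame(*triad, "CA")
        f1 = residue_frame(*(R @ p + t for p in triad), "CA")
        assert np.allclose(f1.axes, R @ f0.axes, atol=1e-9)
        assert np.allclose(f1.origin, R @ f0.origin + t, atol=1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(CollinearBackboneError):
            residue_frame(
                np.array([0.0, 0, 0]), np.array([1.0, 0, 0]), np.array([2.0, 0, 0])
            )

    def test_ideal_cb_matches_ccd_alanine(self):
        # oracle: CCD ideal coordinates via biotite's residue library
        from biotite.structure.info import residue as ccd_residue

        ala = ccd_residue("ALA")
        coords = {name: ala.coord[i] for i, name in enumerate(ala.atom_name)}
        cb = ideal_cb_position(coords["N"], coords["CA"], coords["C"])
        assert np.linalg.norm(cb - coords["CB"]) < 0.1


class TestSphereOffsets:
    def test_count_matches_enumeration(self):
        got = sphere_offsets(4.0, 1.0)
        count = sum(
            1
            for i in range(-4, 5)
            for j in range(-4, 5)
            for k in range(-4, 5)
            if i * i + j * j + k * k <= 16
        )
        assert len(got) == count

    def test_lexicographic_and_bounded(self):
        off = sphere_offsets(4.0, 1.0)
        assert np.all(np.linalg.norm(off, axis=1) <= 4.0 + 1e-9)
        keys = [tuple(o) for o in np.round(off, 6)]
        assert keys == sorted(keys)


class TestCaTarget:
    def test_uniform_density_gives_floored_variance(self):
        model, _ = make_model(SyntheticSpec(n_res=40, fold="helix", rng_seed=1))
        dmap = make_map(model, 3.0, 1.0)
        flat = dmap.copy(values=np.full(dmap.shape, 2.0))
        ref = ReferenceData(map=flat, model=model, resolution=3.0)
        tpl = build_ca_target(ref)
        assert np.allclose(tpl.mean, 2.0)
        assert np.all(tpl.variance <= 1e-10)
        assert np.all(tpl.variance > 0)

    def test_moments_match_two_pass_oracle(self, reference):
        tpl = build_ca_target(reference, radius=3.0, step=1.5)
        # independent accumulation: per-residue frames + interpolation
        from embuild.reference_targets import usable_residue_frames

        frames = [f for _, f in usable_residue_frames(reference.model, "CA")]
        samples = []
        for f in frames:
            pts = f.to_world(tpl.offsets)
            try:
                samples.append([interpolate(reference.map, p) for p in pts])
            except Exception:
                continue
        samples = np.array(samples)
        assert np.allclose(tpl.mean, samples.mean(axis=0), atol=1e-9)
        assert np.allclose(
            np.maximum(samples.var(axis=0), tpl.variance.min()),
            tpl.variance,
            atol=1e-9,
        )

    def test_too_few_residues_rejected(self):
        model, _ = make_model(SyntheticSpec(n_res=10, fold="helix", rng_seed=2))
        ref = simulate_reference(model, 3.0)
        with pytest.raises(ValueError, match="usable residues"):
            build_ca_target(ref)

    def test_rotated_reference_equivalence(self):
        """Templates from a rigidly rotated reference agree within
        interpolation error."""
        model, _ = make_model(SyntheticSpec(n_res=40, fold="helix", rng_seed=4))
        ref = simulate_reference(model, 3.0)
        tpl = build_ca_target(ref, step=1.0)
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        rot_model = model.clone()
        for chain in rot_model[0]:
            for res in chain:
                for a in res:
                    p = R @ np.array([a.pos.x, a.pos.y, a.pos.z])
                    import gemmi

                    a.pos = gemmi.Position(*p)
        rot_ref = simulate_reference(rot_model, 3.0)
        rot_tpl = build_ca_target(rot_ref, step=1.0)
        rms = np.sqrt(np.mean((tpl.mean - rot_tpl.mean) ** 2))
        assert rms < 0.02 * np.ptp(tpl.mean)


class TestCbTargets:
    def test_single_type_reference(self):
        model, _ = make_model(
            SyntheticSpec(n_res=40, fold="helix", sequence="A" * 40, rng_seed=1)
        )
        ref = simulate_reference(model, 3.0)
        got = build_cb_targets(ref, types="A")
        assert set(got) == {"A"}
        with pytest.raises(ValueError, match="under-represents"):
            build_cb_targets(ref)

    def test_per_type_accumulation_oracle(self, reference, cb_targets):
        # spot-check one type against a fresh single-type accumulation
        tpl = cb_targets["W"]
        from embuild.reference_targets import usable_residue_frames
        from embuild.synthetic import THREE_TO_ONE

        frames = [
            f
            for name, f in usable_residue_frames(reference.model, "CB")
            if THREE_TO_ONE.get(name) == "W"
        ]
        samples = np.array(
            [[interpolate(reference.map, p) for p in f.to_world(tpl.offsets)] for f in frames]
        )
        assert np.allclose(tpl.mean, samples.mean(axis=0), atol=1e-9)

    def test_glycine_centre_is_virtual(self, reference, cb_targets):
        """The G template centre is a constructed CB, not a real atom."""
        assert cb_targets["G"].centre_role == "CB"
        # glycine residues in the reference have no CB atom at all
        for chain in reference.model[0]:
            for res in chain:
                if res.name == "GLY":
                    assert all(a.name != "CB" for a in res)


class TestSimulateReference:
    def test_deterministic(self):
        model, _ = make_model(SyntheticSpec(n_res=20, fold="strand", rng_seed=6))
        a = simulate_reference(model, 3.0)
        b = simulate_reference(model, 3.0)
        assert np.array_equal(a.map.values, b.map.values)

    def test_coarser_resolution_lowers_variance(self):
        model, _ = make_model(SyntheticSpec(n_res=20, fold="strand", rng_seed=6))
        fine = simulate_reference(model, 3.0)
        coarse = simulate_reference(model, 6.0)
        assert coarse.map.values.var() < fine.map.values.var()

    def test_self_consistency_scores(self, reference, ca_target, helix30):
        """True CA placements outscore random placements in a fresh map."""
        from embuild.reference_targets import usable_residue_frames
        from embuild.search import score_placements

        model, _, dmap, _ = helix30
        frames = usable_residue_frames(model, "CA")
        pos = np.array([f.origin for _, f in frames])
        rot = np.array([f.axes for _, f in frames])
        true_scores = score_placements(dmap, ca_target, pos, rot, "llk")
        rng = np.random.default_rng(0)
        rpos = rng.uniform(dmap.origin + 5, dmap.origin + dmap.cell - 5, (40, 3))
        from embuild.search import rotation_set

        rand_scores = score_placements(dmap, ca_target, rpos, rotation_set(40), "llk")
        rand_scores = rand_scores[rand_scores > -1e29]
        assert np.median(true_scores) > np.median(rand_scores)
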