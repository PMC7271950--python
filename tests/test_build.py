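"""Chain growing, joining, pruning and junk filtering."""

import numpy as np
import pytest

from embuild.build import (
    ChainFragment,
    GrowSettings,
    filter_junk,
    grow_chain,
    join_fragments,
    orient_fragment,
    prune_overlaps,
    refine_fragment,
    split_by_score,
    trim_overlaps,
)
from embuild.map_io import DensityMap
from embuild.search import ScoredPlacement
from embuild.synthetic import make_mask


def frag_from(cas, scores=None, types=None, fid="f"):
    cas = np.asarray(cas, dtype=float)
    return ChainFragment(
        cas=cas,
        scores=np.zeros(len(cas)) if scores is None else np.asarray(scores, float),
        types=types or [],
        id=fid,
    )


def line(n, start=0.0, step=3.8, axis=0):
    cas = np.zeros((n, 3))
    cas[:, axis] = start + step * np.arange(n)
    cas[:, 1] = 0.3 * (-1) ** np.arange(n)  # avoid exact collinearity
    return cas


class TestChainFragment:
    def test_distance_invariant_enforced(self):
        with pytest.raises(ValueError, match="CA-CA"):
            frag_from([[0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(ValueError, match="CA-CA"):
            frag_from([[0, 0, 0], [6.0, 0, 0]])

    def test_reversed_round_trip(self):
        f = frag_from(line(5), scores=np.arange(5.0), types=list("ACDEF"))
        r = f.reversed().reversed()
        assert np.array_equal(r.cas, f.cas)
        assert r.types == f.types


class TestGrowChain:
    def test_zero_map_stops_immediately(self, ca_target):
        m = DensityMap(np.zeros((24, 24, 24)), np.ones(3))
        seed = ScoredPlacement(np.full(3, 12.0), np.eye(3), 0.0, "llk")
        frag = grow_chain(m, seed, ca_target, GrowSettings(score_floor=-1.0), "llk")
        assert len(frag) == 1

    def test_deterministic(self, helix30, ca_target):
        _, _, dmap, cas = helix30
        from embuild.geometry import place_backbone, residue_frame

        n_at, c_at = place_backbone(cas)
        fr = residue_frame(n_at[15], cas[15], c_at[15], "CA")
        seed = ScoredPlacement(cas[15].copy(), fr.axes, 0.0, "correlation")
        gs = GrowSettings(score_floor=-200.0, max_length=20)
        f1 = grow_chain(dmap, seed, ca_target, gs, "correlation")
        f2 = grow_chain(dmap, seed, ca_target, gs, "correlation")
        assert np.array_equal(f1.cas, f2.cas)

    def test_traces_follow_the_helix(self, helix30, target_set):
        """From a mid-helix seed the grown trace stays on the chain
        envelope: most true CAs end up close to the trace, and the trace
        does not wander off into empty space."""
        _, _, dmap, cas = helix30
        from embuild.geometry import place_backbone, residue_frame
        from embuild.pipeline import _null_score_median

        null = _null_score_median(dmap, target_set.ca, "correlation")
        n_at, c_at = place_backbone(cas)
        fr = residue_frame(n_at[15], cas[15], c_at[15], "CA")
        seed = ScoredPlacement(cas[15].copy(), fr.axes, 0.0, "correlation")
        frag = grow_chain(
            dmap,
            seed,
            target_set.ca,
            GrowSettings(score_floor=0.8 * null, max_length=30),
            "correlation",
        )
        frag = refine_fragment(dmap, frag, target_set.ca, "correlation")
        from scipy.spatial.distance import cdist

        D = cdist(frag.cas, cas)
        assert len(frag) >= 15
        # coverage: most of the helix has trace nearby
        assert np.sum(D.min(axis=0) < 2.0) >= 12
        # no residue built far from the molecule
        assert D.min(axis=1).max() < 6.0


class TestJoin:
    def test_split_helix_rejoined(self, helix30):
        _, _, _, cas = helix30
        a = frag_from(cas[:15], fid="a")
        b = frag_from(cas[14:], fid="b")  # shares residue 14: termini ~0 A apart
        out = join_fragments([a, b])
        assert len(out) == 1
        assert len(out[0]) == 30

    def test_distant_fragments_unchanged(self):
        a = frag_from(line(6), fid="a")
        b = frag_from(line(6, start=100.0), fid="b")
        out = join_fragments([a, b])
        assert len(out) == 2

    def test_idempotent(self, helix30):
        _, _, _, cas = helix30
        frags = [frag_from(cas[:15], fid="a"), frag_from(cas[14:], fid="b")]
        once = join_fragments(frags)
        twice = join_fragments(once)
        assert len(once) == len(twice)
        assert all(np.array_equal(x.cas, y.cas) for x, y in zip(once, twice))


class TestPrune:
    def test_identical_fragments_deduplicated(self):
        a = frag_from(line(8), fid="a")
        b = frag_from(line(8), fid="b")
        assert len(prune_overlaps([a, b])) == 1

    def test_disjoint_survive(self):
        frags = [frag_from(line(8, start=100.0 * i), fid=str(i)) for i in range(3)]
        assert len(prune_overlaps(frags)) == 3

    def test_matches_exhaustive_dominance_oracle(self):
        """Greedy keep-best equals brute-force application of the same
        dominance rule on small instances."""
        rng = np.random.default_rng(0)
        for trial in range(5):
            frags = []
            for i in range(4):
                start = rng.uniform(0, 12)
                n = rng.integers(6, 10)
                cas = line(int(n), start=start)
                cas[:, 2] += rng.uniform(0, 2.5)
                frags.append(frag_from(cas, scores=rng.standard_normal(int(n)), fid=str(i)))
            got = {f.id for f in prune_overlaps(frags, clash_radius=2.0)}
            # oracle: walk fragments in dominance order, drop shadowed ones
            order = sorted(
                range(len(frags)),
                key=lambda i: (-len(frags[i]), -frags[i].mean_score(), frags[i].id, i),
            )
            kept, kept_cas = [], []
            for i in order:
                f = frags[i]
                if kept_cas:
                    allc = np.vstack(kept_cas)
                    d = np.min(
                        np.linalg.norm(f.cas[:, None, :] - allc[None, :, :], axis=2), axis=1
                    )
                    if np.mean(d < 2.0) > 0.5:
                        continue
                kept.append(f.id)
                kept_cas.append(f.cas)
            assert got == set(kept)


class TestFilterJunk:
    def test_length_boundary(self):
        short = frag_from(line(5), fid="s")
        ok = frag_from(line(6), fid="l")
        out = filter_junk([short, ok], min_length=6)
        assert [f.id for f in out] == ["l"]

    def test_mask_removes_outside_fragment(self, helix30):
        model, _, dmap, cas = helix30
        mask = make_mask(model, 4.0, dmap)
        inside = frag_from(cas[:10], fid="in")
        corner = dmap.origin + 2.0
        junk_cas = line(8) + corner
        outside = frag_from(junk_cas, fid="out")
        out = filter_junk([inside, outside], min_length=6, mask=mask, mask_threshold=0.5)
        assert [f.id for f in out] == ["in"]

    def test_no_mask_identity(self):
        frags = [frag_from(line(8), fid="a")]
        assert filter_junk(frags, min_length=6) == frags


class TestSplitTrimOrient:
    def test_split_by_score(self):
        scores = [-10, -10, -500, -10, -10, -10]
        f = frag_from(line(6), scores=scores)
        pieces = split_by_score(f, cut=-100.0, min_len=2)
        assert [len(p) for p in pieces] == [2, 3]

    def test_trim_overlaps_keeps_novel_parts(self):
        a = frag_from(line(10), fid="a")
        # b shadows the second half of a, then continues beyond it
        b = frag_from(line(10, start=5 * 3.8) + np.array([0.5, 0.5, 0.0]), fid="b")
        out = trim_overlaps([a, b], clash_radius=2.0)
        total = sum(len(f) for f in out)
        assert total < len(a) + len(b)
        assert any(f.id.startswith("a") for f in out)
        # the novel tail of b survives
        assert any(f.id.startswith("b") for f in out)

    def test_orient_prefers_true_direction(self, hts60, target_set):
        _, _, dmap, cas = hts60
        fwd = frag_from(cas[5:20], fid="w")
        out_f = orient_fragment(dmap, fwd, target_set.ca, "correlation")
        out_r = orient_fragment(dmap, fwd.reversed(), target_set.ca, "correlation")
        assert np.allclose(out_f.cas, fwd.cas)
        assert np.allclose(out_r.cas, fwd.cas)
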