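"""Growing CA chains from seeds; joining, pruning and filtering fragments.

Chains are grown residue by residue at the canonical 3.8 A CA-CA spacing
over a cone of plausible pseudo-bond angles, scoring every candidate next
CA with the main-chain density target and keeping a small beam of the best
partial extensions.  Growth runs in both directions from the seed.  The
resulting fragments are merged where their termini abut, de-duplicated
where they trace the same density, and cleansed of short or out-of-mask
junk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    CollinearBackboneError,
    backbone_dirs_from_tangents,
    frames_batch,
    place_backbone,
    residue_frame,
)
from .map_io import DensityMap
from .reference_targets import TargetTemplate
from .search import SENTINEL, ScoredPlacement, score_placements

__all__ = [
    "ChainFragment",
    "GrowSettings",
    "grow_chain",
    "extend_fragment",
    "refine_fragment",
    "join_fragments",
    "prune_overlaps",
    "trim_overlaps",
    "filter_junk",
    "split_by_score",
    "orient_fragment",
]

CA_CA = 3.8  # canonical trans CA-CA distance, Angstrom
CA_CA_MIN, CA_CA_MAX = 2.9, 4.5  # accepted spacing window (cis/trans)
# tighter trans-only window used while optimising positions (keeps growth
# from drifting out of register along the chain)
CA_TRANS_MIN, CA_TRANS_MAX = 3.55, 4.10
CA_SKIP_MIN = 4.2  # minimum CA(i)-CA(i+2) distance (open pseudo-angle)
SELF_CLASH = 3.4  # Angstrom, candidate too close to the growing chain


@dataclass
class ChainFragment:
    """An ordered N->C trace of residues with per-residue target scores.

    ``types`` holds one-letter residue codes, "X" for not-yet-sequenced.
    """

    cas: np.ndarray  # (L, 3)
    scores: np.ndarray  # (L,)
    types: list[str] = field(default_factory=list)
    id: str = ""

    def __post_init__(self) -> None:
        self.cas = np.asarray(self.cas, dtype=np.float64).reshape(-1, 3)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.cas) < 1:
            raise ValueError("fragment needs >= 1 residue")
        if not self.types:
            self.types = ["X"] * len(self.cas)
        if len(self.types) != len(self.cas) or len(self.scores) != len(self.cas):
            raise ValueError("types/scores length mismatch")
        d = self.ca_distances()
        if len(d) and (d.min() < CA_CA_MIN - 1e-6 or d.max() > CA_CA_MAX + 1e-6):
            raise ValueError(
                f"consecutive CA-CA distances must lie in "
                f"[{CA_CA_MIN}, {CA_CA_MAX}] A; got range "
                f"[{d.min():.2f}, {d.max():.2f}]"
            )

    def __len__(self) -> int:
        return len(self.cas)

    def ca_distances(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.cas, axis=0), axis=1)

    def backbone(self) -> tuple[np.ndarray, np.ndarray]:
        """Ideal-geometry N and C atoms along the trace."""
        if len(self) == 1:
            ca = self.cas[0]
            return (ca + np.array([-1.46, 0.0, 0.0]))[None, :], (
                ca + np.array([1.52, 0.0, 0.0])
            )[None, :]
        return place_backbone(self.cas)

    def reversed(self) -> "ChainFragment":
        """The same trace read C->N (N/C roles re-derived from the order)."""
        return ChainFragment(
            cas=self.cas[::-1].copy(),
            scores=self.scores[::-1].copy(),
            types=self.types[::-1],
            id=self.id,
        )

    def mean_score(self) -> float:
        return float(np.mean(self.scores))


@dataclass
class GrowSettings:
    step_candidates: int = 32  # 4 pseudo-angle x 8 pseudo-torsion samples
    score_floor: float = SENTINEL
    beam_width: int = 4
    max_length: int = 500

    def __post_init__(self) -> None:
        if min(self.step_candidates, self.beam_width, self.max_length) < 1:
            raise ValueError("all growth counts must be >= 1")


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    return v, np.cross(u, v)


def _candidate_dirs(u: np.ndarray, n_candidates: int) -> np.ndarray:
    """Deterministic cone of next-step directions around the tangent u.

    The pseudo-bond angle at the current CA (between the incoming and
    outgoing CA-CA vectors) is restricted to [75, 145] degrees, i.e. the
    outgoing direction deviates 35-105 degrees from the incoming tangent.
    """
    n_ang = 4
    n_tor = max(n_candidates // n_ang, 1)
    angles = np.deg2rad(np.linspace(35.0, 105.0, n_ang))
    torsions = np.arange(n_tor) * (2.0 * np.pi / n_tor)
    v, w = _perp_basis(u)
    dirs = []
    for a in angles:
        for t in torsions:
            dirs.append(np.cos(a) * u + np.sin(a) * (np.cos(t) * v + np.sin(t) * w))
    return np.array(dirs)


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def _path_screw_context(path: list[np.ndarray]):
    """Cached per-path part of the screw extrapolation: the last two steps
    and the inverse of their triad."""
    if len(path) < 3:
        return None
    s1 = path[-2] - path[-3]
    s2 = path[-1] - path[-2]
    c1 = _cross3(s1, s2)
    n1 = np.linalg.norm(c1)
    if n1 < 1e-6:
        return None
    A = np.stack([s1, s2, c1], axis=1)
    try:
        a_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return None
    return s2, c1, n1, a_inv


def _predict_u_out(path: list[np.ndarray], cand: np.ndarray, ctx=None) -> np.ndarray | None:
    """Outgoing tangent of a candidate, extrapolating the chain's local
    screw motion from the last two actual steps."""
    if ctx is None:
        ctx = _path_screw_context(path)
    if ctx is None:
        return None
    s2, c1, n1, a_inv = ctx
    s3 = cand - path[-1]
    c2 = _cross3(s2, s3)
    n2 = np.linalg.norm(c2)
    if n2 < 1e-6:
        return None
    B = np.stack([s2, s3, c2 * (n1 / n2)], axis=1)
    R = B @ a_inv
    # orthonormalise (the two step pairs need not be perfectly consistent)
    u, _, vt = np.linalg.svd(R)
    R = u @ vt
    if np.linalg.det(R) < 0:
        return None
    u_out = R @ s3
    n = np.linalg.norm(u_out)
    return u_out / n if n > 1e-9 else None


_HYP_ANGLES = np.deg2rad([35.0, 70.0, 105.0])
_HYP_TORSIONS = np.arange(5) * (2.0 * np.pi / 5)


def _u_out_hypotheses(u_in: np.ndarray) -> np.ndarray:
    """Fallback cone of outgoing-tangent hypotheses for early growth steps."""
    v, w = _perp_basis(u_in)
    out = []
    for a in _HYP_ANGLES:
        for t in _HYP_TORSIONS:
            out.append(np.cos(a) * u_in + np.sin(a) * (np.cos(t) * v + np.sin(t) * w))
    return np.array(out)


def _candidate_scores(
    dmap: DensityMap,
    ca_tpl: TargetTemplate,
    mode: str,
    paths: list[list[np.ndarray]],
    owner: list[int],
    cands: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Score candidate next-CAs, marginalising the unknown outgoing tangent.

    Returns (scores, best frame per candidate).
    """
    tips = np.array([paths[o][-1] for o in owner])
    u_in = cands - tips
    u_in = u_in / np.linalg.norm(u_in, axis=1, keepdims=True)
    ctxs = {o: _path_screw_context(paths[o]) for o in set(owner)}
    hyp_list: list[np.ndarray] = []
    counts = np.empty(len(cands), dtype=int)
    for i, cand in enumerate(cands):
        u_out = _predict_u_out(paths[owner[i]], cand, ctxs[owner[i]])
        hyps = u_out[None, :] if u_out is not None else _u_out_hypotheses(u_in[i])
        hyp_list.append(hyps)
        counts[i] = len(hyps)
    uout_all = np.vstack(hyp_list)
    rep = np.repeat(np.arange(len(cands)), counts)
    cand_all = cands[rep]
    uin_all = u_in[rep]
    d_n, d_c = backbone_dirs_from_tangents(uin_all, uout_all)
    axes, valid = frames_batch(
        cand_all + 1.46 * d_n, cand_all, cand_all + 1.52 * d_c
    )
    for j in np.flatnonzero(~valid):
        v, w = _perp_basis(uin_all[j])
        axes[j] = np.stack([uin_all[j], v, w], axis=1)
    sc = score_placements(dmap, ca_tpl, cand_all, axes, mode)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    scores = np.empty(len(cands))
    frames = np.empty((len(cands), 3, 3))
    for i, s in enumerate(starts):
        seg = sc[s : s + counts[i]]
        j = s + int(np.argmax(seg))
        scores[i] = sc[j]
        frames[i] = axes[j]
    return scores, frames


def _refine_tip(
    dmap: DensityMap,
    ca_tpl: TargetTemplate,
    path: list[np.ndarray],
    cand: np.ndarray,
    score: float,
    mode: str,
    steps: tuple[float, ...] = (0.4, 0.15),
    max_iter: int = 3,
) -> tuple[np.ndarray, float]:
    """Local hill-climb of a freshly proposed CA, keeping it at bonding
    distance from the current tip.  Converts the discrete direction cone
    into a placement at the local score optimum."""
    eye = np.eye(3)
    moves = np.vstack([eye, -eye])
    tip = path[-1]
    pos = cand.copy()
    for step in steps:
        for _ in range(max_iter):
            cand_pos = pos[None, :] + step * moves
            dist = np.linalg.norm(cand_pos - tip[None, :], axis=1)
            good = (dist >= CA_TRANS_MIN) & (dist <= CA_TRANS_MAX)
            if len(path) >= 2:
                d2 = np.linalg.norm(cand_pos - path[-2][None, :], axis=1)
                good &= d2 >= CA_SKIP_MIN
            if not np.any(good):
                break
            cand_pos = cand_pos[good]
            sc, _ = _candidate_scores(
                dmap, ca_tpl, mode, [path], [0] * len(cand_pos), cand_pos
            )
            best = int(np.argmax(sc))
            if sc[best] <= score + 1e-12:
                break
            score = float(sc[best])
            pos = cand_pos[best].copy()
    return pos, score


def _grow_one_way(
    dmap: DensityMap,
    path_init: list[np.ndarray],
    start_dir: np.ndarray,
    ca_tpl: TargetTemplate,
    settings: GrowSettings,
    mode: str,
    position_filter=None,
    max_new: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Beam-search extension from the tip of ``path_init`` along
    ``start_dir``.

    ``path_init`` supplies chain context (existing predecessor CAs) so the
    local screw motion is known from the first step when extending an
    existing fragment.  Returns the new CA positions (excluding the
    initial path) and their scores.
    """
    n_init = len(path_init)
    # beam states: (path [list of CA], per-residue scores, total, prev_dir)
    beams = [(list(path_init), [0.0] * n_init, 0.0, start_dir)]
    limit = settings.max_length if max_new is None else max_new
    for _ in range(limit):
        all_cands, all_tips, all_prev, owner = [], [], [], []
        for bi, (path, _, _, pdir) in enumerate(beams):
            tip = path[-1]
            u = pdir if len(path) == 1 else (tip - path[-2]) / np.linalg.norm(tip - path[-2])
            dirs = _candidate_dirs(u, settings.step_candidates)
            cands = tip + CA_CA * dirs
            # self-clash: keep away from the chain body (tip excepted)
            if len(path) > 2:
                body = np.array(path[:-1])
                dmin = np.min(
                    np.linalg.norm(cands[:, None, :] - body[None, :, :], axis=2), axis=1
                )
                cands = cands[dmin >= SELF_CLASH]
            if position_filter is not None and len(cands):
                cands = cands[position_filter(cands)]
            for c in cands:
                all_cands.append(c)
                all_tips.append(tip)
                all_prev.append(u)
                owner.append(bi)
        if not all_cands:
            break
        cands = np.array(all_cands)
        paths = [b[0] for b in beams]
        scores, _ = _candidate_scores(dmap, ca_tpl, mode, paths, owner, cands)
        order = np.argsort(-scores, kind="stable")
        new_beams = []
        for idx in order:
            if scores[idx] <= SENTINEL / 2:
                break
            path, res_scores, total, _ = beams[owner[idx]]
            tip = path[-1]
            pos, sc = _refine_tip(
                dmap, ca_tpl, path, cands[idx], float(scores[idx]), mode
            )
            if sc < settings.score_floor:
                continue
            new_beams.append(
                (
                    path + [pos],
                    res_scores + [sc],
                    total + sc,
                    (pos - tip) / np.linalg.norm(pos - tip),
                )
            )
            if len(new_beams) >= settings.beam_width:
                break
        if not new_beams:
            break
        beams = new_beams
    best = max(beams, key=lambda b: (len(b[0]), b[2]))
    path, res_scores, _, _ = best
    return np.array(path[n_init:]).reshape(-1, 3), np.array(res_scores[n_init:])


def grow_chain(
    dmap: DensityMap,
    seed: ScoredPlacement,
    ca_tpl: TargetTemplate,
    settings: GrowSettings,
    mode: str = "llk",
    position_filter=None,
    frag_id: str = "",
) -> ChainFragment:
    """Grow a fragment in both directions from a seed placement.

    The seed's orientation x axis defines the initial chain tangent; growth
    proceeds C-ward along it and N-ward against it, stopping when the best
    candidate falls below the score floor or the length cap is reached.
    Deterministic.
    """
    seed_score = float(
        score_placements(dmap, ca_tpl, seed.position, seed.orientation, mode)[0]
    )
    if seed_score <= SENTINEL / 2:
        return ChainFragment(
            cas=seed.position[None, :], scores=np.array([seed_score]), id=frag_id
        )
    u = seed.orientation[:, 0]
    fwd_ca, fwd_sc = _grow_one_way(
        dmap, [seed.position], u, ca_tpl, settings, mode, position_filter
    )
    bwd_ca, bwd_sc = _grow_one_way(
        dmap, [seed.position], -u, ca_tpl, settings, mode, position_filter
    )
    cas = np.vstack([bwd_ca[::-1], seed.position[None, :], fwd_ca])
    scores = np.concatenate([bwd_sc[::-1], [seed_score], fwd_sc])
    return ChainFragment(cas=cas, scores=scores, id=frag_id)


def extend_fragment(
    dmap: DensityMap,
    frag: ChainFragment,
    ca_tpl: TargetTemplate,
    settings: GrowSettings,
    mode: str = "llk",
    position_filter=None,
) -> ChainFragment:
    """Extend an existing fragment from both termini (model-extension path)."""
    if len(frag) < 2:
        return frag
    cas, scores, types = frag.cas, frag.scores, list(frag.types)
    ctx = min(len(cas), 4)
    u_c = (cas[-1] - cas[-2]) / np.linalg.norm(cas[-1] - cas[-2])
    add_ca, add_sc = _grow_one_way(
        dmap, [c for c in cas[-ctx:]], u_c, ca_tpl, settings, mode, position_filter
    )
    u_n = (cas[0] - cas[1]) / np.linalg.norm(cas[0] - cas[1])
    pre_ca, pre_sc = _grow_one_way(
        dmap, [c for c in cas[:ctx][::-1]], u_n, ca_tpl, settings, mode, position_filter
    )
    new_cas = np.vstack([pre_ca[::-1], cas, add_ca])
    new_sc = np.concatenate([pre_sc[::-1], scores, add_sc])
    new_types = ["X"] * len(pre_ca) + types + ["X"] * len(add_ca)
    return ChainFragment(cas=new_cas, scores=new_sc, types=new_types, id=frag.id)


def refine_fragment(
    dmap: DensityMap,
    frag: ChainFragment,
    ca_tpl: TargetTemplate,
    mode: str = "llk",
    sweeps: int = 3,
    steps: tuple[float, ...] = (0.5, 0.25, 0.12),
    max_iter: int = 5,
) -> ChainFragment:
    """Positional smoothing of a grown trace under the main-chain target.

    Each residue's frame is now fully determined by its actual neighbours,
    so residues placed early in growth (when the local chain direction was
    still a guess) can be re-optimised.  Moves are accepted only when they
    improve the target score and keep both neighbouring CA-CA distances in
    the allowed window.
    """
    if len(frag) < 3:
        return frag
    cas = frag.cas.copy()
    L = len(cas)
    moves = np.vstack([np.eye(3), -np.eye(3)])
    n_moves = len(moves)
    for _ in range(sweeps):
        for step in steps:
            for it in range(max_iter):
                parity = it % 2  # red-black: neighbours stay fixed
                n_at, c_at = place_backbone(cas)
                axes, _ = frames_batch(n_at, cas, c_at)
                cur = score_placements(dmap, ca_tpl, cas, axes, mode)
                rel_n = n_at - cas
                rel_c = c_at - cas
                cand = (cas[:, None, :] + step * moves[None, :, :]).reshape(-1, 3)
                rn = np.repeat(rel_n, n_moves, axis=0)
                rc = np.repeat(rel_c, n_moves, axis=0)
                ax2, v2 = frames_batch(cand + rn, cand, cand + rc)
                sc = score_placements(dmap, ca_tpl, cand, ax2, mode)
                sc[~v2] = SENTINEL
                sc = sc.reshape(L, n_moves)
                cand = cand.reshape(L, n_moves, 3)
                # neighbour-distance feasibility against current positions;
                # the i+/-2 bound keeps the pseudo-bond angle open and the
                # trace free of knots
                feas = np.ones((L, n_moves), dtype=bool)
                d_prev = np.linalg.norm(cand[1:] - cas[:-1, None, :], axis=2)
                feas[1:] &= (d_prev >= CA_TRANS_MIN) & (d_prev <= CA_TRANS_MAX)
                d_next = np.linalg.norm(cand[:-1] - cas[1:, None, :], axis=2)
                feas[:-1] &= (d_next >= CA_TRANS_MIN) & (d_next <= CA_TRANS_MAX)
                if L > 2:
                    d2p = np.linalg.norm(cand[2:] - cas[:-2, None, :], axis=2)
                    feas[2:] &= d2p >= CA_SKIP_MIN
                    d2n = np.linalg.norm(cand[:-2] - cas[2:, None, :], axis=2)
                    feas[:-2] &= d2n >= CA_SKIP_MIN
                sc[~feas] = SENTINEL
                best = np.argmax(sc, axis=1)
                improve = sc[np.arange(L), best] > cur + 1e-12
                improve &= np.arange(L) % 2 == parity
                if not np.any(improve):
                    continue
                cas[improve] = cand[improve, best[improve]]
    n_at, c_at = place_backbone(cas)
    axes, _ = frames_batch(n_at, cas, c_at)
    scores = score_placements(dmap, ca_tpl, cas, axes, mode)
    return ChainFragment(cas=cas, scores=scores, types=list(frag.types), id=frag.id)


def split_by_score(
    frag: ChainFragment, cut: float, min_len: int = 2
) -> list[ChainFragment]:
    """Break a trace at residues scoring below ``cut``.

    Growth is deliberately permissive (so it can cross locally weak
    density); the sub-threshold residues — junk tails, jumps between
    chains, stretches built into noise — are excised here, leaving the
    well-supported sub-fragments.
    """
    out: list[ChainFragment] = []
    start: int | None = None
    for i, s in enumerate(frag.scores):
        if s >= cut and start is None:
            start = i
        elif s < cut and start is not None:
            if i - start >= min_len:
                out.append(
                    ChainFragment(
                        frag.cas[start:i].copy(),
                        frag.scores[start:i].copy(),
                        list(frag.types[start:i]),
                        f"{frag.id}.{start}",
                    )
                )
            start = None
    if start is not None and len(frag) - start >= min_len:
        out.append(
            ChainFragment(
                frag.cas[start:].copy(),
                frag.scores[start:].copy(),
                list(frag.types[start:]),
                f"{frag.id}.{start}",
            )
        )
    return out


def orient_fragment(
    dmap: DensityMap, frag: ChainFragment, ca_tpl: TargetTemplate, mode: str = "llk"
) -> ChainFragment:
    """Pick the trace direction (N->C vs C->N) better supported by density.

    A CA trace alone is directionless, but the target statistics are
    asymmetric along the chain (carbonyl and CB lobes sit at fixed frame
    positions), so scoring the residue frames of both readings decides the
    direction.
    """
    if len(frag) < 3:
        return frag
    best = None
    best_val = -np.inf
    for cand in (frag, frag.reversed()):
        n_at, c_at = place_backbone(cand.cas)
        axes, valid = frames_batch(n_at, cand.cas, c_at)
        sc = score_placements(dmap, ca_tpl, cand.cas, axes, mode)
        ok = sc > SENTINEL / 2
        val = float(np.mean(sc[ok])) if np.any(ok) else -np.inf
        if val > best_val:
            best_val = val
            best = cand
    return best if best is not None else frag


def _legal_junction(cas: np.ndarray, j: int) -> bool:
    """Local geometry checks around a proposed junction residue j: bonded
    neighbours in the spacing window, no immediate foldback (the i+/-2
    distance stays open)."""
    lo = max(j - 2, 0)
    hi = min(j + 3, len(cas))
    seg = cas[lo:hi]
    d1 = np.linalg.norm(np.diff(seg, axis=0), axis=1)
    if len(d1) and (d1.min() < CA_CA_MIN or d1.max() > CA_CA_MAX):
        return False
    if len(seg) >= 3:
        d2 = np.linalg.norm(seg[2:] - seg[:-2], axis=1)
        if d2.min() < CA_SKIP_MIN:
            return False
    return True


def _try_join(a: ChainFragment, b: ChainFragment, tol: float) -> ChainFragment | None:
    """Concatenate b after a if their termini abut with legal geometry."""
    if len(a) < 2 or len(b) < 2:
        return None
    gap = float(np.linalg.norm(b.cas[0] - a.cas[-1]))
    if gap > max(tol, CA_CA_MAX):
        return None
    if gap <= tol and gap < CA_CA_MIN:
        # termini trace the same residue: drop the duplicate
        cas = np.vstack([a.cas, b.cas[1:]])
        if not _legal_junction(cas, len(a) - 1):
            return None
        return ChainFragment(
            cas=cas,
            scores=np.concatenate([a.scores, b.scores[1:]]),
            types=a.types + b.types[1:],
            id=a.id,
        )
    if CA_CA_MIN <= gap <= CA_CA_MAX:
        cas = np.vstack([a.cas, b.cas])
        if not (_legal_junction(cas, len(a) - 1) and _legal_junction(cas, len(a))):
            return None
        return ChainFragment(
            cas=cas,
            scores=np.concatenate([a.scores, b.scores]),
            types=a.types + b.types,
            id=a.id,
        )
    return None


def join_fragments(frags: list[ChainFragment], tol: float = 2.0) -> list[ChainFragment]:
    """Merge fragments whose termini abut with consistent directions.

    Termini closer than ``tol`` are treated as duplicated residues; termini
    at bonding distance (2.9-4.5 A) are concatenated directly.  Reversed
    matches are tried too, since grown traces have arbitrary direction.
    Order-stable and idempotent.
    """
    work = list(frags)
    merged = True
    while merged:
        merged = False
        for i in range(len(work)):
            if merged:
                break
            for j in range(len(work)):
                if i == j:
                    continue
                a, b = work[i], work[j]
                cand = (
                    _try_join(a, b, tol)
                    or _try_join(a, b.reversed(), tol)
                    or _try_join(b, a, tol)
                    or _try_join(b.reversed(), a, tol)
                )
                if cand is not None:
                    cand.id = a.id or b.id
                    work[i] = cand
                    del work[j]
                    merged = True
                    break
    return work


def trim_overlaps(
    frags: list[ChainFragment], clash_radius: float = 2.4, min_len: int = 3
) -> list[ChainFragment]:
    """Residue-level de-duplication: walking fragments in keep-best order,
    residues that duplicate an already-kept fragment's trace are excised
    and the remainder split into pieces.

    Complements :func:`prune_overlaps` (which drops whole fragments): a
    long trace that shadows a better fragment for part of its length keeps
    only its novel part.
    """
    order = sorted(
        range(len(frags)),
        key=lambda i: (-len(frags[i]), -frags[i].mean_score(), frags[i].id, i),
    )
    kept: list[ChainFragment] = []
    kept_cas: list[np.ndarray] = []
    for i in order:
        f = frags[i]
        if kept_cas:
            tree = cKDTree(np.vstack(kept_cas))
            d, _ = tree.query(f.cas)
            novel = d >= clash_radius
        else:
            novel = np.ones(len(f), dtype=bool)
        start = None
        pieces = []
        for j in range(len(f) + 1):
            if j < len(f) and novel[j]:
                if start is None:
                    start = j
            elif start is not None:
                if j - start >= min_len:
                    pieces.append(
                        ChainFragment(
                            f.cas[start:j].copy(),
                            f.scores[start:j].copy(),
                            list(f.types[start:j]),
                            f"{f.id}t{start}",
                        )
                    )
                start = None
        for p in pieces:
            kept.append(p)
            kept_cas.append(p.cas)
    # restore deterministic rank order
    return sorted(kept, key=lambda f: (-len(f), -f.mean_score(), f.id))


def prune_overlaps(frags: list[ChainFragment], clash_radius: float = 2.0) -> list[ChainFragment]:
    """Greedy keep-best de-duplication of fragments tracing the same density.

    Fragments are ranked by (length, mean score); a fragment is dropped when
    more than half of its CAs lie within ``clash_radius`` of an already-kept
    fragment's CAs.
    """
    order = sorted(
        range(len(frags)),
        key=lambda i: (-len(frags[i]), -frags[i].mean_score(), frags[i].id, i),
    )
    kept: list[ChainFragment] = []
    kept_cas: list[np.ndarray] = []
    for i in order:
        f = frags[i]
        if kept_cas:
            tree = cKDTree(np.vstack(kept_cas))
            d, _ = tree.query(f.cas)
            if np.mean(d < clash_radius) > 0.5:
                continue
        kept.append(f)
        kept_cas.append(f.cas)
    return kept


def filter_junk(
    frags: list[ChainFragment],
    min_length: int = 6,
    mask: DensityMap | None = None,
    mask_threshold: float = 0.5,
) -> list[ChainFragment]:
    """Remove short fragments and, when a mask is given, fragments built
    outside the volume of interest (over half their CAs in sub-threshold
    mask voxels)."""
    out = []
    for f in frags:
        if len(f) < min_length:
            continue
        if mask is not None:
            idx = np.rint(mask.grid_coords(f.cas)).astype(int)
            n = np.array(mask.shape)
            inside = np.all(idx >= 0, axis=1) & np.all(idx < n[None, :], axis=1)
            vals = np.full(len(f), -np.inf)
            vals[inside] = mask.values[tuple(idx[inside].T)]
            if np.mean(vals >= mask_threshold) <= 0.5:
                continue
        out.append(f)
    return out
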