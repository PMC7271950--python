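"""Placement scoring and seed search against a likelihood density target.

Two scoring modes exist for a :class:`~embuild.reference_targets.TargetTemplate`:

``llk``
    The plain log-likelihood score -sum_i (rho_i - mu_i)^2 / (2 sigma_i^2)
    (up to a placement-independent constant).  It assumes the map is on the
    same density scale as the reference used to build the target.

``correlation``
    The same quadratic form evaluated after refitting the map's scale and
    offset per placement by weighted least squares, which makes the score
    invariant under any affine intensity transform of the map.  Cryo-EM
    maps are not on an absolute scale, so this is the mode of choice there.

Seeds (starting points for chain growing) come from either

* :func:`fast_seed_search` — scans the map for very short ideal helix-like
  and strand-like CA motifs with a Pearson-correlation score that is
  intrinsically scale- and offset-free; or
* :func:`fourier_seed_search` — the exhaustive search, evaluating the llk
  target at every grid node for every orientation via FFT cross-correlation
  of the expanded quadratic form.  It reproduces direct scoring to
  numerical precision but inherits llk's scale sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import scipy.fft

from .map_io import DensityMap, interpolate_or_nan
from .reference_targets import TargetTemplate

__all__ = [
    "SENTINEL",
    "ScoredPlacement",
    "SeedSearchSettings",
    "rotation_set",
    "llk_score",
    "correlation_score",
    "score_placements",
    "refine_placement",
    "fast_seed_search",
    "fourier_seed_search",
]

SENTINEL = -1.0e30  # score for out-of-volume / degenerate placements


@dataclass
class ScoredPlacement:
    """A candidate position + orientation with its target score."""

    position: np.ndarray  # (3,) Angstrom
    orientation: np.ndarray  # (3, 3) rotation, canonical -> world
    score: float
    mode: str  # "llk" | "correlation" | "fast"


@dataclass
class SeedSearchSettings:
    n_seeds: int = 20
    n_rotations: int = 288
    score_floor: float = SENTINEL
    nms_radius: float = 2.0  # Angstrom, below the 3.8 A CA-CA spacing
    prefilter: int = 800  # density-ranked candidate nodes for fast mode
    coarse_rotations: int = 72  # first-pass rotation count for fast mode

    def __post_init__(self) -> None:
        if self.n_seeds < 1 or self.n_rotations < 1:
            raise ValueError("n_seeds and n_rotations must be >= 1")


def rotation_set(n: int = 288) -> np.ndarray:
    """Deterministic quasi-uniform set of n rotation matrices (SO(3)).

    Super-Fibonacci sampling: low-discrepancy, identical across runs for a
    given n.
    """
    phi = np.sqrt(2.0)
    psi = 1.533751168755204288118041
    i = np.arange(n) + 0.5
    t = i / n
    d = 2.0 * np.pi * i
    r = np.sqrt(t)
    rr = np.sqrt(1.0 - t)
    a = d / phi
    b = d / psi
    quat = np.stack([r * np.sin(a), r * np.cos(a), rr * np.sin(b), rr * np.cos(b)], axis=1)
    from scipy.spatial.transform import Rotation

    return Rotation.from_quat(quat).as_matrix()


def _sample(dmap: DensityMap, tpl: TargetTemplate, positions: np.ndarray, rotations: np.ndarray) -> np.ndarray:
    """Sampled density (n, m) at every placement's transformed offsets.

    Out-of-volume samples are NaN.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    rotations = np.asarray(rotations, dtype=np.float64)
    if rotations.ndim == 2:
        rotations = np.broadcast_to(rotations, (len(positions), 3, 3))
    pts = positions[:, None, :] + np.einsum("nij,mj->nmi", rotations, tpl.offsets)
    rho = interpolate_or_nan(dmap, pts.reshape(-1, 3))
    return rho.reshape(len(positions), -1)


def _llk_from_samples(rho: np.ndarray, tpl: TargetTemplate) -> np.ndarray:
    w = 0.5 / tpl.variance
    scores = -np.nansum(w[None, :] * (rho - tpl.mean[None, :]) ** 2, axis=1)
    scores[np.any(np.isnan(rho), axis=1)] = SENTINEL
    return scores


def _correlation_from_samples(
    rho: np.ndarray, tpl: TargetTemplate, map_scale: float = 0.0
) -> np.ndarray:
    """Refit map scale/offset per placement, then evaluate the llk form.

    ``map_scale`` (the map's global dynamic range) anchors the degeneracy
    test so it is invariant under affine transforms of the map.
    """
    w = 1.0 / tpl.variance
    sw = np.sum(w)
    mu_c = tpl.mean - np.sum(w * tpl.mean) / sw
    bad = np.any(np.isnan(rho), axis=1)
    rho = np.where(np.isnan(rho), 0.0, rho)
    # centred formulation: with rho_c and mu_c the weighted means are zero,
    # the offset parameter drops out, and the large common offset of the
    # samples never enters a product (numerically stable, so the score is
    # affine-invariant to near machine precision)
    rho_c = rho - ((rho @ w) / sw)[:, None]
    s_rr = (rho_c**2) @ w
    s_rm = rho_c @ (w * mu_c)
    s_mm = float(np.sum(w * mu_c**2))
    # degeneracy: no usable spread in the sampled density, judged against
    # the map's dynamic range (both sides scale as a^2 and ignore b under
    # rho -> a rho + b, so the classification is affine-invariant)
    degenerate = s_rr <= sw * (1e-6 * map_scale) ** 2 + 1e-30
    safe = np.where(degenerate, 1.0, s_rr)
    scores = -0.5 * (s_mm - s_rm**2 / safe)
    scores[bad | degenerate] = SENTINEL
    return scores


def score_placements(
    dmap: DensityMap,
    tpl: TargetTemplate,
    positions: np.ndarray,
    rotations: np.ndarray,
    mode: str = "llk",
) -> np.ndarray:
    """Vectorised scoring of many placements (one rotation each or shared).

    ``tpl`` may be a single template or a sequence of templates; in the
    latter case each placement gets the best score over the templates
    (best-of-class scoring for conformation-conditioned targets).
    """
    if isinstance(tpl, (list, tuple)):
        if len(tpl) > 1 and all(
            np.array_equal(t.offsets, tpl[0].offsets) for t in tpl[1:]
        ):
            # shared offset grid: sample the map once, evaluate every class
            rho = _sample(dmap, tpl[0], positions, rotations)
            if mode == "llk":
                return np.max(np.stack([_llk_from_samples(rho, t) for t in tpl]), axis=0)
            scale = float(np.ptp(dmap.values))
            return np.max(
                np.stack([_correlation_from_samples(rho, t, scale) for t in tpl]), axis=0
            )
        stacked = np.stack(
            [score_placements(dmap, t, positions, rotations, mode) for t in tpl]
        )
        return np.max(stacked, axis=0)
    rho = _sample(dmap, tpl, positions, rotations)
    if mode == "llk":
        return _llk_from_samples(rho, tpl)
    if mode == "correlation":
        return _correlation_from_samples(rho, tpl, float(np.ptp(dmap.values)))
    raise ValueError(f"unknown scoring mode {mode!r}")


def llk_score(dmap: DensityMap, tpl: TargetTemplate, position: np.ndarray, orientation: np.ndarray) -> float:
    """Log-likelihood score of one placement (higher is better).

    Returns the sentinel minimum when any transformed offset leaves the
    interpolatable volume.
    """
    return float(score_placements(dmap, tpl, position, orientation, "llk")[0])


def correlation_score(dmap: DensityMap, tpl: TargetTemplate, position: np.ndarray, orientation: np.ndarray) -> float:
    """Scale/offset-corrected llk score of one placement.

    Invariant under rho -> a * rho + b of the whole map (a > 0).
    """
    return float(score_placements(dmap, tpl, position, orientation, "correlation")[0])


def _non_max_suppress(
    positions: np.ndarray, scores: np.ndarray, radius: float, n_keep: int, order_keys: np.ndarray
) -> np.ndarray:
    """Greedy NMS; ties broken by score then lexicographic grid index."""
    order = np.lexsort(tuple(order_keys.T[::-1]) + (-scores,))
    kept: list[int] = []
    for idx in order:
        p = positions[idx]
        if all(np.linalg.norm(p - positions[j]) >= radius for j in kept):
            kept.append(int(idx))
            if len(kept) >= n_keep:
                break
    return np.array(kept, dtype=int)


def refine_placement(
    dmap: DensityMap,
    tpl: TargetTemplate,
    placement: ScoredPlacement,
    mode: str = "llk",
    trans_steps: tuple[float, ...] = (0.6, 0.3, 0.15),
    rot_steps_deg: tuple[float, ...] = (12.0, 6.0, 3.0),
    max_iter: int = 8,
) -> ScoredPlacement:
    """Deterministic local hill-climb of a placement (coarse-to-fine).

    At each level the position is nudged along the coordinate axes and the
    orientation by small rotations about them, accepting any improvement;
    step sizes then halve.  Converts grid/rotation-set discretisation into
    placements at the score optimum.
    """
    from scipy.spatial.transform import Rotation

    pos = placement.position.astype(np.float64).copy()
    rot = placement.orientation.astype(np.float64).copy()
    score = float(score_placements(dmap, tpl, pos, rot, mode)[0])
    eye = np.eye(3)
    for ts, rs in zip(trans_steps, rot_steps_deg):
        rotvecs = np.deg2rad(rs) * np.vstack([eye, -eye])
        perturb = Rotation.from_rotvec(rotvecs).as_matrix()
        for _ in range(max_iter):
            cand_pos = np.vstack([pos + ts * d for d in np.vstack([eye, -eye])] + [pos] * 6)
            cand_rot = np.concatenate([np.broadcast_to(rot, (6, 3, 3)), perturb @ rot])
            sc = score_placements(dmap, tpl, cand_pos, cand_rot, mode)
            best = int(np.argmax(sc))
            if sc[best] <= score + 1e-12:
                break
            score = float(sc[best])
            pos, rot = cand_pos[best].copy(), cand_rot[best].copy()
    return ScoredPlacement(position=pos, orientation=rot, score=score, mode=mode)


# ---------------------------------------------------------------------------
# fast mode: short helix / strand CA-motif search, scale invariant


def _mini_template(kind: str, resolution: float) -> tuple[TargetTemplate, np.ndarray, np.ndarray]:
    """4-residue ideal helix/strand CA pattern rendered at the working
    resolution, in a canonical principal-axis frame.

    Returns the template plus the canonical-frame position and residue
    frame of an interior CA, used to report seed placements *on* a CA
    rather than at the motif centroid.
    """
    from .geometry import place_backbone, residue_frame
    from .synthetic import _helix_ca, _strand_ca, gaussian_b_total

    cas = _helix_ca(4) if kind == "helix" else _strand_ca(4)
    cas = cas - cas.mean(axis=0)
    # canonical orientation: principal axes along x, y, z
    u, _, vt = np.linalg.svd(cas, full_matrices=False)
    rot = vt.T
    if np.linalg.det(rot) < 0:
        rot[:, 2] *= -1
    cas = cas @ rot
    radius = float(np.max(np.linalg.norm(cas, axis=1))) + 1.5
    step = 1.6
    k = int(np.floor(radius / step))
    pts = np.array(
        [
            (i * step, j * step, l * step)
            for i, j, l in product(range(-k, k + 1), repeat=3)
            if (i * step) ** 2 + (j * step) ** 2 + (l * step) ** 2 <= radius**2
        ]
    )
    sigma = np.sqrt(gaussian_b_total(resolution) / (8.0 * np.pi**2))
    d2 = np.sum((pts[:, None, :] - cas[None, :, :]) ** 2, axis=2)
    mu = np.sum(np.exp(-d2 / (2.0 * sigma**2)), axis=1)
    tpl = TargetTemplate(
        offsets=pts,
        mean=mu,
        variance=np.ones_like(mu),
        radius=radius,
        centre_role="CA",
        resolution=resolution,
    )
    n_at, c_at = place_backbone(cas)
    anchor_frame = residue_frame(n_at[1], cas[1], c_at[1], "CA")
    return tpl, cas[1], anchor_frame.axes


def fast_seed_search(
    dmap: DensityMap,
    settings: SeedSearchSettings | None = None,
    resolution: float = 3.0,
) -> list[ScoredPlacement]:
    """Seed search for very short helix-like and strand-like CA features.

    Scores candidate placements by the Pearson correlation between the
    sampled map density and the mini-template density, which is independent
    of the map's scale and offset.  Candidate nodes are the density-ranked
    top of the grid (density rank is preserved by any affine transform with
    positive scale, so the ranking is itself scale-free).  Deterministic.
    """
    settings = settings or SeedSearchSettings()
    if float(np.ptp(dmap.values)) == 0.0:
        return []
    minis = [_mini_template("helix", resolution), _mini_template("strand", resolution)]
    templates = [m[0] for m in minis]
    margin = max(t.radius for t in templates)
    shape = np.array(dmap.shape)
    lo = np.ceil(margin / dmap.spacing).astype(int)
    hi = shape - 1 - lo
    if np.any(lo > hi):
        return []
    sub = dmap.values[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    idx = np.argwhere(np.ones_like(sub, dtype=bool)) + lo
    dens = sub.ravel()
    k = min(settings.prefilter, len(dens))
    top = np.argpartition(-dens, k - 1)[:k]
    nodes = idx[top]
    node_pos = dmap.origin + nodes * dmap.spacing

    def scan(nodes, node_pos, rots):
        best_score = np.full(len(nodes), -np.inf)
        best_rot = np.zeros(len(nodes), dtype=int)
        best_tpl = np.zeros(len(nodes), dtype=int)
        for ti, tpl in enumerate(templates):
            mu_c = tpl.mean - tpl.mean.mean()
            mu_norm = np.linalg.norm(mu_c)
            for ri, rot in enumerate(rots):
                rho = _sample(dmap, tpl, node_pos, rot)
                rho_c = rho - rho.mean(axis=1, keepdims=True)
                denom = np.linalg.norm(rho_c, axis=1) * mu_norm
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = (rho_c @ mu_c) / denom
                r = np.where((denom <= 1e-12) | np.isnan(r), -1.0, r)
                better = r > best_score
                best_score[better] = r[better]
                best_rot[better] = ri
                best_tpl[better] = ti
        return best_score, best_rot, best_tpl

    # coarse pass over all candidate nodes, full rotation set only on the
    # most promising ones (the refinement stage absorbs the residual
    # orientation error)
    coarse, _, _ = scan(nodes, node_pos, rotation_set(settings.coarse_rotations))
    n_fine = min(len(nodes), max(6 * settings.n_seeds, 60))
    fine_sel = np.argsort(-coarse, kind="stable")[:n_fine]
    nodes = nodes[fine_sel]
    node_pos = node_pos[fine_sel]
    rots = rotation_set(settings.n_rotations)
    best_score, best_rot, best_tpl = scan(nodes, node_pos, rots)
    ok = best_score >= max(settings.score_floor, -1.0)
    if not np.any(ok):
        return []
    # report each placement anchored on an interior CA of the motif, with
    # that residue's frame as the seed orientation
    anchors = np.empty((len(nodes), 3))
    frames = np.empty((len(nodes), 3, 3))
    for i in np.flatnonzero(ok):
        rot = rots[best_rot[i]]
        _, ca_local, axes_local = minis[best_tpl[i]]
        anchors[i] = node_pos[i] + rot @ ca_local
        frames[i] = rot @ axes_local
    keep = _non_max_suppress(
        anchors[ok], best_score[ok], settings.nms_radius, settings.n_seeds, nodes[ok]
    )
    sel = np.flatnonzero(ok)[keep]
    return [
        ScoredPlacement(
            position=anchors[i].copy(),
            orientation=frames[i].copy(),
            score=float(best_score[i]),
            mode="fast",
        )
        for i in sel
    ]


# ---------------------------------------------------------------------------
# exhaustive Fourier search: llk target at every grid node via FFT


_CORNERS = np.array(list(product((0, 1), repeat=3)), dtype=np.int64)  # (8, 3)


def _trilinear_kernels(
    g: np.ndarray, w_quad: np.ndarray, w_lin: np.ndarray, shape: tuple[int, int, int]
) -> tuple[dict[tuple[int, int, int], np.ndarray], np.ndarray]:
    """Cross-correlation kernels of the expanded quadratic llk form.

    ``g`` are template offsets in (fractional) grid units.  Because scoring
    interpolates trilinearly, rho(x + d) is linear in the 8 surrounding grid
    values; squaring it yields products of grid values at small lags, so the
    quadratic term decomposes into one kernel per lag delta.  Only
    lexicographically positive lags are kept (the symmetric partner is
    folded in with weight 2).
    """
    n = np.array(shape)
    base = np.floor(g).astype(np.int64)
    frac = g - base
    # per-offset trilinear corner weights (m, 8)
    cw = np.ones((len(g), 8))
    for axis in range(3):
        f = frac[:, axis]
        cw *= np.where(_CORNERS[None, :, axis] == 1, f[:, None], 1.0 - f[:, None])
    flat_shape = int(np.prod(n))

    def flat_idx(cells: np.ndarray) -> np.ndarray:
        c = cells % n
        return (c[..., 0] * n[1] + c[..., 1]) * n[2] + c[..., 2]

    quad: dict[tuple[int, int, int], np.ndarray] = {}
    for ga in range(8):
        for gb in range(8):
            delta = tuple(int(v) for v in _CORNERS[gb] - _CORNERS[ga])
            if delta < (0, 0, 0):
                continue  # folded into the positive-lag partner
            mult = 1.0 if delta == (0, 0, 0) else 2.0
            if delta == (0, 0, 0) and ga != gb:
                continue
            arr = quad.setdefault(delta, np.zeros(flat_shape))
            np.add.at(arr, flat_idx(base + _CORNERS[ga]), mult * w_quad * cw[:, ga] * cw[:, gb])
    lin = np.zeros(flat_shape)
    for ga in range(8):
        np.add.at(lin, flat_idx(base + _CORNERS[ga]), w_lin * cw[:, ga])
    return {k: v.reshape(shape) for k, v in quad.items()}, lin.reshape(shape)


def fourier_seed_search(
    dmap: DensityMap,
    tpl: TargetTemplate,
    settings: SeedSearchSettings | None = None,
) -> list[ScoredPlacement]:
    """Exhaustive llk search over all grid nodes and all orientations.

    For each orientation the quadratic form is expanded into convolutions
    (sum rho^2 / sigma^2, sum mu rho / sigma^2 and a constant), each
    evaluated at every node simultaneously with FFTs; node scores equal
    :func:`llk_score` at that node to numerical precision.  Nodes whose
    transformed offsets would leave the volume get the sentinel score.
    Not scale/offset invariant.
    """
    settings = settings or SeedSearchSettings()
    if float(np.ptp(dmap.values)) == 0.0:
        return []
    shape = dmap.shape
    n = np.array(shape)
    rho = dmap.values
    rots = rotation_set(settings.n_rotations)
    w_quad = 0.5 / tpl.variance
    w_lin = tpl.mean / tpl.variance  # carries the factor 2 * 0.5
    const = float(np.sum(0.5 * tpl.mean**2 / tpl.variance))
    # FFTs of the lagged product maps rho(x) * rho(x + delta)
    deltas = [
        d
        for d in product((-1, 0, 1), repeat=3)
        if tuple(d) >= (0, 0, 0)
    ]
    fp: dict[tuple[int, int, int], np.ndarray] = {}
    for d in deltas:
        p = rho * np.roll(rho, shift=tuple(-np.array(d)), axis=(0, 1, 2))
        fp[d] = scipy.fft.rfftn(p)
    fr = scipy.fft.rfftn(rho)

    best_score = np.full(shape, -np.inf)
    best_rot = np.zeros(shape, dtype=np.int32)
    for ri, rot in enumerate(rots):
        g = (tpl.offsets @ rot.T) / dmap.spacing
        quad_k, lin_k = _trilinear_kernels(g, w_quad, w_lin, shape)
        acc = -conj_mul(lin_k, fr)
        for d, arr in quad_k.items():
            acc += conj_mul(arr, fp[d])
        field = scipy.fft.irfftn(acc, s=shape)
        scores = -(field + const)
        # validity: node + offset must stay inside [0, n-1] on every axis
        lo = np.maximum(np.ceil(-np.min(g, axis=0) - 1e-9), 0).astype(int)
        hi = np.minimum(np.floor(n - 1 - np.max(g, axis=0) + 1e-9), n - 1).astype(int)
        mask = np.zeros(shape, dtype=bool)
        if np.all(lo <= hi):
            mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
        scores[~mask] = SENTINEL
        better = scores > best_score
        best_score[better] = scores[better]
        best_rot[better] = ri
    flat_ok = best_score > max(settings.score_floor, SENTINEL / 2)
    if not np.any(flat_ok):
        return []
    nodes = np.argwhere(flat_ok)
    scores = best_score[flat_ok]
    node_pos = dmap.origin + nodes * dmap.spacing
    keep = _non_max_suppress(node_pos, scores, settings.nms_radius, settings.n_seeds, nodes)
    return [
        ScoredPlacement(
            position=node_pos[i].copy(),
            orientation=rots[best_rot[tuple(nodes[i])]].copy(),
            score=float(scores[i]),
            mode="llk",
        )
        for i in keep
    ]


def conj_mul(kernel: np.ndarray, f_other: np.ndarray) -> np.ndarray:
    """conj(FFT(kernel)) * f_other — the cross-correlation spectrum."""
    return np.conj(scipy.fft.rfftn(kernel)) * f_other


def node_scores_fourier(dmap: DensityMap, tpl: TargetTemplate, rot: np.ndarray) -> np.ndarray:
    """llk score at every grid node for one orientation (FFT route).

    Exposed for oracle tests against direct scoring.
    """
    shape = dmap.shape
    n = np.array(shape)
    rho = dmap.values
    w_quad = 0.5 / tpl.variance
    w_lin = tpl.mean / tpl.variance
    const = float(np.sum(0.5 * tpl.mean**2 / tpl.variance))
    g = (tpl.offsets @ rot.T) / dmap.spacing
    quad_k, lin_k = _trilinear_kernels(g, w_quad, w_lin, shape)
    fr = scipy.fft.rfftn(rho)
    acc = -conj_mul(lin_k, fr)
    for d, arr in quad_k.items():
        p = rho * np.roll(rho, shift=tuple(-np.array(d)), axis=(0, 1, 2))
        acc += conj_mul(arr, scipy.fft.rfftn(p))
    field = scipy.fft.irfftn(acc, s=shape)
    scores = -(field + const)
    lo = np.maximum(np.ceil(-np.min(g, axis=0) - 1e-9), 0).astype(int)
    hi = np.minimum(np.floor(n - 1 - np.max(g, axis=0) + 1e-9), n - 1).astype(int)
    mask = np.zeros(shape, dtype=bool)
    if np.all(lo <= hi):
        mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
    scores[~mask] = SENTINEL
    return scores
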