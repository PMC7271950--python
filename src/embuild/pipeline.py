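"""The iterative model-building pipeline.

One cycle is: find chain seeds, grow/extend fragments under the main-chain
target, merge and clean them, dock the sequence, and tidy the model with a
per-residue rigid real-space fit.  The map is prepared once (resolution
truncation plus optional global sharpening); the model from each cycle
seeds the next, and the cycle whose model best explains the map — by
shell-count-weighted average Fourier shell correlation (FSC_average)
between the map and a density rendering of the model — is reported as the
result.

`known-structure` selections and a `nonprotein-radius` preserve parts of an
input model verbatim and keep new main chain out of an exclusion radius
around them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import gemmi
import numpy as np

from . import map_io
from .build import (
    ChainFragment,
    GrowSettings,
    extend_fragment,
    filter_junk,
    grow_chain,
    join_fragments,
    orient_fragment,
    prune_overlaps,
    refine_fragment,
    trim_overlaps,
    split_by_score,
)
from .geometry import frames_batch, ideal_cb_position, place_backbone
from .map_io import DensityMap
from .reference_targets import (
    ReferenceData,
    TargetTemplate,
    build_ca_target,
    build_ca_targets_by_conformation,
    build_cb_targets,
)
from .search import (
    SENTINEL,
    SeedSearchSettings,
    fast_seed_search,
    fourier_seed_search,
    refine_placement,
    rotation_set,
    score_placements,
)
from .sequencing import align_to_sequence, apply_assignment, score_residue_types
from .synthetic import AA_THREE, make_map

__all__ = [
    "BuildSettings",
    "CycleResult",
    "prepare_map",
    "compute_fsc",
    "run_cycle",
    "run_pipeline",
    "apply_model_controls",
]

logger = logging.getLogger(__name__)

# growth floor, segment cut and end-trim thresholds as fractions of the
# background (null) score median (scores are <= 0, so a fraction < 1 of the
# null median is *better* than background).  Growth stops near background
# level; the cut and trim then excise residues not clearly better than
# background.  Null-anchoring makes the thresholds scale-free.
FLOOR_FRACTION = 0.8
CUT_FRACTION = 0.8
TRIM_FRACTION = 0.65
EXTEND_FRACTION = 0.6


@dataclass
class BuildSettings:
    """Inputs of a pipeline run (mirrors the tool's command line)."""

    resolution: float
    sharpen_b: float = 0.0  # A^2; 0 = no sharpening, < 0 sharpens
    cycles: int = 5
    correlation_mode: bool = True
    fast_mode: bool = True
    seed: int = 0
    n_seeds: int = 40
    n_rotations: int = 288
    beam_width: int = 4
    step_candidates: int = 32
    min_fragment_length: int = 6
    sequence_threshold: float = 1.5  # z-unit docking margin, see sequencing
    mask: DensityMap | None = None
    mask_threshold: float = 0.5
    known_structure: list[str] = field(default_factory=list)
    nonprotein_radius: float | None = None

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def score_mode(self) -> str:
        return "correlation" if self.correlation_mode else "llk"


@dataclass
class TargetSet:
    """The search targets a cycle needs.

    ``ca`` is the conformation-conditioned list used for growing and
    refinement (best-of-class scoring); ``ca_blend`` the single blended
    target (used where one template is required, e.g. the Fourier seed
    search); ``cb`` the per-type side-chain classification targets.
    """

    ca: list[TargetTemplate]
    ca_blend: TargetTemplate
    cb: dict[str, TargetTemplate]

    @classmethod
    def from_reference(cls, reference: ReferenceData) -> "TargetSet":
        return cls(
            ca=build_ca_targets_by_conformation(reference),
            ca_blend=build_ca_target(reference),
            cb=build_cb_targets(reference, variance_floor_frac=0.08),
        )


@dataclass
class CycleResult:
    model: gemmi.Structure
    fragments: list[ChainFragment]
    fsc_average: float
    stats: dict

    def __post_init__(self) -> None:
        if not np.isfinite(self.fsc_average):
            raise ValueError("fsc_average must be finite")


def prepare_map(dmap: DensityMap, settings: BuildSettings) -> DensityMap:
    """Resolution truncation + optional global sharpening (via the
    structure-factor store), back onto the same grid."""
    sf = map_io.map_to_structure_factors(dmap, settings.resolution)
    sf = map_io.apply_sharpening(sf, settings.sharpen_b)
    return map_io.structure_factors_to_map(
        sf, dmap.shape, spacing=dmap.spacing, origin=dmap.origin
    )


def compute_fsc(
    map_a: DensityMap, map_b: DensityMap, n_shells: int = 20
) -> tuple[np.ndarray, float]:
    """Fourier shell correlation and its reflection-count-weighted average.

    Shells are equal-width in 1/d up to the Nyquist sphere of the grid; the
    DC term is excluded.  Returns (per-shell FSC, FSC_average).
    """
    if not map_a.same_geometry(map_b):
        raise ValueError("maps must share grid geometry")
    fa = np.fft.fftn(map_a.values)
    fb = np.fft.fftn(map_b.values)
    h, k, l = map_io._miller_grids(map_a.shape)
    cell = map_a.cell
    s = np.sqrt((h / cell[0]) ** 2 + (k / cell[1]) ** 2 + (l / cell[2]) ** 2)
    s_max = 1.0 / (2.0 * float(np.max(map_a.spacing)))
    edges = np.linspace(0.0, s_max, n_shells + 1)
    fsc = np.full(n_shells, np.nan)
    counts = np.zeros(n_shells, dtype=int)
    for i in range(n_shells):
        sel = (s > edges[i]) & (s <= edges[i + 1]) if i > 0 else (
            (s > 0) & (s <= edges[1])
        )
        n = int(np.sum(sel))
        if n == 0:
            continue
        num = np.real(np.sum(fa[sel] * np.conj(fb[sel])))
        den = np.sqrt(np.sum(np.abs(fa[sel]) ** 2) * np.sum(np.abs(fb[sel]) ** 2))
        counts[i] = n
        fsc[i] = num / den if den > 0 else 0.0
    valid = counts > 0
    if not np.any(valid) or np.all(np.isnan(fsc[valid])):
        return fsc, 0.0
    avg = float(np.sum(fsc[valid] * counts[valid]) / np.sum(counts[valid]))
    return fsc, avg


def render_model(
    model: gemmi.Structure, like: DensityMap, resolution: float
) -> DensityMap:
    """Density rendering of a model on an existing grid (for model-vs-map
    FSC)."""
    return make_map(model, resolution=resolution, like=like, clip=True)


# ---------------------------------------------------------------------------
# known-structure / nonprotein-radius model controls

_SPEC_RE = re.compile(
    r"^(?P<chain>[A-Za-z0-9*]+)"
    r"(?:/(?P<first>\d+|\*)-(?P<last>\d+|\*))?"
    r"(?:/(?P<atom>[A-Za-z0-9'*]+))?"
    r"(?::(?P<radius>[0-9.]+))?$"
)


def _parse_selection(spec: str) -> tuple[str, int | None, int | None, str, float]:
    m = _SPEC_RE.match(spec.strip())
    if not m:
        raise ValueError(
            f"malformed known-structure selection {spec!r}; expected "
            "chain[/first-last][/atom][:radius] with * wildcards"
        )
    first = m.group("first")
    last = m.group("last")
    return (
        m.group("chain"),
        None if first in (None, "*") else int(first),
        None if last in (None, "*") else int(last),
        m.group("atom") or "*",
        float(m.group("radius") or 0.0),
    )


def apply_model_controls(
    model: gemmi.Structure | None, settings: BuildSettings
) -> tuple[gemmi.Structure, list[tuple[np.ndarray, float]]]:
    """Atoms to preserve verbatim, plus exclusion zones for new main chain.

    known-structure selections (chain[/range][/atom]:radius) preserve the
    matching atoms; nonprotein-radius preserves everything that is neither
    protein nor water.  Each returned zone is (atom positions, radius).
    """
    preserved = gemmi.Structure()
    preserved.add_model(gemmi.Model("1"))
    zones: list[tuple[np.ndarray, float]] = []
    if model is None:
        return preserved, zones
    selections = [_parse_selection(s) for s in settings.known_structure]
    for chain in model[0]:
        out_chain = gemmi.Chain(chain.name)
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            is_protein = info is not None and info.is_amino_acid()
            is_water = info is not None and info.is_water()
            keep_atoms = []
            zone_radius = 0.0
            for cname, first, last, atom, radius in selections:
                if cname != "*" and cname != chain.name:
                    continue
                num = res.seqid.num
                if first is not None and num < first:
                    continue
                if last is not None and num > last:
                    continue
                for a in res:
                    if atom == "*" or a.name == atom:
                        keep_atoms.append(a)
                zone_radius = max(zone_radius, radius)
            if (
                settings.nonprotein_radius is not None
                and not is_protein
                and not is_water
            ):
                keep_atoms.extend(list(res))
                zone_radius = max(zone_radius, settings.nonprotein_radius)
            if keep_atoms:
                out_res = gemmi.Residue()
                out_res.name = res.name
                out_res.seqid = res.seqid
                seen = set()
                for a in keep_atoms:
                    if a.name in seen:
                        continue
                    seen.add(a.name)
                    out_res.add_atom(a.clone())
                out_chain.add_residue(out_res)
                if zone_radius > 0:
                    pos = np.array(
                        [[a.pos.x, a.pos.y, a.pos.z] for a in out_res]
                    )
                    zones.append((pos, zone_radius))
        if len(out_chain) > 0:
            preserved[0].add_chain(out_chain)
    return preserved, zones


def _exclusion_filter(zones: list[tuple[np.ndarray, float]]):
    if not zones:
        return None

    def keep(cands: np.ndarray) -> np.ndarray:
        ok = np.ones(len(cands), dtype=bool)
        for pos, radius in zones:
            d = np.min(
                np.linalg.norm(cands[:, None, :] - pos[None, :, :], axis=2), axis=1
            )
            ok &= d >= radius
        return ok

    return keep


# ---------------------------------------------------------------------------
# cycle machinery


def model_to_fragments(model: gemmi.Structure) -> list[ChainFragment]:
    """Convert protein chains of a model into chain fragments (split where
    the CA trace breaks)."""
    from .synthetic import THREE_TO_ONE

    frags: list[ChainFragment] = []
    for chain in model[0]:
        cas, types = [], []
        for res in chain:
            ca = next((a for a in res if a.name == "CA"), None)
            info = gemmi.find_tabulated_residue(res.name)
            if ca is None or (info is not None and not info.is_amino_acid()):
                continue
            cas.append([ca.pos.x, ca.pos.y, ca.pos.z])
            types.append(THREE_TO_ONE.get(res.name, "X"))
        if len(cas) < 2:
            continue
        cas = np.array(cas)
        d = np.linalg.norm(np.diff(cas, axis=0), axis=1)
        breaks = np.flatnonzero((d < 2.9) | (d > 4.5))
        start = 0
        for b in list(breaks) + [len(cas) - 1]:
            end = b + 1
            if end - start >= 2:
                frags.append(
                    ChainFragment(
                        cas=cas[start:end].copy(),
                        scores=np.zeros(end - start),
                        types=types[start:end],
                        id=f"{chain.name}.{start}",
                    )
                )
            start = end
    return frags


def fragments_to_model(
    frags: list[ChainFragment], preserved: gemmi.Structure
) -> gemmi.Structure:
    """Assemble fragments (+ preserved atoms, verbatim) into a structure."""
    st = gemmi.Structure()
    st.name = "embuild"
    model = gemmi.Model("1")
    used = set()
    for chain in preserved[0]:
        model.add_chain(gemmi.Chain(chain.name))
        for res in chain:
            model[chain.name].add_residue(res)
        used.add(chain.name)
    names = [c for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"]
    ni = 0
    for frag in frags:
        while ni < len(names) and names[ni] in used:
            ni += 1
        cname = names[ni] if ni < len(names) else f"X{len(used)}"
        ni += 1
        used.add(cname)
        chain = gemmi.Chain(cname)
        n_at, c_at = frag.backbone()
        axes, _ = frames_batch(n_at, frag.cas, c_at)
        for i in range(len(frag)):
            res = gemmi.Residue()
            t = frag.types[i]
            res.name = AA_THREE.get(t, "UNK")
            res.seqid = gemmi.SeqId(i + 1, " ")
            o_pos = c_at[i] + 1.23 * axes[i][:, 2]
            cb = ideal_cb_position(n_at[i], frag.cas[i], c_at[i])
            atoms = [
                ("N", "N", n_at[i]),
                ("CA", "C", frag.cas[i]),
                ("C", "C", c_at[i]),
                ("O", "O", o_pos),
            ]
            if t not in ("G",):
                atoms.append(("CB", "C", cb))
            for name, elem, pos in atoms:
                a = gemmi.Atom()
                a.name = name
                a.element = gemmi.Element(elem)
                a.pos = gemmi.Position(*pos)
                a.occ = 1.0
                a.b_iso = 30.0
                res.add_atom(a)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def _trim_ends(frag: ChainFragment, cut: float) -> ChainFragment | None:
    """Strip weakly supported terminal residues (they corrupt the docking
    register more than they add coverage)."""
    lo, hi = 0, len(frag)
    while lo < hi and frag.scores[lo] < cut:
        lo += 1
    while hi > lo and frag.scores[hi - 1] < cut:
        hi -= 1
    if hi - lo < 2:
        return None
    if lo == 0 and hi == len(frag):
        return frag
    return ChainFragment(
        cas=frag.cas[lo:hi].copy(),
        scores=frag.scores[lo:hi].copy(),
        types=list(frag.types[lo:hi]),
        id=frag.id,
    )


def _null_score_median(
    dmap: DensityMap, tpl: TargetTemplate, mode: str, n_nodes: int = 343
) -> float:
    """Median target score of quasi-random placements (background level)."""
    shape = np.array(dmap.shape)
    stride = np.maximum(shape // 7, 1)
    nodes = np.array(
        [
            [i, j, k]
            for i in range(3, shape[0] - 3, stride[0])
            for j in range(3, shape[1] - 3, stride[1])
            for k in range(3, shape[2] - 3, stride[2])
        ]
    )
    pos = dmap.origin + nodes * dmap.spacing
    sc = score_placements(dmap, tpl, pos, rotation_set(len(pos)), mode)
    sc = sc[sc > SENTINEL / 2]
    if len(sc) == 0:
        return -1.0
    return float(np.median(sc))


def real_space_fit(
    dmap: DensityMap, frag: ChainFragment, iters: int = 4, max_shift: float = 1.5
) -> ChainFragment:
    """Per-residue rigid-body real-space fit (the refinement stand-in).

    Each residue's atom constellation — backbone N/CA/C/O plus, once the
    sequence is docked, its side-chain atoms at standard geometry — is
    translated (<= 1 A total, coarse-to-fine axis steps) to maximise the
    mean interpolated density, keeping CA-CA distances with neighbours
    legal.  A lightweight tidy-up, not a reciprocal-space refinement; the
    side-chain term is what sharpens positions after sequencing.
    """
    from .build import CA_SKIP_MIN, CA_TRANS_MAX, CA_TRANS_MIN
    from .synthetic import sidechain_atoms

    cas = frag.cas.copy()
    base = frag.cas.copy()
    if len(cas) < 2:
        return frag
    moves = np.vstack([np.eye(3), -np.eye(3)])
    for _ in range(iters):
        n_at, c_at = place_backbone(cas)
        axes, _ = frames_batch(n_at, cas, c_at)
        o_at = c_at + 1.23 * axes[:, :, 2]
        for i in range(len(cas)):
            rel = [n_at[i] - cas[i], np.zeros(3), c_at[i] - cas[i], o_at[i] - cas[i]]
            t = frag.types[i]
            if t not in ("X", "G"):
                side = sidechain_atoms(t, n_at[i], cas[i], c_at[i])
                rel.extend(side - cas[i])
            else:
                cb = ideal_cb_position(n_at[i], cas[i], c_at[i])
                rel.append(cb - cas[i])
                rel.append(cb + 1.4 * (cb - cas[i]) / np.linalg.norm(cb - cas[i]) - cas[i])
            rel = np.array(rel)
            pos = cas[i].copy()
            v = map_io.interpolate_or_nan(dmap, rel + pos)
            best = -np.inf if np.any(np.isnan(v)) else float(v.mean())
            for step in (0.5, 0.25, 0.12):
                improved = True
                while improved:
                    improved = False
                    for d in moves:
                        cand = pos + step * d
                        if np.linalg.norm(cand - base[i]) > max_shift:
                            continue
                        ok = True
                        if i > 0:
                            dd = np.linalg.norm(cand - cas[i - 1])
                            ok &= CA_TRANS_MIN <= dd <= CA_TRANS_MAX
                        if i < len(cas) - 1:
                            dd = np.linalg.norm(cand - cas[i + 1])
                            ok &= CA_TRANS_MIN <= dd <= CA_TRANS_MAX
                        if i > 1:
                            ok &= np.linalg.norm(cand - cas[i - 2]) >= CA_SKIP_MIN
                        if i < len(cas) - 2:
                            ok &= np.linalg.norm(cand - cas[i + 2]) >= CA_SKIP_MIN
                        if not ok:
                            continue
                        v = map_io.interpolate_or_nan(dmap, rel + cand)
                        if np.any(np.isnan(v)):
                            continue
                        s = float(v.mean())
                        if s > best + 1e-12:
                            best = s
                            pos = cand.copy()
                            improved = True
            cas[i] = pos
    return ChainFragment(
        cas=cas, scores=frag.scores.copy(), types=list(frag.types), id=frag.id
    )


def run_cycle(
    dmap: DensityMap,
    sequences: list[tuple[str, str]],
    settings: BuildSettings,
    targets: TargetSet | tuple[TargetTemplate, dict[str, TargetTemplate]],
    prior_model: gemmi.Structure | None = None,
    input_model: gemmi.Structure | None = None,
) -> CycleResult:
    """One build cycle on a prepared map.

    ``prior_model`` (the previous cycle's model) is converted to fragments
    and extended rather than rebuilt; ``input_model`` supplies
    known-structure / nonprotein-radius material.  Deterministic.
    """
    if isinstance(targets, TargetSet):
        ca_tpl: TargetTemplate | list[TargetTemplate] = targets.ca
        ca_blend = targets.ca_blend
        cb_targets = targets.cb
    else:
        ca_tpl, cb_targets = targets
        ca_blend = ca_tpl if not isinstance(ca_tpl, list) else ca_tpl[0]
    mode = settings.score_mode
    preserved, zones = apply_model_controls(input_model, settings)
    pos_filter = _exclusion_filter(zones)
    total_seq = sum(len(s) for _, s in sequences)
    max_len = max(total_seq + 20, 40)

    seed_settings = SeedSearchSettings(
        n_seeds=settings.n_seeds, n_rotations=settings.n_rotations, nms_radius=2.5
    )
    if settings.fast_mode:
        seeds = fast_seed_search(dmap, seed_settings, resolution=settings.resolution)
    else:
        seeds = fourier_seed_search(dmap, ca_blend, seed_settings)
    if pos_filter is not None and seeds:
        keep = pos_filter(np.array([s.position for s in seeds]))
        seeds = [s for s, k in zip(seeds, keep) if k]
    seeds = [refine_placement(dmap, ca_tpl, s, mode) for s in seeds]
    seeds.sort(key=lambda s: -s.score)

    null_med = _null_score_median(dmap, ca_tpl, mode)
    cut = CUT_FRACTION * null_med if null_med < 0 else SENTINEL
    trim_cut = TRIM_FRACTION * null_med if null_med < 0 else SENTINEL
    floor = FLOOR_FRACTION * null_med if null_med < 0 else SENTINEL
    # extensions of an already-built model only proceed into clearly
    # supported density (stricter floor than de-novo growth), so converged
    # fragments are not churned by junk tails every cycle
    extend_grow = GrowSettings(
        step_candidates=settings.step_candidates,
        score_floor=EXTEND_FRACTION * null_med if null_med < 0 else SENTINEL,
        beam_width=settings.beam_width,
        max_length=15,  # per-terminus extension budget per cycle
    )

    frags: list[ChainFragment] = []
    covered: list[np.ndarray] = []

    def claimed_filter(extra_skip: int | None = None):
        """Reject growth candidates inside regions another fragment has
        already claimed (kills shadow traces running alongside built
        chain) and inside preserved-atom exclusion zones."""
        zones_cas = [c for j, c in enumerate(covered) if j != extra_skip]
        if not zones_cas and pos_filter is None:
            return None
        claimed = np.vstack(zones_cas) if zones_cas else None

        def keep(cands: np.ndarray) -> np.ndarray:
            ok = np.ones(len(cands), dtype=bool)
            if claimed is not None:
                d = np.min(
                    np.linalg.norm(cands[:, None, :] - claimed[None, :, :], axis=2),
                    axis=1,
                )
                ok &= d >= 2.4
            if pos_filter is not None:
                ok &= pos_filter(cands)
            return ok

        return keep

    # carry the previous model forward: extend its fragments
    if prior_model is not None:
        prior_frags = model_to_fragments(prior_model)
        covered = [f.cas for f in prior_frags]
        for j, f in enumerate(prior_frags):
            n_before = len(f)
            g = extend_fragment(dmap, f, ca_tpl, extend_grow, mode, claimed_filter(j))
            if len(g) > n_before:
                # re-optimise only when the extension actually added
                # residues; untouched fragments were converged last cycle
                g = refine_fragment(dmap, g, ca_tpl, mode)
                g = real_space_fit(dmap, g)
            frags.append(g)
            covered[j] = g.cas
    if not seeds and not frags:
        empty = fragments_to_model([], preserved)
        return CycleResult(
            model=empty,
            fragments=[],
            fsc_average=0.0,
            stats={"n_fragments": 0, "n_built": 0, "n_sequenced": 0},
        )
    short_grow = GrowSettings(
        step_candidates=settings.step_candidates,
        score_floor=floor,
        beam_width=settings.beam_width,
        max_length=30,
    )
    for i, s in enumerate(seeds):
        if covered:
            d = min(
                float(np.min(np.linalg.norm(c - s.position, axis=1))) for c in covered
            )
            if d < 1.5:
                continue
        f = grow_chain(dmap, s, ca_tpl, short_grow, mode, pos_filter, frag_id=f"s{i}")
        if len(f) < 3:
            continue
        f = refine_fragment(dmap, f, ca_tpl, mode)
        f = real_space_fit(dmap, f)
        frags.append(f)
        covered.append(f.cas)

    pieces: list[ChainFragment] = []
    for f in frags:
        pieces.extend(split_by_score(f, cut))
    pieces = [_trim_ends(p, trim_cut) for p in pieces]
    pieces = [p for p in pieces if p is not None]
    pieces = trim_overlaps(pieces)
    pieces = join_fragments(pieces)
    pieces = prune_overlaps(pieces, clash_radius=2.8)
    pieces = filter_junk(
        pieces,
        min_length=settings.min_fragment_length,
        mask=settings.mask,
        mask_threshold=settings.mask_threshold,
    )
    pieces = [orient_fragment(dmap, f, ca_tpl, mode) for f in pieces]

    sequenced: list[ChainFragment] = []
    n_seq_res = 0
    for f in pieces:
        f = _dock_hierarchical(dmap, f, cb_targets, sequences, settings, mode)
        n_seq_res += sum(1 for t in f.types if t != "X")
        sequenced.append(f)
    fitted = [real_space_fit(dmap, f) for f in sequenced]

    model = fragments_to_model(fitted, preserved)
    if sum(len(f) for f in fitted) == 0 and len(preserved[0]) == 0:
        fsc_avg = 0.0
    else:
        rendered = render_model(model, dmap, settings.resolution)
        _, fsc_avg = compute_fsc(dmap, rendered)
    stats = {
        "n_fragments": len(fitted),
        "n_built": int(sum(len(f) for f in fitted)),
        "n_sequenced": int(n_seq_res),
        "n_seeds": len(seeds),
        "score_floor": floor,
    }
    return CycleResult(model=model, fragments=fitted, fsc_average=fsc_avg, stats=stats)


def _dock_hierarchical(
    dmap: DensityMap,
    frag: ChainFragment,
    cb_targets,
    sequences,
    settings: BuildSettings,
    mode: str,
    min_half: int = 6,
) -> ChainFragment:
    """Dock a fragment; if the whole fragment fails, dock its halves.

    Traces occasionally carry a register defect (an extra or missing
    residue) mid-fragment; the ungapped alignment then rejects the whole
    fragment even though each side of the defect is cleanly docked on its
    own.  Recursing into halves recovers those residues.
    """
    matrix = score_residue_types(dmap, frag, cb_targets, mode)
    asg = align_to_sequence(matrix, sequences, settings.sequence_threshold)
    if asg.assigned or len(frag) < 2 * min_half:
        return apply_assignment(frag, asg)
    mid = len(frag) // 2
    halves = []
    for cas, scores, types in (
        (frag.cas[:mid], frag.scores[:mid], frag.types[:mid]),
        (frag.cas[mid:], frag.scores[mid:], frag.types[mid:]),
    ):
        half = ChainFragment(cas=cas.copy(), scores=scores.copy(), types=list(types), id=frag.id)
        halves.append(
            _dock_hierarchical(dmap, half, cb_targets, sequences, settings, mode, min_half)
        )
    return ChainFragment(
        cas=frag.cas.copy(),
        scores=frag.scores.copy(),
        types=halves[0].types + halves[1].types,
        id=frag.id,
    )


def run_pipeline(
    dmap: DensityMap,
    sequences: list[tuple[str, str]],
    settings: BuildSettings,
    reference: ReferenceData,
    initial_model: gemmi.Structure | None = None,
    truth_model: gemmi.Structure | None = None,
) -> tuple[list[CycleResult], int]:
    """Run the full multi-cycle pipeline on a raw map.

    Returns all cycle results and the index of the best cycle (highest
    FSC_average; ties go to the earliest cycle).  When ``truth_model`` is
    given, per-cycle completeness statistics are added to the stats dicts.
    """
    from .evaluation import completeness

    prepared = prepare_map(dmap, settings)
    targets = TargetSet.from_reference(reference)
    results: list[CycleResult] = []
    prior = initial_model
    for i in range(settings.cycles):
        res = run_cycle(
            prepared,
            sequences,
            settings,
            targets,
            prior_model=prior,
            input_model=initial_model,
        )
        if truth_model is not None:
            res.stats.update(completeness(res.model, truth_model).as_dict())
        logger.info(
            "cycle %d: %d fragments, %d residues, %d sequenced, FSC_avg %.3f",
            i + 1,
            res.stats["n_fragments"],
            res.stats["n_built"],
            res.stats["n_sequenced"],
            res.fsc_average,
        )
        results.append(res)
        prior = res.model
    fscs = np.array([r.fsc_average for r in results])
    best = int(np.argmax(fscs))  # argmax returns the earliest maximum
    return results, best
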