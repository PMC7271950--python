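"""Likelihood search targets from a reference map/model pair.

A target is the per-offset mean and variance of reference-map density over
all occurrences of a motif, superposed in a canonical residue frame:

* the CA target — density statistics in a 4 A sphere centred on CA — is
  used to locate and extend the main chain;
* the CB targets — one per residue type, a 5.5 A sphere centred on the
  (constructed) CB — classify side-chain types for sequencing.

The reference should be at a resolution similar to the map being
interpreted.  Any map/model pair can serve; :func:`simulate_reference`
renders one from a coordinate model so the whole system runs without
external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import gemmi
import numpy as np

from .geometry import CollinearBackboneError, ResidueFrame, residue_frame
from .map_io import DensityMap, interpolate_or_nan

__all__ = [
    "ResidueFrame",
    "TargetTemplate",
    "ReferenceData",
    "residue_frame",
    "sphere_offsets",
    "build_ca_target",
    "build_ca_targets_by_conformation",
    "build_cb_targets",
    "simulate_reference",
]

logger = logging.getLogger(__name__)

VARIANCE_FLOOR_FRACTION = 1e-6  # of the squared mean dynamic range
MIN_CA_RESIDUES = 30
MIN_TYPE_COUNT = 10


@dataclass
class TargetTemplate:
    """Per-offset density statistics of a search motif.

    ``offsets`` is a deterministic, lexicographically ordered sub-grid of
    displacements inside the target sphere (canonical frame, Angstrom);
    ``mean`` and ``variance`` are the per-offset statistics over all motif
    occurrences in the reference; variances are floored so that likelihood
    scores stay finite.
    """

    offsets: np.ndarray  # (m, 3)
    mean: np.ndarray  # (m,)
    variance: np.ndarray  # (m,) > 0
    radius: float
    centre_role: str  # "CA" | "CB"
    resolution: float
    residue_type: str | None = None
    n_occurrences: int = 0

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.float64)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.variance = np.asarray(self.variance, dtype=np.float64)
        if np.any(self.variance <= 0):
            raise ValueError("all variances must exceed the floor (> 0)")


@dataclass
class ReferenceData:
    """A reference map with its fitted coordinate model."""

    map: DensityMap
    model: gemmi.Structure
    resolution: float


def sphere_offsets(radius: float, step: float) -> np.ndarray:
    """Regular sub-grid of displacements with |d| <= radius.

    Lexicographic order over the integer sub-grid indices, so the offset
    set is stable across runs and comparable between templates.
    """
    k = int(np.floor(radius / step))
    pts = [
        (i * step, j * step, l * step)
        for i, j, l in product(range(-k, k + 1), repeat=3)
        if (i * i + j * j + l * l) * step * step <= radius * radius + 1e-12
    ]
    return np.array(pts, dtype=np.float64)


def backbone_positions(res: gemmi.Residue) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """N, CA, C positions of a residue, or None if any is missing."""
    atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z]) for a in res}
    if not all(k in atoms for k in ("N", "CA", "C")):
        return None
    return atoms["N"], atoms["CA"], atoms["C"]


def usable_residue_frames(
    model: gemmi.Structure, centre_role: str
) -> list[tuple[str, ResidueFrame]]:
    """Frames for every residue with a non-degenerate N/CA/C triad.

    Returns (residue name, frame) pairs; degenerate residues are skipped
    with a logged warning.
    """
    frames: list[tuple[str, ResidueFrame]] = []
    for chain in model[0]:
        for res in chain:
            bb = backbone_positions(res)
            if bb is None:
                logger.warning("skipping %s %s: missing backbone atom", chain.name, res.seqid)
                continue
            try:
                frames.append((res.name, residue_frame(*bb, centre_role)))
            except CollinearBackboneError:
                logger.warning("skipping %s %s: collinear backbone", chain.name, res.seqid)
    return frames


def default_step(ref: ReferenceData) -> float:
    """Offset sub-grid step: max(map spacing, resolution / 4)."""
    return float(max(np.max(ref.map.spacing), ref.resolution / 4.0))


def _accumulate(
    ref: ReferenceData, frames: list[ResidueFrame], offsets: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-offset mean and population variance over all frames whose whole
    sphere is inside the map."""
    pts = np.stack([f.to_world(offsets) for f in frames])  # (r, m, 3)
    rho = interpolate_or_nan(ref.map, pts.reshape(-1, 3)).reshape(len(frames), -1)
    ok = ~np.any(np.isnan(rho), axis=1)
    rho = rho[ok]
    if len(rho) == 0:
        raise ValueError("no reference residue lies fully inside the map")
    mean = rho.mean(axis=0)
    var = rho.var(axis=0)  # population variance
    return mean, var, len(rho)


def _floor_variance(mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    floor = VARIANCE_FLOOR_FRACTION * float(np.ptp(mean)) ** 2
    if floor <= 0.0:
        floor = 1e-12
    return np.maximum(var, floor)


def build_ca_target(
    ref: ReferenceData,
    radius: float = 4.0,
    step: float | None = None,
    variance_floor_frac: float | None = None,
) -> TargetTemplate:
    """The main-chain search target: density statistics in a 4 A sphere
    centred on CA, accumulated over every usable reference residue.

    ``variance_floor_frac`` optionally floors per-offset sigmas at that
    fraction of the mean's dynamic range (an error-model term for
    references whose occurrences are nearly identical).
    """
    step = step if step is not None else default_step(ref)
    frames = usable_residue_frames(ref.model, "CA")
    if len(frames) < MIN_CA_RESIDUES:
        raise ValueError(
            f"reference has {len(frames)} usable residues; "
            f">= {MIN_CA_RESIDUES} are required for stable variance estimates"
        )
    offsets = sphere_offsets(radius, step)
    mean, var, n = _accumulate(ref, [f for _, f in frames], offsets)
    var = _floor_variance(mean, var)
    if variance_floor_frac is not None:
        var = np.maximum(var, (variance_floor_frac * float(np.ptp(mean))) ** 2)
    return TargetTemplate(
        offsets=offsets,
        mean=mean,
        variance=var,
        radius=radius,
        centre_role="CA",
        resolution=ref.resolution,
        n_occurrences=n,
    )


def _frames_by_conformation(model: gemmi.Structure) -> dict[str, list[ResidueFrame]]:
    """Frames of usable residues split into compact (helix-like) and
    extended (strand-like) local conformations, by the CA(i)-CA(i+3)
    distance within the chain (< 7 A = compact)."""
    classes: dict[str, list[ResidueFrame]] = {"compact": [], "extended": []}
    for chain in model[0]:
        entries = []  # (ca, frame or None) per residue, chain order
        for res in chain:
            bb = backbone_positions(res)
            if bb is None:
                entries.append(None)
                continue
            try:
                entries.append((bb[1], residue_frame(*bb, "CA")))
            except CollinearBackboneError:
                entries.append(None)
        for i, e in enumerate(entries):
            if e is None:
                continue
            d = None
            for j in (i + 3, i - 3):
                if 0 <= j < len(entries) and entries[j] is not None:
                    d = float(np.linalg.norm(entries[j][0] - e[0]))
                    break
            if d is None:
                continue
            classes["compact" if d < 7.0 else "extended"].append(e[1])
    return classes


def build_ca_targets_by_conformation(
    ref: ReferenceData,
    radius: float = 4.0,
    step: float | None = None,
    variance_floor_frac: float = 0.08,
    min_class: int = 20,
) -> list[TargetTemplate]:
    """Main-chain targets conditioned on local conformation class.

    One blended target averages away the systematic differences between
    helical and extended CA environments, which biases placement optima;
    accumulating compact and extended reference residues separately (and
    scoring candidates with the best class) keeps each target sharp.
    Classes with too few occurrences fall back to the blended target.
    """
    step = step if step is not None else default_step(ref)
    offsets = sphere_offsets(radius, step)
    classes = _frames_by_conformation(ref.model)
    out: list[TargetTemplate] = []
    for name, sel in classes.items():
        if len(sel) < min_class:
            continue
        mean, var, n = _accumulate(ref, sel, offsets)
        var = _floor_variance(mean, var)
        var = np.maximum(var, (variance_floor_frac * float(np.ptp(mean))) ** 2)
        out.append(
            TargetTemplate(
                offsets=offsets,
                mean=mean,
                variance=var,
                radius=radius,
                centre_role="CA",
                resolution=ref.resolution,
                residue_type=name,
                n_occurrences=n,
            )
        )
    if not out:
        out = [build_ca_target(ref, radius, step, variance_floor_frac)]
    return out


def build_cb_targets(
    ref: ReferenceData,
    radius: float = 5.5,
    step: float | None = None,
    types: str | None = None,
    min_count: int = MIN_TYPE_COUNT,
    variance_floor_frac: float | None = None,
) -> dict[str, TargetTemplate]:
    """Side-chain classification targets: one 5.5 A CB-centred template per
    residue type, accumulated only over residues of that type.

    The CB centre is always the ideal CB constructed from N/CA/C, so
    glycine participates like every other type.
    """
    from .synthetic import AA_ORDER, THREE_TO_ONE

    step = step if step is not None else default_step(ref)
    wanted = types if types is not None else AA_ORDER
    frames = usable_residue_frames(ref.model, "CB")
    by_type: dict[str, list[ResidueFrame]] = {t: [] for t in wanted}
    for name, frame in frames:
        one = THREE_TO_ONE.get(name)
        if one in by_type:
            by_type[one].append(frame)
    deficient = [t for t in wanted if len(by_type[t]) < min_count]
    if deficient:
        raise ValueError(
            f"reference under-represents residue types {deficient} "
            f"(need >= {min_count} occurrences each)"
        )
    offsets = sphere_offsets(radius, step)
    out: dict[str, TargetTemplate] = {}
    for t in wanted:
        mean, var, n = _accumulate(ref, by_type[t], offsets)
        var = _floor_variance(mean, var)
        if variance_floor_frac is not None:
            var = np.maximum(var, (variance_floor_frac * float(np.ptp(mean))) ** 2)
        out[t] = TargetTemplate(
            offsets=offsets,
            mean=mean,
            variance=var,
            radius=radius,
            centre_role="CB",
            resolution=ref.resolution,
            residue_type=t,
            n_occurrences=n,
        )
    return out


def simulate_reference(
    model: gemmi.Structure,
    resolution: float,
    spacing: float = 1.0,
    b_iso: float = 0.0,
) -> ReferenceData:
    """Render a reference map from a coordinate model.

    Stands in for an experimental reference map/model pair so that target
    construction needs no external data; deterministic (no noise).
    """
    from .synthetic import make_map

    dmap = make_map(model, resolution=resolution, spacing=spacing, b_iso=b_iso)
    return ReferenceData(map=dmap, model=model, resolution=resolution)
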