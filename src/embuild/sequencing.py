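"""Sequence docking: assign residue types to traced fragments.

Each traced residue is scored against the 20 CB-centred side-chain density
targets, giving a fragment-length x 20 log-likelihood matrix.  The matrix
is slid along every input sequence (ungapped, forward direction); the
best-scoring placement is accepted only when it beats the runner-up by a
confidence margin, otherwise the whole fragment stays unsequenced — the
three outcomes per residue being correctly sequenced, incorrectly
sequenced, or not sequenced once compared against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .build import ChainFragment
from .geometry import frames_batch
from .map_io import DensityMap
from .reference_targets import TargetTemplate
from .search import SENTINEL, score_placements
from .synthetic import AA_ORDER

__all__ = [
    "NOT_SEQUENCED",
    "TypeScoreMatrix",
    "SequenceAssignment",
    "read_fasta",
    "score_residue_types",
    "align_to_sequence",
    "apply_assignment",
]

NOT_SEQUENCED = "-"
# best-vs-runner-up margin (in per-residue z-score units) below which a
# fragment stays unsequenced; calibrated so decoy placements are rejected
DEFAULT_THRESHOLD = 1.5
MIN_OVERLAP = 6


@dataclass
class TypeScoreMatrix:
    """Per-residue scores for each of the 20 amino-acid types.

    Column order is the 20 standard amino acids, alphabetical by one-letter
    code (``AA_ORDER``).
    """

    scores: np.ndarray  # (L, 20)
    fragment_id: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(AA_ORDER):
            raise ValueError("scores must be (fragment length, 20)")


@dataclass
class SequenceAssignment:
    """Docking result: one type (or NOT_SEQUENCED) per fragment residue."""

    types: list[str]
    sequence_id: str | None = None
    offset: int | None = None  # fragment residue 0 -> sequence[offset]
    confidence: float = 0.0  # best-total minus second-best-total

    @property
    def assigned(self) -> bool:
        return any(t != NOT_SEQUENCED for t in self.types)


def read_fasta(path: str) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file (multi-record)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def score_residue_types(
    dmap: DensityMap,
    frag: ChainFragment,
    cb_targets: dict[str, TargetTemplate],
    mode: str = "llk",
) -> TypeScoreMatrix:
    """Score every residue of a fragment against all 20 CB targets.

    The placement for each residue is the CB-centred frame constructed from
    its (ideal-geometry) backbone; a degenerate frame fills the row with the
    sentinel minimum.  All 20 targets share the same offset sub-grid, so the
    map is sampled once per residue.
    """
    offsets = cb_targets[AA_ORDER[0]].offsets
    for t in AA_ORDER:
        if not np.array_equal(cb_targets[t].offsets, offsets):
            raise ValueError("CB targets must share one offset sub-grid")
    n_at, c_at = frag.backbone()
    axes, valid = frames_batch(n_at, frag.cas, c_at)
    L = len(frag)
    out = np.full((L, len(AA_ORDER)), SENTINEL)
    if np.any(valid):
        idx = np.flatnonzero(valid)
        from .geometry import ideal_cb_position

        centres = np.array(
            [ideal_cb_position(n_at[i], frag.cas[i], c_at[i]) for i in idx]
        )
        for ti, t in enumerate(AA_ORDER):
            tpl = cb_targets[t]
            out[idx, ti] = score_placements(dmap, tpl, centres, axes[idx], mode)
    return TypeScoreMatrix(scores=out, fragment_id=frag.id)


def _placement_candidates(
    scores: np.ndarray, seq: str, max_overhang: int = 4
) -> list[tuple[float, int, int, int]]:
    """(centred total, offset, first row, last row + 1) of every ungapped
    placement with enough overlap.

    Scores are centred per residue (row mean subtracted), so each residue
    contributes "how much better this type fits than an average type" and
    rows outside the overlap implicitly contribute zero — placements of
    different overlap are therefore comparable.  A few residues at either
    fragment end may overhang the sequence, letting a trace with a short
    junk tail dock its good core.
    """
    L = len(scores)
    S = len(seq)
    # normalise: z-score each residue's type profile (so no single residue
    # dominates the total), then remove per-type column bias, leaving the
    # residue-specific type preference
    cen = scores - scores.mean(axis=1, keepdims=True)
    cen = cen / (cen.std(axis=1, keepdims=True) + 1e-9)
    cen = cen - cen.mean(axis=0, keepdims=True)
    cols = np.array([AA_ORDER.index(c) if c in AA_ORDER else -1 for c in seq])
    out = []
    for off in range(-max_overhang, S - L + max_overhang + 1):
        a = max(0, -off)
        b = min(L, S - off)
        if b - a < max(MIN_OVERLAP, L - 2 * max_overhang):
            continue
        sel = cols[off + a : off + b]
        if np.any(sel < 0):
            continue
        total = float(cen[np.arange(a, b), sel].sum())
        out.append((total, off, a, b))
    return out


def align_to_sequence(
    matrix: TypeScoreMatrix,
    sequences: list[tuple[str, str]],
    threshold: float = DEFAULT_THRESHOLD,
) -> SequenceAssignment:
    """Dock a fragment's type-score matrix into the input sequences.

    Slides the matrix over every sequence at every ungapped offset
    (forward direction only; each fragment end may overhang the sequence
    by a few residues) and totals the row-centred scores over the overlap.
    The fragment is assigned only when the best placement's total beats
    the runner-up's by ``threshold`` and the overlap is at least 6
    residues; otherwise every residue is NOT_SEQUENCED.  Ties break by
    sequence order, then smaller offset.
    """
    L = len(matrix.scores)
    if L < 1:
        return SequenceAssignment(types=[])
    candidates: list[tuple[float, int, int, int, int]] = []
    for si, (_, seq) in enumerate(sequences):
        for total, off, a, b in _placement_candidates(matrix.scores, seq):
            candidates.append((total, si, off, a, b))
    unassigned = SequenceAssignment(types=[NOT_SEQUENCED] * L)
    if not candidates or L < MIN_OVERLAP:
        return unassigned
    # higher total first; ties by sequence order then smaller offset
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    best = candidates[0]
    second_total = candidates[1][0] if len(candidates) > 1 else -np.inf
    total, si, off, a, b = best
    gap = total - second_total
    if gap < threshold:
        return unassigned
    seq = sequences[si][1]
    types = [NOT_SEQUENCED] * L
    types[a:b] = list(seq[off + a : off + b])
    return SequenceAssignment(
        types=types,
        sequence_id=sequences[si][0],
        offset=off,
        confidence=float(gap),
    )


def apply_assignment(frag: ChainFragment, asg: SequenceAssignment) -> ChainFragment:
    """Write docked types onto a fragment; unassigned residues become UNK
    (one-letter "X")."""
    if asg.types and len(asg.types) != len(frag):
        raise ValueError(
            f"assignment length {len(asg.types)} != fragment length {len(frag)}"
        )
    types = [
        ("X" if t == NOT_SEQUENCED else t) for t in (asg.types or [NOT_SEQUENCED] * len(frag))
    ]
    return ChainFragment(
        cas=frag.cas.copy(),
        scores=frag.scores.copy(),
        types=types,
        id=frag.id,
    )
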