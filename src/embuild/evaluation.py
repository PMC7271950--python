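"""Model-quality measurements: completeness, sequencing classes, benchmarks.

Completeness follows the standard cryo-EM model-building convention: a
built residue is correctly positioned when its CA lies within 1 A of a
distinct reference CA (one-to-one matching), and correctly sequenced when
it is correctly positioned *and* carries the reference residue type.
Percentages are quoted against the reference model's residue count.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .build import ChainFragment
from .geometry import place_backbone
from .map_io import DensityMap
from .reference_targets import TargetTemplate
from .sequencing import NOT_SEQUENCED, align_to_sequence, score_residue_types
from .synthetic import THREE_TO_ONE

__all__ = [
    "CompletenessStats",
    "FragmentBenchmarkRow",
    "model_ca_positions",
    "model_ca_types",
    "match_ca",
    "completeness",
    "fragment_benchmark",
    "bin_by_resolution",
]


@dataclass
class CompletenessStats:
    n_built: int
    n_correct_ca: int
    n_correct_seq: int
    reference_size: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_correct_seq <= self.n_correct_ca):
            raise ValueError("correct-sequence count cannot exceed correct-CA count")
        if self.n_correct_ca > min(self.n_built, self.reference_size):
            raise ValueError("matched count exceeds model sizes")

    @property
    def pct_ca(self) -> float:
        return 100.0 * self.n_correct_ca / self.reference_size if self.reference_size else 0.0

    @property
    def pct_seq(self) -> float:
        return 100.0 * self.n_correct_seq / self.reference_size if self.reference_size else 0.0

    def as_dict(self) -> dict:
        return {
            "n_built": self.n_built,
            "n_correct_ca": self.n_correct_ca,
            "n_correct_seq": self.n_correct_seq,
            "reference_size": self.reference_size,
            "pct_ca": self.pct_ca,
            "pct_seq": self.pct_seq,
        }


@dataclass
class FragmentBenchmarkRow:
    length: int
    n_fragments: int
    n_residues: int
    frac_correct: float
    frac_incorrect: float
    frac_not_sequenced: float

    def __post_init__(self) -> None:
        s = self.frac_correct + self.frac_incorrect + self.frac_not_sequenced
        if self.n_residues and abs(s - 1.0) > 1e-12:
            raise ValueError(f"class fractions must sum to 1, got {s}")


def model_ca_positions(model: gemmi.Structure) -> np.ndarray:
    """(n, 3) CA coordinates of every residue with a CA atom."""
    out = []
    for chain in model[0]:
        for res in chain:
            for a in res:
                if a.name == "CA":
                    out.append([a.pos.x, a.pos.y, a.pos.z])
                    break
    return np.array(out, dtype=np.float64).reshape(-1, 3)


def model_ca_types(model: gemmi.Structure) -> list[str]:
    """One-letter types aligned with :func:`model_ca_positions` ("X" for
    non-standard residues)."""
    out = []
    for chain in model[0]:
        for res in chain:
            if any(a.name == "CA" for a in res):
                out.append(THREE_TO_ONE.get(res.name, "X"))
    return out


def match_ca(
    built: np.ndarray, reference: np.ndarray, cutoff: float = 1.0
) -> list[tuple[int, int]]:
    """Greedy nearest-first one-to-one matching of CA positions.

    All built/reference pairs closer than the cutoff are sorted by distance
    and accepted greedily, each atom used at most once.  Deterministic; ties
    break by (built index, reference index).
    """
    if len(built) == 0 or len(reference) == 0:
        return []
    D = cdist(built, reference)
    bi, ri = np.nonzero(D <= cutoff)
    order = np.lexsort((ri, bi, D[bi, ri]))
    used_b: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for k in order:
        b, r = int(bi[k]), int(ri[k])
        if b in used_b or r in used_r:
            continue
        used_b.add(b)
        used_r.add(r)
        pairs.append((b, r))
    return pairs


def completeness(
    built: gemmi.Structure | tuple[np.ndarray, list[str]],
    reference: gemmi.Structure | tuple[np.ndarray, list[str]],
    cutoff: float = 1.0,
) -> CompletenessStats:
    """Completeness of a built model against the reference model.

    Accepts either gemmi structures or pre-extracted (CA positions, types)
    pairs.  UNK ("X") built residues never count as correctly sequenced.
    """
    b_pos, b_types = (
        (model_ca_positions(built), model_ca_types(built))
        if isinstance(built, gemmi.Structure)
        else built
    )
    r_pos, r_types = (
        (model_ca_positions(reference), model_ca_types(reference))
        if isinstance(reference, gemmi.Structure)
        else reference
    )
    pairs = match_ca(b_pos, r_pos, cutoff)
    n_seq = sum(
        1 for b, r in pairs if b_types[b] != "X" and b_types[b] == r_types[r]
    )
    return CompletenessStats(
        n_built=len(b_pos),
        n_correct_ca=len(pairs),
        n_correct_seq=n_seq,
        reference_size=len(r_pos),
    )


def fragment_benchmark(
    dmap: DensityMap,
    model: gemmi.Structure,
    sequences: list[tuple[str, str]],
    cb_targets: dict[str, TargetTemplate],
    lengths: list[int],
    threshold: float,
    mode: str = "llk",
) -> list[FragmentBenchmarkRow]:
    """Sequencing success versus fragment length.

    The ground-truth model is chopped into non-overlapping, left-anchored
    windows of each requested length (each chain being a maximal correctly
    traced segment); every window is sequenced against the input sequences
    and its residues tallied as correctly sequenced, incorrectly sequenced
    or not sequenced.
    """
    if any(length < 6 for length in lengths):
        raise ValueError("benchmark lengths must be >= 6")
    segments: list[tuple[np.ndarray, list[str]]] = []
    for chain in model[0]:
        cas, types = [], []
        for res in chain:
            for a in res:
                if a.name == "CA":
                    cas.append([a.pos.x, a.pos.y, a.pos.z])
                    types.append(THREE_TO_ONE.get(res.name, "X"))
                    break
        if len(cas) >= 2:
            segments.append((np.array(cas), types))
    rows = []
    for L in lengths:
        counts = {"correct": 0, "incorrect": 0, "not": 0}
        n_frag = 0
        for cas, types in segments:
            for start in range(0, len(cas) - L + 1, L):
                window = ChainFragment(
                    cas=cas[start : start + L].copy(),
                    scores=np.zeros(L),
                    id=f"bench-{L}-{start}",
                )
                mat = score_residue_types(dmap, window, cb_targets, mode)
                asg = align_to_sequence(mat, sequences, threshold)
                truth = types[start : start + L]
                for got, want in zip(asg.types, truth):
                    if got == NOT_SEQUENCED:
                        counts["not"] += 1
                    elif got == want:
                        counts["correct"] += 1
                    else:
                        counts["incorrect"] += 1
                n_frag += 1
        total = sum(counts.values())
        rows.append(
            FragmentBenchmarkRow(
                length=L,
                n_fragments=n_frag,
                n_residues=total,
                frac_correct=counts["correct"] / total if total else 0.0,
                frac_incorrect=counts["incorrect"] / total if total else 0.0,
                frac_not_sequenced=counts["not"] / total if total else 0.0,
            )
        )
    return rows


def bin_by_resolution(
    records: list[tuple[float, float]], bin_edges: list[float]
) -> pd.DataFrame:
    """Mean and population SD of a percentage metric per resolution bin.

    Bins are closed on the left, open on the right; empty bins are absent
    from the output.
    """
    if not records:
        raise ValueError("no records to bin")
    df = pd.DataFrame(records, columns=["resolution", "pct"])
    edges = np.asarray(bin_edges, dtype=float)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = df[(df.resolution >= lo) & (df.resolution < hi)]
        if len(sel) == 0:
            continue
        out.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "n": len(sel),
                "mean": float(sel.pct.mean()),
                "sd": float(sel.pct.std(ddof=0)),
            }
        )
    return pd.DataFrame(out)
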