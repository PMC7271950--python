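"""Residue-frame geometry shared by target building and fixture generation.

A residue's local frame is a deterministic orthonormal basis built from its
N, CA and C atoms: the x axis follows the (C - N) direction (orthogonalised),
the z axis is the normal of the N-CA-C plane and y completes a right-handed
set.  The frame origin sits either on CA or on the ideal CB position
constructed from backbone geometry (which also serves glycine).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResidueFrame",
    "CollinearBackboneError",
    "residue_frame",
    "ideal_cb_position",
    "backbone_dirs_from_tangents",
    "place_backbone",
]

# CA-CB bond length and ideal tetrahedral geometry coefficients
# (the standard construction of CB from the N, CA, C triad)
_CB_COEFF_A = -0.58273431  # along cross(CA-N, C-CA)
_CB_COEFF_B = 0.56802827  # along CA-N
_CB_COEFF_C = -0.54067466  # along C-CA


class CollinearBackboneError(ValueError):
    """N, CA, C are (nearly) collinear: no frame can be built."""


@dataclass
class ResidueFrame:
    """Origin (Angstrom) plus a rotation from canonical to world coords."""

    origin: np.ndarray  # (3,)
    axes: np.ndarray  # (3, 3), columns are the world-frame x, y, z axes

    def to_world(self, local: np.ndarray) -> np.ndarray:
        """Map canonical-frame offsets (n, 3) to world positions."""
        return self.origin + np.asarray(local) @ self.axes.T


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise CollinearBackboneError("zero-length backbone vector")
    return v / n


def ideal_cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """CB constructed from N/CA/C with standard tetrahedral geometry.

    Used both for glycine (which has no real CB) and to place CB-centred
    side-chain search targets in a model-independent way.
    """
    n, ca, c = (np.asarray(p, dtype=np.float64) for p in (n, ca, c))
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return _CB_COEFF_A * a + _CB_COEFF_B * b + _CB_COEFF_C * cc + ca


def frames_batch(
    n: np.ndarray, ca: np.ndarray, c: np.ndarray, min_sin: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised residue frames for (m, 3) backbone triads.

    Returns (axes (m, 3, 3), valid (m,)); invalid (near-collinear) entries
    get an arbitrary orthonormal frame and valid=False.
    """
    n = np.atleast_2d(np.asarray(n, dtype=np.float64))
    ca = np.atleast_2d(np.asarray(ca, dtype=np.float64))
    c = np.atleast_2d(np.asarray(c, dtype=np.float64))
    v1 = c - n
    z = np.cross(n - ca, c - ca)
    nz = np.linalg.norm(z, axis=1)
    lim = min_sin * np.maximum(
        np.linalg.norm(n - ca, axis=1) * np.linalg.norm(c - ca, axis=1), 1e-12
    )
    valid = nz >= lim
    z = np.where(valid[:, None], z / np.where(valid, nz, 1.0)[:, None], [[0.0, 0.0, 1.0]])
    x = v1 - np.sum(v1 * z, axis=1, keepdims=True) * z
    nx = np.linalg.norm(x, axis=1)
    bad_x = nx < 1e-9
    x = np.where(bad_x[:, None], [[1.0, 0.0, 0.0]], x / np.where(bad_x, 1.0, nx)[:, None])
    valid &= ~bad_x
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=2), valid


# tilt of the CA->N and CA->C bonds toward the local curvature centre;
# gives an N-CA-C angle near the canonical 110 degrees and, crucially, a
# local atom constellation that is the same for every secondary structure
_BB_TILT = 0.7


def backbone_dirs_from_tangents(u_in: np.ndarray, u_out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CA->N and CA->C unit directions from incoming/outgoing chain tangents.

    Both bonds tilt toward the local curvature centre by a fixed amount, so
    a residue's own N/CA/C constellation (in its frame) is independent of
    the trace's curvature — helix and strand residues differ only through
    their neighbours, the way real backbones do.
    """
    u_in = np.atleast_2d(u_in)
    u_out = np.atleast_2d(u_out)
    t = u_in + u_out
    tn = np.linalg.norm(t, axis=1, keepdims=True)
    nvec = u_out - u_in
    nn = np.linalg.norm(nvec, axis=1, keepdims=True)
    # degenerate (straight or reversing) traces: fall back to any
    # deterministic perpendicular
    t = np.where(tn > 1e-6, t / np.where(tn > 0, tn, 1.0), u_in)
    fallback = np.cross(u_in, np.array([0.12, 0.36, 0.93]))
    fn = np.linalg.norm(fallback, axis=1, keepdims=True)
    fallback = fallback / np.where(fn > 1e-9, fn, 1.0)
    nvec = np.where(nn > 1e-6, nvec / np.where(nn > 0, nn, 1.0), fallback)
    d_n = -t + _BB_TILT * nvec
    d_c = t + _BB_TILT * nvec
    d_n = d_n / np.linalg.norm(d_n, axis=1, keepdims=True)
    d_c = d_c / np.linalg.norm(d_c, axis=1, keepdims=True)
    return d_n, d_c


def place_backbone(cas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ideal N and C atoms along a CA trace.

    Tangents come from the neighbouring CAs (terminal residues use an
    extrapolated virtual neighbour); bond directions follow
    :func:`backbone_dirs_from_tangents`, so every residue gets a full,
    non-collinear N/CA/C triad with a curvature-independent local shape.
    """
    cas = np.asarray(cas, dtype=np.float64)
    if len(cas) < 2:
        raise ValueError("need >= 2 CA positions to place backbone atoms")
    if len(cas) >= 3:
        virtual_prev = cas[0] - (cas[2] - cas[1])
        virtual_next = cas[-1] + (cas[-2] - cas[-3])
    else:
        step = cas[1] - cas[0]
        perp = np.cross(step, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(step, [1.0, 0.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        virtual_prev = cas[0] - step + 1.2 * perp
        virtual_next = cas[-1] + step + 1.2 * perp
    ext = np.vstack([virtual_prev, cas, virtual_next])
    u_in = cas - ext[:-2]
    u_out = ext[2:] - cas
    u_in = u_in / np.linalg.norm(u_in, axis=1, keepdims=True)
    u_out = u_out / np.linalg.norm(u_out, axis=1, keepdims=True)
    d_n, d_c = backbone_dirs_from_tangents(u_in, u_out)
    return cas + 1.46 * d_n, cas + 1.52 * d_c


def residue_frame(
    n: np.ndarray,
    ca: np.ndarray,
    c: np.ndarray,
    centre_role: str = "CA",
    min_sin: float = 0.05,
) -> ResidueFrame:
    """Deterministic orthonormal frame from backbone atoms.

    Raises :class:`CollinearBackboneError` when the three atoms are too
    close to a line (callers skip such residues with a warning).
    """
    n, ca, c = (np.asarray(p, dtype=np.float64) for p in (n, ca, c))
    v1 = c - n
    z = np.cross(n - ca, c - ca)
    nz = np.linalg.norm(z)
    if nz < min_sin * max(np.linalg.norm(n - ca) * np.linalg.norm(c - ca), 1e-12):
        raise CollinearBackboneError("N, CA, C nearly collinear")
    z = z / nz
    x = _unit(v1 - np.dot(v1, z) * z)
    y = np.cross(z, x)
    axes = np.stack([x, y, z], axis=1)
    if centre_role.upper() == "CA":
        origin = ca
    elif centre_role.upper() == "CB":
        origin = ideal_cb_position(n, ca, c)
    else:
        raise ValueError(f"unknown centre_role {centre_role!r}")
    return ResidueFrame(origin=origin, axes=axes)
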