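"""Density maps, structure factors and the map-preparation primitives.

A :class:`DensityMap` is a real-valued 3-D grid on an orthogonal box with a
fixed voxel spacing and an origin in Angstroms.  Maps interconvert with a
:class:`StructureFactorSet` (a P1 list of Miller indices with amplitude and
phase) through plain discrete Fourier transforms; resolution truncation and
global B-factor sharpening/blurring act on the structure-factor side, which
is how cryo-EM maps are conventionally prepared before model building.

Conventions fixed here (and relied on by everything downstream):

* grids are indexed ``values[ix, iy, iz]`` in canonical x, y, z order;
* the box is periodic with period ``cell = spacing * shape`` per axis;
* the DC structure-factor amplitude equals ``mean(density) * n_voxels``
  (i.e. amplitudes are plain unnormalised DFT magnitudes);
* interpolation is trilinear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "DensityMap",
    "StructureFactorSet",
    "MapFormatError",
    "OutsideVolumeError",
    "read_mrc",
    "write_mrc",
    "map_to_structure_factors",
    "apply_sharpening",
    "structure_factors_to_map",
    "interpolate",
    "apply_mask",
]


class MapFormatError(ValueError):
    """Raised for malformed or unsupported MRC headers."""


class OutsideVolumeError(ValueError):
    """Raised when a position falls outside the interpolatable volume."""


@dataclass
class DensityMap:
    """A 3-D density grid on an orthogonal cell.

    Parameters
    ----------
    values:
        Array of shape ``(nx, ny, nz)``; finite reals.
    spacing:
        Voxel edge lengths in Angstrom, one per axis, all > 0.
    origin:
        Position of grid index (0, 0, 0) in Angstrom.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise MapFormatError(
                f"grid must be 3-D with >= 2 samples per axis, got shape "
                f"{self.values.shape}"
            )
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise MapFormatError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise MapFormatError("density values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def cell(self) -> np.ndarray:
        """Box edge lengths (Angstrom): ``spacing * shape`` per axis."""
        return self.spacing * np.array(self.shape)

    def same_geometry(self, other: "DensityMap", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def copy(self, values: np.ndarray | None = None) -> "DensityMap":
        return DensityMap(
            self.values.copy() if values is None else values,
            self.spacing.copy(),
            self.origin.copy(),
        )

    def grid_coords(self, positions: np.ndarray) -> np.ndarray:
        """World (Angstrom) positions -> fractional grid indices."""
        return (np.asarray(positions, dtype=np.float64) - self.origin) / self.spacing


@dataclass
class StructureFactorSet:
    """P1 structure factors: Miller indices with amplitude and phase.

    ``hkl`` holds all retained indices (Friedel mates included), ``d_min``
    the resolution cutoff and ``grid_shape`` the grid the set came from.
    """

    hkl: np.ndarray  # (n, 3) int
    amplitude: np.ndarray  # (n,) >= 0
    phase: np.ndarray  # (n,) in [0, 2*pi)
    cell: np.ndarray  # (3,) Angstrom
    d_min: float
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=np.int64)
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        self.phase = np.mod(np.asarray(self.phase, dtype=np.float64), 2 * np.pi)
        self.cell = np.asarray(self.cell, dtype=np.float64)

    @property
    def inv_d(self) -> np.ndarray:
        """1/d (Angstrom^-1) of every index."""
        return np.sqrt(np.sum((self.hkl / self.cell) ** 2, axis=1))

    def complex_values(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


def _check_orthogonal(cell: gemmi.UnitCell) -> None:
    for name, ang in (("alpha", cell.alpha), ("beta", cell.beta), ("gamma", cell.gamma)):
        if abs(ang - 90.0) > 1e-3:
            raise MapFormatError(
                f"non-orthogonal cell: header angle {name} = {ang:.3f} deg "
                "(only 90-degree cells are supported)"
            )


def read_mrc(path: str) -> DensityMap:
    """Read an MRC/CCP4 2014 volume into canonical x,y,z axis order.

    The origin of the grid honours the MRC ORIGIN record when it is nonzero,
    falling back to ``nstart * spacing`` otherwise.  Non-orthogonal cells,
    non-volume modes and degenerate (2-D) grids are rejected with a
    diagnostic naming the offending header field.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read MRC file {path}: {exc}") from exc
    mode = m.header_i32(4)
    if mode not in (0, 1, 2):
        raise MapFormatError(f"unsupported MRC MODE {mode}; need a real volume (mode 0/1/2)")
    _check_orthogonal(m.grid.unit_cell)
    mapc, mapr, maps_ = (m.header_i32(i) for i in (17, 18, 19))
    if sorted((mapc, mapr, maps_)) != [1, 2, 3]:
        raise MapFormatError(
            f"invalid axis order records MAPC/MAPR/MAPS = {mapc}/{mapr}/{maps_}"
        )
    nstart_file = np.array([m.header_i32(i) for i in (5, 6, 7)], dtype=float)
    origin_rec = np.array([m.header_float(i) for i in (50, 51, 52)])
    # reorder axes so the array is indexed [x, y, z]
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, copy=True).astype(np.float64)
    if values.ndim != 3 or min(values.shape) < 2:
        raise MapFormatError(
            f"MRC NX/NY/NZ describe a non-volume grid of shape {values.shape}"
        )
    cell = np.array([m.grid.unit_cell.a, m.grid.unit_cell.b, m.grid.unit_cell.c])
    spacing = cell / np.array(values.shape)
    # nstart in file order -> crystal xyz order
    nstart = np.zeros(3)
    for file_axis, cryst_axis in enumerate((mapc, mapr, maps_)):
        nstart[cryst_axis - 1] = nstart_file[file_axis]
    if np.any(origin_rec != 0.0):
        origin = origin_rec
    else:
        origin = nstart * spacing
    if not np.all(np.isfinite(values)):
        raise MapFormatError("map contains non-finite density values")
    return DensityMap(values, spacing, origin)


def write_mrc(dmap: DensityMap, path: str) -> None:
    """Write a map as MRC 2014 mode-2 (float32), canonical x,y,z axes."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.values, dtype=np.float32))
    c = dmap.cell
    grid.unit_cell = gemmi.UnitCell(c[0], c[1], c[2], 90.0, 90.0, 90.0)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for i, v in zip((50, 51, 52), dmap.origin):
        m.set_header_float(i, float(v))
    m.write_ccp4_map(str(path))


def _miller_grids(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer Miller indices for every FFT sample, in fftn layout."""
    axes = [np.rint(np.fft.fftfreq(n) * n).astype(np.int64) for n in shape]
    return np.meshgrid(*axes, indexing="ij")  # type: ignore[return-value]


def nyquist_d_min(dmap: DensityMap) -> float:
    """The smallest legal d_min for this grid: twice the largest spacing."""
    return 2.0 * float(np.max(dmap.spacing))


def map_to_structure_factors(dmap: DensityMap, d_min: float) -> StructureFactorSet:
    """Forward DFT of the grid, truncated at the given resolution.

    Retains every Miller index with 1/d(h,k,l) <= 1/d_min.  DC amplitude
    equals mean density times the number of voxels.
    """
    nyq = nyquist_d_min(dmap)
    if d_min < nyq - 1e-9:
        raise ValueError(
            f"d_min = {d_min:g} A is below the Nyquist limit of this grid; "
            f"the minimum legal d_min is {nyq:g} A"
        )
    F = np.fft.fftn(dmap.values)
    h, k, l = _miller_grids(dmap.shape)
    cell = dmap.cell
    inv_d2 = (h / cell[0]) ** 2 + (k / cell[1]) ** 2 + (l / cell[2]) ** 2
    keep = inv_d2 <= (1.0 / d_min) ** 2 + 1e-12
    hkl = np.stack([h[keep], k[keep], l[keep]], axis=1)
    fv = F[keep]
    return StructureFactorSet(
        hkl=hkl,
        amplitude=np.abs(fv),
        phase=np.angle(fv) % (2 * np.pi),
        cell=cell,
        d_min=float(d_min),
        grid_shape=dmap.shape,
    )


def apply_sharpening(sf: StructureFactorSet, b_factor: float) -> StructureFactorSet:
    """Scale amplitudes by exp(-B s^2 / 4), s = 1/d.

    ``b_factor`` < 0 sharpens (boosts high resolution), > 0 blurs, 0 is the
    identity.  Phases are untouched.
    """
    if b_factor == 0.0:
        scale = np.ones_like(sf.amplitude)
    else:
        scale = np.exp(-b_factor * sf.inv_d**2 / 4.0)
    return StructureFactorSet(
        hkl=sf.hkl.copy(),
        amplitude=sf.amplitude * scale,
        phase=sf.phase.copy(),
        cell=sf.cell.copy(),
        d_min=sf.d_min,
        grid_shape=sf.grid_shape,
    )


def structure_factors_to_map(
    sf: StructureFactorSet,
    grid_shape: tuple[int, int, int] | None = None,
    spacing: np.ndarray | None = None,
    origin: np.ndarray | None = None,
) -> DensityMap:
    """Inverse DFT back to a real grid (Hermitian symmetry enforced)."""
    shape = tuple(grid_shape) if grid_shape is not None else sf.grid_shape
    n = np.array(shape)
    if np.any(np.abs(sf.hkl) > n[None, :] // 2):
        bad = sf.hkl[np.any(np.abs(sf.hkl) > n[None, :] // 2, axis=1)][0]
        raise ValueError(f"Miller index {tuple(bad)} outside grid of shape {shape}")
    G = np.zeros(shape, dtype=np.complex128)
    idx = tuple((sf.hkl % n).T)
    G[idx] = sf.complex_values()
    # enforce Hermitian symmetry: average each term with the conjugate of
    # its Friedel mate so the inverse transform is exactly real
    Gflip = np.conj(np.roll(G[::-1, ::-1, ::-1], 1, axis=(0, 1, 2)))
    G = 0.5 * (G + Gflip)
    values = np.fft.ifftn(G).real
    if spacing is None:
        spacing = sf.cell / n
    if origin is None:
        origin = np.zeros(3)
    return DensityMap(values, spacing, origin)


def interpolate(dmap: DensityMap, positions: np.ndarray) -> np.ndarray | float:
    """Trilinear interpolation of the density at world positions (Angstrom).

    Accepts a single (3,) position or an (n, 3) array.  Positions outside
    the interpolatable volume (grid index range [0, n-1] per axis) raise
    :class:`OutsideVolumeError`; callers that want a sentinel should clip or
    mask first.
    """
    pos = np.asarray(positions, dtype=np.float64)
    single = pos.ndim == 1
    coords = dmap.grid_coords(pos.reshape(-1, 3))
    hi = np.array(dmap.shape) - 1
    if np.any(coords < -1e-9) or np.any(coords > hi[None, :] + 1e-9):
        raise OutsideVolumeError("position outside the interpolatable volume")
    out = map_coordinates(dmap.values, coords.T, order=1, mode="nearest")
    return float(out[0]) if single else out


def interpolate_or_nan(dmap: DensityMap, positions: np.ndarray) -> np.ndarray:
    """Vectorised trilinear interpolation; out-of-volume positions -> NaN."""
    pos = np.asarray(positions, dtype=np.float64).reshape(-1, 3)
    coords = dmap.grid_coords(pos)
    hi = np.array(dmap.shape) - 1
    bad = np.any(coords < -1e-9, axis=1) | np.any(coords > hi[None, :] + 1e-9, axis=1)
    out = map_coordinates(dmap.values, np.clip(coords, 0, hi[None, :]).T, order=1)
    out[bad] = np.nan
    return out


def apply_mask(dmap: DensityMap, mask: DensityMap, threshold: float) -> DensityMap:
    """Zero voxels where the mask is below the threshold."""
    if not dmap.same_geometry(mask):
        raise ValueError("mask and map grid geometry differ")
    return dmap.copy(values=np.where(mask.values < threshold, 0.0, dmap.values))
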