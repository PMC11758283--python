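"""Domain types and reciprocal-space geometry shared by all pipeline stages.

Conventions
-----------
* Resolution is expressed as ``q = 1/d`` (1/angstrom) throughout.
* Quaternions are scalar-first ``(w, x, y, z)``; a rotation acts on
  reciprocal vectors as ``g' = R(quat) @ g``.
* The reciprocal basis ``B`` has the reciprocal cell vectors
  ``a*, b*, c*`` as columns, so ``g = B @ (h, k, l)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HC_KEV_ANGSTROM",
    "UnitCell",
    "BeamConfig",
    "MillerIndexSet",
    "Snapshot",
    "SnapshotSeries",
    "DiffractionVolume",
    "VolumeSeries",
    "wavelength_from_energy",
    "reciprocal_vector",
    "build_index_set",
    "default_cell",
    "quat_to_matrix",
]

#: Planck constant times speed of light in keV * angstrom.
HC_KEV_ANGSTROM = 12.39842

#: Safety cap for :func:`build_index_set` (number of reflections).
DEFAULT_INDEX_CAP = 2_000_000


def wavelength_from_energy(energy_kev: float) -> float:
    """X-ray wavelength (angstrom) for a photon energy in keV."""
    if energy_kev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_ANGSTROM / energy_kev


def quat_to_matrix(quat: np.ndarray) -> np.ndarray:
    """Rotation matrix for a scalar-first unit quaternion.

    The quaternion is normalized defensively; callers should already hold
    unit quaternions (see :class:`Snapshot` invariants).
    """
    w, x, y, z = np.asarray(quat, dtype=float)
    n = np.sqrt(w * w + x * x + y * y + z * z)
    if n == 0:
        raise ValueError("zero quaternion has no associated rotation")
    w, x, y, z = w / n, x / n, y / n, z / n
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell (edges in angstrom, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    point_group_label: str = "1"

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell edge {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180)")

    @property
    def direct_basis(self) -> np.ndarray:
        """Direct-space basis with the cell vectors a, b, c as rows."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        a, b, c = self.a, self.b, self.c
        cx = c * np.cos(be)
        cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        cz2 = c * c - cx * cx - cy * cy
        if cz2 <= 0:
            raise ValueError("degenerate cell: angles are inconsistent")
        return np.array(
            [
                [a, 0.0, 0.0],
                [b * np.cos(ga), b * np.sin(ga), 0.0],
                [cx, cy, np.sqrt(cz2)],
            ]
        )

    @property
    def reciprocal_basis(self) -> np.ndarray:
        """Matrix B with reciprocal cell vectors as columns; g = B @ hkl."""
        return np.linalg.inv(self.direct_basis)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.direct_basis)))

    def q_of(self, hkl: np.ndarray) -> np.ndarray:
        """|g| = 1/d for an (..., 3) array of Miller indices."""
        g = reciprocal_vector(self, hkl)
        return np.linalg.norm(g, axis=-1)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        q = self.q_of(hkl)
        with np.errstate(divide="ignore"):
            return np.where(q > 0, 1.0 / q, np.inf)


def default_cell() -> UnitCell:
    """Hexagonal PYP-like default cell (a convenience, not ground truth)."""
    return UnitCell(66.9, 66.9, 40.8, 90.0, 90.0, 120.0, point_group_label="6")


def reciprocal_vector(cell: UnitCell, hkl: np.ndarray) -> np.ndarray:
    """Reciprocal-lattice vector(s) g = B @ (h,k,l) in 1/angstrom.

    ``hkl`` may be a single triple or an (m, 3) array; indices must be
    integral (integer dtype or integer-valued floats).
    """
    arr = np.asarray(hkl)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected Miller triples of length 3, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("Miller indices must be integers")
        arr = np.round(arr).astype(int)
    return arr @ cell.reciprocal_basis.T


@dataclass(frozen=True)
class BeamConfig:
    """X-ray beam: photon energy (keV) and spot-sphere radius R (1/angstrom)."""

    photon_energy: float
    spot_radius_R: float

    def __post_init__(self) -> None:
        if self.photon_energy <= 0:
            raise ValueError("photon energy must be positive")
        if self.spot_radius_R <= 0:
            raise ValueError("spot radius must be positive")

    @property
    def wavelength(self) -> float:
        return wavelength_from_energy(self.photon_energy)


class MillerIndexSet:
    """Ordered, duplicate-free set of Miller triples with a row bijection.

    Parameters
    ----------
    hkl : (D, 3) integer array (will be lexicographically sorted)
    q : (D,) array of 1/d values aligned with ``hkl`` after sorting, or a
        :class:`UnitCell` from which they are computed.
    """

    def __init__(self, hkl: np.ndarray, q: np.ndarray | UnitCell):
        hkl = np.asarray(hkl, dtype=np.int64).reshape(-1, 3)
        order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
        hkl = hkl[order]
        if isinstance(q, UnitCell):
            qv = q.q_of(hkl)
        else:
            qv = np.asarray(q, dtype=float)[order]
        if len(hkl) != len(qv):
            raise ValueError("hkl and q length mismatch")
        if len(hkl) > 1 and np.any(np.all(np.diff(hkl, axis=0) == 0, axis=1)):
            raise ValueError("duplicate Miller triples")
        self.hkl = hkl
        self.q = qv
        self._row = {tuple(t): i for i, t in enumerate(hkl.tolist())}

    def __len__(self) -> int:
        return len(self.hkl)

    def __contains__(self, triple) -> bool:
        return tuple(int(v) for v in triple) in self._row

    def row_of(self, triple) -> int:
        return self._row[tuple(int(v) for v in triple)]

    def rows_of(self, hkl: np.ndarray) -> np.ndarray:
        """Rows for an (m, 3) array of triples; KeyError if any is foreign."""
        return np.array(
            [self._row[tuple(t)] for t in np.asarray(hkl, dtype=np.int64).tolist()],
            dtype=np.int64,
        )

    def subset(self, rows: np.ndarray) -> "MillerIndexSet":
        rows = np.asarray(rows, dtype=np.int64)
        return MillerIndexSet(self.hkl[rows], self.q[rows])

    def same_as(self, other: "MillerIndexSet") -> bool:
        return len(self) == len(other) and bool(np.array_equal(self.hkl, other.hkl))


def build_index_set(
    cell: UnitCell, d_min: float, max_size: int = DEFAULT_INDEX_CAP
) -> MillerIndexSet:
    """All Miller triples with 1/d <= 1/d_min, excluding (0,0,0).

    The origin carries no Bragg information and is excluded by design.
    Raises if the set would exceed ``max_size``.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    q_max = 1.0 / d_min
    # |h| = |a_vec . g| <= |a_vec| q_max, similarly for k, l.
    lengths = np.linalg.norm(cell.direct_basis, axis=1)
    bounds = np.floor(lengths * q_max).astype(int)
    n_box = int(np.prod(2 * bounds.astype(np.int64) + 1))
    if n_box > 40 * max_size:
        raise ValueError(
            f"index box of {n_box} candidates exceeds sanity bound for "
            f"cap {max_size}; increase d_min or max_size"
        )
    h = np.arange(-bounds[0], bounds[0] + 1)
    k = np.arange(-bounds[1], bounds[1] + 1)
    l = np.arange(-bounds[2], bounds[2] + 1)
    hh, kk, ll = np.meshgrid(h, k, l, indexing="ij")
    hkl = np.column_stack([hh.ravel(), kk.ravel(), ll.ravel()])
    q = cell.q_of(hkl)
    keep = (q <= q_max) & ~np.all(hkl == 0, axis=1)
    hkl, q = hkl[keep], q[keep]
    if len(hkl) > max_size:
        raise ValueError(
            f"index set of {len(hkl)} reflections exceeds cap max_size={max_size}"
        )
    return MillerIndexSet(hkl, q)


@dataclass
class Snapshot:
    """One sparse, partial, timestamped still observation.

    ``rows`` indexes into the experiment's :class:`MillerIndexSet`.
    """

    timestamp: float
    orientation: np.ndarray  # unit quaternion, scalar first
    rows: np.ndarray  # (m,) int
    intensity: np.ndarray  # (m,)
    partiality: np.ndarray  # (m,) in [0, 1]
    scale_G: float = 1.0
    bfactor_B: float = 0.0

    def __post_init__(self) -> None:
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.partiality = np.asarray(self.partiality, dtype=float)
        if self.orientation.shape != (4,):
            raise ValueError("orientation must be a length-4 quaternion")
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-9:
            raise ValueError("orientation quaternion must have unit norm")
        if not (len(self.rows) == len(self.intensity) == len(self.partiality)):
            raise ValueError("record arrays must have equal length")
        if len(self.partiality) and (
            self.partiality.min() < 0 or self.partiality.max() > 1.0 + 1e-12
        ):
            raise ValueError("partiality must lie in [0, 1]")

    @property
    def n_records(self) -> int:
        return len(self.rows)

    def copy(self) -> "Snapshot":
        return Snapshot(
            self.timestamp,
            self.orientation.copy(),
            self.rows.copy(),
            self.intensity.copy(),
            self.partiality.copy(),
            self.scale_G,
            self.bfactor_B,
        )


@dataclass
class SnapshotSeries:
    """Time-ordered snapshots sharing one index set, cell and beam."""

    snapshots: list[Snapshot]
    index_set: MillerIndexSet
    cell: UnitCell
    beam: BeamConfig

    def __post_init__(self) -> None:
        ts = self.timestamps
        if len(ts) > 1 and np.any(np.diff(ts) < 0):
            raise ValueError("snapshots must be ordered by timestamp")
        nmax = max((s.rows.max(initial=-1) for s in self.snapshots), default=-1)
        if nmax >= len(self.index_set):
            raise ValueError("snapshot references a row outside the index set")

    def __len__(self) -> int:
        return len(self.snapshots)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([s.timestamp for s in self.snapshots], dtype=float)

    def copy(self) -> "SnapshotSeries":
        return SnapshotSeries(
            [s.copy() for s in self.snapshots], self.index_set, self.cell, self.beam
        )


@dataclass
class DiffractionVolume:
    """Complete intensity assignment over a Miller index set."""

    index_set: MillerIndexSet
    intensity: np.ndarray
    timestamp: float | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.index_set),):
            raise ValueError("intensity must have one entry per Miller index")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("volume intensities must be finite")


@dataclass
class VolumeSeries:
    """Uniformly spaced time series of complete diffraction volumes.

    ``intensities`` is (D, N): one column per time point in index-set order.
    """

    index_set: MillerIndexSet
    intensities: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        D, N = self.intensities.shape
        if D != len(self.index_set):
            raise ValueError("row count must match the index set")
        if N != len(self.timestamps):
            raise ValueError("column count must match the timestamps")
        if N > 1:
            dt = np.diff(self.timestamps)
            if dt[0] <= 0 or np.any(np.abs(dt - dt[0]) > 1e-9 * abs(dt[0])):
                raise ValueError("timestamps must be uniformly increasing")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[1]

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.timestamps[1] - self.timestamps[0])

    def volume(self, i: int) -> DiffractionVolume:
        return DiffractionVolume(
            self.index_set, self.intensities[:, i], float(self.timestamps[i])
        )
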