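"""Monte Carlo merging baseline and quantitative comparison metrics.

Comparisons operate on intensities. The R-factor uses a symmetric
denominator, R = sum|I1 - I2| / sum (|I1| + |I2|)/2, which stays well
defined on zero-mean standardized data; the conventional sum|I1| form is
available behind ``denominator="reference"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import DiffractionVolume, MillerIndexSet, SnapshotSeries

logger = logging.getLogger(__name__)

__all__ = [
    "MergedVolume",
    "QShellScheme",
    "ShellRFactors",
    "monte_carlo_merge",
    "average_volumes",
    "common_finite",
    "standardize_volume",
    "pearson",
    "pearson_series",
    "qshell_rfactor",
    "completeness",
]


@dataclass
class MergedVolume:
    """Merge result: per-index mean intensity (NaN where never observed)
    plus measurement counts."""

    index_set: MillerIndexSet
    intensity: np.ndarray
    n_meas: np.ndarray

    @property
    def n_observed(self) -> int:
        return int(np.count_nonzero(self.n_meas))


def _friedel_partner_rows(index_set: MillerIndexSet) -> np.ndarray:
    """Row of (-h,-k,-l) for each row, or the row itself if absent."""
    partner = np.arange(len(index_set))
    for i, t in enumerate(index_set.hkl.tolist()):
        mate = (-t[0], -t[1], -t[2])
        if mate in index_set:
            partner[i] = index_set.row_of(mate)
    return partner


def monte_carlo_merge(
    series: SnapshotSeries,
    merge_friedel: bool = True,
    divide_partiality: bool = False,
    p_floor: float = 0.05,
) -> MergedVolume:
    """Unweighted per-reflection mean of all observed intensities.

    With ``merge_friedel`` each observation also contributes to its Friedel
    mate; ``divide_partiality`` corrects each record by its stored
    partiality first (records below ``p_floor`` dropped).
    """
    if len(series) == 0:
        raise ValueError("cannot merge an empty series")
    D = len(series.index_set)
    s = np.zeros(D)
    n = np.zeros(D, dtype=np.int64)
    for snap in series.snapshots:
        rows, I, p = snap.rows, snap.intensity, snap.partiality
        if divide_partiality:
            keep = p >= p_floor
            rows, I = rows[keep], I[keep] / p[keep]
        np.add.at(s, rows, I)
        np.add.at(n, rows, 1)
    if merge_friedel:
        partner = _friedel_partner_rows(series.index_set)
        nonself = partner != np.arange(D)
        s2, n2 = s.copy(), n.copy()
        s2[nonself] = s[nonself] + s[partner[nonself]]
        n2[nonself] = n[nonself] + n[partner[nonself]]
        s, n = s2, n2
    never = n == 0
    if never.any():
        logger.info("merge: %d reflections never observed", never.sum())
    with np.errstate(invalid="ignore"):
        mean = np.where(never, np.nan, s / np.maximum(n, 1))
    return MergedVolume(series.index_set, mean, n)


def average_volumes(series) -> DiffractionVolume:
    """Per-index arithmetic mean over a VolumeSeries (or anything with
    ``index_set`` and an ``intensities`` (D, N) array)."""
    return DiffractionVolume(series.index_set, series.intensities.mean(axis=1))


def common_finite(v1, v2) -> np.ndarray:
    """Rows where both volumes hold finite intensities (shared index set)."""
    if not v1.index_set.same_as(v2.index_set):
        raise ValueError(
            f"index sets differ: {len(v1.index_set)} vs {len(v2.index_set)} reflections"
        )
    return np.flatnonzero(np.isfinite(v1.intensity) & np.isfinite(v2.intensity))


def standardize_volume(v, common_indices: np.ndarray | None = None) -> DiffractionVolume:
    """Zero-mean, unit-variance rescaling over ``common_indices`` (all
    finite rows by default); non-common rows become NaN-free affine images
    of themselves under the same map."""
    I = np.asarray(v.intensity, dtype=float)
    rows = (
        np.flatnonzero(np.isfinite(I)) if common_indices is None else np.asarray(common_indices)
    )
    if len(rows) < 2:
        raise ValueError("need at least 2 common indices to standardize")
    mean = I[rows].mean()
    std = I[rows].std()
    if std == 0:
        raise ValueError("cannot standardize a constant volume")
    out = (np.nan_to_num(I, nan=mean) - mean) / std
    return DiffractionVolume(v.index_set, out, getattr(v, "timestamp", None))


def pearson(v1, v2, common_indices: np.ndarray | None = None) -> float:
    """Pearson linear correlation of two volumes over common indices."""
    rows = common_finite(v1, v2) if common_indices is None else np.asarray(common_indices)
    if len(rows) < 3:
        raise ValueError("need at least 3 common indices for a correlation")
    x = v1.intensity[rows]
    y = v2.intensity[rows]
    dx = x - x.mean()
    dy = y - y.mean()
    den = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if den == 0:
        raise ValueError("correlation undefined for constant input")
    return float((dx * dy).sum() / den)


def pearson_series(truth, recon) -> np.ndarray:
    """Per-time Pearson correlation between two (D, N) intensity arrays on
    the same index ordering (e.g. ground truth vs reconstruction)."""
    a = np.asarray(truth.intensities if hasattr(truth, "intensities") else truth)
    b = np.asarray(recon.intensities if hasattr(recon, "intensities") else recon)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    da = a - a.mean(axis=0)
    db = b - b.mean(axis=0)
    den = np.sqrt((da * da).sum(axis=0) * (db * db).sum(axis=0))
    if np.any(den == 0):
        raise ValueError("correlation undefined for constant columns")
    return (da * db).sum(axis=0) / den


@dataclass(frozen=True)
class QShellScheme:
    """Resolution shells in q = 1/d with strictly increasing edges.

    ``edges`` has n_shells + 1 entries; reflection q is assigned to the
    shell whose half-open interval [edge_i, edge_{i+1}) contains it (the
    last shell is closed above).
    """

    edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("shell edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @property
    def n_shells(self) -> int:
        return len(self.edges) - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def assign(self, q: np.ndarray) -> np.ndarray:
        """Shell index per reflection; -1 outside the scheme's range."""
        q = np.asarray(q, dtype=float)
        idx = np.searchsorted(self.edges, q, side="right") - 1
        idx[q == self.edges[-1]] = self.n_shells - 1
        idx[(q < self.edges[0]) | (q > self.edges[-1])] = -1
        return idx

    @classmethod
    def equal_count(cls, q: np.ndarray, n_shells: int = 20) -> "QShellScheme":
        """Shells holding (nearly) equal reflection counts."""
        q = np.sort(np.asarray(q, dtype=float))
        if n_shells < 1 or len(q) < n_shells:
            raise ValueError("need at least one reflection per shell")
        quantiles = np.linspace(0.0, 1.0, n_shells + 1)
        edges = np.quantile(q, quantiles)
        edges[0] -= 1e-12 + 1e-12 * abs(edges[0])
        edges[-1] += 1e-12 + 1e-12 * abs(edges[-1])
        edges = np.maximum.accumulate(edges)
        # Collapse degenerate edges (heavily tied q values).
        keep = np.concatenate(([True], np.diff(edges) > 0))
        return cls(edges[keep])


@dataclass
class ShellRFactors:
    """Per-shell R-factors (NaN marks empty shells) with summaries."""

    scheme: QShellScheme
    r: np.ndarray
    n_refl: np.ndarray

    @property
    def median(self) -> float:
        return float(np.nanmedian(self.r))

    @property
    def max(self) -> float:
        return float(np.nanmax(self.r))


def qshell_rfactor(
    v1,
    v2,
    scheme: QShellScheme | int = 20,
    denominator: str = "symmetric",
) -> ShellRFactors:
    """Per-q-shell R-factor between two volumes over common indices.

    symmetric:  R = sum|I1 - I2| / sum (|I1| + |I2|)/2
    reference:  R = sum|I1 - I2| / sum|I1|
    """
    rows = common_finite(v1, v2)
    q = v1.index_set.q[rows]
    if isinstance(scheme, int):
        scheme = QShellScheme.equal_count(q, scheme)
    I1 = v1.intensity[rows]
    I2 = v2.intensity[rows]
    shell = scheme.assign(q)
    r = np.full(scheme.n_shells, np.nan)
    n_refl = np.zeros(scheme.n_shells, dtype=np.int64)
    for s in range(scheme.n_shells):
        in_shell = shell == s
        n_refl[s] = np.count_nonzero(in_shell)
        if n_refl[s] == 0:
            logger.warning("q-shell %d is empty; R undefined", s)
            continue
        num = np.abs(I1[in_shell] - I2[in_shell]).sum()
        if denominator == "symmetric":
            den = 0.5 * (np.abs(I1[in_shell]) + np.abs(I2[in_shell])).sum()
        elif denominator == "reference":
            den = np.abs(I1[in_shell]).sum()
        else:
            raise ValueError(f"unknown denominator convention {denominator!r}")
        r[s] = num / den if den > 0 else np.nan
    return ShellRFactors(scheme=scheme, r=r, n_refl=n_refl)


def completeness(
    series: SnapshotSeries, full_set: MillerIndexSet | None = None
) -> tuple[np.ndarray, float]:
    """Per-snapshot recorded fraction and its mean.

    ``full_set`` defaults to the series' own index set; snapshots index into
    that set, so only its size enters.
    """
    full_set = full_set if full_set is not None else series.index_set
    if len(full_set) == 0:
        raise ValueError("full reflection set is empty")
    frac = np.array([len(np.unique(s.rows)) for s in series.snapshots]) / len(full_set)
    return frac, float(frac.mean())
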