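"""Per-snapshot scaling and the sparse-to-dense bridge for the NLSA stage.

Scale fitting mirrors the usual crystallographic linear model: for snapshot
j with records (I_obs, p, q),

    ln( I_obs / (p * I_ref) ) = ln G_j - B_j q^2 / 2

solved per snapshot by weighted least squares, alternated with a
partiality-corrected re-merge of the reference.

Densification turns a snapshot series into a D x N matrix standardized per
reflection over observed entries, with missing entries imputed at the
(standardized) mean, 0, and a boolean observation mask kept alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import DiffractionVolume, MillerIndexSet, Snapshot, SnapshotSeries

logger = logging.getLogger(__name__)

__all__ = ["ScaleModel", "DenseSeries", "fit_scales", "apply_scales", "standardize_densify"]

#: Minimum usable records for a per-snapshot scale fit.
DEFAULT_N_MIN = 10
#: Partiality floor below which records are excluded from fits/division.
DEFAULT_P_FLOOR = 0.05


@dataclass
class ScaleModel:
    """Fitted per-snapshot scale G_j and Debye-Waller B_j with diagnostics."""

    g: np.ndarray
    b: np.ndarray
    n_used: np.ndarray
    residual: np.ndarray
    flagged: np.ndarray  # snapshots that fell back to G=1, B=0

    def __post_init__(self) -> None:
        if np.any(self.g <= 0):
            raise ValueError("scale factors must be positive")


@dataclass
class DenseSeries:
    """Dense standardized matrix (D x N) with observation mask and the
    inverse-transform constants.

    Rows follow ``index_set`` order; ``index_set`` may be a subset of the
    experiment's full set when some reflections were never observed.
    """

    values: np.ndarray
    mask: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    timestamps: np.ndarray
    index_set: MillerIndexSet

    @property
    def n_reflections(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def destandardize(self, standardized: np.ndarray) -> np.ndarray:
        """Inverse transform: x * std_hkl + mean_hkl, row-wise."""
        return standardized * self.std[:, None] + self.mean[:, None]


def _snapshot_fit(
    snap: Snapshot,
    ref_intensity: np.ndarray,
    q2: np.ndarray,
    n_min: int,
    p_floor: float,
) -> tuple[float, float, int, float]:
    """WLS fit of (ln G, B) for one snapshot; returns (G, B, n_used, rss)."""
    I = snap.intensity
    p = snap.partiality
    ref = ref_intensity[snap.rows]
    ok = (I > 0) & (p >= p_floor) & (ref > 0) & np.isfinite(ref)
    n_used = int(np.count_nonzero(ok))
    if n_used < n_min:
        return 1.0, 0.0, n_used, np.nan
    y = np.log(I[ok] / (p[ok] * ref[ok]))
    x = -0.5 * q2[snap.rows[ok]]
    w = p[ok]
    # Normal equations for y = lnG + B * x with weights w.
    sw = w.sum()
    sx = (w * x).sum()
    sxx = (w * x * x).sum()
    sy = (w * y).sum()
    sxy = (w * x * y).sum()
    det = sw * sxx - sx * sx
    if det <= 0 or not np.isfinite(det):
        ln_g, b = sy / sw, 0.0
    else:
        ln_g = (sxx * sy - sx * sxy) / det
        b = (sw * sxy - sx * sy) / det
    resid = y - ln_g - b * x
    return float(np.exp(ln_g)), float(b), n_used, float((w * resid**2).sum())


def _corrected_merge(
    series: SnapshotSeries, model: ScaleModel, p_floor: float
) -> np.ndarray:
    """Partiality- and scale-corrected per-reflection mean (NaN where unseen)."""
    D = len(series.index_set)
    q2 = series.index_set.q**2
    s = np.zeros(D)
    n = np.zeros(D, dtype=np.int64)
    for j, snap in enumerate(series.snapshots):
        ok = snap.partiality >= p_floor
        rows = snap.rows[ok]
        corr = snap.intensity[ok] / (
            model.g[j] * np.exp(-0.5 * model.b[j] * q2[rows]) * snap.partiality[ok]
        )
        np.add.at(s, rows, corr)
        np.add.at(n, rows, 1)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, s / np.maximum(n, 1), np.nan)


def fit_scales(
    series: SnapshotSeries,
    reference: DiffractionVolume | None = None,
    iterations: int = 2,
    n_min: int = DEFAULT_N_MIN,
    p_floor: float = DEFAULT_P_FLOOR,
) -> ScaleModel:
    """Fit per-snapshot (G_j, B_j) against a reference volume.

    With ``reference=None`` the reference is bootstrapped from a
    partiality-corrected merge of the series itself and refined for
    ``iterations`` rounds of alternating snapshot fits and re-merges.
    Snapshots with fewer than ``n_min`` usable records fall back to
    (G=1, B=0) and are flagged.
    """
    if len(series) == 0:
        raise ValueError("cannot fit scales on an empty series")
    N = len(series)
    q2 = series.index_set.q**2
    model = ScaleModel(
        g=np.ones(N),
        b=np.zeros(N),
        n_used=np.zeros(N, dtype=np.int64),
        residual=np.full(N, np.nan),
        flagged=np.zeros(N, dtype=bool),
    )
    if reference is not None and not reference.index_set.same_as(series.index_set):
        raise ValueError("reference volume must share the series index set")
    ref = (
        reference.intensity
        if reference is not None
        else _corrected_merge(series, model, p_floor)
    )
    for it in range(max(1, iterations)):
        for j, snap in enumerate(series.snapshots):
            g, b, n_used, rss = _snapshot_fit(snap, ref, q2, n_min, p_floor)
            model.g[j], model.b[j] = g, b
            model.n_used[j], model.residual[j] = n_used, rss
            model.flagged[j] = n_used < n_min
        if model.flagged.any():
            logger.warning("%d snapshots flagged (G=1, B=0)", model.flagged.sum())
        if reference is None and it + 1 < max(1, iterations):
            ref = _corrected_merge(series, model, p_floor)
    return model


def apply_scales(
    series: SnapshotSeries,
    model: ScaleModel,
    divide_partiality: bool = False,
    p_floor: float = DEFAULT_P_FLOOR,
) -> SnapshotSeries:
    """Replace each record intensity by I / (G_j exp(-B_j q^2/2)), and
    additionally divide by the stored partiality when requested.

    With partiality division, records below the partiality floor are
    dropped (counted in the log).
    """
    if len(model.g) != len(series):
        raise ValueError("scale model does not cover every snapshot")
    q2 = series.index_set.q**2
    out = []
    n_dropped = 0
    for j, snap in enumerate(series.snapshots):
        s = snap.copy()
        corr = model.g[j] * np.exp(-0.5 * model.b[j] * q2[s.rows])
        if divide_partiality:
            keep = s.partiality >= p_floor
            n_dropped += int(np.count_nonzero(~keep))
            s.rows = s.rows[keep]
            s.intensity = s.intensity[keep] / (corr[keep] * s.partiality[keep])
            s.partiality = s.partiality[keep]
        else:
            s.intensity = s.intensity / corr
        out.append(s)
    if n_dropped:
        logger.info("partiality division dropped %d records below floor", n_dropped)
    return SnapshotSeries(out, series.index_set, series.cell, series.beam)


def standardize_densify(series: SnapshotSeries) -> DenseSeries:
    """Sparse series -> dense standardized matrix with observation mask.

    Per reflection, mean/std are computed over observed entries only;
    observed entries become (I - mean)/std and unobserved entries are
    imputed as 0 (the standardized mean). Reflections never observed are
    excluded from the matrix (logged); constant reflections get std = 0
    and a zero row (flagged in the log).
    """
    if len(series) == 0:
        raise ValueError("cannot densify an empty series")
    D = len(series.index_set)
    N = len(series)
    raw = np.zeros((D, N))
    mask = np.zeros((D, N), dtype=bool)
    for j, snap in enumerate(series.snapshots):
        raw[snap.rows, j] = snap.intensity
        mask[snap.rows, j] = True
    count = mask.sum(axis=1)
    seen = count > 0
    if not seen.all():
        logger.info("excluding %d never-observed reflections", np.count_nonzero(~seen))
    raw, mask, count = raw[seen], mask[seen], count[seen]
    index_set = series.index_set.subset(np.flatnonzero(seen))
    with np.errstate(invalid="ignore"):
        mean = np.where(mask, raw, 0.0).sum(axis=1) / count
        var = np.where(mask, (raw - mean[:, None]) ** 2, 0.0).sum(axis=1) / count
    std = np.sqrt(np.clip(var, 0.0, None))
    degenerate = std == 0
    if degenerate.any():
        logger.warning(
            "%d constant reflections standardized to zero rows",
            np.count_nonzero(degenerate),
        )
    safe_std = np.where(degenerate, 1.0, std)
    values = np.where(mask, (raw - mean[:, None]) / safe_std[:, None], 0.0)
    return DenseSeries(
        values=values,
        mask=mask,
        mean=mean,
        std=std,
        timestamps=series.timestamps,
        index_set=index_set,
    )
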