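"""Synthetic ground-truth dynamics and their degradation into snapshot series.

The generative chain is: a smooth two-endmember mixing path produces a
complete :class:`~trsfx.core.VolumeSeries`; each frame is observed as a
randomly oriented Ewald cut with spot-sphere partiality, a per-crystal
multiplicative scale (and optional Debye-Waller factor), additive Gaussian
intensity noise scaled to per-reflection variability, and Gaussian timestamp
jitter with optional out-of-range culling.

All randomness flows from one master seed through named substreams
(endmembers, orientations, scales, noise, jitter) so each stage is
independently reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    BeamConfig,
    DiffractionVolume,
    MillerIndexSet,
    Snapshot,
    SnapshotSeries,
    UnitCell,
    VolumeSeries,
    quat_to_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AlphaPath",
    "DynamicsSpec",
    "JitterConfig",
    "NoiseConfig",
    "wilson_intensities",
    "correlated_endmembers",
    "make_volume_series",
    "random_orientation",
    "partiality_factor",
    "ewald_cut",
    "add_noise",
    "apply_jitter",
    "spot_radius_rule",
    "calibrate_spot_radius",
    "substream_rngs",
    "observation_probability",
    "simulate_dataset",
]

_SUBSTREAMS = ("endmembers", "orientations", "scales", "noise", "jitter")


def substream_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Named, independent random substreams derived from one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_SUBSTREAMS, children)}


@dataclass(frozen=True)
class AlphaPath:
    """Mixing coordinate alpha(t) in [0, 1].

    A cubic smooth step centred at ``t0`` with full width ``width``, plus an
    optional damped oscillation riding on the stepped portion:

        alpha(t) = clip(s(t) * (1 + amp * sin(2 pi (t - t0)/period)
                                  * exp(-max(t - t0, 0)/decay)), 0, 1)

    with s the smooth step. ``amp = 0`` gives the pure monotone step.
    """

    t0: float = 0.0
    width: float = 1.0
    osc_amplitude: float = 0.0
    osc_period: float = 1.0
    osc_decay: float = math.inf

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        u = np.clip((t - self.t0) / self.width + 0.5, 0.0, 1.0)
        s = u * u * (3.0 - 2.0 * u)
        if self.osc_amplitude != 0.0:
            phase = 2.0 * np.pi * (t - self.t0) / self.osc_period
            damp = np.exp(-np.maximum(t - self.t0, 0.0) / self.osc_decay)
            s = s * (1.0 + self.osc_amplitude * np.sin(phase) * damp)
        return np.clip(s, 0.0, 1.0)


@dataclass
class DynamicsSpec:
    """Ground-truth dynamics: two endmember volumes mixed along alpha(t)."""

    index_set: MillerIndexSet
    i_a: np.ndarray
    i_b: np.ndarray
    n_frames: int
    dt: float = 1.0
    alpha: AlphaPath = field(default_factory=AlphaPath)
    t_start: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.i_a = np.asarray(self.i_a, dtype=float)
        self.i_b = np.asarray(self.i_b, dtype=float)
        D = len(self.index_set)
        if self.i_a.shape != (D,) or self.i_b.shape != (D,):
            raise ValueError("endmember intensity sets must match the index set")
        if self.i_a.min() < 0 or self.i_b.min() < 0:
            raise ValueError("endmember intensities must be non-negative")
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        if self.dt <= 0:
            raise ValueError("frame spacing must be positive")


@dataclass(frozen=True)
class JitterConfig:
    """Gaussian timestamp jitter (same time units as the series)."""

    sigma: float
    cull_out_of_range: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("jitter sigma must be non-negative")


@dataclass(frozen=True)
class NoiseConfig:
    """Additive Gaussian noise: sigma_hkl = kappa * std of that reflection's
    observed intensities across the series."""

    kappa: float

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("noise scale kappa must be non-negative")


def wilson_intensities(
    index_set: MillerIndexSet, rng: np.random.Generator, b_wilson: float = 30.0
) -> np.ndarray:
    """Exponentially distributed intensities with a Wilson-like resolution
    falloff exp(-B q^2 / 2) as the per-reflection mean."""
    mean = np.exp(-0.5 * b_wilson * index_set.q**2)
    return rng.exponential(mean)


def correlated_endmembers(
    index_set: MillerIndexSet,
    rng: np.random.Generator,
    b_wilson: float = 30.0,
    mix: float = 0.85,
) -> tuple[np.ndarray, np.ndarray]:
    """Two endmember volumes sharing a fraction ``mix`` of their structure.

    ``i_b = mix * i_a + (1 - mix) * e`` with ``e`` an independent Wilson
    draw, mimicking a modest excited-state intensity change.
    """
    if not 0.0 <= mix <= 1.0:
        raise ValueError("mix must lie in [0, 1]")
    i_a = wilson_intensities(index_set, rng, b_wilson)
    e = wilson_intensities(index_set, rng, b_wilson)
    return i_a, mix * i_a + (1.0 - mix) * e


def make_volume_series(spec: DynamicsSpec) -> VolumeSeries:
    """Frame t carries (1 - alpha(t)) * I_A + alpha(t) * I_B per index."""
    t = spec.t_start + spec.dt * np.arange(spec.n_frames)
    a = spec.alpha(t)
    intensities = np.outer(spec.i_a, 1.0 - a) + np.outer(spec.i_b, a)
    return VolumeSeries(spec.index_set, intensities, t)


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """Unit quaternion uniform on SO(3) (4 standard normals, normalized)."""
    q = rng.standard_normal(4)
    n = np.linalg.norm(q)
    while n < 1e-12:  # pragma: no cover - probability zero in practice
        q = rng.standard_normal(4)
        n = np.linalg.norm(q)
    return q / n


def partiality_factor(dist, R: float):
    """Partiality from the spot-sphere / Ewald-sphere circular cross section.

    The intersection circle has radius S = sqrt(R^2 - dist^2); the recorded
    fraction is the area ratio p = (S/R)^2 = 1 - (dist/R)^2, zero beyond R.
    """
    dist = np.asarray(dist, dtype=float)
    if R <= 0:
        raise ValueError("spot radius R must be positive")
    if np.any(dist < 0):
        raise ValueError("distance must be non-negative")
    p = 1.0 - (dist / R) ** 2
    return np.clip(p, 0.0, None) * (dist <= R)


def _ewald_distances(
    g: np.ndarray, orientation: np.ndarray, wavelength: float
) -> np.ndarray:
    """|  |g_rot + k_in| - 1/lambda  | with k_in = (0, 0, -1/lambda)."""
    rot = quat_to_matrix(orientation)
    g_rot = g @ rot.T
    k = 1.0 / wavelength
    shifted = g_rot.copy()
    shifted[:, 2] -= k
    return np.abs(np.linalg.norm(shifted, axis=1) - k)


def ewald_cut(
    volume: DiffractionVolume,
    orientation: np.ndarray,
    beam: BeamConfig,
    cell: UnitCell,
    partiality_mode: str = "area",
) -> Snapshot:
    """Observe a complete volume as a randomly oriented still.

    Reflections whose rotated reciprocal vector lies within ``R`` of the
    Ewald sphere are recorded with intensity ``p * I``; others are absent.
    ``partiality_mode`` selects the area ratio ``(S/R)^2`` (default) or the
    radius ratio ``S/R``.
    """
    g = volume.index_set.hkl @ cell.reciprocal_basis.T
    return ewald_cut_g(volume, g, orientation, beam, partiality_mode)


def ewald_cut_g(
    volume: DiffractionVolume,
    g: np.ndarray,
    orientation: np.ndarray,
    beam: BeamConfig,
    partiality_mode: str = "area",
) -> Snapshot:
    """Like :func:`ewald_cut` but with precomputed reciprocal vectors ``g``
    (one row per index-set entry), avoiding repeated basis products."""
    dist = _ewald_distances(g, orientation, beam.wavelength)
    R = beam.spot_radius_R
    hit = dist <= R
    rows = np.flatnonzero(hit)
    p = partiality_factor(dist[rows], R)
    if partiality_mode == "radius":
        p = np.sqrt(p)
    elif partiality_mode != "area":
        raise ValueError(f"unknown partiality mode {partiality_mode!r}")
    snap = Snapshot(
        timestamp=volume.timestamp if volume.timestamp is not None else 0.0,
        orientation=np.asarray(orientation, dtype=float),
        rows=rows,
        intensity=p * volume.intensity[rows],
        partiality=p,
    )
    if snap.n_records == 0:
        logger.debug("empty snapshot at t=%s", snap.timestamp)
    return snap


def add_noise(
    series: SnapshotSeries, cfg: NoiseConfig, rng: np.random.Generator
) -> SnapshotSeries:
    """Add N(0, sigma_hkl^2) to every record, sigma_hkl = kappa times the
    standard deviation of that reflection's observed intensities.

    Reflections observed fewer than twice get sigma = 0 (logged).
    """
    if len(series) == 0:
        raise ValueError("cannot add noise to an empty series")
    if cfg.kappa == 0.0:
        return series.copy()
    D = len(series.index_set)
    count = np.zeros(D, dtype=np.int64)
    s1 = np.zeros(D)
    s2 = np.zeros(D)
    for snap in series.snapshots:
        np.add.at(count, snap.rows, 1)
        np.add.at(s1, snap.rows, snap.intensity)
        np.add.at(s2, snap.rows, snap.intensity**2)
    sigma = np.zeros(D)
    multi = count >= 2
    mean = np.where(multi, s1 / np.maximum(count, 1), 0.0)
    var = np.where(multi, s2 / np.maximum(count, 1) - mean**2, 0.0)
    sigma[multi] = cfg.kappa * np.sqrt(np.clip(var[multi], 0.0, None))
    n_single = int(np.count_nonzero((count > 0) & ~multi))
    if n_single:
        logger.warning(
            "%d reflections observed fewer than twice: no noise added", n_single
        )
    out = []
    for snap in series.snapshots:
        s = snap.copy()
        s.intensity = s.intensity + rng.standard_normal(len(s.rows)) * sigma[s.rows]
        out.append(s)
    return SnapshotSeries(out, series.index_set, series.cell, series.beam)


def apply_jitter(
    series: SnapshotSeries, cfg: JitterConfig, rng: np.random.Generator
) -> SnapshotSeries:
    """Perturb timestamps with N(0, sigma^2), re-sort, optionally cull
    snapshots whose new timestamp leaves the original [t_min, t_max]."""
    if cfg.sigma == 0.0:
        return series.copy()
    ts = series.timestamps
    t_min, t_max = float(ts.min()), float(ts.max())
    new_ts = ts + rng.normal(0.0, cfg.sigma, size=len(ts))
    keep = np.ones(len(ts), dtype=bool)
    if cfg.cull_out_of_range:
        keep = (new_ts >= t_min) & (new_ts <= t_max)
    order = np.argsort(new_ts[keep], kind="stable")
    kept_idx = np.flatnonzero(keep)[order]
    out = []
    for i in kept_idx:
        s = series.snapshots[i].copy()
        s.timestamp = float(new_ts[i])
        out.append(s)
    return SnapshotSeries(out, series.index_set, series.cell, series.beam)


def spot_radius_rule(a: float, factor: float = 25.0) -> float:
    """Geometric spot-radius reading: one ``factor``-th of the reciprocal
    spacing 1/a."""
    return (1.0 / a) / factor


def observation_probability(index_set: MillerIndexSet, R: float) -> np.ndarray:
    """Analytic probability that a reflection at |g| = q is recorded by a
    uniformly oriented Ewald cut: min(R/q, 1).

    Derived from the uniform distribution of the rotated point on its
    radius-q sphere and the geometry of the Ewald sphere through the origin
    (valid for q well below 2/lambda).
    """
    if R <= 0:
        raise ValueError("spot radius R must be positive")
    q = index_set.q
    with np.errstate(divide="ignore"):
        return np.minimum(np.where(q > 0, R / q, np.inf), 1.0)


def calibrate_spot_radius(
    index_set: MillerIndexSet, target_completeness: float = 0.02
) -> float:
    """Spot radius giving a requested mean per-snapshot recorded fraction.

    Inverts mean(min(R/q, 1)) = target via bisection on the analytic
    observation probability.
    """
    if not 0.0 < target_completeness <= 1.0:
        raise ValueError("target completeness must lie in (0, 1]")
    q = index_set.q
    lo, hi = 0.0, float(q.max())
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(np.minimum(mid / q, 1.0))) if mid > 0 else 0.0
        if frac < target_completeness:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_dataset(
    dynamics: DynamicsSpec,
    beam: BeamConfig,
    cell: UnitCell,
    noise: NoiseConfig,
    jitter: JitterConfig,
    scale_spread: float = 0.1,
    bfactor_spread: float = 0.0,
    seed: int | None = None,
    partiality_mode: str = "area",
) -> tuple[VolumeSeries, SnapshotSeries]:
    """Full generative pipeline: volumes -> oriented Ewald cuts ->
    per-crystal scale/Debye-Waller -> additive noise -> timestamp jitter.

    Returns the ground truth volume series and the degraded snapshot
    series. Deterministic under ``seed`` (defaults to ``dynamics.seed``).
    """
    if seed is None:
        seed = dynamics.seed
    rngs = substream_rngs(seed)
    truth = make_volume_series(dynamics)
    g = dynamics.index_set.hkl @ cell.reciprocal_basis.T
    q2 = dynamics.index_set.q**2
    snaps = []
    for i in range(truth.n_frames):
        vol = truth.volume(i)
        quat = random_orientation(rngs["orientations"])
        snap = ewald_cut_g(vol, g, quat, beam, partiality_mode)
        G = float(np.exp(rngs["scales"].normal(0.0, np.log1p(scale_spread))))
        B = (
            float(abs(rngs["scales"].normal(0.0, bfactor_spread)))
            if bfactor_spread > 0
            else 0.0
        )
        snap.scale_G = G
        snap.bfactor_B = B
        factor = G * np.exp(-0.5 * B * q2[snap.rows])
        snap.intensity = snap.intensity * factor
        snaps.append(snap)
    series = SnapshotSeries(snaps, dynamics.index_set, cell, beam)
    series = add_noise(series, noise, rngs["noise"])
    series = apply_jitter(series, jitter, rngs["jitter"])
    frac = np.mean([s.n_records for s in series.snapshots]) / len(dynamics.index_set)
    logger.info(
        "simulated %d snapshots, mean completeness %.3f%%", len(series), 100 * frac
    )
    return truth, series
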