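"""Text formats: snapshot streams, reflection lists, volume series, configs.

All formats are plain text and canonical for tests. Floats are written
with 17 significant digits so write/read round-trips are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import (
    BeamConfig,
    DiffractionVolume,
    MillerIndexSet,
    Snapshot,
    SnapshotSeries,
    UnitCell,
    VolumeSeries,
    build_index_set,
)

__all__ = [
    "StreamFormatError",
    "write_snapshot_stream",
    "read_snapshot_stream",
    "write_reflections",
    "read_reflections",
    "write_volume_series",
    "read_volume_series",
    "read_config",
    "write_manifest",
]

_F = "%.17g"


class StreamFormatError(ValueError):
    """Malformed snapshot stream, carrying the offending line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def _fmt(x: float) -> str:
    return _F % x


def write_snapshot_stream(series: SnapshotSeries, path: str | Path) -> None:
    """Write a snapshot series in the block text format.

    Header comments carry the cell, resolution cutoff, beam energy and spot
    radius so the stream is self-contained for re-reading.
    """
    cell = series.cell
    d_min = 1.0 / series.index_set.q.max() if len(series.index_set) else 0.0
    lines = [
        "# trsfx snapshot stream v1",
        f"# cell {_fmt(cell.a)} {_fmt(cell.b)} {_fmt(cell.c)} "
        f"{_fmt(cell.alpha)} {_fmt(cell.beta)} {_fmt(cell.gamma)}",
        f"# d_min {_fmt(d_min)}",
        f"# energy_kev {_fmt(series.beam.photon_energy)}",
        f"# spot_radius {_fmt(series.beam.spot_radius_R)}",
    ]
    hkl = series.index_set.hkl
    for snap in series.snapshots:
        lines.append("BEGIN SNAPSHOT")
        lines.append(f"timestamp_fs {_fmt(snap.timestamp)}")
        lines.append("quat " + " ".join(_fmt(v) for v in snap.orientation))
        lines.append(f"scale {_fmt(snap.scale_G)} {_fmt(snap.bfactor_B)}")
        for r, I, p in zip(snap.rows, snap.intensity, snap.partiality):
            h, k, l = hkl[r]
            lines.append(f"{h} {k} {l} {_fmt(I)} {_fmt(p)}")
        lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_snapshot_stream(
    path: str | Path,
    index_set: MillerIndexSet | None = None,
    cell: UnitCell | None = None,
    beam: BeamConfig | None = None,
) -> SnapshotSeries:
    """Parse a snapshot stream; geometry defaults to the file header."""
    header: dict[str, list[float]] = {}
    snapshots: list[Snapshot] = []
    state = "between"  # between | header_of_block | records
    ts = quat = scale = None
    records: list[tuple[int, int, int, float, float]] = []
    begin_line = 0

    def finish(line_no: int) -> None:
        nonlocal ts, quat, scale, records
        if ts is None or quat is None:
            raise StreamFormatError(line_no, "snapshot block missing timestamp or quat")
        snapshots.append((ts, quat, scale or (1.0, 0.0), records))
        ts = quat = scale = None
        records = []

    with open(path) as fh:
        line_no = 0
        for raw in fh:
            line_no += 1
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] in {"cell", "d_min", "energy_kev", "spot_radius"}:
                    header[parts[0]] = [float(v) for v in parts[1:]]
                continue
            if line == "BEGIN SNAPSHOT":
                if state != "between":
                    raise StreamFormatError(line_no, "nested BEGIN SNAPSHOT")
                state = "records"
                begin_line = line_no
                continue
            if line == "END":
                if state != "records":
                    raise StreamFormatError(line_no, "END outside a snapshot block")
                finish(line_no)
                state = "between"
                continue
            if state != "records":
                raise StreamFormatError(line_no, f"unexpected content {line!r}")
            parts = line.split()
            try:
                if parts[0] == "timestamp_fs":
                    ts = float(parts[1])
                elif parts[0] == "quat":
                    quat = tuple(float(v) for v in parts[1:5])
                    if len(quat) != 4:
                        raise StreamFormatError(line_no, "quat needs 4 components")
                elif parts[0] == "scale":
                    scale = (float(parts[1]), float(parts[2]))
                else:
                    h, k, l = (int(parts[i]) for i in range(3))
                    records.append((h, k, l, float(parts[3]), float(parts[4])))
            except StreamFormatError:
                raise
            except (ValueError, IndexError) as exc:
                raise StreamFormatError(line_no, f"cannot parse record: {exc}") from exc
    if state != "between":
        raise StreamFormatError(begin_line, "snapshot block not closed by END")

    if cell is None:
        if "cell" not in header:
            raise StreamFormatError(0, "no cell in header and none supplied")
        cell = UnitCell(*header["cell"][:6])
    if index_set is None:
        if "d_min" not in header:
            raise StreamFormatError(0, "no d_min in header and no index set supplied")
        index_set = build_index_set(cell, header["d_min"][0] * (1 - 1e-12))
    if beam is None:
        if "energy_kev" not in header or "spot_radius" not in header:
            raise StreamFormatError(0, "no beam parameters in header or arguments")
        beam = BeamConfig(header["energy_kev"][0], header["spot_radius"][0])

    built: list[Snapshot] = []
    for ts_v, quat_v, (g, b), recs in snapshots:
        if recs:
            hkl = np.array([r[:3] for r in recs], dtype=np.int64)
            rows = index_set.rows_of(hkl)
            intensity = np.array([r[3] for r in recs])
            part = np.array([r[4] for r in recs])
        else:
            rows = np.empty(0, dtype=np.int64)
            intensity = np.empty(0)
            part = np.empty(0)
        built.append(Snapshot(ts_v, np.array(quat_v), rows, intensity, part, g, b))
    return SnapshotSeries(built, index_set, cell, beam)


def write_reflections(
    index_set: MillerIndexSet,
    intensity: np.ndarray,
    path: str | Path,
    sigma: np.ndarray | None = None,
    nmeas: np.ndarray | None = None,
    drop_nan: bool = True,
) -> None:
    """Merged reflection list: rows ``h k l I [sigma] [nmeas]``.

    Columns are positional, so requesting ``nmeas`` without ``sigma``
    writes a zero sigma column to keep the layout unambiguous.
    """
    if nmeas is not None and sigma is None:
        sigma = np.zeros(len(index_set))
    cols = "h k l I" + (" sigma" if sigma is not None else "") + (
        " nmeas" if nmeas is not None else ""
    )
    lines = [f"# {cols}"]
    for i, (h, k, l) in enumerate(index_set.hkl):
        I = intensity[i]
        if drop_nan and not np.isfinite(I):
            continue
        row = f"{h} {k} {l} {_fmt(I)}"
        if sigma is not None:
            row += f" {_fmt(sigma[i])}"
        if nmeas is not None:
            row += f" {int(nmeas[i])}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_reflections(path: str | Path):
    """Read ``h k l I [sigma] [nmeas]`` rows (comments allowed, extra
    columns tolerated). Returns (hkl, I, sigma, nmeas); absent columns are
    None."""
    hkl, I, sig, nm = [], [], [], []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: line {line_no}: need at least h k l I")
            hkl.append([int(parts[0]), int(parts[1]), int(parts[2])])
            I.append(float(parts[3]))
            sig.append(float(parts[4]) if len(parts) > 4 else np.nan)
            nm.append(int(float(parts[5])) if len(parts) > 5 else -1)
    hkl_arr = np.array(hkl, dtype=np.int64).reshape(-1, 3)
    sig_arr = np.array(sig)
    nm_arr = np.array(nm)
    return (
        hkl_arr,
        np.array(I),
        None if np.all(np.isnan(sig_arr)) else sig_arr,
        None if np.all(nm_arr < 0) else nm_arr,
    )


def write_volume_series(
    series: VolumeSeries, path: str | Path, cell: UnitCell | None = None
) -> None:
    """Volume series as text: one reflection per row, one time per column."""
    lines = ["# trsfx volume series v1"]
    if cell is not None:
        lines.append(
            f"# cell {_fmt(cell.a)} {_fmt(cell.b)} {_fmt(cell.c)} "
            f"{_fmt(cell.alpha)} {_fmt(cell.beta)} {_fmt(cell.gamma)}"
        )
    lines.append("# timestamps " + " ".join(_fmt(t) for t in series.timestamps))
    for i, (h, k, l) in enumerate(series.index_set.hkl):
        vals = " ".join(_fmt(v) for v in series.intensities[i])
        lines.append(f"{h} {k} {l} {_fmt(series.index_set.q[i])} {vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_volume_series(path: str | Path) -> VolumeSeries:
    timestamps = None
    hkl, q, rows = [], [], []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "timestamps":
                    timestamps = np.array([float(v) for v in parts[1:]])
                continue
            parts = line.split()
            hkl.append([int(parts[0]), int(parts[1]), int(parts[2])])
            q.append(float(parts[3]))
            rows.append([float(v) for v in parts[4:]])
    if timestamps is None:
        raise ValueError(f"{path}: missing '# timestamps' header")
    index_set = MillerIndexSet(np.array(hkl), np.array(q))
    # MillerIndexSet sorts rows; mirror that ordering on the intensities.
    order = np.lexsort(
        (np.array(hkl)[:, 2], np.array(hkl)[:, 1], np.array(hkl)[:, 0])
    )
    return VolumeSeries(index_set, np.array(rows)[order], timestamps)


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` (or ``key value``) file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                key, _, value = line.partition("=")
            else:
                key, _, value = line.partition(" ")
            key, value = key.strip(), value.strip()
            if not key or not value:
                raise ValueError(f"{path}: line {line_no}: expected 'key = value'")
            if key in out:
                raise ValueError(f"{path}: line {line_no}: duplicate key {key!r}")
            out[key] = value
    return out


def write_manifest(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
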