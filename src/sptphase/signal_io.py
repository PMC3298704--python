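"""Trial recordings on disk: a self-describing delimited text format.

A trial file is a ``#``-prefixed ``key: value`` header followed by two CSV
blocks separated by a blank line::

    # trial_id: s01_t1
    # fs_force: 600
    # fs_kin: 60
    # force_units: N
    # length_units: m
    time,f_trailing_hand,f_initial_seat,f_target_seat
    0.000000,2.71,762.93,0.04
    ...

    time,c7_x,c7_y,c7_z
    0.000000,0.012345,-0.0042,0.591
    ...

Forces are vertical reaction forces, positive upward (support force is
positive); positions are metres. Units other than N/m may be declared in the
header and are converted on read. Occluded marker samples are empty cells:
runs of up to 3 occluded kinematic frames are linearly interpolated with a
warning, longer runs are an error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RawTrial",
    "ValidationReport",
    "TrialParseError",
    "read_trial",
    "write_trial",
    "validate_trial",
    "events_to_json",
    "phases_to_json",
]

HEADER_KEYS = ("trial_id", "fs_force", "fs_kin", "force_units", "length_units")
FORCE_COLUMNS = ("time", "f_trailing_hand", "f_initial_seat", "f_target_seat")
KIN_COLUMNS = ("time", "c7_x", "c7_y", "c7_z")

_FORCE_UNITS = {"N": 1.0, "kN": 1000.0, "lbf": 4.4482216152605}
_LENGTH_UNITS = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}

MAX_OCCLUSION_RUN = 3


class TrialParseError(ValueError):
    """Malformed trial file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass
class RawTrial:
    """Unprocessed multi-rate signals for one transfer attempt."""

    trial_id: str
    force_time: np.ndarray
    f_trailing_hand: np.ndarray
    f_initial_seat: np.ndarray
    f_target_seat: np.ndarray
    kin_time: np.ndarray
    c7_xyz: np.ndarray
    fs_force: float = 600.0
    fs_kin: float = 60.0
    occluded_frames: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int))

    @property
    def n_force(self) -> int:
        return len(self.force_time)

    @property
    def n_kin(self) -> int:
        return len(self.kin_time)

    @property
    def duration_s(self) -> float:
        return self.n_kin / self.fs_kin


@dataclass
class ValidationReport:
    """Findings from :func:`validate_trial`; empty means accepted."""

    issues: list[tuple[str, str]] = field(default_factory=list)

    def add(self, severity: str, message: str) -> None:
        self.issues.append((severity, message))

    @property
    def errors(self) -> list[str]:
        return [m for s, m in self.issues if s == "error"]

    @property
    def warnings(self) -> list[str]:
        return [m for s, m in self.issues if s == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors


def _parse_float(cell: str, line_no: int, col: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise TrialParseError(f"non-numeric value {cell!r} in column {col!r}",
                              line_no) from None


def read_trial(path, format_hint: str = "auto") -> RawTrial:
    """Read and unit-normalize a trial file.

    ``format_hint`` accepts ``auto`` or ``csv`` (the native dialect); both
    currently parse the same dialect — ``auto`` is the extension point for
    optional C3D ingestion.
    """
    if format_hint not in ("auto", "csv"):
        raise ValueError(f"unknown format_hint {format_hint!r}")
    path = Path(path)
    lines = path.read_text().splitlines()

    header: dict[str, str] = {}
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        body = lines[i][1:].strip()
        if ":" not in body:
            raise TrialParseError("header line without 'key: value'", i + 1)
        key, _, value = body.partition(":")
        header[key.strip()] = value.strip()
        i += 1
    missing = [k for k in HEADER_KEYS if k not in header]
    if missing:
        raise TrialParseError(f"missing header keys: {', '.join(missing)}",
                              i or 1)
    try:
        fs_force = float(header["fs_force"])
        fs_kin = float(header["fs_kin"])
    except ValueError:
        raise TrialParseError("sampling rates in header must be numeric", 1) from None
    if header["force_units"] not in _FORCE_UNITS:
        raise TrialParseError(f"unknown force_units {header['force_units']!r}", 1)
    if header["length_units"] not in _LENGTH_UNITS:
        raise TrialParseError(f"unknown length_units {header['length_units']!r}", 1)
    f_scale = _FORCE_UNITS[header["force_units"]]
    l_scale = _LENGTH_UNITS[header["length_units"]]

    def read_block(start: int, columns) -> tuple[list[list[float | None]], int]:
        if start >= len(lines) or lines[start].strip() == "":
            raise TrialParseError("expected a column-header line", start + 1)
        cols = tuple(c.strip() for c in lines[start].split(","))
        if cols != columns:
            raise TrialParseError(
                f"expected columns {','.join(columns)}, got {','.join(cols)}",
                start + 1)
        rows: list[list[float | None]] = []
        j = start + 1
        while j < len(lines) and lines[j].strip() != "":
            cells = lines[j].split(",")
            if len(cells) != len(columns):
                raise TrialParseError(
                    f"expected {len(columns)} cells, got {len(cells)}", j + 1)
            row = [None if c.strip() == "" else _parse_float(c, j + 1, columns[k])
                   for k, c in enumerate(cells)]
            rows.append(row)
            j += 1
        if not rows:
            raise TrialParseError("empty data block", start + 1)
        return rows, j

    force_rows, j = read_block(i, FORCE_COLUMNS)
    for r, row in enumerate(force_rows):
        if any(c is None for c in row):
            raise TrialParseError("empty cell in force block", i + 2 + r)
    while j < len(lines) and lines[j].strip() == "":
        j += 1
    kin_rows, _ = read_block(j, KIN_COLUMNS)
    for r, row in enumerate(kin_rows):
        if row[0] is None:
            raise TrialParseError("empty time cell in kinematic block", j + 2 + r)

    force = np.array(force_rows, dtype=float)
    kin = np.array([[np.nan if c is None else c for c in row]
                    for row in kin_rows], dtype=float)

    c7 = kin[:, 1:4] * l_scale
    occluded = np.nonzero(np.isnan(c7).any(axis=1))[0]
    if len(occluded):
        c7 = _interpolate_occlusions(c7, occluded)
        warnings.warn(
            f"{len(occluded)} occluded kinematic frame(s) linearly interpolated",
            stacklevel=2)

    return RawTrial(
        trial_id=header["trial_id"],
        force_time=force[:, 0],
        f_trailing_hand=force[:, 1] * f_scale,
        f_initial_seat=force[:, 2] * f_scale,
        f_target_seat=force[:, 3] * f_scale,
        kin_time=kin[:, 0],
        c7_xyz=c7,
        fs_force=fs_force,
        fs_kin=fs_kin,
        occluded_frames=occluded,
    )


def _interpolate_occlusions(c7: np.ndarray, occluded: np.ndarray) -> np.ndarray:
    """Fill short occlusion runs (<= MAX_OCCLUSION_RUN) by linear interpolation."""
    runs = np.split(occluded, np.nonzero(np.diff(occluded) > 1)[0] + 1)
    n = c7.shape[0]
    for run in runs:
        if len(run) > MAX_OCCLUSION_RUN:
            raise TrialParseError(
                f"occlusion run of {len(run)} kinematic frames exceeds the "
                f"{MAX_OCCLUSION_RUN}-frame interpolation limit")
        if run[0] == 0 or run[-1] == n - 1:
            raise TrialParseError("occlusion at trial boundary cannot be "
                                  "interpolated")
    out = c7.copy()
    idx = np.arange(n)
    good = ~np.isnan(c7).any(axis=1)
    for k in range(3):
        out[~good, k] = np.interp(idx[~good], idx[good], c7[good, k])
    return out


def write_trial(trial: RawTrial, path) -> None:
    """Write a trial in the native dialect (SI units, 6-decimal precision)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# trial_id: {trial.trial_id}\n")
        fh.write(f"# fs_force: {trial.fs_force:g}\n")
        fh.write(f"# fs_kin: {trial.fs_kin:g}\n")
        fh.write("# force_units: N\n")
        fh.write("# length_units: m\n")
        fh.write(",".join(FORCE_COLUMNS) + "\n")
        for row in zip(trial.force_time, trial.f_trailing_hand,
                       trial.f_initial_seat, trial.f_target_seat):
            fh.write(",".join(f"{v:.6f}" for v in row) + "\n")
        fh.write("\n")
        fh.write(",".join(KIN_COLUMNS) + "\n")
        for t, xyz in zip(trial.kin_time, trial.c7_xyz):
            fh.write(f"{t:.6f}," + ",".join(f"{v:.6f}" for v in xyz) + "\n")


def validate_trial(trial: RawTrial,
                   negative_force_tol_N: float = 10.0) -> ValidationReport:
    """Sanity-check a raw trial; never mutates its input.

    Errors block processing (invariant violations); warnings flag content
    that is suspicious but processable.
    """
    rep = ValidationReport()
    n_f = trial.n_force
    for name in ("f_trailing_hand", "f_initial_seat", "f_target_seat"):
        if len(getattr(trial, name)) != n_f:
            rep.add("error", f"force channel {name} length differs from force_time")
    if trial.c7_xyz.shape[0] != trial.n_kin:
        rep.add("error", "c7_xyz length differs from kin_time")

    factor = trial.fs_force / trial.fs_kin
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        rep.add("error",
                f"non-integer decimation factor {trial.fs_force:g}/{trial.fs_kin:g}")

    if n_f and trial.n_kin:
        if abs(trial.force_time[0] - trial.kin_time[0]) > 1.0 / trial.fs_kin:
            rep.add("error", "force and kinematic grids do not start at the "
                             "same instant (within one kinematic frame)")
    for arr, label in ((trial.force_time, "force_time"),
                       (trial.kin_time, "kin_time")):
        if len(arr) > 1 and np.any(np.diff(arr) <= 0):
            rep.add("error", f"{label} is not strictly increasing")

    for name in ("f_trailing_hand", "f_initial_seat", "f_target_seat"):
        ch = getattr(trial, name)
        if len(ch) == n_f:
            if np.any(ch < -negative_force_tol_N):
                rep.add("warning",
                        f"{name} has vertical forces below "
                        f"-{negative_force_tol_N:g} N (sign convention is "
                        "reaction force positive upward)")
            if len(ch) and np.max(np.abs(ch)) < 1e-9:
                rep.add("warning", f"{name} is identically zero; events on "
                                   "this channel will not be detectable")

    if trial.n_kin and len(trial.occluded_frames) > 0.10 * trial.n_kin:
        rep.add("warning",
                f"{len(trial.occluded_frames)} of {trial.n_kin} kinematic "
                "frames (>10%) were occluded")
    if trial.duration_s < 2.0:
        rep.add("warning", "trial shorter than 2 s of quiet baseline plus "
                           "movement; detection may fail")
    if trial.n_kin < 20:
        rep.add("warning", "fewer than 20 kinematic frames of quiet-sitting "
                           "baseline available")
    return rep


def events_to_json(markers, path=None) -> str:
    """Serialize event markers (seconds + frame indices) as JSON."""
    text = json.dumps(markers.to_dict(), indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def phases_to_json(phase_set, path=None, trial_id: str | None = None) -> str:
    """Serialize a PhaseSet (seconds and percents) as JSON."""
    d = phase_set.to_dict()
    if trial_id is not None:
        d = {"trial_id": trial_id, **d}
    text = json.dumps(d, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
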