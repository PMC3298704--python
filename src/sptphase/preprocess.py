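"""Signal conditioning for sitting pivot transfer recordings.

Force channels are low-pass filtered with a zero-lag (forward-backward)
Butterworth filter at 10 Hz and decimated from the acquisition rate (600 Hz)
to the kinematic rate (60 Hz); marker trajectories are filtered at 6 Hz.
Trunk movement is summarized as the C7 marker speed, the Euclidean norm of
the time derivative of its filtered 3D trajectory. All channels end up on a
single 60 Hz grid (:class:`ProcessedTrial`) ready for event detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "PreprocessConfig",
    "ProcessedTrial",
    "zero_lag_lowpass",
    "downsample",
    "c7_speed",
    "preprocess_trial",
]


@dataclass
class PreprocessConfig:
    """Filtering / resampling parameters.

    Parameters
    ----------
    force_cutoff_hz : float
        Low-pass cutoff for the force channels (Hz).
    kin_cutoff_hz : float
        Low-pass cutoff for marker trajectories (Hz).
    filter_order : int
        Effective Butterworth order *after* the forward-backward pass.
        The default 4 therefore designs a 2nd-order filter and applies it
        twice — the dominant convention in gait/transfer labs.
    target_fs : float
        Common output rate (Hz) all channels are aligned to.
    order_per_pass : bool
        If True, design the full ``filter_order`` per pass instead
        (an effectively 8th-order response for ``filter_order=4``).
    """

    force_cutoff_hz: float = 10.0
    kin_cutoff_hz: float = 6.0
    filter_order: int = 4
    target_fs: float = 60.0
    order_per_pass: bool = False

    def __post_init__(self) -> None:
        nyq = self.target_fs / 2.0
        if not (0 < self.force_cutoff_hz < nyq and 0 < self.kin_cutoff_hz < nyq):
            raise ValueError(
                "cutoff frequencies must lie strictly below target_fs/2 "
                f"({nyq:g} Hz)"
            )
        if self.filter_order < 2 or self.filter_order % 2:
            raise ValueError("filter_order must be an even integer >= 2")


@dataclass
class ProcessedTrial:
    """Filtered, time-aligned 60 Hz view of one transfer attempt."""

    trial_id: str
    time: np.ndarray
    f_trailing_hand: np.ndarray
    f_initial_seat: np.ndarray
    f_target_seat: np.ndarray
    c7_xyz: np.ndarray
    c7_speed: np.ndarray
    fs: float = 60.0

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("f_trailing_hand", "f_initial_seat", "f_target_seat",
                     "c7_speed"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length differs from time grid")
        if self.c7_xyz.shape != (n, 3):
            raise ValueError("c7_xyz must have shape (n_frames, 3)")
        if np.any(self.c7_speed < 0):
            raise ValueError("c7_speed must be nonnegative")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs


def _padlen(fs: float, cutoff: float, order: int) -> int:
    # 3x the filter's characteristic length (one cutoff period) per side.
    return int(np.ceil(3.0 * fs / cutoff)) * max(order // 2, 1)


def zero_lag_lowpass(x: np.ndarray, fs: float, cutoff: float,
                     order: int = 4, order_per_pass: bool = False) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter (forward-backward pass).

    ``order`` is the effective order after the dual pass; the underlying
    design order is ``order // 2`` unless ``order_per_pass`` is set.
    Reflective edge padding avoids startup transients corrupting the quiet
    baseline at the start of a trial.
    """
    x = np.asarray(x, dtype=float)
    if cutoff <= 0 or cutoff >= fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2); got {cutoff} at fs={fs}")
    if order < 2 or order % 2:
        raise ValueError("order must be an even integer >= 2")
    design_order = order if order_per_pass else order // 2
    pad = _padlen(fs, cutoff, design_order * 2)
    n = x.shape[0]
    if n <= pad:
        raise ValueError(
            f"series of {n} samples too short for stable edge padding "
            f"({pad} samples) at cutoff {cutoff} Hz / fs {fs} Hz"
        )
    sos = _sig.butter(design_order, cutoff, btype="low", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, x, axis=0, padtype="even", padlen=pad)


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Exact-factor decimation: every (fs_in/fs_out)-th sample, index 0 first.

    The input is assumed already band-limited below ``fs_out/2``;
    no anti-alias filtering happens here.
    """
    x = np.asarray(x)
    factor = fs_in / fs_out
    if factor < 1 or abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"non-integer decimation factor {fs_in}/{fs_out} = {factor:g}"
        )
    return x[:: int(round(factor))]


def c7_speed(trajectory: np.ndarray, fs: float) -> np.ndarray:
    """Marker speed: norm of the time derivative of a 3D trajectory.

    Central finite differences in the interior, one-sided at the ends
    (``np.gradient`` semantics), then the per-frame Euclidean norm.
    """
    xyz = np.asarray(trajectory, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ValueError("trajectory must have shape (n_frames, 3)")
    if xyz.shape[0] < 3:
        raise ValueError("need at least 3 frames to differentiate")
    if np.isnan(xyz).any():
        raise ValueError("trajectory contains occluded (NaN) samples")
    vel = np.gradient(xyz, 1.0 / fs, axis=0)
    return np.linalg.norm(vel, axis=1)


def preprocess_trial(raw, cfg: PreprocessConfig | None = None) -> ProcessedTrial:
    """Filter, decimate and align one raw trial onto the target grid.

    Forces: filtered at ``force_cutoff_hz`` (at the acquisition rate), then
    decimated by the exact factor ``fs_force / target_fs``. Kinematics:
    filtered at ``kin_cutoff_hz``; the kinematic rate must equal
    ``target_fs``. C7 speed is computed from the filtered trajectory.
    """
    cfg = cfg or PreprocessConfig()
    if abs(raw.fs_kin - cfg.target_fs) > 1e-9:
        raise ValueError(
            f"kinematic rate {raw.fs_kin} Hz != target rate {cfg.target_fs} Hz; "
            "interpolating resampling is out of scope"
        )
    forces = []
    for name in ("f_trailing_hand", "f_initial_seat", "f_target_seat"):
        y = zero_lag_lowpass(getattr(raw, name), raw.fs_force,
                             cfg.force_cutoff_hz, cfg.filter_order,
                             cfg.order_per_pass)
        forces.append(downsample(y, raw.fs_force, cfg.target_fs))

    xyz = np.column_stack([
        zero_lag_lowpass(raw.c7_xyz[:, k], raw.fs_kin, cfg.kin_cutoff_hz,
                         cfg.filter_order, cfg.order_per_pass)
        for k in range(3)
    ])

    n = min(min(len(f) for f in forces), xyz.shape[0])
    forces = [f[:n] for f in forces]
    xyz = xyz[:n]
    speed = c7_speed(xyz, cfg.target_fs)
    time = np.arange(n) / cfg.target_fs
    return ProcessedTrial(
        trial_id=raw.trial_id,
        time=time,
        f_trailing_hand=forces[0],
        f_initial_seat=forces[1],
        f_target_seat=forces[2],
        c7_xyz=xyz,
        c7_speed=speed,
        fs=cfg.target_fs,
    )
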