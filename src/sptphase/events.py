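"""Relative threshold-based detection of sitting pivot transfer events.

Five time markers bound the four phases of a transfer:

* **E1** (pre-lift start / movement onset): C7 marker speed exceeds the
  quiet-sitting band — baseline mean + 2 SD over the first 20 frames — for
  more than half a second.
* **E2** (upper-limb loading start): vertical force under the trailing hand
  exceeds 5% of its maximum over the whole recording for more than 0.5 s.
* **E3** (lift-pivot start / buttocks lift-off): vertical force under the
  initial seat falls below 5% of its maximum for more than 1 s.
* **E4** (post-lift start / landing): vertical force under the target seat
  exceeds 5% of its maximum for more than 1 s.
* **E5** (end of transfer): the target-seat force has stabilized — every
  remaining sample stays within 2 SD of the post-lift mean (see
  :func:`resolve_end` for how the circular definition is resolved).

All thresholds are relative (fractions of per-trial maxima, multiples of
per-trial baseline variability), so detection is invariant to force-plate
gain and marker-frame translation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionConfig",
    "BaselineStats",
    "EventMarkers",
    "EventNotFoundError",
    "baseline_stats",
    "sustained_crossing",
    "resolve_end",
    "detect_events",
]

EVENT_NAMES = ("e1_prelift_start", "e2_loading_start", "e3_liftpivot_start",
               "e4_postlift_start", "e5_end")


@dataclass
class DetectionConfig:
    """Tunable parameters of the relative-threshold detector.

    baseline_frames
        Number of initial quiet-sitting frames used for the C7 speed
        baseline (and the measurement-noise allowance of the end rule).
    c7_sd_multiplier
        Width of the movement-onset band in baseline SDs.
    force_fraction
        Relative force threshold, as a fraction of each channel's maximum
        over the complete recording.
    hold_short_s / hold_long_s
        Persistence required for the C7/trailing-hand rules (0.5 s) and the
        seat rules (1 s).
    end_sd_multiplier
        Width of the end-of-transfer stability band in post-lift SDs.
    min_speed_m_s
        Absolute floor on the movement-onset threshold; guards the
        degenerate noise-free case where the baseline SD is exactly zero.
        5 mm/s is far below any voluntary trunk movement.
    end_rel_floor
        Minimum half-width of the end-rule stability band, as a fraction of
        the target-seat channel maximum. Deviations smaller than ~1% of the
        seated load are treated as stationary; like every other threshold of
        the detector this floor is relative, so gain invariance is kept.
    """

    baseline_frames: int = 20
    c7_sd_multiplier: float = 2.0
    force_fraction: float = 0.05
    hold_short_s: float = 0.5
    hold_long_s: float = 1.0
    end_sd_multiplier: float = 2.0
    min_speed_m_s: float = 0.005
    end_rel_floor: float = 0.0125

    def __post_init__(self) -> None:
        if not 0 < self.force_fraction < 1:
            raise ValueError("force_fraction must lie in (0, 1)")
        if self.hold_short_s <= 0 or self.hold_long_s <= 0:
            raise ValueError("persistence holds must be positive")
        if self.baseline_frames < 2:
            raise ValueError("baseline_frames must be >= 2")


@dataclass(frozen=True)
class BaselineStats:
    """Quiet-sitting summary of a series' first ``n`` frames."""

    mean: float
    sd: float
    n: int


class EventNotFoundError(RuntimeError):
    """A detection rule found no qualifying frame.

    Carries the event name so batch runs can triage which rule failed.
    """

    def __init__(self, event: str, message: str):
        self.event = event
        super().__init__(f"{event}: {message}")


@dataclass(frozen=True)
class EventMarkers:
    """The five detected event times (seconds) bounding the four phases."""

    e1_prelift_start: float
    e2_loading_start: float
    e3_liftpivot_start: float
    e4_postlift_start: float
    e5_end: float
    fs: float = 60.0

    def __post_init__(self) -> None:
        t = self.times
        if not all(t[i] < t[i + 1] for i in range(4)):
            raise ValueError(f"event times must be strictly increasing: {t}")

    @property
    def times(self) -> tuple[float, float, float, float, float]:
        return (self.e1_prelift_start, self.e2_loading_start,
                self.e3_liftpivot_start, self.e4_postlift_start, self.e5_end)

    @property
    def frames(self) -> tuple[int, int, int, int, int]:
        """Frame indices (0-based) on the detection grid."""
        return tuple(int(round(t * self.fs)) for t in self.times)

    @classmethod
    def from_frames(cls, frames, fs: float) -> "EventMarkers":
        return cls(*(f / fs for f in frames), fs=fs)

    def to_dict(self) -> dict:
        d = {name: t for name, t in zip(EVENT_NAMES, self.times)}
        d["fs"] = self.fs
        d["frames"] = list(self.frames)
        return d


def baseline_stats(series: np.ndarray, n: int) -> BaselineStats:
    """Sample mean and SD (n-1 denominator) of the first ``n`` frames."""
    series = np.asarray(series, dtype=float)
    if len(series) < n:
        raise ValueError(
            f"series of {len(series)} frames shorter than baseline of {n}"
        )
    head = series[:n]
    return BaselineStats(mean=float(head.mean()),
                         sd=float(head.std(ddof=1)),
                         n=n)


def sustained_crossing(series: np.ndarray, threshold: float, direction: str,
                       hold_s: float, fs: float, search_from: int = 0) -> int:
    """First frame from which ``series`` stays beyond ``threshold``.

    Returns the first frame ``f >= search_from`` such that the series is
    strictly above (or below) the threshold for every frame of the
    persistence window ``[f, f + ceil(hold_s * fs))``.  "More than half a
    second" is implemented as a full run of ``ceil(hold_s * fs)`` frames;
    windows truncated by the end of the trial do not qualify.
    """
    series = np.asarray(series, dtype=float)
    run = math.ceil(hold_s * fs)
    if run < 1:
        raise ValueError("hold_s * fs must be >= 1")
    if direction == "above":
        cond = series > threshold
    elif direction == "below":
        cond = series < threshold
    else:
        raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")
    n = len(cond)
    search_from = max(int(search_from), 0)
    if n - search_from < run:
        raise EventNotFoundError(
            "sustained_crossing",
            f"no window of {run} frames {direction} {threshold:g} "
            f"from frame {search_from}",
        )
    # run-length via cumulative sum of the boolean condition
    csum = np.concatenate(([0], np.cumsum(cond[search_from:])))
    full = np.nonzero(csum[run:] - csum[:-run] == run)[0]
    if len(full) == 0:
        raise EventNotFoundError(
            "sustained_crossing",
            f"no window of {run} frames {direction} {threshold:g} "
            f"from frame {search_from}",
        )
    return search_from + int(full[0])


def resolve_end(f_target_seat: np.ndarray, e4: int, cfg: DetectionConfig,
                fs: float) -> int:
    """End-of-transfer marker on the target-seat force.

    The post-lift mean/SD and the phase boundary define each other, so the
    marker is resolved by a suffix-window scan: E5 is the first frame
    ``f > e4`` such that the window ``[f, end of trial]`` (at least
    ``hold_long_s`` long) looks like stationary quiet sitting:

    * every sample lies within ``mean ± band`` of the window, and
    * the fitted linear trend over the window is negligible
      (|slope| x window length <= band),

    with ``band = max(k * window SD, 2k * baseline SD,
    end_rel_floor * channel max)`` for ``k = end_sd_multiplier``.  The
    baseline-SD floor is the measurement noise of the (unloaded) target-seat
    channel during quiet sitting; it keeps the all-samples check from
    tripping on the ordinary extreme-value exceedance of a +-2 SD band under
    noise.  The relative floor absorbs the exponentially decaying remnants
    the zero-phase filter leaves after a transition (deviations below a
    small fraction of the seated load are stationary for this purpose).  An
    unsettled signal (continuing ramp) fails the trend guard everywhere.
    """
    x = np.asarray(f_target_seat, dtype=float)
    n = len(x)
    run = math.ceil(cfg.hold_long_s * fs)
    k = cfg.end_sd_multiplier
    noise_sd = baseline_stats(x, min(cfg.baseline_frames, n)).sd
    floor = max(2.0 * k * noise_sd,
                cfg.end_rel_floor * float(np.max(np.abs(x))))
    for f in range(e4 + 1, n - run + 1):
        w = x[f:]
        m = w.mean()
        sd = w.std(ddof=1)
        band = max(k * sd, floor)
        dev = np.abs(w - m)
        if dev.max() > band:
            continue
        t = np.arange(len(w)) / fs
        tc = t - t.mean()
        slope = float(tc @ (w - m) / (tc @ tc))
        if abs(slope) * (len(w) / fs) > band:
            continue
        return f
    raise EventNotFoundError(
        "e5_end", "target-seat force never stabilizes before the trial end"
    )


def detect_events(trial, cfg: DetectionConfig | None = None) -> EventMarkers:
    """Run the five detection rules sequentially on a processed trial.

    Each rule searches strictly after the previous marker, which guarantees
    the ordering invariant e1 < e2 < e3 < e4 < e5; any rule that cannot fire
    raises :class:`EventNotFoundError` naming the event.
    """
    cfg = cfg or DetectionConfig()
    fs = trial.fs

    base = baseline_stats(trial.c7_speed, cfg.baseline_frames)
    thr1 = max(base.mean + cfg.c7_sd_multiplier * base.sd, cfg.min_speed_m_s)
    thr2 = cfg.force_fraction * float(np.max(trial.f_trailing_hand))
    thr3 = cfg.force_fraction * float(np.max(trial.f_initial_seat))
    thr4 = cfg.force_fraction * float(np.max(trial.f_target_seat))
    logger.info(
        "thresholds trial=%s: c7_speed>%.5g m/s, trailing>%.4g N, "
        "initial<%.4g N, target>%.4g N (force_fraction=%.3g)",
        getattr(trial, "trial_id", "?"), thr1, thr2, thr3, thr4,
        cfg.force_fraction,
    )

    def _find(event, series, thr, direction, hold, start):
        try:
            return sustained_crossing(series, thr, direction, hold, fs,
                                      search_from=start)
        except EventNotFoundError as err:
            raise EventNotFoundError(event, str(err)) from None

    e1 = _find("e1_prelift_start", trial.c7_speed, thr1, "above",
               cfg.hold_short_s, 0)
    e2 = _find("e2_loading_start", trial.f_trailing_hand, thr2, "above",
               cfg.hold_short_s, e1 + 1)
    e3 = _find("e3_liftpivot_start", trial.f_initial_seat, thr3, "below",
               cfg.hold_long_s, e2 + 1)
    e4 = _find("e4_postlift_start", trial.f_target_seat, thr4, "above",
               cfg.hold_long_s, e3 + 1)
    e5 = resolve_end(trial.f_target_seat, e4, cfg, fs)
    if e5 <= e4:
        raise EventNotFoundError("e5_end", "end marker not after landing")

    markers = EventMarkers.from_frames((e1, e2, e3, e4, e5), fs)
    logger.info("events trial=%s: frames %s", getattr(trial, "trial_id", "?"),
                markers.frames)
    return markers
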