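"""Phase durations, time normalization, and trial-to-trial stability stats.

Consecutive event markers bound the four transfer phases; the usual summary
is the absolute duration of each phase plus its relative contribution to the
transfer cycle (total = E5 - E1, normalized to 100%). Cohort reporting
mirrors the standard layout: per-subject two-trial averages, group mean (SD)
per phase, and a dependent-samples t-test between the two trials as a
stability check of the detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "PHASE_NAMES",
    "PhaseSet",
    "TTestResult",
    "CohortSummary",
    "segment_phases",
    "time_normalize",
    "paired_t_test",
    "cohort_summary",
]

PHASE_NAMES = ("pre_lift", "upper_limb_loading", "lift_pivot", "post_lift")


@dataclass(frozen=True)
class PhaseSet:
    """Absolute (s) and relative (%) durations of the four phases."""

    durations_s: tuple[float, float, float, float]
    total_s: float
    percents: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.durations_s):
            raise ValueError("phase durations must be nonnegative")
        if abs(sum(self.percents) - 100.0) > 0.01:
            raise ValueError("relative durations must sum to 100%")

    def to_dict(self) -> dict:
        d = {f"{name}_s": v for name, v in zip(PHASE_NAMES, self.durations_s)}
        d["total_s"] = self.total_s
        d.update({f"{name}_pct": v for name, v in zip(PHASE_NAMES, self.percents)})
        return d


def segment_phases(events) -> PhaseSet:
    """Phase durations from ordered event markers.

    pre-lift = E2-E1, loading = E3-E2, lift-pivot = E4-E3,
    post-lift = E5-E4; total = E5-E1. Percentages are computed on the
    unrounded durations so they sum to 100 exactly.
    """
    t1, t2, t3, t4, t5 = events.times
    durations = (t2 - t1, t3 - t2, t4 - t3, t5 - t4)
    total = t5 - t1
    percents = tuple(100.0 * d / total for d in durations)
    return PhaseSet(durations_s=durations, total_s=total, percents=percents)


def time_normalize(trial, events, n_points: int = 100,
                   kind: str = "linear") -> tuple[pd.DataFrame, dict]:
    """Resample the transfer cycle [E1, E5] onto ``n_points`` instants.

    Returns a DataFrame indexed by cycle percentage (0-100) with one column
    per channel, plus the event positions re-expressed in % of cycle.
    Linear interpolation by default; ``kind='cubic'`` for smooth channels.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    t1, t5 = events.times[0], events.times[-1]
    if t1 < trial.time[0] - 1e-9 or t5 > trial.time[-1] + 1e-9:
        raise ValueError("events lie outside the trial's time span")
    grid = np.linspace(t1, t5, n_points)
    pct = np.linspace(0.0, 100.0, n_points)

    channels = {
        "f_trailing_hand": trial.f_trailing_hand,
        "f_initial_seat": trial.f_initial_seat,
        "f_target_seat": trial.f_target_seat,
        "c7_speed": trial.c7_speed,
    }
    if kind == "linear":
        data = {k: np.interp(grid, trial.time, v) for k, v in channels.items()}
    else:
        from scipy.interpolate import interp1d
        data = {k: interp1d(trial.time, v, kind=kind)(grid)
                for k, v in channels.items()}
    frame = pd.DataFrame(data, index=pd.Index(pct, name="cycle_pct"))
    event_pct = {
        name: 100.0 * (t - t1) / (t5 - t1)
        for name, t in zip(
            ("e1_prelift_start", "e2_loading_start", "e3_liftpivot_start",
             "e4_postlift_start", "e5_end"),
            events.times,
        )
    }
    return frame, event_pct


@dataclass(frozen=True)
class TTestResult:
    """Dependent-samples t-test outcome."""

    t: float
    p: float
    n: int
    degenerate: bool = False


def paired_t_test(x1, x2) -> TTestResult:
    """Student t-test for dependent samples on differences ``x1 - x2``.

    t = mean(d) / (sd(d)/sqrt(n)) with an n-1 denominator SD; two-sided p
    from the t distribution with n-1 degrees of freedom. A zero-variance
    difference vector is flagged degenerate: identical samples report
    (t=0, p=1); a constant nonzero shift reports (t=+-inf, p=0).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = len(x1)
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = x1 - x2
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, p=1.0, n=n, degenerate=True)
        return TTestResult(t=math.copysign(math.inf, mean), p=0.0, n=n,
                           degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * _st.t.sf(abs(t), df=n - 1)
    return TTestResult(t=float(t), p=float(p), n=n)


@dataclass
class CohortSummary:
    """Group summary over subjects with two trials each.

    ``table`` has one row per phase (plus the full cycle): mean and SD per
    trial, mean and SD of the per-subject two-trial averages, the paired
    t-test between trials, and the mean relative duration.
    """

    n_subjects: int
    table: pd.DataFrame
    alpha: float = 0.05

    def to_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.6g")

    def render(self) -> str:
        disp = self.table.copy()
        for col in ("trial1_mean_s", "trial1_sd_s", "trial2_mean_s",
                    "trial2_sd_s", "average_mean_s", "average_sd_s"):
            disp[col] = disp[col].map(lambda v: f"{v:.2f}")
        disp["p_value"] = disp["p_value"].map(
            lambda v: "--" if np.isnan(v) else f"{v:.3f}")
        disp["percent"] = disp["percent"].map(
            lambda v: "100" if v >= 99.995 else f"{v:.1f}")
        return disp.to_string()


def cohort_summary(subjects) -> CohortSummary:
    """Summarize a cohort of per-subject (trial 1, trial 2) PhaseSet pairs.

    Per-subject two-trial averages are computed first, then group mean/SD;
    dependent-samples t-tests compare the absolute duration of each phase
    (and the full cycle) between the two trials.
    """
    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects with two trials each")
    for pair in subjects:
        if len(pair) != 2:
            raise ValueError("every subject needs exactly two trials")

    t1 = np.array([[p for p in s[0].durations_s] + [s[0].total_s]
                   for s in subjects])          # (n_subj, 5)
    t2 = np.array([[p for p in s[1].durations_s] + [s[1].total_s]
                   for s in subjects])
    avg = 0.5 * (t1 + t2)
    pct = 0.5 * (np.array([s[0].percents for s in subjects])
                 + np.array([s[1].percents for s in subjects]))

    rows = []
    labels = list(PHASE_NAMES) + ["spt_cycle"]
    for j, label in enumerate(labels):
        res = paired_t_test(t1[:, j], t2[:, j])
        rows.append({
            "phase": label,
            "trial1_mean_s": t1[:, j].mean(),
            "trial1_sd_s": t1[:, j].std(ddof=1),
            "trial2_mean_s": t2[:, j].mean(),
            "trial2_sd_s": t2[:, j].std(ddof=1),
            "average_mean_s": avg[:, j].mean(),
            "average_sd_s": avg[:, j].std(ddof=1),
            "t": res.t,
            "p_value": np.nan if res.degenerate and res.p == 1.0 else res.p,
            "degenerate": res.degenerate,
            "percent": pct[:, j].mean() if j < 4 else 100.0,
        })
    table = pd.DataFrame(rows).set_index("phase")
    return CohortSummary(n_subjects=len(subjects), table=table)
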