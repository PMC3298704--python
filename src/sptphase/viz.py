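"""Per-trial diagnostic figure: the four detector channels with markers."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .events import DetectionConfig, baseline_stats

__all__ = ["plot_trial"]

_EVENT_LABELS = ("E1", "E2", "E3", "E4", "E5")


def plot_trial(trial, markers=None, cfg: DetectionConfig | None = None,
               path=None):
    """Four-panel plot (C7 speed, trailing hand, initial seat, target seat)
    with the relative thresholds and, if given, the detected event markers.

    Returns the matplotlib figure; saves to ``path`` if provided.
    """
    cfg = cfg or DetectionConfig()
    base = baseline_stats(trial.c7_speed, cfg.baseline_frames)
    panels = [
        ("C7 speed (m/s)", trial.c7_speed,
         max(base.mean + cfg.c7_sd_multiplier * base.sd, cfg.min_speed_m_s)),
        ("trailing hand (N)", trial.f_trailing_hand,
         cfg.force_fraction * np.max(trial.f_trailing_hand)),
        ("initial seat (N)", trial.f_initial_seat,
         cfg.force_fraction * np.max(trial.f_initial_seat)),
        ("target seat (N)", trial.f_target_seat,
         cfg.force_fraction * np.max(trial.f_target_seat)),
    ]
    fig, axes = plt.subplots(4, 1, sharex=True, figsize=(8, 9))
    for ax, (label, y, thr) in zip(axes, panels):
        ax.plot(trial.time, y, lw=1.0, color="C0")
        ax.axhline(thr, ls=":", color="0.4", lw=0.8)
        ax.set_ylabel(label)
        if markers is not None:
            for name, t in zip(_EVENT_LABELS, markers.times):
                ax.axvline(t, ls="--", color="C3", lw=0.8)
                if ax is axes[0]:
                    ax.annotate(name, (t, ax.get_ylim()[1]), fontsize=8,
                                ha="center", va="bottom", color="C3")
    axes[-1].set_xlabel("time (s)")
    fig.suptitle(f"trial {trial.trial_id}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
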