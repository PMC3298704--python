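"""Synthetic sitting pivot transfer trials with known ground truth.

A trial is built from a support-force budget that is closed to body weight
at every instant: the person starts seated on the initial seat (hands
resting lightly), shifts weight onto the hands during upper-limb loading,
is carried entirely by the hands during the lift-pivot, and lands on the
target seat, which then carries most of the weight. Hand-offs are smoothstep
transitions anchored so that each channel crosses the detector's relative
threshold (5% of channel maximum; movement onset for C7) exactly at the
nominal event time — so the recorded ground truth is the time the phase
transition occurs, and a correct pipeline must recover it.

The C7 marker is exactly static during the quiet-sitting baseline, then
moves along a smooth 3D path whose speed rises quickly at movement onset
and decays after landing. White Gaussian noise is added to forces (before
filtering) and marker positions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import optimize as _opt
from scipy import stats as _st
from scipy.integrate import cumulative_trapezoid

from .signal_io import RawTrial

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_trial",
    "generate_cohort",
    "draw_cohort_durations",
    "DEFAULT_PHASE_MEANS_S",
    "DEFAULT_PHASE_SDS_S",
]

# Cohort defaults: typical adult phase durations for seated lateral
# transfers (pre-lift, upper-limb loading, lift-pivot, post-lift).
DEFAULT_PHASE_MEANS_S = (0.74, 0.28, 0.72, 0.27)
DEFAULT_PHASE_SDS_S = (0.29, 0.13, 0.24, 0.14)

# Relative force threshold the transitions are anchored to; mirrors the
# detector's default force_fraction.
_THRESHOLD_FRACTION = 0.05


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters for one trial.

    body_weight_N
        Total supported weight (default: a 78.8 kg adult).
    baseline_s
        Quiet sitting before movement onset; must cover the detector's
        20-frame baseline.
    true_durations_s
        Ground-truth durations of the four phases.
    ramp_s
        Smoothness time constant of fast transitions (C7 speed onset);
        also sets the validity floor (3 x ramp_s ~ 0.1 s) for sampled
        durations — phase transitions shorter than the settling time of
        the 10 Hz measurement chain are not resolvable and not generated.
    noise_sd_N / marker_noise_sd_m
        White-noise levels on forces (per 600 Hz sample, before filtering)
        and marker coordinates.
    trailing_share
        Fraction of the hand-borne load carried by the trailing hand
        (peak trailing force ~ trailing_share x body weight mid-lift).
    target_share
        Fraction of body weight on the target seat once seated (the rest
        stays on the hands).
    rest_hand_frac
        Fraction of body weight resting on the hands during quiet sitting.
    tail_s
        Quiet sitting recorded after the transfer ends (must exceed the
        detector's 1 s end-rule window).
    """

    body_weight_N: float = 773.0
    baseline_s: float = 1.0
    true_durations_s: tuple[float, float, float, float] = DEFAULT_PHASE_MEANS_S
    ramp_s: float = 0.035
    noise_sd_N: float = 2.0
    c7_path_amplitude_m: float = 0.45
    marker_noise_sd_m: float = 1e-4
    fs_force: float = 600.0
    fs_kin: float = 60.0
    tail_s: float = 1.5
    trailing_share: float = 0.35
    target_share: float = 0.92
    rest_hand_frac: float = 0.01
    seed: int = 0
    trial_id: str = "synthetic"

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.true_durations_s):
            raise ValueError("phase durations must be positive")
        if self.ramp_s >= min(self.true_durations_s):
            raise ValueError("ramp_s must be shorter than every phase duration")
        if self.noise_sd_N < 0 or self.marker_noise_sd_m < 0:
            raise ValueError("noise levels must be nonnegative")
        factor = self.fs_force / self.fs_kin
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError("fs_force must be an integer multiple of fs_kin")
        if not 0 < self.trailing_share < 1 or not 0 < self.target_share < 1:
            raise ValueError("force shares must lie in (0, 1)")

    @property
    def event_times(self) -> tuple[float, float, float, float, float]:
        e1 = self.baseline_s
        d = self.true_durations_s
        return (e1, e1 + d[0], e1 + d[0] + d[1], e1 + d[0] + d[1] + d[2],
                e1 + sum(d))


@dataclass(frozen=True)
class GroundTruth:
    """True event times of a generated trial, plus the generating spec."""

    e1: float
    e2: float
    e3: float
    e4: float
    e5: float
    spec: SyntheticSpec

    @property
    def times(self) -> tuple[float, float, float, float, float]:
        return (self.e1, self.e2, self.e3, self.e4, self.e5)

    @property
    def durations_s(self) -> tuple[float, float, float, float]:
        t = self.times
        return tuple(t[i + 1] - t[i] for i in range(4))


def _smoothstep(w: np.ndarray) -> np.ndarray:
    w = np.clip(w, 0.0, 1.0)
    return w * w * (3.0 - 2.0 * w)


def _smoothstep_inv(y: float) -> float:
    """w in [0, 1] with 3w^2 - 2w^3 = y."""
    return float(_opt.brentq(lambda w: w * w * (3 - 2 * w) - y, 0.0, 1.0))


# Linear fraction of the target-seat settle transition: the force approaches
# its plateau at a nonzero terminal rate and arrives with a slope
# discontinuity, which is what makes the stabilization instant localizable
# at any settle speed (a zero-slope approach is ambiguous near the end).
_SETTLE_LINEAR_FRACTION = 0.3


def _settle_shape(w: np.ndarray) -> np.ndarray:
    wc = np.clip(w, 0.0, 1.0)
    return ((1.0 - _SETTLE_LINEAR_FRACTION) * _smoothstep(wc)
            + _SETTLE_LINEAR_FRACTION * wc)


def _settle_shape_inv(y: float) -> float:
    return float(_opt.brentq(lambda w: _settle_shape(np.asarray(w)) - y,
                             0.0, 1.0))


def _force_budget(spec: SyntheticSpec, t: np.ndarray) -> dict[str, np.ndarray]:
    """Noise-free support forces; they sum to body weight at every instant.

    ``u`` is the fraction of seat-borne weight moved off the initial seat,
    ``v`` the fraction of the target plateau reached. Both are smoothsteps
    anchored so the 5%-of-maximum crossings of the trailing hand, initial
    seat and target seat fall exactly at e2, e3 and e4, and the target
    plateau is reached exactly at e5.
    """
    bw = spec.body_weight_N
    e1, e2, e3, e4, e5 = spec.event_times
    f5 = _THRESHOLD_FRACTION

    h0 = spec.rest_hand_frac * bw                 # resting hand load
    initial0 = bw - h0                            # initial seat at baseline
    plateau = spec.target_share * bw              # target seat when seated
    trail_rest = spec.trailing_share * h0
    trail_max = trail_rest + spec.trailing_share * initial0

    # initial-seat hand-off: anchored at the trailing-hand crossing (e2)
    # and the initial-seat crossing (e3)
    u_at_e2 = (f5 * trail_max - trail_rest) / (spec.trailing_share * initial0)
    w_a = _smoothstep_inv(u_at_e2)
    w_b = _smoothstep_inv(1.0 - f5)
    du = (e3 - e2) / (w_b - w_a)
    t_u0 = e2 - w_a * du
    u = _smoothstep((t - t_u0) / du)

    # target-seat loading: 5% crossing at e4, plateau reached at e5
    w_c = _settle_shape_inv(f5)
    dv = (e5 - e4) / (1.0 - w_c)
    t_v0 = e4 - w_c * dv
    v = _settle_shape((t - t_v0) / dv)

    initial = initial0 * (1.0 - u)
    target = plateau * v
    hands = bw - initial - target
    trailing = trail_rest + spec.trailing_share * (hands - h0)
    leading = hands - trailing
    return {"initial": initial, "target": target,
            "trailing": trailing, "leading": leading}


def _c7_speed_profile(spec: SyntheticSpec, t: np.ndarray) -> np.ndarray:
    """Unit-peak speed profile: zero until e1, fast smoothstep rise,
    sustained through the transfer, decaying after e5."""
    e1, _, _, _, e5 = spec.event_times
    rise_s = max(0.06, 2.0 * spec.ramp_s)
    fall_s = 0.3
    rise = _smoothstep((t - e1) / rise_s)
    fall = 1.0 - _smoothstep((t - e5) / fall_s)
    return rise * fall


def generate_trial(spec: SyntheticSpec,
                   rng: np.random.Generator | None = None
                   ) -> tuple[RawTrial, GroundTruth]:
    """Synthesize one trial and its ground-truth event times."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    e5 = spec.event_times[-1]
    duration = e5 + spec.tail_s
    factor = int(round(spec.fs_force / spec.fs_kin))
    n_kin = int(round(duration * spec.fs_kin))
    n_force = n_kin * factor
    t_force = np.arange(n_force) / spec.fs_force
    t_kin = np.arange(n_kin) / spec.fs_kin

    budget = _force_budget(spec, t_force)
    noise = lambda: rng.normal(0.0, spec.noise_sd_N, n_force) \
        if spec.noise_sd_N > 0 else 0.0

    # C7: speed profile scaled so total displacement matches the path
    # amplitude, integrated along a fixed 3D direction
    profile = _c7_speed_profile(spec, t_kin)
    travel = np.trapezoid(profile, dx=1.0 / spec.fs_kin)
    v_peak = spec.c7_path_amplitude_m / travel
    displacement = cumulative_trapezoid(v_peak * profile,
                                        dx=1.0 / spec.fs_kin, initial=0.0)
    direction = np.array([0.80, 0.55, 0.23])
    direction /= np.linalg.norm(direction)
    start = np.array([0.10, -0.20, 0.60])
    c7 = start + displacement[:, None] * direction
    if spec.marker_noise_sd_m > 0:
        c7 = c7 + rng.normal(0.0, spec.marker_noise_sd_m, (n_kin, 3))

    raw = RawTrial(
        trial_id=spec.trial_id,
        force_time=t_force,
        f_trailing_hand=budget["trailing"] + noise(),
        f_initial_seat=budget["initial"] + noise(),
        f_target_seat=budget["target"] + noise(),
        kin_time=t_kin,
        c7_xyz=c7,
        fs_force=spec.fs_force,
        fs_kin=spec.fs_kin,
    )
    e = spec.event_times
    return raw, GroundTruth(*e, spec=spec)


@lru_cache(maxsize=128)
def _matched_truncnorm_params(mean: float, sd: float,
                              floor: float) -> tuple[float, float]:
    """Parameters (mu, sigma) such that a normal truncated below at
    ``floor`` has exactly the requested mean and SD.

    Keeps the sampled duration distribution centred on the target moments
    despite the validity floor (plain truncation would inflate the mean of
    short phases). The truncated-normal family cannot exceed
    ``sd = mean - floor`` (its exponential limit); SDs above ~97% of that
    bound are rejected.
    """
    if (floor - mean) / sd < -6.0:
        return mean, sd          # truncation mass negligible
    if sd >= 0.97 * (mean - floor):
        raise ValueError(
            f"duration SD {sd:g} not representable above the validity floor "
            f"{floor:g} (limit ~{mean - floor:g})")

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a = (floor - mu) / sigma
        m, v = _st.truncnorm.stats(a, np.inf, loc=mu, scale=sigma,
                                   moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = _opt.root(moments, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(
            f"moment matching failed for mean={mean}, sd={sd}, floor={floor}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def draw_cohort_durations(n_subjects: int,
                          duration_means_s=DEFAULT_PHASE_MEANS_S,
                          duration_sds_s=DEFAULT_PHASE_SDS_S,
                          n_trials: int = 2,
                          rng: np.random.Generator | None = None,
                          trial_correlation: float = 0.8,
                          floor_s: float = 0.06) -> np.ndarray:
    """Sample ground-truth phase durations for a cohort.

    Per-subject mean durations follow truncated normal distributions
    (truncated below at ``floor_s``) whose parameters are moment-matched so
    the sampled distribution has exactly the requested mean and SD; each
    trial adds within-subject jitter sized so the trial-to-trial correlation
    is ``trial_correlation`` (per-trial variance = between-subject variance
    / correlation). Returns an array of shape ``(n_subjects, n_trials, 4)``
    in seconds.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0 < trial_correlation <= 1:
        raise ValueError("trial_correlation must lie in (0, 1]")
    means = np.asarray(duration_means_s, dtype=float)
    sds = np.asarray(duration_sds_s, dtype=float)
    if means.shape != (4,) or sds.shape != (4,):
        raise ValueError("need four phase means and four SDs")
    if np.any(sds < 0):
        raise ValueError("duration SDs must be nonnegative")
    if np.any(means <= floor_s) and np.any(sds[means <= floor_s] == 0):
        raise ValueError("mean durations at or below the validity floor "
                         f"({floor_s:g} s) with zero SD cannot be sampled")

    out = np.empty((n_subjects, n_trials, 4))
    for j in range(4):
        mu, sigma = means[j], sds[j]
        if sigma == 0:
            theta = np.full(n_subjects, mu)
            jitter_sd = 0.0
        else:
            mu_t, sigma_t = _matched_truncnorm_params(mu, sigma, floor_s)
            a = (floor_s - mu_t) / sigma_t
            theta = _st.truncnorm.rvs(a, np.inf, loc=mu_t, scale=sigma_t,
                                      size=n_subjects, random_state=rng)
            jitter_sd = sigma * np.sqrt(1.0 / trial_correlation - 1.0)
        for trial in range(n_trials):
            if jitter_sd == 0:
                vals = theta.copy()
            else:
                vals = theta + rng.normal(0.0, jitter_sd, n_subjects)
                bad = vals < floor_s
                tries = 0
                while np.any(bad) and tries < 100:
                    vals[bad] = theta[bad] + rng.normal(0.0, jitter_sd,
                                                        bad.sum())
                    bad = vals < floor_s
                    tries += 1
                vals = np.maximum(vals, floor_s)
            out[:, trial, j] = vals
    return out


def generate_cohort(n_subjects: int,
                    duration_means_s=DEFAULT_PHASE_MEANS_S,
                    duration_sds_s=DEFAULT_PHASE_SDS_S,
                    n_trials: int = 2,
                    seed: int = 0,
                    trial_correlation: float = 0.8,
                    base_spec: SyntheticSpec | None = None
                    ) -> list[list[tuple[RawTrial, GroundTruth]]]:
    """Generate a cohort of subjects with ``n_trials`` transfers each.

    Returns a subject-major nested list: ``cohort[s][t]`` is the
    ``(RawTrial, GroundTruth)`` pair of subject ``s``, trial ``t``.
    Fully reproducible from ``seed``.
    """
    base = base_spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    durations = draw_cohort_durations(
        n_subjects, duration_means_s, duration_sds_s, n_trials, rng,
        trial_correlation, floor_s=3.0 * base.ramp_s)
    cohort = []
    for s in range(n_subjects):
        trials = []
        for t in range(n_trials):
            spec = replace(
                base,
                true_durations_s=tuple(durations[s, t]),
                seed=int(rng.integers(2 ** 31)),
                trial_id=f"s{s + 1:02d}_t{t + 1}",
            )
            trials.append(generate_trial(spec))
        cohort.append(trials)
    return cohort
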