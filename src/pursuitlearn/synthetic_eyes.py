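"""Synthetic 1 kHz eye-position traces with an explicit passive-learning law.

The generator stands in for raw primate data.  Its ground truth is a
double-exponential growth of the predictive learned velocity

    g(T) = A1 (1 - exp(-T / tau1)) + A2 (1 - exp(-T / tau2)) + c   [deg/s]

driven by an *effective exposure* count T that eye-movement learning trials
advance by 1 and congruent fixation trials advance by a fractional weight
(``w_passive``), with further multipliers for unrewarded-cue and
vanish-window fixation trials.  Washout-block trials decay the accumulated
exposure multiplicatively.

Pursuit itself is a first-order velocity lag on the target velocity, delayed
by the ~100 ms pursuit reaction time; the predictive learned component ramps
up ahead of the direction change so that its mean over the 200-300 ms
analysis window equals g exactly.  Catch-up saccades are raised-cosine
velocity pulses triggered by predicted position error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.signal import lfilter

from .paradigm import (
    EYE_MOVEMENT,
    FIXATION,
    SessionSpec,
    TrialSpec,
    target_kinematics,
    _unit,
)

__all__ = [
    "SimConfig",
    "LearningState",
    "EyeTrace",
    "SimulatedTrial",
    "HOMOGENEOUS_PRESET",
    "RICH_PRESET",
    "learning_level",
    "update_exposure",
    "simulate_trial",
    "simulate_session",
    "simulate_block_responses",
    "write_traces_csv",
    "read_traces_csv",
]


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the trace generator (times ms, speeds deg/s)."""

    dt_ms: int = 1
    latency_ms: int = 100          # pursuit reaction time
    pursuit_tau_ms: float = 40.0   # first-order velocity time constant
    pursuit_gain: float = 0.95
    pos_noise_sd_deg: float = 0.03

    # learning law (ground truth of the double-exponential fit)
    A1_dps: float = 2.0
    tau1_trials: float = 0.04
    A2_dps: float = 1.0
    tau2_trials: float = 30.0
    c_dps: float = 0.0

    # exposure weights
    w_passive: float = 0.33
    w_reward_unrewarded: float = 0.5
    w_position: float = 0.4
    # chosen so the accumulated exposure is negligible by the midpoint of a
    # washout block: the last-25-trials baseline window must see a fully
    # extinguished fast component (any residual T above ~0.1 trials saturates
    # it when tau1 is a small fraction of a trial)
    washout_decay: float = 0.8

    # residual movement during fixation
    fix_residual_base_dps: float = 1.0
    fix_residual_learned_dps: float = 0.3

    # catch-up saccades
    saccade_threshold_deg: float = 1.5
    saccade_duration_ms: int = 30

    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tau1_trials < self.tau2_trials:
            raise ValueError("tau1_trials must be smaller than tau2_trials")
        for w in (self.w_passive, self.w_reward_unrewarded, self.w_position, self.washout_decay):
            if not 0.0 <= w <= 1.0:
                raise ValueError("exposure weights must lie in [0, 1]")
        if self.pos_noise_sd_deg < 0:
            raise ValueError("noise SD must be non-negative")


#: single-direction sessions (paradigms 1-5): very fast learning, tau1 = 0.04 trials
HOMOGENEOUS_PRESET = SimConfig(tau1_trials=0.04)
#: multi-direction sessions (paradigm 6): slower fast component, tau1 = 1.2 trials
RICH_PRESET = SimConfig(tau1_trials=1.2)


def learning_level(T_eff: float, config: SimConfig) -> float:
    """Predictive learned velocity g (deg/s) at accumulated exposure ``T_eff``."""
    if np.any(np.asarray(T_eff) < 0):
        raise ValueError("T_eff must be non-negative")
    T = np.asarray(T_eff, dtype=float)
    g = (
        config.A1_dps * (1.0 - np.exp(-T / config.tau1_trials))
        + config.A2_dps * (1.0 - np.exp(-T / config.tau2_trials))
        + config.c_dps
    )
    return float(g) if np.isscalar(T_eff) else g


@dataclass
class LearningState:
    """Accumulated effective exposure, kept per (base, learned) direction context.

    Paradigms with a single geometry see the familiar scalar behaviour; the
    alternating-direction paradigm 2 and the multi-direction paradigm 6 keep
    independent counts per context.
    """

    exposures: dict = field(default_factory=dict)
    history: list = field(default_factory=list)

    @staticmethod
    def context(trial: TrialSpec) -> tuple:
        return (round(trial.base_direction_deg) % 360, round(trial.learned_direction_deg) % 360)

    def T_eff(self, trial: TrialSpec) -> float:
        return self.exposures.get(self.context(trial), 0.0)


def update_exposure(state: LearningState, trial: TrialSpec, config: SimConfig) -> LearningState:
    """Advance (or decay) the learning state after one trial.

    Increment rules: 1 for eye-movement trials carrying the full 20 deg/s
    change; ``w_passive`` (times the unrewarded-cue / vanish-window
    multipliers) for fixation trials carrying the change; 0 for no-change and
    small-angle trials.  Trials inside washout blocks decay the context's
    exposure multiplicatively instead.
    """
    key = LearningState.context(trial)
    T = state.exposures.get(key, 0.0)
    if trial.block_type == "washout":
        T *= config.washout_decay
        increment = 0.0
    elif trial.full_change:
        if trial.kind == EYE_MOVEMENT:
            increment = 1.0
        else:
            increment = config.w_passive
            if trial.vanish_window_ms is not None:
                increment *= config.w_position
            if trial.cue_color == "noreward_cue":
                increment *= config.w_reward_unrewarded
        T += increment
    else:
        increment = 0.0
    state.exposures[key] = T
    state.history.append((trial.trial_id, increment, T))
    return state


@dataclass
class EyeTrace:
    """Raw two-channel eye position record at 1 kHz."""

    trial_id: int
    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid_mask: np.ndarray

    @property
    def position(self) -> np.ndarray:
        return np.column_stack([self.x_deg, self.y_deg])


def _predictive_profile(spec: TrialSpec, t: np.ndarray) -> np.ndarray:
    """Unit predictive-velocity profile whose mean over the closed
    [change-50, change+50] ms window is exactly 1."""
    c = spec.change_time_ms
    end = spec.motion_end_ms
    prof = np.zeros_like(t, dtype=float)
    rise = (t >= c - 100) & (t < c)
    prof[rise] = (t[rise] - (c - 100)) / 100.0
    hold = (t >= c) & (t < end)
    prof[hold] = 1.0
    fall = (t >= end) & (t < end + 50)
    prof[fall] = 1.0 - (t[fall] - end) / 50.0
    win = (t >= c - 50) & (t <= c + 50)
    m = prof[win].mean()
    return prof / m


def _raised_cosine_pulse(amp: np.ndarray, dur_ms: int, dt_ms: int) -> np.ndarray:
    """Saccadic velocity pulse (deg/s) whose displacement integrates to ``amp``.

    Peak speed is 2|amp|/dur and peak acceleration 2*pi*|amp|/dur^2, so any
    pulse correcting an error above ~0.8 deg exceeds both the 50 deg/s and
    1000 deg/s^2 detection thresholds.
    """
    k = np.arange(dur_ms // dt_ms)
    shape = 1.0 - np.cos(2.0 * np.pi * (k + 0.5) / k.size)
    # normalise exactly so that sum(shape) * dt/1000 == 1 (unit displacement)
    shape = shape / (shape.sum() * dt_ms / 1000.0)
    return amp[None, :] * shape[:, None]


def _gauss_bump(t: np.ndarray, center_ms: float, sd_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center_ms) / sd_ms) ** 2)


def smooth_eye_velocity(spec: TrialSpec, g_dps: float, config: SimConfig, rng=None) -> np.ndarray:
    """Saccade- and noise-free eye velocity (n, 2) in deg/s.

    Eye-movement trials: delayed first-order lag on the target velocity plus
    the predictive learned-direction component.  Fixation trials: residual
    velocity bumps around the (reacted-to) change time.
    """
    traj = target_kinematics(spec, config.dt_ms)
    t = traj.t_ms
    n = t.size
    v = np.zeros((n, 2))
    w_hat = _unit(spec.learned_direction_deg)
    if spec.kind == EYE_MOVEMENT:
        lat = config.latency_ms // config.dt_ms
        u = np.zeros_like(traj.velocity_dps)
        u[lat:] = traj.velocity_dps[:-lat] if lat else traj.velocity_dps
        alpha = np.exp(-config.dt_ms / config.pursuit_tau_ms)
        v = lfilter([(1.0 - alpha) * config.pursuit_gain], [1.0, -alpha], u, axis=0)
        if g_dps:
            v = v + g_dps * _predictive_profile(spec, t)[:, None] * w_hat[None, :]
    else:
        center = spec.change_time_ms + config.latency_ms
        base_amp = config.fix_residual_base_dps
        learned_amp = (
            config.fix_residual_learned_dps
            if (spec.full_change and spec.vanish_window_ms is None)
            else 0.0
        )
        if rng is not None:
            base_amp *= rng.gamma(4.0, 0.25)
            learned_amp *= rng.gamma(4.0, 0.25) if learned_amp else 1.0
        bump = _gauss_bump(t, center, 50.0)
        u_hat = _unit(spec.base_direction_deg)
        v = base_amp * bump[:, None] * u_hat[None, :]
        if learned_amp:
            v = v + learned_amp * bump[:, None] * w_hat[None, :]
    return v


def simulate_trial(spec: TrialSpec, g_dps: float, config: SimConfig, rng) -> EyeTrace:
    """Generate the raw eye-position trace of one trial.

    The trace is position only; velocity/acceleration are the preprocessor's
    job.  Catch-up saccades fire on eye-movement trials whenever the position
    error, predicted one reaction time ahead, exceeds the threshold.
    """
    if g_dps < 0:
        raise ValueError("g_dps must be non-negative; sign comes from the learned direction")
    traj = target_kinematics(spec, config.dt_ms)
    t = traj.t_ms
    n = t.size
    dt_s = config.dt_ms / 1000.0

    v = smooth_eye_velocity(spec, g_dps, config, rng=rng)
    pos = np.cumsum(v, axis=0) * dt_s

    if spec.kind == EYE_MOVEMENT:
        # A catch-up saccade is programmed when the position error, predicted
        # one reaction time ahead, exceeds the threshold; programming uses the
        # error state one reaction time in the past (sensory delay) and is
        # cancelled if the prediction no longer holds at execution time.  The
        # cancellation is what keeps classic step-ramp (Rashbass) trials
        # saccade-free: the initial 4 deg step error has resolved itself by
        # the time the saccade would land.
        err = traj.position_deg - pos
        rel_v = traj.velocity_dps - v
        dur = config.saccade_duration_ms // config.dt_ms
        lat = config.latency_ms // config.dt_ms
        horizon_s = config.latency_ms / 1000.0
        E = np.linalg.norm(err + rel_v * horizon_s, axis=1)
        i = int(np.searchsorted(t, 0)) + lat
        i_stop = n - dur
        while i < i_stop:
            if E[i - lat] > config.saccade_threshold_deg and E[i] > config.saccade_threshold_deg:
                amp = err[i].copy()
                pulse = _raised_cosine_pulse(amp, config.saccade_duration_ms, config.dt_ms)
                disp = np.cumsum(pulse, axis=0) * dt_s
                pos[i : i + dur] += disp
                pos[i + dur :] += amp
                err[i : i + dur] -= disp
                err[i + dur :] -= amp
                E[i:] = np.linalg.norm(err[i:] + rel_v[i:] * horizon_s, axis=1)
                i += dur + lat  # refractory: one reaction time after the saccade
            else:
                i += 1

    if config.pos_noise_sd_deg > 0:
        pos = pos + rng.normal(0.0, config.pos_noise_sd_deg, size=pos.shape)

    return EyeTrace(
        trial_id=spec.trial_id,
        t_ms=t.astype(int),
        x_deg=pos[:, 0],
        y_deg=pos[:, 1],
        valid_mask=np.ones(n, dtype=bool),
    )


@dataclass
class SimulatedTrial:
    """One simulated trial: its spec, optional trace, and learning ground truth."""

    block_index: int
    block_type: str
    spec: TrialSpec
    trace: Optional[EyeTrace]
    g_dps: float
    T_eff: float


def _trial_rng(seed: int, block_index: int, trial_index: int):
    return np.random.default_rng(np.random.SeedSequence([seed, block_index, trial_index]))


def simulate_session(
    session: SessionSpec,
    config: SimConfig,
    trials_filter=None,
) -> list:
    """Simulate every trial of a session in order, threading the learning state.

    ``trials_filter(block_index, block, trial_index, spec) -> bool`` may skip
    trace generation for trials no analysis needs; exposure bookkeeping always
    runs.  Per-trial RNG streams are derived from ``config.seed`` and the
    (block, trial) position, so traces are bit-identical regardless of which
    other trials are materialised.
    """
    state = LearningState()
    out: list = []
    for bi, block in enumerate(session.blocks):
        for ti, spec in enumerate(block.trials):
            g = learning_level(state.T_eff(spec), config)
            T_before = state.T_eff(spec)
            want = trials_filter is None or trials_filter(bi, block, ti, spec)
            trace = None
            if want:
                rng = _trial_rng(config.seed, bi, ti)
                trace = simulate_trial(spec, g, config, rng)
            out.append(
                SimulatedTrial(
                    block_index=bi,
                    block_type=block.block_type,
                    spec=spec,
                    trace=trace,
                    g_dps=g,
                    T_eff=T_before,
                )
            )
            update_exposure(state, spec, config)
    return out


def simulate_block_responses(
    n_blocks: int,
    n_trials: int,
    config: SimConfig,
    rng,
    response_noise_sd_dps: float = 0.3,
) -> np.ndarray:
    """Response-level shortcut for learning-curve studies.

    Simulates ``n_blocks`` independent motor blocks at the level of the
    per-trial learned response: the learning law evaluated at T = 0..n-1
    (each block starts fully washed out) plus Gaussian response noise.
    Returns an (n_blocks, n_trials) array.
    """
    T = np.arange(n_trials, dtype=float)
    g = learning_level(T, config)
    return g[None, :] + rng.normal(0.0, response_noise_sd_dps, size=(n_blocks, n_trials))


# ---------------------------------------------------------------------------
# plain-text IO


def write_traces_csv(records: Iterable[SimulatedTrial], path) -> None:
    """Traces as tidy CSV: block_index, trial_id, t_ms, eye_x_deg, eye_y_deg."""
    import pandas as pd

    frames = []
    for rec in records:
        tr = rec.trace
        if tr is None:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "block_index": rec.block_index,
                    "trial_id": tr.trial_id,
                    "t_ms": tr.t_ms,
                    "eye_x_deg": tr.x_deg,
                    "eye_y_deg": tr.y_deg,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_traces_csv(path) -> dict:
    """Inverse of :func:`write_traces_csv`; keys are (block_index, trial_id)."""
    import pandas as pd

    df = pd.read_csv(path)
    out = {}
    for (bi, tid), grp in df.groupby(["block_index", "trial_id"], sort=True):
        out[(int(bi), int(tid))] = EyeTrace(
            trial_id=int(tid),
            t_ms=grp["t_ms"].to_numpy(),
            x_deg=grp["eye_x_deg"].to_numpy(),
            y_deg=grp["eye_y_deg"].to_numpy(),
            valid_mask=np.ones(len(grp), dtype=bool),
        )
    return out
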