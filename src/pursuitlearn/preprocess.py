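"""Saccade-aware preprocessing of raw eye-position traces.

Recipe: smooth position with a Gaussian kernel (sigma = 5 ms), differentiate
centrally for velocity and again for acceleration; flag saccadic samples by
kinematic thresholds (|acceleration| > 1000 deg/s^2 anywhere, speed > 15
deg/s during fixation phases, speed > 50 deg/s while the target moves); merge
and pad the flagged intervals, treat them as missing data; average aligned
trials over the valid samples only; and finally smooth the averaged trace
with a 21 ms moving average.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Sequence

import numpy as np

from .paradigm import TrialSpec
from .synthetic_eyes import EyeTrace

__all__ = [
    "SaccadeInterval",
    "AveragedTrace",
    "gaussian_kernel",
    "kinematics_from_position",
    "target_moving_schedule",
    "detect_saccades",
    "mask_saccades",
    "average_aligned",
    "ACCEL_THRESHOLD_DPS2",
    "FIXATION_SPEED_THRESHOLD_DPS",
    "PURSUIT_SPEED_THRESHOLD_DPS",
]

ACCEL_THRESHOLD_DPS2 = 1000.0
FIXATION_SPEED_THRESHOLD_DPS = 15.0
PURSUIT_SPEED_THRESHOLD_DPS = 50.0

GAUSS_SIGMA_MS = 5.0
MOVING_AVERAGE_SPAN_MS = 21


@dataclass(frozen=True)
class SaccadeInterval:
    """A detected saccadic epoch, inclusive on both ends, trial-aligned ms."""

    start_ms: int
    end_ms: int
    trigger: str  # "acceleration" | "velocity_fixation" | "velocity_pursuit"

    def __post_init__(self) -> None:
        if self.start_ms > self.end_ms:
            raise ValueError("start_ms must not exceed end_ms")


@dataclass
class AveragedTrace:
    t_ms: np.ndarray
    mean_dps: np.ndarray
    sem_dps: np.ndarray
    n_valid: np.ndarray


def gaussian_kernel(sigma_ms: float = GAUSS_SIGMA_MS, dt_ms: int = 1) -> np.ndarray:
    """Unit-sum Gaussian kernel truncated at +/- 4 sigma."""
    radius = int(round(4 * sigma_ms / dt_ms))
    x = np.arange(-radius, radius + 1) * dt_ms
    k = np.exp(-0.5 * (x / sigma_ms) ** 2)
    return k / k.sum()


def _smooth_edge_renorm(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same'-mode convolution renormalised near the edges so a constant
    input maps to itself everywhere."""
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def kinematics_from_position(trace: EyeTrace, dt_ms: int = 1, sigma_ms: float = GAUSS_SIGMA_MS):
    """Velocity (deg/s) and acceleration (deg/s^2) from a raw position trace.

    Position is Gaussian-smoothed, then central-difference differentiated
    once for velocity and again for acceleration (one-sided at the ends).
    """
    kernel = gaussian_kernel(sigma_ms, dt_ms)
    n = trace.t_ms.size
    if n < kernel.size:
        raise ValueError(f"trace of {n} samples is shorter than the {kernel.size}-tap kernel")
    pos = np.column_stack([trace.x_deg, trace.y_deg])
    sm = np.column_stack([_smooth_edge_renorm(pos[:, c], kernel) for c in range(2)])
    vel = np.gradient(sm, axis=0) * (1000.0 / dt_ms)
    acc = np.gradient(vel, axis=0) * (1000.0 / dt_ms)
    return vel, acc


def target_moving_schedule(spec: TrialSpec, t_ms: np.ndarray) -> np.ndarray:
    """Boolean per-sample schedule: True while the target moves, [0, motion end].

    The thresholds key on target motion, not trial kind: on fixation trials
    the covert target still moves, so the pursuit-phase rule applies there too.
    """
    return (t_ms >= 0) & (t_ms <= spec.motion_end_ms)


def _flag_saccadic(velocity: np.ndarray, acceleration: np.ndarray, moving: np.ndarray):
    speed = np.hypot(velocity[:, 0], velocity[:, 1])
    accmag = np.hypot(acceleration[:, 0], acceleration[:, 1])
    acc_hit = accmag > ACCEL_THRESHOLD_DPS2
    vel_fix = ~moving & (speed > FIXATION_SPEED_THRESHOLD_DPS)
    vel_pur = moving & (speed > PURSUIT_SPEED_THRESHOLD_DPS)
    return acc_hit, vel_fix, vel_pur


def detect_saccades(
    velocity: np.ndarray,
    acceleration: np.ndarray,
    moving: np.ndarray,
    t_ms: np.ndarray,
    *,
    pad_ms: int = 5,
    merge_ms: int = 10,
    dt_ms: int = 1,
) -> List[SaccadeInterval]:
    """Detect saccadic intervals from velocity/acceleration traces.

    Contiguous supra-threshold samples form intervals; intervals closer than
    ``merge_ms`` are merged, every interval is padded by ``pad_ms`` on each
    side, and overlaps after padding are merged again.  The reported trigger
    is the rule active at the interval's first flagged sample (acceleration
    taking precedence on ties).
    """
    n = t_ms.size
    if not (velocity.shape[0] == acceleration.shape[0] == moving.size == n):
        raise ValueError("velocity, acceleration, schedule, and time axis lengths differ")
    acc_hit, vel_fix, vel_pur = _flag_saccadic(velocity, acceleration, moving)
    flagged = acc_hit | vel_fix | vel_pur
    if not flagged.any():
        return []

    idx = np.flatnonzero(flagged)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])

    # merge runs separated by fewer than merge_ms unflagged samples
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if (s - merged[-1][1] - 1) * dt_ms < merge_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    pad = pad_ms // dt_ms
    padded = [[max(0, s - pad), min(n - 1, e + pad)] for s, e in merged]
    final = [padded[0]]
    for s, e in padded[1:]:
        if s <= final[-1][1] + 1:
            final[-1][1] = max(final[-1][1], e)
        else:
            final.append([s, e])

    out = []
    for s, e in final:
        first = next(i for i in range(s, e + 1) if flagged[i])
        if acc_hit[first]:
            trig = "acceleration"
        elif vel_fix[first]:
            trig = "velocity_fixation"
        else:
            trig = "velocity_pursuit"
        out.append(SaccadeInterval(start_ms=int(t_ms[s]), end_ms=int(t_ms[e]), trigger=trig))
    return out


def mask_saccades(trace: EyeTrace, intervals: Sequence[SaccadeInterval]) -> EyeTrace:
    """Return a copy of the trace with saccadic samples marked missing.

    Only the valid mask changes; positions are left untouched (no
    interpolation).  Re-applying the same intervals is a no-op.
    """
    mask = trace.valid_mask.copy()
    for iv in intervals:
        mask &= ~((trace.t_ms >= iv.start_ms) & (trace.t_ms <= iv.end_ms))
    return replace(trace, valid_mask=mask)


def moving_average_missing(x: np.ndarray, span: int = MOVING_AVERAGE_SPAN_MS) -> np.ndarray:
    """Centred moving average that shrinks at the edges and skips NaNs.

    Samples that are NaN on input stay NaN on output and never enter a
    neighbour's window.
    """
    finite = np.isfinite(x)
    filled = np.where(finite, x, 0.0)
    win = np.ones(span)
    num = np.convolve(filled, win, mode="same")
    den = np.convolve(finite.astype(float), win, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~finite] = np.nan
    return out


def average_aligned(
    values: np.ndarray,
    valid: np.ndarray,
    t_ms: np.ndarray = None,
    smooth_span_ms: int = MOVING_AVERAGE_SPAN_MS,
) -> AveragedTrace:
    """Missing-data-aware average of motion-onset-aligned traces.

    ``values`` is (n_trials, n_samples); samples where ``valid`` is False are
    excluded.  Mean and SEM are computed over the valid samples only (SEM
    defined where at least two are valid), then the mean is smoothed with the
    centred moving average (pass ``smooth_span_ms=None`` to skip it, e.g. for
    baseline traces that will be subtracted sample-wise).
    """
    values = np.asarray(values, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if values.ndim != 2 or values.shape != valid.shape:
        raise ValueError("values and valid must be matching 2-D arrays (trials x samples)")
    if values.shape[0] == 0:
        raise ValueError("need at least one trace to average")
    if t_ms is None:
        t_ms = np.arange(values.shape[1])

    ok = valid & np.isfinite(values)
    n_valid = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(ok, values, 0.0).sum(axis=0) / n_valid
        dev = np.where(ok, values - mean[None, :], 0.0)
        var = (dev**2).sum(axis=0) / np.maximum(n_valid - 1, 1)
        sem = np.sqrt(var / n_valid)
    mean[n_valid == 0] = np.nan
    sem[n_valid < 2] = np.nan
    if smooth_span_ms:
        mean = moving_average_missing(mean, span=smooth_span_ms)
    return AveragedTrace(t_ms=np.asarray(t_ms), mean_dps=mean, sem_dps=sem, n_valid=n_valid)
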