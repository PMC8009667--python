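"""Double-exponential learning-curve fitting and fast/slow decomposition.

The growth of the learned response over trials is modelled as

    L(T) = A1 (1 - exp(-T / tau1)) + A2 (1 - exp(-T / tau2)) + c

with T the trial number minus one, amplitudes A1, A2 >= 0, time constants
bounded to [1e-3, 1e3] trials and relabelled so tau1 <= tau2.  Fitting is
nonlinear least squares with a multi-start over a log-spaced (tau1, tau2)
grid; at each start the amplitudes and baseline are solved by constrained
linear least squares.

A fast time constant well below one trial is *set-identified* rather than
point-identified at integer trial spacing: every tau1 small enough that the
fast component saturates within the first trial fits the data equally well.
When the profiled SSE over tau1 is flat at the resolution of the residual
noise (Delta-chi-square <= 1) across more than two decades, the reported tau1
is the geometric midpoint of that flat set, and the set itself is returned as
``tau1_interval``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import least_squares, lsq_linear

__all__ = ["DoubleExpFit", "fit_double_exponential", "fraction_fast", "average_by_trial_index"]

TAU_MIN = 1e-3
TAU_MAX = 1e3
#: a Delta-chi2 <= 1 flat set spanning more than this ratio marks tau1 as
#: set-identified only
FLAT_SPAN_RATIO = 100.0


@dataclass
class DoubleExpFit:
    A1_dps: float
    tau1_trials: float
    A2_dps: float
    tau2_trials: float
    c_dps: float
    residual_sse: float
    n_points: int
    converged: bool
    fraction_fast_100: float
    tau1_interval: Optional[Tuple[float, float]] = None

    def predict(self, T) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        return (
            self.A1_dps * (1.0 - np.exp(-T / self.tau1_trials))
            + self.A2_dps * (1.0 - np.exp(-T / self.tau2_trials))
            + self.c_dps
        )


def _basis(T: np.ndarray, tau: float) -> np.ndarray:
    return 1.0 - np.exp(-T / tau)


def _solve_amplitudes(T, y, tau1, tau2):
    """Best (A1, A2, c) with A1, A2 >= 0 for fixed time constants."""
    M = np.column_stack([_basis(T, tau1), _basis(T, tau2), np.ones_like(T)])
    res = lsq_linear(M, y, bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]))
    sse = float(np.sum((M @ res.x - y) ** 2))
    return res.x, sse


def _model(theta, T):
    a1, a2, c, lt1, lt2 = theta
    return a1 * _basis(T, np.exp(lt1)) + a2 * _basis(T, np.exp(lt2)) + c


def fit_double_exponential(
    trial_index,
    values,
    *,
    n_grid: int = 8,
    n_refine: int = 3,
) -> DoubleExpFit:
    """Fit the double-exponential learning model to (trial index, response) data.

    ``trial_index`` is T = trial number - 1.  Multi-start: every ordered pair
    from a log-spaced tau grid is scored with the amplitudes solved linearly;
    the best ``n_refine`` starts are polished by bounded nonlinear least
    squares, components are relabelled so tau1 <= tau2, and the flat-set rule
    described in the module docstring handles an unidentifiable fast constant.
    """
    T = np.asarray(trial_index, dtype=float)
    y = np.asarray(values, dtype=float)
    if T.shape != y.shape or T.ndim != 1:
        raise ValueError("trial_index and values must be matching 1-D sequences")
    if T.size < 6:
        raise ValueError(f"need at least 6 points to fit 5 parameters, got {T.size}")
    if not (np.isfinite(T).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in fit input")
    order = np.argsort(T)
    T, y = T[order], y[order]
    n = T.size

    taus = np.logspace(np.log10(TAU_MIN), np.log10(TAU_MAX), n_grid)
    starts = []
    for i, t1 in enumerate(taus):
        for t2 in taus[i:]:
            x, sse = _solve_amplitudes(T, y, t1, t2)
            starts.append((sse, t1, t2, x))
    starts.sort(key=lambda s: s[0])
    grid_best_sse = starts[0][0]

    best = None
    converged = False
    for sse0, t1, t2, x in starts[:n_refine]:
        theta0 = np.array([x[0], x[1], x[2], np.log(t1), np.log(t2)])
        lb = [0.0, 0.0, -np.inf, np.log(TAU_MIN), np.log(TAU_MIN)]
        ub = [np.inf, np.inf, np.inf, np.log(TAU_MAX), np.log(TAU_MAX)]
        sol = least_squares(
            lambda th: _model(th, T) - y, theta0, bounds=(lb, ub), method="trf"
        )
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol.x)
            converged = bool(sol.success)
    sse_best, theta = best
    a1, a2, c = theta[0], theta[1], theta[2]
    t1, t2 = float(np.exp(theta[3])), float(np.exp(theta[4]))
    if t1 > t2:
        a1, a2, t1, t2 = a2, a1, t2, t1

    interval = None
    amp_total = a1 + a2
    if amp_total > 0 and a1 <= 1e-7 * amp_total:
        # a vanishing fast amplitude means the data want a single exponential;
        # report the active component in the first slot with A2 at its bound
        a1, t1, a2, t2 = a2, t2, 0.0, t2
    else:
        # profile the fast constant, re-solving amplitudes at each candidate
        prof_taus = np.logspace(np.log10(TAU_MIN), np.log10(max(t2, TAU_MIN * 10)), 61)
        prof_taus = prof_taus[prof_taus <= t2]
        dof = max(n - 5, 1)
        threshold = sse_best + max(sse_best, 1e-12) / dof  # Delta-chi2 = 1
        flat = []
        for tt in prof_taus:
            _, sse_t = _solve_amplitudes(T, y, tt, t2)
            if sse_t <= threshold:
                flat.append(tt)
        interval = (float(min(flat)), float(max(flat))) if flat else None

        if interval and interval[1] / interval[0] > FLAT_SPAN_RATIO:
            t1_mid = float(np.sqrt(interval[0] * interval[1]))
            x_mid, sse_mid = _solve_amplitudes(T, y, t1_mid, t2)
            # keep the centred solution only if it is as good as any grid start
            if sse_mid <= grid_best_sse:
                a1, a2, c = x_mid
                t1, sse_best = t1_mid, sse_mid

    fit = DoubleExpFit(
        A1_dps=float(a1),
        tau1_trials=float(t1),
        A2_dps=float(a2),
        tau2_trials=float(t2),
        c_dps=float(c),
        residual_sse=float(sse_best),
        n_points=n,
        converged=converged,
        fraction_fast_100=float("nan"),
        tau1_interval=interval,
    )
    fit.fraction_fast_100 = fraction_fast(fit, 100)
    return fit


def fraction_fast(fit: DoubleExpFit, n_trials: int = 100, mode: str = "sum") -> float:
    """Share of the modelled learning in the first ``n_trials`` attributable
    to the fast component (baseline c excluded).

    ``mode='sum'`` (default) ratios the summed fast-component learning over
    T = 0..n-1 to the summed total learning; ``mode='final'`` ratios the
    component values at T = n-1 instead.  NaN when there is no learning.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    T = np.arange(n_trials, dtype=float)
    fast = fit.A1_dps * _basis(T, fit.tau1_trials)
    slow = fit.A2_dps * _basis(T, fit.tau2_trials)
    if mode == "sum":
        num, den = fast.sum(), fast.sum() + slow.sum()
    elif mode == "final":
        num, den = fast[-1], fast[-1] + slow[-1]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if den == 0:
        return float("nan")
    return float(num / den)


def average_by_trial_index(responses: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Average an (n_blocks, n_trials) response array by within-block trial
    index; returns (T, mean) with T = trial number - 1, NaNs ignored."""
    responses = np.asarray(responses, dtype=float)
    mean = np.nanmean(responses, axis=0)
    T = np.arange(responses.shape[1], dtype=float)
    ok = np.isfinite(mean)
    return T[ok], mean[ok]
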