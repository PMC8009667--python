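"""End-to-end glue: simulate a session, preprocess traces, extract responses.

This module wires the paradigm builder, the trace generator, the saccade-aware
preprocessor, and the response metrics into one call that produces a tidy
per-trial response table ready for block statistics or learning-curve fits.
Traces are only materialised for trials an analysis consumes (eye-movement
trials of learning blocks, the last 25 eye-movement trials of washout blocks,
and fixation trials when the residual-movement analyses are requested).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .metrics import (
    RESPONSE_WINDOW_MS,
    learned_response,
    learned_velocity,
    washout_baseline,
)
from .paradigm import EYE_MOVEMENT, SessionSpec, _unit
from .preprocess import (
    detect_saccades,
    kinematics_from_position,
    mask_saccades,
    target_moving_schedule,
)
from .synthetic_eyes import EyeTrace, SimConfig, simulate_session

__all__ = ["SessionResult", "preprocess_trace", "analyze_session"]


@dataclass
class SessionResult:
    """Per-trial learned responses plus the supporting baselines."""

    responses: pd.DataFrame
    baselines: Dict[int, object] = field(default_factory=dict)
    fixation: Optional[pd.DataFrame] = None

    def block_means(self) -> pd.DataFrame:
        return (
            self.responses.groupby(["block_type", "block_id"])["value_dps"].mean().reset_index()
        )


def preprocess_trace(spec, trace: EyeTrace):
    """Velocity from raw position with saccadic samples marked missing.

    Returns ``(velocity_xy, valid_mask, saccade_intervals)``.
    """
    vel, acc = kinematics_from_position(trace)
    moving = target_moving_schedule(spec, trace.t_ms)
    intervals = detect_saccades(vel, acc, moving, trace.t_ms)
    masked = mask_saccades(trace, intervals)
    return vel, masked.valid_mask, intervals


def _em_positions(block):
    return [i for i, t in enumerate(block.trials) if t.kind == EYE_MOVEMENT]


def analyze_session(
    session: SessionSpec,
    config: SimConfig,
    *,
    include_fixation: bool = False,
    subject: str = "S0",
) -> SessionResult:
    """Simulate and analyse one session.

    The response table has one row per analysed eye-movement trial with the
    baseline-subtracted learned response (``value_dps``), the generator's
    ground-truth predictive velocity (``g_true_dps``) and exposure count
    (``T_eff``), and block bookkeeping columns.  Washout rows come from the
    last 25 eye-movement trials measured against their own baseline.
    """
    needed: Dict[int, set] = {}
    for bi, block in enumerate(session.blocks):
        em = _em_positions(block)
        if block.block_type == "washout":
            needed[bi] = set(em[-25:])
        else:
            sel = set(em)
            if include_fixation:
                sel |= {i for i, t in enumerate(block.trials) if t.kind != EYE_MOVEMENT}
            needed[bi] = sel

    records = simulate_session(
        session, config, trials_filter=lambda bi, blk, ti, spec: ti in needed[bi]
    )

    by_block: Dict[int, list] = {}
    for rec in records:
        by_block.setdefault(rec.block_index, []).append(rec)

    # washout baselines (and washout self-responses)
    baselines: Dict[int, object] = {}
    rows = []
    fixation_rows = []
    for bi, block in enumerate(session.blocks):
        if block.block_type != "washout":
            continue
        w_hat = _unit(block.learned_direction_deg)
        ems = [r for r in by_block[bi] if r.trace is not None]
        vel_list, mask_list = [], []
        for r in ems:
            vel, valid, _ = preprocess_trace(r.spec, r.trace)
            vel_list.append(vel @ w_hat)
            mask_list.append(valid)
        t_ms = ems[0].trace.t_ms
        base = washout_baseline(
            np.array(vel_list), np.array(mask_list), t_ms, block_id=block.block_id
        )
        baselines[bi] = base
        for ei, (r, lv, valid) in enumerate(zip(ems, vel_list, mask_list)):
            values = lv - base.mean_dps
            ok = valid & np.isfinite(base.mean_dps)
            rows.append(
                dict(
                    subject=subject,
                    block_id=bi,
                    block_type="washout",
                    trial_index=r.spec.trial_id,
                    em_index=ei,
                    value_dps=learned_response(values, ok, t_ms),
                    g_true_dps=r.g_dps,
                    T_eff=r.T_eff,
                )
            )

    # learning blocks
    for bi, block in enumerate(session.blocks):
        if block.block_type == "washout":
            continue
        wblock = session.corresponding_washout(bi)
        baseline = baselines[wblock.block_id] if wblock is not None else None
        recs = by_block.get(bi, [])
        fix_base_vel: list = []
        pending_fix: list = []
        ei = 0
        for r in sorted(recs, key=lambda r: r.spec.trial_id):
            if r.trace is None:
                continue
            vel, valid, _ = preprocess_trace(r.spec, r.trace)
            t_ms = r.trace.t_ms
            if r.spec.kind == EYE_MOVEMENT:
                lv, ok = learned_velocity(vel, baseline, block.learned_direction_deg, valid)
                value = learned_response(lv, ok, t_ms)
                rows.append(
                    dict(
                        subject=subject,
                        block_id=bi,
                        block_type=block.block_type,
                        trial_index=r.spec.trial_id,
                        em_index=ei,
                        value_dps=value,
                        g_true_dps=r.g_dps,
                        T_eff=r.T_eff,
                        base_velocity=float(np.mean(pending_fix)) if pending_fix else np.nan,
                    )
                )
                pending_fix = []
                ei += 1
            else:
                u_hat = _unit(block.base_direction_deg)
                bv = learned_response(vel @ u_hat, valid, t_ms)
                pending_fix.append(bv)
                fix_base_vel.append(
                    dict(
                        subject=subject,
                        block_id=bi,
                        block_type=block.block_type,
                        trial_index=r.spec.trial_id,
                        base_velocity=bv,
                        learned_velocity_mean=learned_response(
                            vel @ _unit(block.learned_direction_deg), valid, t_ms
                        ),
                    )
                )
        if include_fixation:
            fixation_rows.extend(fix_base_vel)

    responses = pd.DataFrame(rows)
    fixation = pd.DataFrame(fixation_rows) if include_fixation else None
    return SessionResult(responses=responses, baselines=baselines, fixation=fixation)
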