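"""Learned-velocity / learned-response statistics and block comparisons.

The learning readout is the *learned response*: the eye velocity projected
onto the learned direction, minus the washout baseline (the missing-aware
average of the last 25 eye-movement trials of the corresponding washout
block), averaged over the closed 200-300 ms window after motion onset - the
100 ms surrounding the change in target direction.  Signs are adjusted so
positive values mean movement toward the learned direction.

Block-level comparisons reproduce the study's statistical toolkit: Friedman
across matched motor/fixation/washout triples with Bonferroni-corrected
signed-rank post-hocs, paired signed-rank for adjacent-block designs,
rank-sum for unpaired contrasts, a subject + base-velocity regression, and
base-velocity tercile grouping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .paradigm import _unit
from .preprocess import AveragedTrace, average_aligned

__all__ = [
    "LearnedResponse",
    "RatioTable",
    "RESPONSE_WINDOW_MS",
    "washout_baseline",
    "learned_velocity",
    "learned_response",
    "block_ratios",
    "friedman_with_posthoc",
    "paired_signed_rank",
    "rank_sum",
    "base_velocity_regression",
    "tercile_groups",
    "compare_conditions",
]

#: closed analysis window, ms after motion onset (101 samples at 1 kHz)
RESPONSE_WINDOW_MS = (200, 300)


@dataclass(frozen=True)
class LearnedResponse:
    trial_id: int
    block_id: int
    block_type: str
    value_dps: float
    sign_adjusted: bool = True


@dataclass
class RatioTable:
    """Per-block-type mean learned responses and their ratio to the motor mean."""

    means: pd.Series
    ratios: pd.Series
    passive_upper: Optional[float] = None  # fixation-congruent blocks
    passive_lower: Optional[float] = None  # paradigm-2 fixation-only blocks


def washout_baseline(
    em_velocity: np.ndarray,
    valid: np.ndarray,
    t_ms: np.ndarray,
    *,
    block_id=None,
    n_last: int = 25,
) -> AveragedTrace:
    """Baseline learned-direction velocity from a washout block.

    ``em_velocity`` holds the learned-direction velocity of the block's
    eye-movement trials in presentation order, (n_trials, n_samples); the
    last ``n_last`` are averaged (missing-aware, no display smoothing so
    that subtracting the baseline from its own trials cancels exactly).
    """
    n = em_velocity.shape[0]
    if n < n_last:
        name = f" {block_id}" if block_id is not None else ""
        raise ValueError(
            f"washout block{name} has only {n} eye-movement trials; {n_last} required"
        )
    return average_aligned(
        em_velocity[-n_last:], valid[-n_last:], t_ms, smooth_span_ms=None
    )


def learned_velocity(
    velocity_xy: np.ndarray,
    baseline: Optional[AveragedTrace],
    learned_direction_deg: float,
    valid: Optional[np.ndarray] = None,
):
    """Project a 2-channel velocity trace onto the learned direction and
    subtract the washout baseline sample-wise.

    The projection onto the learned-direction unit vector already makes
    positive values mean movement toward the learned direction (the study's
    sign adjustment).  ``baseline=None`` means a zero baseline (the
    alternating-direction paradigm, which has no washout blocks).
    Returns ``(values, valid_mask)``.
    """
    w_hat = _unit(learned_direction_deg)
    proj = velocity_xy @ w_hat
    if valid is None:
        valid = np.ones(proj.size, dtype=bool)
    if baseline is None:
        return proj, valid.copy()
    b = baseline.mean_dps
    out = proj - b
    return out, valid & np.isfinite(b)


def learned_response(
    values: np.ndarray,
    valid: np.ndarray,
    t_ms: np.ndarray,
    window_ms=RESPONSE_WINDOW_MS,
) -> float:
    """Mean learned velocity over the valid samples of the closed analysis
    window; NaN if the whole window is missing (e.g. fully saccadic)."""
    w = (t_ms >= window_ms[0]) & (t_ms <= window_ms[1])
    sel = w & valid & np.isfinite(values)
    if not sel.any():
        return float("nan")
    return float(values[sel].mean())


def block_ratios(responses: pd.DataFrame, *, per_subject: bool = False) -> RatioTable:
    """Mean learned response per block type, as a ratio to the motor mean.

    ``responses`` needs columns ``block_type`` and ``value_dps`` (and
    ``subject`` when ``per_subject``).  Trials are pooled by default; with
    ``per_subject`` means are taken within subject first and then averaged.
    The passive-learning bound pair is reported when the relevant block
    types are present: upper bound from fixation-congruent blocks, lower
    bound from the fixation-only (alternating-direction) blocks.
    """
    df = responses.dropna(subset=["value_dps"])
    if per_subject:
        means = (
            df.groupby(["block_type", "subject"])["value_dps"].mean().groupby("block_type").mean()
        )
    else:
        means = df.groupby("block_type")["value_dps"].mean()
    if "motor" not in means.index:
        raise ValueError("ratio table needs motor blocks")
    motor = means["motor"]
    if motor <= 0:
        raise ValueError(f"motor-block mean learned response is {motor:.3g} <= 0; ratios undefined")
    ratios = means / motor
    upper = float(ratios["fix_congruent"]) if "fix_congruent" in ratios.index else None
    fix_only = [t for t in ("fix_only_right", "fix_only_left") if t in means.index]
    lower = (
        float(df[df.block_type.isin(fix_only)]["value_dps"].mean() / motor) if fix_only else None
    )
    return RatioTable(means=means, ratios=ratios, passive_upper=upper, passive_lower=lower)


# ---------------------------------------------------------------------------
# condition comparisons


def friedman_with_posthoc(triples: pd.DataFrame) -> Dict:
    """Friedman test across matched condition columns with Bonferroni-corrected
    pairwise signed-rank post-hocs.

    ``triples``: one row per matched set, one column per condition.
    """
    cols = list(triples.columns)
    clean = triples.dropna()
    fr_stat, fr_p = stats.friedmanchisquare(*[clean[c] for c in cols])
    pairs = {}
    n_pairs = len(cols) * (len(cols) - 1) // 2
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            w = stats.wilcoxon(clean[a], clean[b], alternative="two-sided")
            pairs[f"{a}_vs_{b}"] = {
                "statistic": float(w.statistic),
                "p_raw": float(w.pvalue),
                "p_bonferroni": float(min(1.0, w.pvalue * n_pairs)),
            }
    return {
        "friedman_statistic": float(fr_stat),
        "friedman_p": float(fr_p),
        "n": int(len(clean)),
        "posthoc": pairs,
    }


def paired_signed_rank(a: Sequence[float], b: Sequence[float]) -> Dict:
    """Two-sided Wilcoxon signed-rank on paired samples (e.g. adjacent blocks)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError(f"unpaired inputs: {a.size} vs {b.size} values")
    ok = np.isfinite(a) & np.isfinite(b)
    w = stats.wilcoxon(a[ok], b[ok], alternative="two-sided")
    return {
        "statistic": float(w.statistic),
        "p": float(w.pvalue),
        "n": int(ok.sum()),
        "median_difference": float(np.median(a[ok] - b[ok])),
    }


def rank_sum(a: Sequence[float], b: Sequence[float]) -> Dict:
    """Two-sided rank-sum for unpaired contrasts."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    r = stats.ranksums(a[np.isfinite(a)], b[np.isfinite(b)])
    return {"statistic": float(r.statistic), "p": float(r.pvalue)}


def base_velocity_regression(records: pd.DataFrame) -> Dict:
    """Linear regression of the learned response on subject identity and the
    mean fixation base velocity (columns: value_dps, subject, base_velocity).

    Subject enters as a categorical indicator.  Returns two-sided p-values
    for the subject factor (smallest indicator p) and the base-velocity slope.
    """
    import statsmodels.formula.api as smf

    df = records.dropna(subset=["value_dps", "base_velocity"]).copy()
    model = smf.ols("value_dps ~ C(subject) + base_velocity", data=df).fit()
    subj_p = [p for name, p in model.pvalues.items() if name.startswith("C(subject)")]
    return {
        "params": {k: float(v) for k, v in model.params.items()},
        "p_base_velocity": float(model.pvalues["base_velocity"]),
        "p_subject": float(min(subj_p)) if subj_p else float("nan"),
        "n": int(model.nobs),
    }


def tercile_groups(base_velocities: Sequence[float]) -> np.ndarray:
    """Label each trial 0/1/2 by the empirical 33.3/66.7 percentiles of its
    session's fixation base velocity."""
    v = np.asarray(base_velocities, dtype=float)
    lo, hi = np.nanpercentile(v, [100 / 3, 200 / 3])
    labels = np.full(v.size, 1, dtype=int)
    labels[v <= lo] = 0
    labels[v > hi] = 2
    return labels


def compare_conditions(responses: pd.DataFrame, grouping: Dict) -> Dict:
    """Dispatch the study's block-comparison statistics.

    ``grouping`` keys select analyses:
      - ``triples``: list of three block types -> Friedman + post-hocs on
        per-block means matched by order of appearance.
      - ``paired``: (type_a, type_b) -> signed-rank on order-matched block means.
      - ``unpaired``: (type_a, type_b) -> rank-sum on trial values.
      - ``regression``: True -> subject/base-velocity regression (requires
        ``subject`` and ``base_velocity`` columns).
    All p-values are two-sided.
    """
    report: Dict = {}
    if "triples" in grouping:
        types = grouping["triples"]
        per_block = (
            responses[responses.block_type.isin(types)]
            .groupby(["block_type", "block_id"])["value_dps"]
            .mean()
            .reset_index()
        )
        cols = {}
        for t in types:
            cols[t] = per_block[per_block.block_type == t]["value_dps"].to_numpy()
        n = min(len(v) for v in cols.values())
        if n == 0:
            missing = [t for t, v in cols.items() if len(v) == 0]
            raise ValueError(f"no blocks of type(s) {missing} to match into triples")
        mat = pd.DataFrame({t: v[:n] for t, v in cols.items()})
        report["friedman"] = friedman_with_posthoc(mat)
    if "paired" in grouping:
        ta, tb = grouping["paired"]
        pa = responses[responses.block_type == ta].groupby("block_id")["value_dps"].mean()
        pb = responses[responses.block_type == tb].groupby("block_id")["value_dps"].mean()
        n = min(len(pa), len(pb))
        if len(pa) != len(pb):
            raise ValueError(
                f"unmatched pairs: {len(pa)} {ta} blocks vs {len(pb)} {tb} blocks"
            )
        report["paired"] = paired_signed_rank(pa.to_numpy()[:n], pb.to_numpy()[:n])
    if "unpaired" in grouping:
        ta, tb = grouping["unpaired"]
        report["unpaired"] = rank_sum(
            responses[responses.block_type == ta]["value_dps"],
            responses[responses.block_type == tb]["value_dps"],
        )
    if grouping.get("regression"):
        report["regression"] = base_velocity_regression(responses)
    return report
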