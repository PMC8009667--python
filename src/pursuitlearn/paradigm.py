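"""Trial, block, and session construction for pursuit direction-change adaptation.

The experimental unit is a *trial*: a moving target appears after 1 s of
fixation, moves in a *base* direction at 20 deg/s and, on learning trials, an
orthogonal 20 deg/s component in the *learned* direction is added 250 ms after
motion onset.  Motion ends 650 ms after onset and the target stays still for a
further 500 ms.  Trials are grouped into blocks of 100 whose composition
defines six paradigms (motor vs. fixation learning, washout, small-angle
mimicry, motion vs. end-point position, reward cueing, and a multi-direction
variant).

All angles are screen-centred degrees, counter-clockwise from rightward = 0.
Time is sampled at 1 ms with sample 0 at motion onset; the pre-motion fixation
second is carried as negative time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "TrialSpec",
    "BlockSpec",
    "SessionSpec",
    "TargetTrajectory",
    "Geometry",
    "make_trial",
    "target_kinematics",
    "build_block",
    "build_session",
    "LEARNING_BLOCK_TYPES",
    "FIXATION_STYLE_BLOCKS",
    "PARADIGM_BLOCKS",
]

EYE_MOVEMENT = "eye_movement"
FIXATION = "fixation"

#: block types whose 90 main trials are interleaved with 10 probe trials,
#: one probe at a random position inside every consecutive group of ten.
FIXATION_STYLE_BLOCKS = frozenset(
    {
        "fix_congruent",
        "fix_incongruent",
        "fix_only_right",
        "fix_only_left",
        "motion",
        "position",
        "congruent_rewarded",
        "incongruent_rewarded",
    }
)
#: all-eye-movement blocks that still use the 90/10 probe structure
PROBE_EM_BLOCKS = frozenset({"small_angle", "no_angle"})

LEARNING_BLOCK_TYPES = FIXATION_STYLE_BLOCKS | PROBE_EM_BLOCKS | {"motor"}

PARADIGM_BLOCKS = {
    1: ("motor", "fix_congruent", "fix_incongruent"),
    2: ("fix_only_right", "fix_only_left"),
    3: ("small_angle", "no_angle"),
    4: ("motion", "position"),
    5: ("congruent_rewarded", "incongruent_rewarded"),
    6: ("motor", "fix_congruent"),
}

STEP_RAMP_ECCENTRICITY_DEG = 4.0


@dataclass(frozen=True)
class Geometry:
    """Base/learned direction pair; the learned axis is orthogonal to the base."""

    base_deg: float = 270.0  # downward
    learned_deg: float = 0.0  # rightward

    def __post_init__(self) -> None:
        d = (self.learned_deg - self.base_deg) % 360.0
        if not (np.isclose(d, 90.0) or np.isclose(d, 270.0)):
            raise ValueError(
                f"learned direction {self.learned_deg} must be +/-90 deg from "
                f"base direction {self.base_deg}"
            )


def _unit(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([np.cos(a), np.sin(a)])


@dataclass(frozen=True)
class TrialSpec:
    """Fully resolved stimulus script of one trial."""

    trial_id: int
    kind: str
    block_type: str
    base_direction_deg: float
    learned_direction_deg: float
    base_speed_dps: float = 20.0
    learned_speed_dps: float = 0.0
    change_time_ms: int = 250
    motion_end_ms: int = 650
    post_motion_hold_ms: int = 500
    pre_motion_fixation_ms: int = 1000
    step_ramp: bool = False
    vanish_window_ms: Optional[tuple] = None
    rewarded: bool = True
    cue_color: str = "neutral"
    fixation_point_present: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (EYE_MOVEMENT, FIXATION):
            raise ValueError(f"unknown trial kind {self.kind!r}")
        d = (self.learned_direction_deg - self.base_direction_deg) % 360.0
        if not (np.isclose(d, 90.0) or np.isclose(d, 270.0)):
            raise ValueError("learned direction must be orthogonal to base")
        if not 0 < self.change_time_ms < self.motion_end_ms:
            raise ValueError("change_time_ms must lie inside the motion epoch")
        if self.kind == FIXATION and not self.fixation_point_present:
            raise ValueError("fixation trials must display the fixation point")
        if self.vanish_window_ms is not None:
            if tuple(self.vanish_window_ms) != (self.change_time_ms, self.motion_end_ms):
                raise ValueError(
                    "vanish window must span (change_time_ms, motion_end_ms)"
                )

    @property
    def has_direction_change(self) -> bool:
        return self.learned_speed_dps > 0

    @property
    def full_change(self) -> bool:
        """True for the instructive 20 deg/s orthogonal change (not the 0.5 mimic)."""
        return self.learned_speed_dps >= 19.99

    @property
    def duration_ms(self) -> int:
        return self.pre_motion_fixation_ms + self.motion_end_ms + self.post_motion_hold_ms

    def time_axis(self, dt_ms: int = 1) -> np.ndarray:
        return np.arange(-self.pre_motion_fixation_ms, self.motion_end_ms + self.post_motion_hold_ms + dt_ms, dt_ms)


@dataclass
class TargetTrajectory:
    """Per-sample nominal target state (position deg, velocity deg/s, visibility)."""

    t_ms: np.ndarray
    position_deg: np.ndarray  # (n, 2)
    velocity_dps: np.ndarray  # (n, 2)
    visible: np.ndarray  # (n,) bool


@dataclass
class BlockSpec:
    block_type: str
    trials: list
    base_direction_deg: float
    learned_direction_deg: float
    block_id: int = 0

    def __post_init__(self) -> None:
        if len(self.trials) != 100:
            raise ValueError("a block consists of exactly 100 trials")


@dataclass
class SessionSpec:
    paradigm_id: int
    blocks: list
    washout_policy: str = "precede"
    #: learning-block index -> corresponding washout-block index (into ``blocks``)
    washout_map: dict = field(default_factory=dict)
    #: paradigm 6 only: ordered (base, learned) pairs of the learning blocks
    direction_schedule: list = field(default_factory=list)

    def learning_blocks(self) -> list:
        return [b for b in self.blocks if b.block_type != "washout"]

    def corresponding_washout(self, block_index: int):
        """Washout block paired with the learning block at ``block_index``.

        Returns ``None`` for paradigm 2, where learning is assessed by the
        left-vs-right contrast and the baseline is the zero trace.
        """
        if self.paradigm_id == 2:
            return None
        return self.blocks[self.washout_map[block_index]]


def make_trial(
    kind: str,
    block_type: str,
    geometry: Geometry,
    rng=None,
    *,
    trial_id: int = 0,
    probe: bool = False,
    congruent: Optional[bool] = None,
) -> TrialSpec:
    """Resolve one trial of the given block type.

    ``probe`` marks the infrequent (10%) test trials of the 90/10 blocks.
    ``congruent`` selects the fixation-trial flavour inside reward blocks
    (45% congruent / 45% incongruent).
    """
    base = geometry.base_deg
    learned = geometry.learned_deg
    common = dict(
        trial_id=trial_id,
        kind=kind,
        block_type=block_type,
        base_direction_deg=base,
        learned_direction_deg=learned,
        fixation_point_present=kind == FIXATION,
    )

    if block_type == "motor":
        return TrialSpec(learned_speed_dps=20.0, **common)
    if block_type == "washout":
        return TrialSpec(learned_speed_dps=0.0, step_ramp=True, **common)
    if block_type in ("fix_congruent", "motion"):
        return TrialSpec(learned_speed_dps=20.0, **common)
    if block_type == "fix_incongruent":
        if kind == FIXATION:
            # the covert target runs the washout-style step ramp, no change
            return TrialSpec(learned_speed_dps=0.0, step_ramp=True, **common)
        return TrialSpec(learned_speed_dps=20.0, **common)
    if block_type in ("fix_only_right", "fix_only_left"):
        if kind == FIXATION:
            return TrialSpec(learned_speed_dps=20.0, **common)
        # probes never move in the learned direction (washout-style step ramp)
        return TrialSpec(learned_speed_dps=0.0, step_ramp=True, **common)
    if block_type == "small_angle":
        speed = 20.0 if probe else 0.5
        return TrialSpec(learned_speed_dps=speed, **common)
    if block_type == "no_angle":
        if probe:
            return TrialSpec(learned_speed_dps=20.0, **common)
        return TrialSpec(learned_speed_dps=0.0, step_ramp=True, **common)
    if block_type == "position":
        if kind == FIXATION:
            return TrialSpec(learned_speed_dps=20.0, vanish_window_ms=(250, 650), **common)
        return TrialSpec(learned_speed_dps=20.0, **common)
    if block_type in ("congruent_rewarded", "incongruent_rewarded"):
        if kind == EYE_MOVEMENT:
            # probes use the regular white target and are always rewarded
            return TrialSpec(learned_speed_dps=20.0, **common)
        if congruent is None:
            raise ValueError("reward-block fixation trials need congruent=True/False")
        rewarded = congruent == (block_type == "congruent_rewarded")
        cue = "reward_cue" if rewarded else "noreward_cue"
        if congruent:
            return TrialSpec(
                learned_speed_dps=20.0, rewarded=rewarded, cue_color=cue, **common
            )
        return TrialSpec(
            learned_speed_dps=0.0,
            step_ramp=True,
            rewarded=rewarded,
            cue_color=cue,
            **common,
        )
    raise ValueError(f"unknown block type {block_type!r}")


def target_kinematics(spec: TrialSpec, dt_ms: int = 1) -> TargetTrajectory:
    """Nominal target trajectory sampled every ``dt_ms``.

    Position is piecewise linear; velocity is its exact (right-continuous)
    derivative.  During a vanish window the target is flagged absent but its
    nominal trajectory continues; after motion end it is stationary.
    """
    for tm in (spec.change_time_ms, spec.motion_end_ms, spec.post_motion_hold_ms, spec.pre_motion_fixation_ms):
        if tm % dt_ms:
            raise ValueError("dt_ms must divide all trial timing fields")
    t = spec.time_axis(dt_ms).astype(float)
    n = t.size
    u = _unit(spec.base_direction_deg)
    w = _unit(spec.learned_direction_deg)

    start = -STEP_RAMP_ECCENTRICITY_DEG * u if spec.step_ramp else np.zeros(2)

    moving = (t >= 0) & (t < spec.motion_end_ms)
    base_t = np.clip(t, 0.0, spec.motion_end_ms) / 1000.0
    learned_t = np.clip(t - spec.change_time_ms, 0.0, spec.motion_end_ms - spec.change_time_ms) / 1000.0

    pos = start[None, :] * (t >= 0)[:, None]
    pos = pos + spec.base_speed_dps * base_t[:, None] * u[None, :]
    pos = pos + spec.learned_speed_dps * learned_t[:, None] * w[None, :]
    # before motion onset the moving target is not yet on screen; its nominal
    # position is held at the screen centre

    vel = np.zeros((n, 2))
    vel[moving] += spec.base_speed_dps * u
    changed = moving & (t >= spec.change_time_ms)
    vel[changed] += spec.learned_speed_dps * w

    visible = t >= 0
    if spec.vanish_window_ms is not None:
        v0, v1 = spec.vanish_window_ms
        visible = visible & ~((t > v0) & (t < v1))
    return TargetTrajectory(t_ms=t, position_deg=pos, velocity_dps=vel, visible=visible)


def _probe_positions(rng) -> np.ndarray:
    """One probe slot per consecutive decade, uniformly placed."""
    return np.array([10 * d + rng.integers(0, 10) for d in range(10)])


def build_block(
    block_type: str,
    geometry: Geometry,
    rng,
    *,
    block_id: int = 0,
) -> BlockSpec:
    """Build one 100-trial block with the composition of its type."""
    trials: list = []
    if block_type == "motor":
        trials = [
            make_trial(EYE_MOVEMENT, "motor", geometry, trial_id=i) for i in range(100)
        ]
    elif block_type == "washout":
        kinds = np.array([EYE_MOVEMENT] * 50 + [FIXATION] * 50)
        rng.shuffle(kinds)
        trials = [
            make_trial(str(k), "washout", geometry, trial_id=i)
            for i, k in enumerate(kinds)
        ]
    elif block_type in FIXATION_STYLE_BLOCKS or block_type in PROBE_EM_BLOCKS:
        probe_at = set(_probe_positions(rng).tolist())
        if block_type in ("congruent_rewarded", "incongruent_rewarded"):
            flavours = [True] * 45 + [False] * 45
            rng.shuffle(flavours)
            fl = iter(flavours)
            for i in range(100):
                if i in probe_at:
                    trials.append(
                        make_trial(EYE_MOVEMENT, block_type, geometry, trial_id=i, probe=True)
                    )
                else:
                    trials.append(
                        make_trial(
                            FIXATION, block_type, geometry, trial_id=i, congruent=next(fl)
                        )
                    )
        else:
            main_kind = EYE_MOVEMENT if block_type in PROBE_EM_BLOCKS else FIXATION
            for i in range(100):
                if i in probe_at:
                    trials.append(
                        make_trial(EYE_MOVEMENT, block_type, geometry, trial_id=i, probe=True)
                    )
                else:
                    trials.append(make_trial(main_kind, block_type, geometry, trial_id=i))
    else:
        raise ValueError(f"unknown block type {block_type!r}")
    return BlockSpec(
        block_type=block_type,
        trials=trials,
        base_direction_deg=geometry.base_deg,
        learned_direction_deg=geometry.learned_deg,
        block_id=block_id,
    )


DEFAULT_GEOMETRY = Geometry(base_deg=270.0, learned_deg=0.0)


def _interleave_with_washouts(types, geoms, rng, policy):
    """Return (block specs list, washout_map) for learning blocks with washouts."""
    blocks: list = []
    washout_map: dict = {}
    for btype, geom in zip(types, geoms):
        if policy == "precede":
            w = build_block("washout", geom, rng, block_id=len(blocks))
            blocks.append(w)
            lb = build_block(btype, geom, rng, block_id=len(blocks))
            blocks.append(lb)
            washout_map[lb.block_id] = w.block_id
        elif policy == "follow":
            lb = build_block(btype, geom, rng, block_id=len(blocks))
            blocks.append(lb)
            w = build_block("washout", geom, rng, block_id=len(blocks))
            blocks.append(w)
            washout_map[lb.block_id] = w.block_id
        else:
            raise ValueError(f"unknown washout policy {policy!r}")
    return blocks, washout_map


def _paradigm6_schedule(n_blocks: int, rng) -> list:
    """Pseudorandom (base, learned) pairs: every combination is selected once
    before any is selected again."""
    bases = [0.0, 90.0, 180.0, 270.0]
    combos = []
    for b in bases:
        combos.append((b, (b + 90.0) % 360.0))  # counter-clockwise
        combos.append((b, (b - 90.0) % 360.0))  # clockwise
    schedule = []
    while len(schedule) < n_blocks:
        order = rng.permutation(len(combos))
        schedule.extend(combos[i] for i in order)
    return schedule[:n_blocks]


def build_session(
    paradigm_id: int,
    n_blocks: int,
    rng,
    *,
    washout_policy: str = "precede",
    geometry: Geometry = DEFAULT_GEOMETRY,
) -> SessionSpec:
    """Build a session of ``n_blocks`` learning blocks for one paradigm.

    Learning blocks are interleaved with washout blocks (paradigm 2 excepted);
    ``n_blocks`` must divide evenly among the paradigm's learning-block types.
    """
    if paradigm_id not in PARADIGM_BLOCKS:
        raise ValueError(f"paradigm_id must be 1..6, got {paradigm_id}")
    types = PARADIGM_BLOCKS[paradigm_id]

    if paradigm_id == 2:
        if n_blocks % 2:
            raise ValueError("paradigm 2 needs an even number of blocks")
        base = geometry.base_deg
        blocks = []
        for i in range(n_blocks):
            learned = (base + 90.0) % 360.0 if i % 2 == 0 else (base - 90.0) % 360.0
            geom = Geometry(base_deg=base, learned_deg=learned)
            blocks.append(build_block(types[i % 2], geom, rng, block_id=i))
        return SessionSpec(paradigm_id=2, blocks=blocks, washout_policy="none")

    if paradigm_id == 6:
        schedule = _paradigm6_schedule(n_blocks, rng)
        type_seq = []
        for start in range(0, n_blocks, 8):
            chunk = min(8, n_blocks - start)
            t = np.array(["motor", "fix_congruent"] * 4)[:chunk]
            rng.shuffle(t)
            type_seq.extend(t.tolist())
        geoms = [Geometry(base_deg=b, learned_deg=l) for b, l in schedule]
        blocks, washout_map = _interleave_with_washouts(type_seq, geoms, rng, washout_policy)
        return SessionSpec(
            paradigm_id=6,
            blocks=blocks,
            washout_policy=washout_policy,
            washout_map=washout_map,
            direction_schedule=schedule,
        )

    k = len(types)
    if n_blocks % k:
        raise ValueError(f"paradigm {paradigm_id} needs a multiple of {k} blocks")
    type_seq = np.array(list(types) * (n_blocks // k))
    rng.shuffle(type_seq)
    geoms = [geometry] * n_blocks
    blocks, washout_map = _interleave_with_washouts(type_seq.tolist(), geoms, rng, washout_policy)
    return SessionSpec(
        paradigm_id=paradigm_id,
        blocks=blocks,
        washout_policy=washout_policy,
        washout_map=washout_map,
    )


# ---------------------------------------------------------------------------
# serialization


def session_to_json(session: SessionSpec, path=None) -> str:
    doc = {
        "paradigm_id": session.paradigm_id,
        "washout_policy": session.washout_policy,
        "washout_map": {str(k): v for k, v in session.washout_map.items()},
        "direction_schedule": [list(p) for p in session.direction_schedule],
        "blocks": [
            {
                "block_id": b.block_id,
                "block_type": b.block_type,
                "base_direction_deg": b.base_direction_deg,
                "learned_direction_deg": b.learned_direction_deg,
                "trials": [asdict(t) for t in b.trials],
            }
            for b in session.blocks
        ],
    }
    text = json.dumps(doc)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def session_from_json(source) -> SessionSpec:
    if isinstance(source, str) and source.lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    blocks = []
    for b in doc["blocks"]:
        trials = []
        for t in b["trials"]:
            if t["vanish_window_ms"] is not None:
                t = {**t, "vanish_window_ms": tuple(t["vanish_window_ms"])}
            trials.append(TrialSpec(**t))
        blocks.append(
            BlockSpec(
                block_type=b["block_type"],
                trials=trials,
                base_direction_deg=b["base_direction_deg"],
                learned_direction_deg=b["learned_direction_deg"],
                block_id=b["block_id"],
            )
        )
    return SessionSpec(
        paradigm_id=doc["paradigm_id"],
        blocks=blocks,
        washout_policy=doc["washout_policy"],
        washout_map={int(k): v for k, v in doc["washout_map"].items()},
        direction_schedule=[tuple(p) for p in doc["direction_schedule"]],
    )


def trajectory_to_frame(spec: TrialSpec, traj: TargetTrajectory):
    """Target trajectory as a tidy table (one row per sample)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "trial_id": spec.trial_id,
            "t_ms": traj.t_ms.astype(int),
            "target_x_deg": traj.position_deg[:, 0],
            "target_y_deg": traj.position_deg[:, 1],
            "target_visible": traj.visible,
        }
    )
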