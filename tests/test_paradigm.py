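"""Block/session composition and target-kinematics contracts."""

import numpy as np
import pytest

from pursuitlearn.paradigm import (
    EYE_MOVEMENT,
    FIXATION,
    Geometry,
    TrialSpec,
    build_block,
    build_session,
    make_trial,
    session_from_json,
    session_to_json,
    target_kinematics,
)


class TestTrialSpec:
    def test_learned_direction_must_be_orthogonal(self):
        with pytest.raises(ValueError):
            TrialSpec(
                trial_id=0,
                kind=EYE_MOVEMENT,
                block_type="motor",
                base_direction_deg=270.0,
                learned_direction_deg=45.0,
            )

    def test_fixation_requires_fixation_point(self):
        with pytest.raises(ValueError):
            TrialSpec(
                trial_id=0,
                kind=FIXATION,
                block_type="fix_congruent",
                base_direction_deg=270.0,
                learned_direction_deg=0.0,
                fixation_point_present=False,
            )

    def test_unknown_block_type_rejected(self, geometry):
        with pytest.raises(ValueError):
            make_trial(EYE_MOVEMENT, "mystery", geometry)


class TestMakeTrial:
    def test_motor_trial_has_full_change(self, geometry):
        t = make_trial(EYE_MOVEMENT, "motor", geometry)
        assert t.change_time_ms == 250
        assert t.learned_speed_dps == 20.0
        assert not t.step_ramp

    def test_incongruent_fixation_has_no_change(self, geometry):
        t = make_trial(FIXATION, "fix_incongruent", geometry)
        assert t.learned_speed_dps == 0.0
        assert not t.has_direction_change

    def test_position_block_fixation_vanishes_around_change(self, geometry):
        t = make_trial(FIXATION, "position", geometry)
        assert t.vanish_window_ms == (250, 650)

    def test_small_angle_main_vs_probe_speeds(self, geometry):
        main = make_trial(EYE_MOVEMENT, "small_angle", geometry)
        probe = make_trial(EYE_MOVEMENT, "small_angle", geometry, probe=True)
        assert main.learned_speed_dps == 0.5
        assert probe.learned_speed_dps == 20.0

    def test_reward_block_cue_and_flag_follow_block_rule(self, geometry):
        cong = make_trial(FIXATION, "congruent_rewarded", geometry, congruent=True)
        incong = make_trial(FIXATION, "congruent_rewarded", geometry, congruent=False)
        assert cong.rewarded and cong.cue_color == "reward_cue"
        assert not incong.rewarded and incong.cue_color == "noreward_cue"
        swapped = make_trial(FIXATION, "incongruent_rewarded", geometry, congruent=True)
        assert not swapped.rewarded and swapped.cue_color == "noreward_cue"


class TestBlockComposition:
    def test_motor_block_all_change_trials(self, geometry, rng):
        b = build_block("motor", geometry, rng)
        assert len(b.trials) == 100
        assert sum(t.kind == EYE_MOVEMENT for t in b.trials) == 100
        assert sum(t.has_direction_change for t in b.trials) == 100

    def test_washout_block_50_50_no_change(self, geometry, rng):
        b = build_block("washout", geometry, rng)
        assert sum(t.kind == EYE_MOVEMENT for t in b.trials) == 50
        assert sum(t.kind == FIXATION for t in b.trials) == 50
        assert sum(t.has_direction_change for t in b.trials) == 0
        assert all(t.step_ramp for t in b.trials)

    @pytest.mark.parametrize(
        "btype", ["fix_congruent", "fix_incongruent", "motion", "position"]
    )
    def test_fixation_block_90_10_one_probe_per_decade(self, btype, geometry, rng):
        b = build_block(btype, geometry, rng)
        em = [i for i, t in enumerate(b.trials) if t.kind == EYE_MOVEMENT]
        assert len(em) == 10
        assert sorted(i // 10 for i in em) == list(range(10))

    def test_reward_block_45_45_10(self, geometry, rng):
        b = build_block("congruent_rewarded", geometry, rng)
        fix = [t for t in b.trials if t.kind == FIXATION]
        em = [t for t in b.trials if t.kind == EYE_MOVEMENT]
        assert len(em) == 10
        assert sum(t.has_direction_change for t in fix) == 45
        assert sum(not t.has_direction_change for t in fix) == 45
        assert sum(t.rewarded for t in fix) == 45

    def test_fix_only_probes_never_move_in_learned_direction(self, geometry, rng):
        b = build_block("fix_only_right", Geometry(270.0, 0.0), rng)
        probes = [t for t in b.trials if t.kind == EYE_MOVEMENT]
        assert all(t.learned_speed_dps == 0.0 and t.step_ramp for t in probes)
        fix = [t for t in b.trials if t.kind == FIXATION]
        assert all(t.learned_speed_dps == 20.0 for t in fix)


class TestSessions:
    def test_paradigm1_counts_and_washout_pairing(self, rng):
        s = build_session(1, 9, rng)
        types = [b.block_type for b in s.learning_blocks()]
        assert sorted(types).count("motor") == 3
        assert types.count("fix_congruent") == 3
        assert types.count("fix_incongruent") == 3
        # every learning block maps to a washout block adjacent to it
        for bi, wi in s.washout_map.items():
            assert s.blocks[wi].block_type == "washout"
            assert abs(bi - wi) == 1

    def test_paradigm2_alternates_opposite_learned_directions(self, rng):
        s = build_session(2, 6, rng)
        assert all(b.block_type != "washout" for b in s.blocks)
        dirs = [b.learned_direction_deg for b in s.blocks]
        for a, b in zip(dirs, dirs[1:]):
            assert (a - b) % 360 == 180
        assert s.corresponding_washout(0) is None

    def test_paradigm6_balanced_before_repeat(self, rng):
        s = build_session(6, 16, rng)
        sched = s.direction_schedule
        assert len(sched) == 16
        # exhaustive check: each consecutive batch of 8 covers all combinations
        for start in range(0, 16, 8):
            batch = set(sched[start : start + 8])
            assert len(batch) == 8
        for base, learned in sched:
            assert (learned - base) % 360 in (90, 270)

    def test_same_seed_reproduces_session(self):
        a = build_session(1, 3, np.random.default_rng(7))
        b = build_session(1, 3, np.random.default_rng(7))
        assert session_to_json(a) == session_to_json(b)

    def test_different_seeds_same_composition(self):
        a = build_session(1, 3, np.random.default_rng(0))
        b = build_session(1, 3, np.random.default_rng(99))
        for sess in (a, b):
            for blk in sess.blocks:
                assert len(blk.trials) == 100
        ca = sorted(b_.block_type for b_ in a.blocks)
        cb = sorted(b_.block_type for b_ in b.blocks)
        assert ca == cb

    def test_invalid_paradigm_rejected(self, rng):
        with pytest.raises(ValueError):
            build_session(7, 3, rng)

    def test_json_roundtrip(self, rng):
        s = build_session(4, 2, rng)
        text = session_to_json(s)
        s2 = session_from_json(text)
        assert session_to_json(s2) == text


class TestTargetKinematics:
    def test_step_ramp_crosses_start_at_200ms(self, geometry):
        spec = make_trial(EYE_MOVEMENT, "washout", geometry)
        traj = target_kinematics(spec)
        i = np.searchsorted(traj.t_ms, 200)
        assert np.allclose(traj.position_deg[i], [0.0, 0.0], atol=1e-9)

    def test_speed_after_change_is_vector_sum(self, geometry):
        spec = make_trial(EYE_MOVEMENT, "motor", geometry)
        traj = target_kinematics(spec)
        i = np.searchsorted(traj.t_ms, 400)
        speed = np.linalg.norm(traj.velocity_dps[i])
        assert np.isclose(speed, 20.0 * np.sqrt(2.0))

    def test_small_angle_learned_component(self, geometry):
        spec = make_trial(EYE_MOVEMENT, "small_angle", geometry)
        traj = target_kinematics(spec)
        i = np.searchsorted(traj.t_ms, 400)
        assert np.isclose(traj.velocity_dps[i] @ np.array([1.0, 0.0]), 0.5)

    def test_vanish_window_flags_absent_but_trajectory_continues(self, geometry):
        spec = make_trial(FIXATION, "position", geometry)
        traj = target_kinematics(spec)
        mid = np.searchsorted(traj.t_ms, 400)
        assert not traj.visible[mid]
        assert np.linalg.norm(traj.velocity_dps[mid]) > 0

    @pytest.mark.parametrize("btype,kind", [("motor", EYE_MOVEMENT), ("washout", EYE_MOVEMENT), ("small_angle", EYE_MOVEMENT), ("position", FIXATION)])
    def test_integrated_velocity_reproduces_position(self, btype, kind, geometry):
        spec = make_trial(kind, btype, geometry)
        traj = target_kinematics(spec)
        m = traj.t_ms >= 0
        pos0 = traj.position_deg[m][0]
        # trapezoidal quadrature of the velocity trace
        integ = pos0 + np.vstack(
            [np.concatenate([[0.0], np.cumsum((traj.velocity_dps[m][1:] + traj.velocity_dps[m][:-1]) / 2, axis=0)[:, c] * 1e-3]) for c in range(2)]
        ).T
        err = np.abs(integ - traj.position_deg[m]).max()
        # within one sample of motion at each segment boundary
        assert err <= 20.0 * np.sqrt(2) * 1e-3 + 1e-9

    def test_stationary_after_motion_end(self, geometry):
        spec = make_trial(EYE_MOVEMENT, "motor", geometry)
        traj = target_kinematics(spec)
        after = traj.t_ms >= spec.motion_end_ms
        assert np.all(traj.velocity_dps[after] == 0)
        assert np.allclose(traj.position_deg[after], traj.position_deg[after][0])
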