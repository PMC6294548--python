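"""Closed-loop engine: calibration, gating, feedback, staircase, sessions."""

import numpy as np
import pandas as pd
import pytest

from meploop.engine import (CalibrationError, SessionConfig, StaircaseState,
                            calibrate_participant, decide_feedback,
                            estimate_rmt, measure_recruitment_curve,
                            records_to_frame, run_block, run_gate,
                            run_training_day, sample_fixation, sham_schedule,
                            update_staircase)
from meploop.participant import Participant, ParticipantParams, make_cohort


@pytest.fixture
def config():
    return SessionConfig()


class TestConfig:
    @pytest.mark.parametrize("kw", [
        {"sham_rate": 0.0},
        {"fixation_range_s": (9.0, 5.0)},
        {"staircase_thresholds": (0.9, 0.7)},
        {"condition": "LEFT"},
        {"trace_mode": "binary"},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SessionConfig(**kw)


class TestRMT:
    def test_noiseless_threshold_found_at_defined_crossing(
            self, noiseless_participant):
        """Without noise the 5-of-10 rule fires deterministically at the
        first grid intensity whose MEP mean reaches 50 uV."""
        p = noiseless_participant.params
        rmt = estimate_rmt(noiseless_participant,
                           intensity_grid=np.arange(30.0, 60.0))
        # the true threshold is at p.rmt by construction of slope_k
        assert abs(rmt - p.rmt) <= 1.0

    def test_unreachable_criterion_signals_failure(self, participant):
        with pytest.raises(CalibrationError):
            estimate_rmt(participant, intensity_grid=np.arange(1.0, 5.0))

    def test_stochastic_rmt_centred_on_median_crossing(self):
        """Monte-Carlo calibrations put the median RMT within one grid step
        of the intensity where P(MEP >= 50 uV) = 0.5."""
        rmts = []
        for s in range(40):
            part = Participant(ParticipantParams(seed=600 + s))
            rmts.append(estimate_rmt(part))
        assert abs(np.median(rmts) - 43.0) <= 1.0


class TestRecruitment:
    def test_noiseless_fit_recovers_plateau_and_half_max(
            self, noiseless_participant):
        cal = measure_recruitment_curve(noiseless_participant, rmt=43.0)
        p = noiseless_participant.params
        assert len(cal.recruitment) == 10
        assert cal.mep_max == pytest.approx(p.mep_max, rel=0.02)
        assert cal.test_intensity == pytest.approx(p.i50, abs=0.3)

    def test_chosen_intensity_averages_130_percent_rmt(self):
        """Across a default cohort the half-max test intensity sits at
        about 130 % RMT."""
        ratios = []
        for part in make_cohort(10, 77):
            cal = calibrate_participant(part)
            ratios.append(cal.test_intensity / cal.rmt)
        assert np.mean(ratios) == pytest.approx(1.30, abs=0.03)


class TestGate:
    def test_quiet_channels_pass_exactly_at_sustain(self, config):
        x = np.full((4, 4000), 4.0)
        ev = run_gate(x, config)
        assert ev.passed and ev.pass_time_s == pytest.approx(0.5)

    def test_one_loud_channel_blocks_forever(self, config):
        x = np.full((4, 4000), 4.0)
        x[2] = 7.5
        ev = run_gate(x, config)
        assert not ev.passed and ev.pass_sample is None

    def test_sustain_counted_from_quiet_onset(self, config):
        x = np.full((4, 6000), 4.0)
        x[1, :2000] = 20.0  # loud for the first second
        ev = run_gate(x, config)
        assert ev.passed
        # rms must first decay below threshold, then hold 500 ms
        assert ev.pass_time_s >= 1.0 + 0.5

    def test_stream_ending_early_is_incomplete(self, config):
        ev = run_gate(np.full((4, 100), 4.0), config)
        assert not ev.passed


class TestFixation:
    def test_support_and_mean(self, config, rng):
        draws = np.array([sample_fixation(config, rng) for _ in range(20_000)])
        assert draws.min() >= 5.5 and draws.max() <= 8.5
        assert draws.mean() == pytest.approx(7.0, abs=0.05)

    def test_degenerate_range(self, rng):
        cfg = SessionConfig(fixation_range_s=(6.0, 6.0))
        assert sample_fixation(cfg, rng) == 6.0


class TestFeedback:
    @pytest.mark.parametrize("mep,crit,cond,expected", [
        (1.2, 1.0, "UP", True),
        (1.2, 1.0, "DOWN", False),
        (0.8, 1.0, "UP", False),
        (0.8, 1.0, "DOWN", True),
        (1.0, 1.0, "UP", False),    # exact tie is never rewarded
        (1.0, 1.0, "DOWN", False),
    ])
    def test_reward_rule(self, mep, crit, cond, expected):
        assert decide_feedback(mep, crit, cond) is expected

    def test_positive_amplitudes_required(self):
        with pytest.raises(ValueError):
            decide_feedback(-1.0, 1.0, "UP")


class TestStaircase:
    @pytest.mark.parametrize("success,cond,factor", [
        (22 / 30, "UP", 1.10),
        (28 / 30, "UP", 1.20),
        (0.60, "UP", 1.00),
        (22 / 30, "DOWN", 0.90),
        (28 / 30, "DOWN", 0.80),
    ])
    def test_step_rules(self, success, cond, factor):
        st = update_staircase(StaircaseState(criterion_mv=1.0), success, cond)
        assert st.criterion_mv == pytest.approx(factor)

    def test_audit_trail_identity(self):
        """Criterion after k blocks equals baseline x product of factors."""
        st = StaircaseState(criterion_mv=1.7)
        for s in (0.8, 0.95, 0.5, 0.73):
            st = update_staircase(st, s, "UP")
        assert st.criterion_mv == pytest.approx(1.7 * np.prod(st.step_factors))
        assert len(st.block_success_history) == 4


class TestSham:
    def test_thirty_trials_give_twenty_rewards(self):
        seq = sham_schedule(30)
        assert seq.sum() == 20

    def test_pattern_is_fixed_and_cyclic(self):
        np.testing.assert_array_equal(sham_schedule(9),
                                      [1, 1, 0, 1, 1, 0, 1, 1, 0])
        np.testing.assert_array_equal(sham_schedule(30), sham_schedule(30))

    def test_rewards_independent_of_amplitudes(self, rng):
        """Across many simulated blocks the sham sequence is uncorrelated
        with the MEP amplitudes."""
        seq = sham_schedule(30).astype(float)
        cors = []
        for _ in range(300):
            amps = rng.lognormal(0.0, 0.25, size=30)
            cors.append(np.corrcoef(seq, amps)[0, 1])
        assert abs(np.mean(cors)) < 0.02


def _lite_cfg(**kw):
    return SessionConfig(trace_mode="lite", tense_prob=0.0, **kw)


class TestBlocksAndSessions:
    def test_training_day_arithmetic(self, participant):
        cal = calibrate_participant(participant)
        rows = run_training_day(participant, _lite_cfg(), cal, day=1,
                                rng=participant.rng)
        df = pd.DataFrame(rows)
        counts = df["trial_type"].value_counts()
        assert counts["baseline_rest"] == 20
        assert counts["feedback"] == 120
        assert counts["post_rest"] == 48

    def test_control_rewards_follow_sham_schedule(self):
        part = Participant(ParticipantParams(seed=21))
        cal = calibrate_participant(part)
        cfg = _lite_cfg(group="control")
        rows = run_training_day(part, cfg, cal, day=1, rng=part.rng)
        fb = pd.DataFrame(rows).query("trial_type == 'feedback'")
        for _, block in fb.groupby("block"):
            np.testing.assert_array_equal(
                block["rewarded"].to_numpy(dtype=bool), sham_schedule(30))

    def test_gate_postcondition_holds_in_trace_log(self):
        """Every logged feedback trial's pre-pulse rms is below the gate
        threshold in all four muscles."""
        part = Participant(ParticipantParams(seed=31))
        cal = calibrate_participant(part)
        cfg = SessionConfig(trace_mode="trace")
        stair = StaircaseState(criterion_mv=cal.baseline_mean)
        recs, _ = run_block(part, cfg, cal, "feedback", part.rng, stair=stair)
        df = pd.DataFrame(recs)
        cols = [f"bg_rms_ch{i}_uv" for i in range(4)]
        assert (df[cols] < cfg.gate_threshold_uv).all().all()

    def test_session_bit_reproducible_under_seed(self):
        from meploop import study
        runs = []
        for _ in range(2):
            part = Participant(ParticipantParams(seed=55))
            trials, _, _ = study.simulate_participant(
                part, days=("UP",), trace_mode="lite", tense_prob=0.0)
            runs.append(trials)
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_opposite_hemisphere_block_layout(self):
        part = Participant(ParticipantParams(seed=61))
        cal = calibrate_participant(part)
        part.state = part.state.__class__(skill_up=1.0, strategy="UP")
        stair = StaircaseState(criterion_mv=cal.baseline_mean)
        recs, _ = run_block(part, _lite_cfg(), cal, "opposite_hemisphere",
                            part.rng, condition="UP", stair=stair)
        df = pd.DataFrame(recs)
        assert len(df) == 40
        assert (df["hemisphere"] == "trained").sum() == 20
        assert df.loc[df.hemisphere == "opposite", "rewarded"].isna().all()
        assert df.loc[df.hemisphere == "trained", "rewarded"].notna().all()

    def test_opposite_hemisphere_effect_is_coupled_but_smaller(self):
        """The untrained hemisphere shows a fraction `coupling` of the
        trained modulation."""
        amps_t, amps_o = [], []
        for s in range(6):
            part = Participant(ParticipantParams(seed=70 + s))
            cal = calibrate_participant(part)
            part.state = part.state.__class__(skill_up=1.0, strategy="UP")
            stair = StaircaseState(criterion_mv=cal.baseline_mean)
            recs, _ = run_block(part, _lite_cfg(), cal, "opposite_hemisphere",
                                part.rng, condition="UP", stair=stair)
            df = pd.DataFrame(recs)
            amps_t.append(df.loc[df.hemisphere == "trained", "mep_mv"].mean()
                          / cal.baseline_mean)
            amps_o.append(df.loc[df.hemisphere == "opposite", "mep_mv"].mean()
                          / cal.baseline_mean)
        assert np.mean(amps_t) > np.mean(amps_o) > 1.0

    def test_feedback_free_block_suppresses_reward(self):
        part = Participant(ParticipantParams(seed=81))
        cal = calibrate_participant(part)
        recs, _ = run_block(part, _lite_cfg(), cal, "feedback_free",
                            part.rng, condition="UP")
        df = pd.DataFrame(recs)
        assert len(df) == 20
        assert df["rewarded"].isna().all()

    def test_retention_block_after_skill_decay(self):
        part = Participant(ParticipantParams(seed=91, retention_frac=0.5))
        part.state = part.state.__class__(skill_up=1.0, skill_down=1.0)
        part.apply_retention()
        assert part.state.skill_up == pytest.approx(0.5)
        cal = calibrate_participant(part)
        stair = StaircaseState(criterion_mv=cal.baseline_mean)
        recs, _ = run_block(part, _lite_cfg(), cal, "retention", part.rng,
                            condition="UP", stair=stair)
        assert len(recs) == 20

    def test_records_to_frame_splits_artifacts(self):
        part = Participant(ParticipantParams(seed=95))
        cal = calibrate_participant(part)
        cfg = SessionConfig(trace_mode="trace")
        recs, _ = run_block(part, cfg, cal, "post_rest", part.rng,
                            n_trials=3)
        df, arts = records_to_frame(recs, subject=0, group="experimental")
        assert len(df) == len(arts) == 3
        assert "_trace" not in df.columns
        assert arts[0]["trace"].shape[0] == 4


class TestLearningDynamics:
    def test_veridical_feedback_raises_up_block_means(self):
        """With veridical feedback, later UP training blocks have larger
        mean MEPs than the first block (operant learning trend)."""
        from meploop import study
        firsts, lasts = [], []
        for s in range(5):
            part = Participant(ParticipantParams(seed=400 + s))
            trials, _, _ = study.simulate_participant(
                part, days=("UP", "UP"), trace_mode="lite")
            fb = trials[trials.trial_type == "feedback"]
            firsts.append(fb[(fb.day == 1) & (fb.block == 1)].mep_mv.mean())
            lasts.append(fb[(fb.day == 2) & (fb.block == 4)].mep_mv.mean())
        assert np.mean(lasts) > 1.2 * np.mean(firsts)

    def test_sham_feedback_leaves_no_trend(self):
        from meploop import study
        trials, _ = study.simulate_cohort(6, group="control", master_seed=17,
                                          days=("UP", "DOWN"),
                                          trace_mode="lite")
        fb = trials[trials.trial_type == "feedback"]
        up = fb[fb.condition == "UP"]["mep_mv"]
        dn = fb[fb.condition == "DOWN"]["mep_mv"]
        # identical in law: means agree within a few percent
        assert up.mean() == pytest.approx(dn.mean(), rel=0.1)
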