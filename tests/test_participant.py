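"""Generative participant model: recruitment, learning, EMG, EEG, paired pulse."""

import numpy as np
import pytest
from scipy import stats

from meploop.bands import BAND_NAMES
from meploop.participant import (LatentState, Participant, ParticipantParams,
                                 PPProtocol, ProtocolError,
                                 calibrate_asymptotes, conditioned_mep,
                                 expected_excitability,
                                 generate_background_emg, generate_mep,
                                 make_cohort, mep_mean, step_excitability)


class TestParams:
    def test_derived_defaults(self):
        p = ParticipantParams(seed=0)
        assert p.i50 == pytest.approx(1.3 * p.rmt)
        assert 0 < p.down_asymptote < 1 < p.up_asymptote

    @pytest.mark.parametrize("kw", [
        {"mep_max": -1.0},
        {"up_asymptote": 0.9, "down_asymptote": 0.5},
        {"retention_frac": 1.5},
        {"coupling": -0.1},
        {"band_d": (1.0, 2.0)},
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            ParticipantParams(seed=0, **kw)

    def test_asymptote_calibration_hits_latent_gain(self):
        """The calibrated asymptote realises the latent trained %-change of
        the MEP mean exactly at the half-max test intensity."""
        p = ParticipantParams(seed=0, mep_noise_cv=0.0, exc_jitter_sd=0.0)
        base = mep_mean(LatentState(), p.i50, p)
        up = mep_mean(LatentState(excitability=p.up_asymptote), p.i50, p)
        dn = mep_mean(LatentState(excitability=p.down_asymptote), p.i50, p)
        assert 100 * (up / base - 1) == pytest.approx(p.latent_up_pct, abs=1e-6)
        assert 100 * (1 - dn / base) == pytest.approx(p.latent_down_pct, abs=1e-6)

    def test_custom_asymptote_targets(self):
        up, dn = calibrate_asymptotes(0.336, 55.9, up_pct=50.0, down_pct=20.0)
        assert up > 1 > dn > 0


class TestLatentState:
    def test_rest_pins_expected_excitability_at_one(self):
        p = ParticipantParams(seed=0)
        s = LatentState(skill_up=0.8, skill_down=0.6, strategy="REST")
        assert expected_excitability(s, p) == 1.0

    def test_full_skill_reaches_asymptote(self):
        p = ParticipantParams(seed=0)
        s = LatentState(skill_up=1.0, strategy="UP")
        assert expected_excitability(s, p) == pytest.approx(p.up_asymptote)
        s = LatentState(skill_down=1.0, strategy="DOWN")
        assert expected_excitability(s, p) == pytest.approx(p.down_asymptote)

    def test_sham_rewards_teach_nothing(self, rng):
        """120 rewarded but non-veridical (control group) trials leave the
        skill exactly where it started."""
        p = ParticipantParams(seed=0)
        s = LatentState(strategy="UP")
        for _ in range(120):
            s = step_excitability(s, p, rewarded=True, veridical=False, rng=rng)
        assert s.skill_up == 0.0

    def test_veridical_rewards_accumulate_and_cap(self, rng):
        p = ParticipantParams(seed=0, learn_rate=0.02)
        s = LatentState(strategy="UP")
        for _ in range(10):
            s = step_excitability(s, p, rewarded=True, veridical=True, rng=rng)
        assert s.skill_up == pytest.approx(0.2)
        for _ in range(100):
            s = step_excitability(s, p, rewarded=True, veridical=True, rng=rng)
        assert s.skill_up == 1.0

    def test_invalid_strategy_rejected(self):
        with pytest.raises(ValueError):
            LatentState(strategy="SIDEWAYS")


class TestMEPGeneration:
    def test_sigmoid_midpoint_and_plateau(self):
        p = ParticipantParams(seed=0, mep_noise_cv=0.0)
        rest = LatentState()
        rng = np.random.default_rng(0)
        assert generate_mep(rest, p.i50, p, rng) == pytest.approx(p.mep_max / 2)
        assert generate_mep(rest, 10 * p.i50, p, rng) == pytest.approx(
            p.mep_max, rel=1e-6)

    def test_noise_cv_recovered_by_monte_carlo(self, rng):
        """Sample CV of 10^4 draws at a fixed input matches mep_noise_cv."""
        p = ParticipantParams(seed=0, mep_noise_cv=0.25)
        amps = np.array([generate_mep(LatentState(), p.i50, p, rng)
                         for _ in range(10_000)])
        assert amps.std() / amps.mean() == pytest.approx(0.25, abs=0.02)
        assert amps.mean() == pytest.approx(p.mep_max / 2, rel=0.02)

    def test_expected_amplitude_increases_with_excitability(self):
        p = ParticipantParams(seed=0)
        means = [mep_mean(LatentState(excitability=e), p.i50, p)
                 for e in (0.9, 1.0, 1.1, 1.2)]
        assert np.all(np.diff(means) > 0)

    def test_negative_intensity_rejected(self, rng):
        p = ParticipantParams(seed=0)
        with pytest.raises(ValueError):
            generate_mep(LatentState(), -1.0, p, rng)


class TestBackgroundEMG:
    def test_sampling_arithmetic(self, rng):
        p = ParticipantParams(seed=0)
        x = generate_background_emg(p, 100.0, rng)
        assert x.shape == (4, 200)

    def test_relaxed_rms_stays_near_rest_level(self, rng):
        """100 ms windows of relaxed EMG stay within [2, 6] uV almost
        always when the rest level is 4 uV."""
        p = ParticipantParams(seed=0)
        x = generate_background_emg(p, 5000.0, rng)
        win = x[:, : 200 * (x.shape[1] // 200)].reshape(4, -1, 200)
        rms = np.sqrt((win ** 2).mean(axis=-1))
        frac = np.mean((rms > 2.0) & (rms < 6.0))
        assert frac >= 0.95

    def test_tense_episode_breaks_the_gate_threshold(self, rng):
        p = ParticipantParams(seed=0)
        x = generate_background_emg(p, 500.0, rng, tense=True, tense_channels=(2,))
        win = x[2].reshape(-1, 200)
        assert np.sqrt((win ** 2).mean(axis=-1)).max() > 7.0

    def test_minimum_duration_enforced(self, rng):
        with pytest.raises(ValueError):
            generate_background_emg(ParticipantParams(seed=0), 0.0, rng)


class TestEEGGeneration:
    def test_epoch_shape_and_determinism(self):
        a = Participant(ParticipantParams(seed=11)).eeg_epoch(n_channels=2)
        b = Participant(ParticipantParams(seed=11)).eeg_epoch(n_channels=2)
        assert a.shape == (2, 1500)
        np.testing.assert_array_equal(a, b)

    def test_single_oscillator_puts_spectral_peak_in_its_band(self):
        """With only the 10 Hz alpha oscillator active over a weak floor,
        the Welch spectrum peaks inside 8-10 Hz."""
        from meploop import eeg
        amps = (0.0, 0.0, 30.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        freqs_cfg = (2.5, 6.0, 10.0, 12.0, 17.5, 26.0, 40.0, 65.0)
        part = Participant(ParticipantParams(
            seed=3, osc_amps=amps, osc_freqs=freqs_cfg, bg_amp=0.5,
            band_d=(0.0,) * 8))
        x = part.eeg_epoch()
        f, psd = eeg.welch_spectrum(x[0])
        peak = f[(f >= 1) & (f <= 100)][np.argmax(psd[(f >= 1) & (f <= 100)])]
        assert 8 <= peak <= 10

    def test_null_band_effects_make_states_exchangeable(self):
        """A null generator (no mean shift, no between-subject spread, no
        trial coupling): UP and DOWN band powers are indistinguishable."""
        from meploop import study
        part = Participant(ParticipantParams(seed=5, band_d=(0.0,) * 8,
                                             band_tau=0.0,
                                             band_link_scale=0.0))
        feats = study.subject_feature_table(part, n_per_state=60)
        ps = [stats.mannwhitneyu(
            feats.loc[feats.condition == "UP", b],
            feats.loc[feats.condition == "DOWN", b]).pvalue
            for b in BAND_NAMES]
        # at alpha=1% across 8 bands, a true null rarely rejects even once
        assert min(ps) > 0.01 / 8

    def test_hotspot_effect_larger_than_opposite_channel(self):
        """Non-hotspot channels carry attenuated state effects."""
        from meploop import study
        import pandas as pd
        diffs_hot, diffs_opp = [], []
        for s in range(6):
            part = Participant(ParticipantParams(seed=40 + s))
            sides = np.concatenate([np.ones(60), -np.ones(60)])
            eps = part.eeg_epochs(sides, n_channels=2, hotspot_index=0)
            f = study._batch_feature_frame(eps, sides,
                                           electrodes=("hotspot", "opposite"))
            g = f.groupby("condition").mean(numeric_only=True)
            d = g.loc["UP"] - g.loc["DOWN"]
            diffs_hot.append(abs(d["theta"]))
            diffs_opp.append(abs(d["theta_opposite"]))
        assert np.mean(diffs_hot) > np.mean(diffs_opp)


class TestConditionedMEP:
    def _protocols(self, p):
        ts = p.i50
        return {
            "SICI": PPProtocol.make("SICI", p.sici_cs_ref, ts),
            "LICI": PPProtocol.make("LICI", p.lici_cs_ref, ts),
            "LCD": PPProtocol.make("LCD", p.lici_cs_ref, ts),
        }

    def test_sici_ratio_at_reference_cs_is_half(self, rng):
        p = ParticipantParams(seed=0, mep_noise_cv=0.0)
        pr = self._protocols(p)["SICI"]
        sp = mep_mean(LatentState(), p.i50, p)
        assert conditioned_mep(LatentState(), pr, p, rng) / sp == pytest.approx(0.5)

    def test_lcd_is_silent_at_rest_and_gains_in_trained_up(self, rng):
        p = ParticipantParams(seed=0, mep_noise_cv=0.0)
        pr = self._protocols(p)["LCD"]
        sp = mep_mean(LatentState(), p.i50, p)
        assert conditioned_mep(LatentState(), pr, p, rng) / sp == pytest.approx(1.0)
        up = LatentState(skill_up=1.0, strategy="UP", excitability=1.0)
        sp_up = mep_mean(up, p.i50, p)
        ratio = conditioned_mep(up, pr, p, rng) / sp_up
        assert 100 * ratio == pytest.approx(150.9)

    def test_protocol_isi_pairing_enforced(self):
        with pytest.raises(ProtocolError):
            PPProtocol("SICI", 70.0, 56.0, isi_ms=100.0)
        with pytest.raises(ProtocolError):
            PPProtocol("LICI", 90.0, 56.0, isi_ms=100.0)  # sub-threshold CS
        with pytest.raises(ProtocolError):
            PPProtocol.make("TRIPLE", 70.0, 56.0)


class TestCohort:
    def test_same_master_seed_reproduces_cohort(self):
        a = make_cohort(4, 99)
        b = make_cohort(4, 99)
        for x, y in zip(a, b):
            assert x.params == y.params
            np.testing.assert_array_equal(x.band_shift, y.band_shift)

    def test_participants_are_distinct(self):
        cohort = make_cohort(5, 1)
        seeds = {p.params.seed for p in cohort}
        assert len(seeds) == 5
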