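import copy

import numpy as np
import pytest

from eegarousal import ConfigError, make_stage_script, synthesize_recording
from eegarousal.questionnaires import score_cohort
from eegarousal.stats import mann_whitney
from eegarousal.synth import (
    DEFAULT_CHANNELS,
    DEFAULT_EFFECTS,
    MINIMAL_CHANNELS,
    CohortConfig,
    generate_cohort,
)
from eegarousal.vigilance import spectral_features

ESS_COLS = [f"ess_{i:02d}" for i in range(1, 9)]


class TestStageScripts:
    @pytest.mark.parametrize("seed", range(8))
    def test_stable_high_never_declines_below_seven(self, seed):
        script = make_stage_script("stable_high", seed=seed)
        assert script.true_score >= 7
        assert set(script.stages) <= {"0", "A1", "A2", "A3"}

    def test_forced_early_sleep_onset_scores_one(self):
        script = make_stage_script("declining", seed=0, c_onset_s=200)
        assert script.stages[200] == "C"
        assert script.true_score == 1

    def test_same_seed_same_script(self):
        a = make_stage_script("declining", seed=11)
        b = make_stage_script("declining", seed=11)
        assert a.stages == b.stages

    def test_custom_profile_passthrough(self):
        stages = ["A1"] * 100
        assert make_stage_script("custom", stages=stages, seed=0).stages == stages

    def test_unknown_profile_rejected(self):
        with pytest.raises(ConfigError):
            make_stage_script("cosmic", seed=0)

    def test_minimum_duration_enforced(self):
        with pytest.raises(ConfigError):
            make_stage_script("stable_high", duration_s=30, seed=0)


class TestRecordingSynthesis:
    def test_channel_layout(self):
        script = make_stage_script("custom", stages=["A1"] * 60, seed=0)
        rec = synthesize_recording(script, seed=0)
        assert len(rec.channel_labels) == len(DEFAULT_CHANNELS) + 4
        assert rec.horizontal_eog() is not None

    def test_missing_roi_rejected(self):
        script = make_stage_script("custom", stages=["A1"] * 60, seed=0)
        with pytest.raises(ConfigError):
            synthesize_recording(script, channels=("F3", "Fz", "F4"), seed=0)

    def test_same_seed_same_signal(self):
        script = make_stage_script("custom", stages=["A1"] * 60, seed=0)
        a = synthesize_recording(script, seed=4, channels=MINIMAL_CHANNELS)
        b = synthesize_recording(script, seed=4, channels=MINIMAL_CHANNELS)
        assert np.array_equal(a.data, b.data)

    def test_noise_free_desynchronized_stage_has_low_relative_alpha(self):
        script = make_stage_script("custom", stages=["0"] * 60, seed=0)
        rec = synthesize_recording(script, seed=0, channels=MINIMAL_CHANNELS,
                                   noise_uv=0.0)
        labels = list(MINIMAL_CHANNELS)
        sps = int(rec.sfreq)
        for sec in range(0, 60, 7):
            seg = rec.data[: len(labels), sec * sps : (sec + 1) * sps]
            f = spectral_features(seg, rec.sfreq, labels)
            assert f.relative_alpha < 0.40


class TestEndToEndCalibration:
    def test_score_recovery_contract(self, roundtrip_results):
        """Generated EEG -> preprocess -> classify -> stability score
        reproduces the script's true score exactly in >= 80% of recordings
        and never misses by more than one point."""
        diffs = np.array(
            [abs(r["est_score"] - r["true_score"]) for r in roundtrip_results]
        )
        assert np.mean(diffs == 0) >= 0.80
        assert diffs.max() <= 1

    def test_recordings_are_clean(self, roundtrip_results):
        assert all(r["artifact_fraction"] <= 0.15 for r in roundtrip_results)


class TestCohortGenerator:
    def test_group_sizes_match_study(self):
        df = generate_cohort(CohortConfig(seed=0))
        counts = df["group"].value_counts()
        assert counts["non_hypoaroused"] == 78 and counts["hypoaroused"] == 24

    def test_generated_items_pass_questionnaire_validation(self):
        df = generate_cohort(CohortConfig(seed=3))
        scored = score_cohort(df)  # raises on any out-of-range item
        assert scored["included"].all()
        assert scored["ess_total"].between(0, 24).all()
        assert scored["bdi_total"].between(0, 63).all()
        for dim in ("general_fatigue", "mental_fatigue", "physical_fatigue"):
            assert scored[dim].between(4, 20).all()

    def test_same_seed_same_cohort(self):
        a = generate_cohort(CohortConfig(seed=9))
        b = generate_cohort(CohortConfig(seed=9))
        assert a.equals(b)

    def test_infeasible_mean_rejected(self):
        eff = copy.deepcopy(DEFAULT_EFFECTS)
        eff["ess_total"]["hypo"] = (30.0, 4.0)  # outside the 0-24 scale
        with pytest.raises(ConfigError):
            CohortConfig(effects=eff)

    def test_large_sample_mean_matches_configured_target(self):
        # trait-sleepiness calibration at n = 10,000 per group
        df = generate_cohort(CohortConfig(n_non_hypo=10_000, n_hypo=10_000, seed=0))
        ess = df[ESS_COLS].sum(axis=1)
        hypo_mean = ess[df["group"] == "hypoaroused"].mean()
        assert abs(hypo_mean - 10.4) < 0.1

    def test_null_configuration_keeps_nominal_type_one_error(self):
        """With identical group parameters the trait-sleepiness comparison
        rejects at close to the nominal 5% rate across simulated cohorts."""
        eff = copy.deepcopy(DEFAULT_EFFECTS)
        for spec in eff.values():
            spec["hypo"] = spec["non"]
        rejections = 0
        n_sim = 1000
        for i in range(n_sim):
            df = generate_cohort(CohortConfig(seed=i, effects=eff))
            ess = df[ESS_COLS].sum(axis=1)
            res = mann_whitney(
                ess[df["group"] == "non_hypoaroused"],
                ess[df["group"] == "hypoaroused"],
            )
            rejections += res.p_two_sided < 0.05
        assert abs(rejections / n_sim - 0.05) < 0.025

    def test_default_effects_yield_usable_power(self):
        """Diagnostic: at the study's group sizes the configured
        trait-sleepiness difference is detected well above chance."""
        rejections = 0
        n_sim = 300
        for i in range(n_sim):
            df = generate_cohort(CohortConfig(seed=5000 + i))
            ess = df[ESS_COLS].sum(axis=1)
            res = mann_whitney(
                ess[df["group"] == "non_hypoaroused"],
                ess[df["group"] == "hypoaroused"],
            )
            rejections += res.p_two_sided < 0.05
        power = rejections / n_sim
        assert 0.3 < power < 0.95
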