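"""Generator contracts: design arithmetic, calibration recovery,
round-trip fixation realization, audio and lip-trace ground truth."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from ccvmotor.gaze_metrics import OcularMeasures, ScreenLayout, screen_measures
from ccvmotor.synthetic_data import (
    CalibrationTable,
    DesignSpec,
    build_design,
    ccv_inventory,
    realize_fixations,
    simulate_timing,
    synthesize_ccv_audio,
)

LAYOUT = ScreenLayout()


class TestDesign:
    def test_inventory_has_72_distinct_ccvs(self):
        inv = ccv_inventory()
        assert len(inv) == 72 and len(set(inv)) == 72

    def test_block_has_180_stimuli_and_45_core_presentations(self):
        design = build_design(DesignSpec(n_subjects=1), seed=3)
        block = design[design["block"] == "oral"]
        assert len(block) == 180
        core = block[
            block["ccv"].str[0].isin(list("bdg"))
            & (block["cluster_type"] == "plosive-plosive")
        ]
        assert len(core) == 45

    def test_same_seed_reproduces_the_trial_list(self):
        a = build_design(DesignSpec(n_subjects=2), seed=9)
        b = build_design(DesignSpec(n_subjects=2), seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_impossible_repetition_scheme_rejected(self):
        with pytest.raises(ValueError):
            build_design(DesignSpec(n_subjects=1, filler_triples=20), seed=0)

    def test_repetition_numbers_count_occurrences(self):
        design = build_design(DesignSpec(n_subjects=1), seed=5)
        block = design[design["block"] == "silent"]
        counts = block.groupby("ccv")["repetition"].max()
        assert counts.isin([2, 3]).all()
        assert (block.groupby("ccv")["repetition"].apply(list).map(sorted)
                == block.groupby("ccv")["repetition"].max().map(lambda m: list(range(1, m + 1)))).all()


class TestTiming:
    def test_zero_noise_reproduces_calibrated_means_exactly(self, calibration):
        stats = calibration.ccv_stats.copy()
        stats["tau_norm_sd"] = 0.0
        stats["T_sd"] = 0.0
        quiet = replace(
            calibration, ccv_stats=stats, default_tau_sd=0.0, default_T_sd=0.0
        )
        design = build_design(DesignSpec(n_subjects=2), seed=1)
        trials = simulate_timing(design, quiet, seed=1)
        oral = trials[(trials["block"] == "oral")].dropna(subset=["tau_norm"])
        for ccv, group in oral.groupby("ccv"):
            assert np.allclose(group["tau_norm"], quiet.tau_mean(ccv))

    def test_subgroup_mean_within_three_sem(self, calibration):
        design = build_design(DesignSpec(n_subjects=28), seed=4)
        trials = simulate_timing(design, calibration, seed=4)
        oral = trials[trials["block"] == "oral"]
        sub = oral[oral["ccv"].isin(["bda", "bga", "dga"])]["tau_norm"].dropna()
        assert abs(sub.mean() - 0.373) <= 3 * sub.sem()

    def test_delta_coupling_recovered_within_two_se(self, calibration):
        from ccvmotor.stats_inference import ols_regression

        design = build_design(DesignSpec(n_subjects=10), seed=6)
        trials = simulate_timing(design, calibration, seed=6)
        oral = trials[trials["block"] == "oral"].dropna(subset=["delta", "tau_norm"])
        res = ols_regression(oral["delta"], {"tau_norm": oral["tau_norm"]})
        t = res.term("tau_norm")
        assert abs(t.estimate - calibration.delta_slope) <= 2 * t.se

    def test_ocular_ordering_holds_on_every_trial(self, calibration):
        design = build_design(DesignSpec(n_subjects=3), seed=7)
        trials = simulate_timing(design, calibration, seed=7).dropna(subset=["ffd"])
        assert (trials["ffd"] <= trials["fprt"] + 1e-9).all()
        assert (trials["fprt"] <= trials["tft"] + 1e-9).all()


class TestFixationRealization:
    def test_single_fixation_triple(self):
        ms = [OcularMeasures(200, 200, 200, True, 0.0)] + [
            OcularMeasures(0, 0, 0, False, None)
        ] * 5
        events = realize_fixations(ms, LAYOUT)
        assert len(events) == 1 and events[0].duration == 200

    def test_example_triple_round_trips(self):
        ms = [
            OcularMeasures(100, 250, 330, True, 0.0),
            OcularMeasures(150, 150, 150, True, 0.0),
        ] + [OcularMeasures(0, 0, 0, False, None)] * 4
        events = realize_fixations(ms, LAYOUT)
        forward = screen_measures(events, LAYOUT)
        assert (forward[0].ffd, forward[0].fprt, forward[0].tft) == (100, 250, 330)

    def test_inconsistent_triple_rejected_at_construction(self):
        with pytest.raises(ValueError):
            OcularMeasures(300.0, 200.0, 100.0, True, 0.0)

    def test_lone_reread_on_last_fixated_aoi_rejected(self):
        ms = [OcularMeasures(100, 100, 100, True, 0.0)] * 5 + [
            OcularMeasures(100, 100, 200, True, 0.0)
        ]
        with pytest.raises(ValueError):
            realize_fixations(ms, LAYOUT)


class TestAudio:
    def test_planted_interval_recovered(self):
        from ccvmotor.acoustic_timing import detect_transition

        audio = synthesize_ccv_audio((0.35, 0.55), T=0.49, onset=0.30, seed=1)
        tau, _ = detect_transition(audio.wave, audio.sample_rate, "plosive-plosive")
        assert tau == pytest.approx(0.20, abs=0.01)

    def test_zero_amplitude_has_no_detectable_onset(self):
        from ccvmotor.acoustic_timing import NoOnsetError, detect_vocal_onset

        audio = synthesize_ccv_audio((0.35, 0.55), onset=0.30, amplitude=0.0, seed=2)
        with pytest.raises(NoOnsetError):
            detect_vocal_onset(audio.wave, audio.sample_rate)

    def test_same_seed_is_bit_identical(self):
        a = synthesize_ccv_audio((0.35, 0.55), onset=0.30, seed=11)
        b = synthesize_ccv_audio((0.35, 0.55), onset=0.30, seed=11)
        assert np.array_equal(a.wave, b.wave)

    def test_landmark_outside_utterance_rejected(self):
        with pytest.raises(ValueError):
            synthesize_ccv_audio((0.1, 0.9), T=0.49, onset=0.30)


class TestLipTraces:
    def test_seeded_reproducibility(self):
        from ccvmotor.synthetic_data import simulate_lip_trace

        a = simulate_lip_trace("oral", 0.8, seed=5)
        b = simulate_lip_trace("oral", 0.8, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_unknown_modality_rejected(self):
        from ccvmotor.synthetic_data import simulate_lip_trace

        with pytest.raises(ValueError):
            simulate_lip_trace("whispered", 0.8)


def test_calibration_subgroup_means_are_consistent(calibration):
    calibration.validate()
    m = calibration.ccv_stats.set_index("ccv")["tau_norm_mean"]
    halves = (m[["bda", "bga", "dga"]].mean() + m[["dba", "gba", "gda"]].mean()) / 2
    voiced = m[["bda", "bga", "dba", "dga", "gba", "gda"]].mean()
    assert halves == pytest.approx(voiced, abs=1e-12)
    assert abs(voiced - 0.382) <= 0.001  # printed group mean, to rounding
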