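"""Cohort generator: determinism, counting contracts, planted parameters."""

import numpy as np
import pandas as pd
import pytest

from speechstate.lexicon import CONCEPTS
from speechstate.synth import (CohortConfig, ConditionEffects, SubjectProfile,
                               generate_cohort, synth_transcript, synth_voice)

SR = 16000


class TestSynthVoice:
    def test_determinism(self, flat_profile):
        w1, t1 = synth_voice(flat_profile, ConditionEffects(), 66.0, SR, 5)
        w2, t2 = synth_voice(flat_profile, ConditionEffects(), 66.0, SR, 5)
        np.testing.assert_array_equal(w1, w2)
        assert t1 == t2

    def test_null_perturbation_continuous_phonation(self):
        from speechstate.audio import extract_acoustic_from_signal
        prof = SubjectProfile(base_f0=120, base_jitter=0.0, base_shimmer=0.0,
                              base_pause_rate=0.0, base_speech_rate=0.0,
                              base_concept_weight=0.1,
                              topic_preference=np.full(12, 1 / 12),
                              verbosity=300)
        wave, truth = synth_voice(prof, ConditionEffects(), 66.0, SR, 6)
        assert truth["n_pauses"] == 0
        feats = extract_acoustic_from_signal(wave, SR)
        assert feats["PauseCount"] == 0
        assert feats["Jitter_h"] < 0.75  # near zero at the percent scale

    def test_planted_f0_recovered_after_trimming(self, flat_profile):
        from speechstate.audio import extract_acoustic_from_signal
        wave, truth = synth_voice(flat_profile, ConditionEffects(), 70.0, SR, 7)
        feats = extract_acoustic_from_signal(wave, SR)
        assert abs(feats["Pitch_a"] - 120.0) <= 3.0
        assert abs(feats["Pitch_a"] - truth["f0_realized_hz"]) <= 3.0

    def test_invalid_parameters_rejected(self, flat_profile):
        with pytest.raises(ValueError, match="duration"):
            synth_voice(flat_profile, ConditionEffects(), -5.0, SR, 0)
        with pytest.raises(ValueError, match="f0"):
            synth_voice(flat_profile, ConditionEffects(pitch_hz=-500), 66.0,
                        SR, 0)

    def test_effects_shift_generator_parameters(self, flat_profile):
        _, truth = synth_voice(flat_profile,
                               ConditionEffects(pitch_hz=15, jitter_pp=0.7),
                               66.0, SR, 8)
        assert truth["f0_target_hz"] == pytest.approx(135.0)
        assert truth["jitter_target_pct"] == pytest.approx(2.2)


class TestSynthTranscript:
    def test_determinism(self, flat_profile, lexicon):
        t1 = synth_transcript(flat_profile, 0.3, seed=3, lexicon=lexicon)
        t2 = synth_transcript(flat_profile, 0.3, seed=3, lexicon=lexicon)
        assert t1 == t2

    def test_boundary_weight_dominated_by_concept_topic(self, flat_profile,
                                                        lexicon,
                                                        semantic_model):
        from speechstate.semantic import extract_semantic
        from speechstate.text import clean_and_tag
        meds = {}
        for w in (0.0, 0.5, 1.0):
            txt = synth_transcript(flat_profile, w, ("love",), lexicon, seed=4)
            feats = extract_semantic(clean_and_tag(txt, lexicon),
                                     semantic_model, ("love",))
            meds[w] = feats["love"]
        assert meds[1.0] == max(meds.values())

    def test_invalid_inputs_rejected(self, flat_profile, lexicon):
        with pytest.raises(ValueError):
            synth_transcript(flat_profile, 1.5, lexicon=lexicon)
        with pytest.raises(ValueError):
            synth_transcript(flat_profile, 0.5, concepts=(), lexicon=lexicon)


class TestGenerateCohort:
    def test_default_design_row_count(self, tmp_path, lexicon):
        cfg = CohortConfig(n_subjects=4, duration_s=66.0, sample_rate=SR,
                           seed=1)
        res = generate_cohort(cfg, tmp_path / "c", lexicon=lexicon,
                              write_corpus=False)
        assert len(res.manifest) == 32  # 4 subjects x 4 conditions x 2 tasks

    def test_minimal_viable_design(self, tmp_path, lexicon):
        cfg = CohortConfig(n_subjects=2, conditions=("PBO", "MDMA1.5"),
                           tasks=("Monologue",), duration_s=66.0,
                           sample_rate=SR, seed=2)
        res = generate_cohort(cfg, tmp_path / "m", lexicon=lexicon,
                              write_corpus=False)
        assert len(res.manifest) == 4

    def test_annotations_only_for_description_task(self, small_cohort):
        mf = small_cohort.manifest
        desc = mf[mf["task"] == "Description"]
        mono = mf[mf["task"] == "Monologue"]
        assert (desc["annotation_path"] != "").all()
        assert (mono["annotation_path"] == "").all()

    def test_every_condition_once_per_subject_per_task(self, small_cohort):
        mf = small_cohort.manifest
        counts = mf.groupby(["subject_id", "task"])["condition"].nunique()
        assert (counts == 2).all()
        assert len(mf) == len(mf.drop_duplicates(
            ["subject_id", "condition", "task"]))

    def test_byte_identical_regeneration(self, tmp_path, lexicon):
        cfg = CohortConfig(n_subjects=2, conditions=("PBO", "OT"),
                           tasks=("Monologue",), duration_s=66.0,
                           sample_rate=SR, seed=9)
        r1 = generate_cohort(cfg, tmp_path / "a", lexicon=lexicon,
                             write_corpus=False)
        r2 = generate_cohort(cfg, tmp_path / "b", lexicon=lexicon,
                             write_corpus=False)
        pd.testing.assert_frame_equal(
            r1.manifest.drop(columns=["audio_path", "transcript_path",
                                      "annotation_path"]),
            r2.manifest.drop(columns=["audio_path", "transcript_path",
                                      "annotation_path"]))
        for p1, p2 in zip(sorted((tmp_path / "a" / "audio").iterdir()),
                          sorted((tmp_path / "b" / "audio").iterdir())):
            assert p1.read_bytes() == p2.read_bytes()
        for p1, p2 in zip(sorted((tmp_path / "a" / "transcripts").iterdir()),
                          sorted((tmp_path / "b" / "transcripts").iterdir())):
            assert p1.read_text() == p2.read_text()

    def test_truth_has_one_entry_per_row(self, small_cohort):
        assert len(small_cohort.truth) == len(small_cohort.manifest)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=1)
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=2, duration_s=50.0)
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=2, sample_rate=8000)
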