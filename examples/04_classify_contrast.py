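"""Detect a planted drug effect with paired-contrast classification.

A 6-subject cohort is generated in which MDMA1.5 shifts pitch (+12 Hz),
jitter (+0.8 pp), and concept loading (+0.5) relative to placebo.  The
full pipeline runs: synthesis, 126 features, (A-B) vs (B-A) contrasts,
nested leave-one-participant-out CV, and weight attribution.
"""

import tempfile

from speechstate import (CohortConfig, ConditionEffects, generate_cohort,
                         make_contrasts, nested_lopo_cv,
                         train_contrast_model, weight_profile)
from speechstate.features import build_feature_table
from speechstate.studies import default_semantic_model

config = CohortConfig(
    n_subjects=6, conditions=("PBO", "MDMA1.5"), tasks=("Monologue",),
    duration_s=70.0, sample_rate=16000, seed=7,
    effect_map={"MDMA1.5": ConditionEffects(pitch_hz=12.0, jitter_pp=0.8,
                                            concept_weight=0.5)},
)
model = default_semantic_model()
with tempfile.TemporaryDirectory() as tmp:
    cohort = generate_cohort(config, tmp, write_corpus=False)
    table, _ = build_feature_table(cohort.manifest, model)

data = make_contrasts(table, "MDMA1.5", "PBO", "Monologue")
result = nested_lopo_cv(data, seed=7)
print(f"nested LOPO CV accuracy: {100 * result.accuracy:.1f}% "
      f"({result.n_correct}/{result.n_total} held-out samples)")
print(f"binomial p vs 50% chance: {result.p_value:.4g}")

final = train_contrast_model(data, seed=7)
print(f"selected model: {final.classifier_id} {final.params}, "
      f"{len(final.selected)} features")
if final.classifier_id == "svm":
    w = weight_profile(final.classifier.coef_.ravel(),
                       final.selected_features)
    top = w[w > 0.10].sort_values(ascending=False)
    print("features contributing >10% of |weight|:")
    for name, v in top.items():
        print(f"  {name}: {100 * v:.0f}%")
# With three planted effects the contrast is easily separable: expect
# accuracy near 100% and the pitch median (A-Pitch_a) dominating the
# weight profile.
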