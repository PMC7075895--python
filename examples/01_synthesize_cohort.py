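"""Generate a small synthetic crossover cohort and inspect its design.

Each of 3 subjects is recorded once per condition and task; condition
MDMA1.5 gets a planted +12 Hz pitch shift.  The printed truth entry shows
the realized generator parameters the extractors should recover.
"""

import json
import tempfile

from speechstate import CohortConfig, ConditionEffects, generate_cohort

config = CohortConfig(
    n_subjects=3,
    conditions=("PBO", "MDMA1.5"),
    tasks=("Monologue", "Description"),
    duration_s=70.0,            # 10 s analyzed after 30 s head/tail trims
    sample_rate=16000,
    seed=42,
    effect_map={"MDMA1.5": ConditionEffects(pitch_hz=12.0)},
)

with tempfile.TemporaryDirectory() as tmp:
    cohort = generate_cohort(config, tmp)
    print(cohort.manifest[["subject_id", "session", "condition", "task"]]
          .to_string(index=False))
    key = "S001_MDMA1.5_Monologue"
    truth = cohort.truth[key]
    print(f"\ntruth for {key}:")
    print(json.dumps({k: v for k, v in truth.items()
                      if k != "pause_intervals"}, indent=1))

# The manifest has one row per subject x condition x task (12 here); the
# MDMA1.5 rows' f0_target is the subject's baseline f0 + 12 Hz.
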