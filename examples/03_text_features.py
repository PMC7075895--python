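"""Score a transcript: 21 LSA concept proximities + 17 psycholinguistic
features.

Two transcripts are generated from the same speaker profile, one with no
concept loading (w=0) and one heavily loaded on the concept *love*
(w=0.8); the semantic feature S-love separates them sharply.
"""

import numpy as np

from speechstate import synth_transcript
from speechstate.studies import default_semantic_model
from speechstate.synth import SubjectProfile
from speechstate.semantic import extract_semantic
from speechstate.text import clean_and_tag, extract_psycholinguistic

profile = SubjectProfile(base_f0=120, base_jitter=1.5, base_shimmer=3.0,
                         base_pause_rate=8.0, base_speech_rate=4.0,
                         base_concept_weight=0.1,
                         topic_preference=np.full(12, 1 / 12),
                         verbosity=300.0)
model = default_semantic_model()

for w in (0.0, 0.8):
    text = synth_transcript(profile, w, ("love",), seed=3)
    ct = clean_and_tag(text)
    sem = extract_semantic(ct, model, ("love",))
    psy = extract_psycholinguistic(ct)
    print(f"concept weight w={w}:")
    print(f"  median proximity to 'love': {sem['love']:+.3f}")
    print(f"  tokens={psy['W-Total']:.0f}  ideas={psy['Ideas']:.0f}  "
          f"density={psy['Density']:.3f}  type-token={psy['TypeToken']:.3f}  "
          f"Honore={psy['Honores']:.0f}  Brunet={psy['Brunets']:.2f}")
# The w=0.8 transcript draws most content words from the love-neighborhood
# topic, so its median LSA proximity to 'love' approaches 1, while the
# psycholinguistic profile (idea density, richness) stays comparable.
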