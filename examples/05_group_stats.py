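"""Group-level structure: paired Wilcoxon + FDR, partial correlations, MDS.

A simulated 20-subject feature table plants two condition effects: a mean
shift on features f0 and f1, and — only under the drug — a coupling
between them.  The Wilcoxon/BH stage finds the shifted features, the
partial correlations reveal the drug-specific coupling, and classical MDS
places the two condition matrices and the identity matrix in a plane.
"""

import numpy as np
import pandas as pd

from speechstate import mds_embed, paired_feature_tests, partial_correlations

rng = np.random.default_rng(0)
rows = []
for i in range(20):
    base = rng.standard_normal(10)
    for cond in ("PBO", "MDMA1.5"):
        x = base + 0.4 * rng.standard_normal(10)
        if cond == "MDMA1.5":
            x[0] += 1.5                       # planted mean shift
            # shifted AND coupled to f0, but only under the drug
            x[1] = 1.3 + 0.9 * (x[0] - 1.5) + 0.3 * rng.standard_normal()
        rows.append([f"S{i:02d}", cond, "Monologue", *x])
cols = ["subject_id", "condition", "task"] + [f"A-f{j}" for j in range(10)]
table = pd.DataFrame(rows, columns=cols)

tests = paired_feature_tests(table, "MDMA1.5", "PBO", "Monologue")
sig = tests[tests["reject"]]
print(f"{len(sig)} of {len(tests)} features pass BH-FDR at q<0.05:")
print(sig[["feature", "W", "p", "q"]].to_string(index=False))

selected = list(sig["feature"])
mats, labels = [], []
for cond in ("PBO", "MDMA1.5"):
    sub = table[table["condition"] == cond]
    pc = partial_correlations(sub[selected].to_numpy(),
                              feature_names=selected)
    mats.append(pc)
    labels.append(cond)
    print(f"\npartial correlation f0~f1 ({cond}): "
          f"{pc.iloc[0, 1]:+.3f}")

identity = pd.DataFrame(np.eye(len(selected)), index=selected,
                        columns=selected)
emb = mds_embed(mats + [identity], labels + ["identity"])
print("\nMDS coordinates (Frobenius distances between matrices):")
for lab, (x, y) in zip(emb.labels, emb.coordinates):
    print(f"  {lab:>9s}: ({x:+.3f}, {y:+.3f})")
# The drug condition shows a strong f0~f1 partial correlation absent under
# placebo, so its matrix sits far from both the placebo matrix and the
# identity in the MDS plane.
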