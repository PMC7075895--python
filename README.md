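# speechstate

Speech-based detection of drug-induced mental states: a reusable analysis
pipeline for within-participants crossover speech studies, with a synthetic
cohort generator standing in for human recordings.

## The problem

Acute psychoactive drug effects (here: MDMA at 0.75 and 1.5 mg/kg,
intranasal oxytocin 20 IU, placebo) alter how people speak — voice quality,
prosody, pausing, semantic content, and syntax. Standard assessment relies
on self-report scales; free speech offers an objective alternative if its
features can discriminate drug conditions at the individual level. This
package implements that analysis end to end for a design in which every
subject is recorded once per condition and task (a 5-minute *Monologue*
spoken alone and a 5-minute *Description* with an interviewer present).

Because no human recordings ship with the package, a first-class synthetic
cohort generator produces waveforms (source–filter voice synthesis with
controllable pitch, jitter, shimmer, and pause structure), transcripts (a
topic-model language over a closed lexicon with known part-of-speech tags),
and a background corpus for the semantic model — all with *planted*,
recoverable condition effects, so every stage of the pipeline is testable
against ground truth.

## Methods at the core

**Features (126 per recording).**

* *Acoustic (88)*: pitch distribution, jitter/shimmer (local and 5-point
  quotients), voice breaks, HNR/NHR/mean autocorrelation, long-term
  spectrum statistics, 16 MFCCs, F1–F3 distributions, vowel-space area and
  /a/-/i/-/u/ triangle geometry, pause/utterance duration distributions,
  speech and articulation rates. Descriptor suffixes: a=median, b=IQR,
  c=kurtosis, d=skewness, e=p5, f=p50, g=p95, h=local, i=frames.
* *Semantic (21)*: latent semantic analysis (log-entropy weighted
  term–document matrix, rank-k SVD); each feature is the median cosine
  proximity between a concept word (*affect, anxiety, …, talk*) and the
  transcript's in-vocabulary lemmas.
* *Psycholinguistic (17)*: CPIDR-style propositional idea count and
  density, part-of-speech ratios, Honoré's statistic
  R = 100·ln N / (1 − V₁/V), Brunet's index W = N^(V^−0.165),
  content/empty-word ratios, type–token ratio, mean log word frequency,
  filler rate.

**Classification.** Within-subject baselines are removed by the paired
contrast: classifying condition A vs B is recast as (A−B) vs (B−A) in
feature-difference space, so each subject contributes an antisymmetric pair
of samples and chance is exactly 50%. A nested leave-one-participant-out
cross-validation holds out both samples of one subject; an inner grouped CV
ranks features by two-sample t-tests and selects the feature count and
classifier (linear SVM without intercept, k-nearest neighbors, random
forest). Significance of the pooled held-out accuracy is the exact binomial
tail P(X ≥ k | n, ½). Linear-model weights are reported as relative
contributions |wᵢ| / Σ|wⱼ|.

**Group inference.** Per-feature paired Wilcoxon signed-rank tests (exact
for n ≤ 25), Benjamini–Hochberg FDR at q < 0.05; partial correlations from
the inverse of a shrinkage-regularized correlation matrix
(ρᵢⱼ = −Θᵢⱼ/√(ΘᵢᵢΘⱼⱼ), Θ = ((1−λ)R + λI)⁻¹ with analytic λ); classical
(Torgerson) MDS of the per-condition×task matrices under the Frobenius
distance.

## Worked example

`examples/04_classify_contrast.py` generates a 6-subject cohort in which
MDMA 1.5 shifts pitch (+12 Hz), jitter (+0.8 pp), and transcript concept
loading (+0.5) relative to placebo, then runs the full pipeline:

```
nested LOPO CV accuracy: 100.0% (12/12 held-out samples)
binomial p vs 50% chance: 0.0002441
selected model: svm {'C': 0.01}, 1 features
features contributing >10% of |weight|:
  A-Pitch_a: 100%
```

All 12 held-out contrast samples are classified correctly (exact binomial
p ≈ 2.4×10⁻⁴ against the 50% chance level), and the weight profile
attributes the discrimination to the pitch median — the largest planted
effect. The other examples cover cohort synthesis and ground truth
(`01`), acoustic parameter recovery (`02`), LSA/psycholinguistic scoring
(`03`), group statistics with partial correlations and MDS (`05`), and
frozen-model transfer to an external cohort with feature masking (`06`).

A thin CLI wraps the same stages
(`speechstate synth|features|stats|classify|transfer|report|all`).

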