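# Methods

This note documents the models, parameter choices, and numerical
conventions behind `speechstate`, and what the synthetic-data studies do
and do not demonstrate.

## Study design emulated

A randomized within-participants crossover: each subject is recorded once
per condition (default PBO, MDMA0.75, MDMA1.5, OT) and task (Monologue —
no listener present; Description — an interviewer may speak and is
annotated for removal). Recordings default to 300 s at 22.05 kHz mono PCM;
the analysis discards the first and last 30 s of every recording and
excises (not silences) annotated interviewer intervals, so all duration
statistics describe participant speech only.

## Synthetic cohort generator

The generator's purpose is statistical, not perceptual: it produces
signals and texts on which every feature of the pipeline is *well defined
and recoverable*, with condition effects planted as known offsets.

**Voice.** A glottal impulse train at the target f0 with i.i.d. cycle-wise
period perturbations rescaled so the realized local jitter equals the
configured percentage exactly; amplitudes perturbed analogously for
shimmer. Pulses are placed with fractional (two-sample linear) splitting
so the laid-down period sequence is not quantized to the sample grid; the
*realized* (not merely requested) f0 median and local jitter are recorded
in the cohort truth. The excitation passes through three cascaded
second-order resonators cycling every 0.3 s among vowel targets /a/ (F1,
F2, F3 = 800, 1200, 2800 Hz), /i/ (300, 2300, 3000), /u/ (350, 800, 2250)
with bandwidths 80/120/160 Hz. A raised-cosine amplitude envelope at the
subject's syllable rate (3.5–5 /s) creates intensity dips so syllable
nuclei and speech rate are measurable. Pauses are log-normal (median
0.5 s, σ=0.5 in log space) at the subject's pause rate; the head and tail
30.6 s are continuous phonation so no planted pause straddles a trim
boundary and the truth pause count is exactly the count inside the
analysis window. White noise sits 50 dB below speech RMS.

Known non-realisms: constant f0 within a recording (no intonation), a
three-vowel inventory, no consonants or coarticulation, stationary noise.
The shimmer estimate is inflated by the syllable envelope (adjacent-cycle
amplitude drift), so shimmer is planted but only loosely recovered;
recovery tolerances are enforced for f0 (±3 Hz), local jitter (±0.5
percentage points), and pause count (±1).

**Language.** A closed synthetic-English lexicon (~1600 words) partitioned
into 21 concept-neighborhood topics (one per concept word of interest) and
12 background topics, plus real English function words, auxiliaries,
determiners, fillers, and a small irregular-lemma table. Every word
carries a fixed Penn-Treebank-style tag, which makes tagging and
lemmatization deterministic without an external tagger model; unknown
words fall back to suffix rules. Transcripts sample content words from the
mixture (1−w)·subject-topic-preference + w·concept topics, interleaved
with function words (30%), fillers (3%), capitalization, and punctuation
so the cleaning stage is exercised. The concept weight w is the planted
semantic effect; a hapax factor flattens within-topic word distributions
to manipulate lexical richness. The background corpus (500 documents of
~200 tokens, fixed seed 777) is drawn from the same topic model, so
concept words and their neighborhoods genuinely co-occur.

## Acoustic features (88)

Pitch is tracked by short-time autocorrelation (40 ms frames, 10 ms hop,
default search band 75–500 Hz) with an unbiased-normalization correction
1/(1−lag/frame) and parabolic lag refinement; frames are voiced when the
normalized peak exceeds 0.45 and frame energy is within 30 dB of the
maximum. Glottal cycle marks are peak-picked within voiced runs with
sub-sample parabolic refinement; jitter_local = mean|ΔTᵢ|/mean Tᵢ, the
5-point period/amplitude quotients use moving-average baselines, and
cycles are never differenced across run boundaries. HNR per voiced frame
is 10·log₁₀(r/(1−r)) at the pitch lag (r clipped to (10⁻⁶, 1−10⁻⁶)), NHR
its reciprocal form. Pauses are intensity-threshold segments (threshold =
max − 25 dB, minimum pause 0.3 s, minimum utterance 0.1 s); syllable
nuclei are intensity peaks with ≥2 dB prominence inside utterances. The
long-term spectrum uses Welch PSD (≤4096-point segments); spectral slope
is the dB-per-octave regression over 50 Hz–8 kHz. MFCCs 1–16 use 25/10 ms
framing and 26 mel filters over the full band. Formants come from LPC
root-solving (autocorrelation method, order 2 + sr/1000 = 12 at the
10 kHz analysis rate, pre-emphasis 0.97) on every second voiced frame;
admissible roots need bandwidth < 700 Hz and frequency in (90, sr/2−100).
Vowel-space total area is the convex hull of (F1, F2); the a-i-u area is
the shoelace area of the triangle of per-corner centroids (nearest
reference target assignment), and the angle is the apex angle at /i/.

Distributional descriptors use linear-interpolation percentiles and
population (biased) moment estimators; a constant series has skewness and
kurtosis 0 by convention. The canonical inventory of exactly 88 names is a
versioned package data file; the extractor fails loudly if it would emit
anything else. Missing values (e.g. too few cycles) are imputed with the
cohort median at table-assembly time and recorded in a missingness mask.

## Semantic features (21)

Term–document counts over the corpus are weighted by log(1+count) times
the entropy global weight 1 + Σⱼ pᵢⱼ log pᵢⱼ / log D, then factored by
SVD; word vectors are the left-singular rows scaled by singular values,
with signs fixed by forcing each singular vector's largest-magnitude entry
positive (builds are bit-reproducible). Default rank 100 (configurable;
rank may equal min(|V|, D), in which case proximities equal cosines of the
weighted matrix rows exactly). A transcript's feature for a concept is the
median cosine proximity over all in-vocabulary lemma occurrences
(multiplicity counts). Eligibility deliberately includes all words, not
nouns only — the alternative is a config switch — because proximity to a
concept is defined for any lemma and restricting to nouns discards most of
the transcript under the synthetic language.

## Psycholinguistic features (17)

The idea counter approximates propositional-density raters by POS classes:
verbs, adjectives, adverbs, prepositions, conjunctions, and modals count;
determiners never count; an auxiliary immediately preceding a verb does
not count. This reproduces the dominant behavior of full rule sets without
their ~35 English-specific adjustment rules. Honoré's statistic uses the
natural logarithm and is undefined (missing, logged) when every type is a
hapax; log frequency is ln(1+count) against the packaged corpus counts;
fillers are um/uh/er/hmm/like plus "you know" bigrams; indefinites and
definites are closed word lists shipped with the lexicon.

## Paired-contrast classification

Contrasts are built per subject as d = x_A − x_B with both signed samples
(d, +1) and (−d, −1); subjects missing either condition are excluded and
logged. Standardization (mean 0, sd 1 with n−1 denominator) is always fit
on training rows only; zero-variance columns are dropped per fold. Feature
ranking uses two-sample t-tests (+1 vs −1 class), ties broken
lexicographically. The linear SVM is fit *without* an intercept: the
contrast construction makes the problem exactly origin-symmetric, so an
intercept could only absorb noise and would break the antisymmetry
prediction(−d) = −prediction(d).

The outer CV loop is leave-one-participant-out with both samples of the
held-out subject co-traveling (asserted on every fold). The inner
selection loop is a grouped 3-fold CV over training subjects; full inner
leave-one-out is available (`inner_cv="lopo"`) but is quadratic in
subjects and was not adopted as the default because a 3-fold inner loop
already stabilizes selection at these cohort sizes at an order of
magnitude less cost. Grids: feature count {1, 2, 5, 13, 34, 89, 126}
(clipped to dimensionality), SVM C ∈ {0.01, 0.1, 1, 10}, k-NN
k ∈ {1, 3, 5}, random forest with 100 trees (bagged trees with
sqrt-feature subsampling, LightGBM backend chosen for single-CPU fit
speed at these sample sizes; seeded). Ties in inner accuracy resolve to
the smallest feature count, then SVM before k-NN before forest. Accuracy
counts held-out samples; the binomial test is the exact one-sided tail at
p=½. Transfer evaluation freezes the trained model, its standardization
parameters, and its selected features, and applies them unchanged to an
external cohort; a feature mask (e.g. "all acoustic") restricts training
when the external cohort lacks a domain.

## Group inference

Wilcoxon signed-rank tests drop zero differences, use the exact null for
n ≤ 25 and the continuity-corrected normal approximation above, and report
W = sum of positive-difference ranks. BH-FDR is the standard step-up
procedure. Partial correlations shrink the *correlation* matrix toward the
identity, R* = (1−λ)R + λI, with λ from the analytic risk-minimizing
(Schäfer–Strimmer-type) formula on standardized data; working on the
correlation scale makes the result exactly invariant to per-feature affine
rescaling, which the covariance-scale analytic intensity is not. The
feature set entering the network is the union of FDR-passing features
across contrasts (config-overridable). MDS is classical Torgerson
double-centering on squared Frobenius distances; axis signs are fixed by
forcing the largest-magnitude coordinate positive per axis (coordinates
are centered, so a sign-by-sum rule would be degenerate).

## Calibration studies and problem sizes

The null-calibration study (and the acceptance script) uses 30-subject,
two-condition, one-task cohorts with 70-s recordings at 16 kHz — the
smallest recording the 30-s trimming admits with a ~10-s analysis window —
over 20 independent seeds; at these sizes a full run completes in minutes
on one CPU while exercising synthesis, all 126 features, contrast
construction, and the nested CV. Per-seed null accuracies are heavy-tailed
(selection on noise in paired designs can produce accuracies far from 50%
in either direction), which is why calibration is asserted on the mean
over seeds against its Monte-Carlo 95% band. The power study plants
class-mean shifts directly in contrast space (5 of 126 features), which
isolates classifier behavior from generator noise.

Passing these studies shows the pipeline is unbiased at the null and
powered for clean planted effects; it does not show that real drugged
speech is detectable — the generator's effects are idealized, its noise
structure is simpler than human recordings, and its language is synthetic.

## Known limitations

* Real-audio robustness (background noise, channel effects, diarization
  errors) is out of scope; interviewer intervals are given, not inferred.
* The 88-feature inventory is this package's documented reconstruction of
  a conventional clinical-voice feature set; other tools' inventories
  differ in descriptor choices.
* CPIDR-style counting is a two-rule approximation, adequate for the
  synthetic language and for relative comparisons.
* Wilcoxon exact/approximate switch at n=25 and zero-difference dropping
  follow the classical convention; alternatives (Pratt) are not offered.
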