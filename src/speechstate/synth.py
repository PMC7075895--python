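"""Synthetic crossover cohort generator.

Emulates a within-participants drug-challenge speech study: every subject is
recorded once per condition and task, and condition effects are *planted* as
known offsets on the generator parameters — pitch median (Hz), jitter (%),
pause rate (per minute), concept-mixture weight of the transcript topic
model, and a lexical-richness (hapax) factor.  The realized parameters are
kept in a cohort-truth record (one JSON entry per manifest row) so that
downstream extractors can be tested for parameter recovery.

Voice signals use a source–filter scheme: a glottal impulse train at the
target f0 with cycle-wise period perturbation (jitter) and amplitude
perturbation (shimmer), filtered through three second-order formant
resonators cycling among the vowel targets /a/, /i/, /u/, with a slow
syllable-rate amplitude envelope and log-normally distributed silent pauses.
The first and last 30 s of each recording are continuous phonation so that
the 30-s trimming applied by the analysis never cuts a planted pause.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

from .lexicon import CONCEPTS, FILLER_WORDS, Lexicon, default_lexicon

DEFAULT_CONDITIONS = ("PBO", "MDMA0.75", "MDMA1.5", "OT")
DEFAULT_TASKS = ("Monologue", "Description")

TRIM_S = 30.0            # head/tail trimmed by the analysis
_EDGE_MARGIN_S = 0.6     # extra phonation beyond the trim boundary

# Formant targets (F1, F2, F3) in Hz and resonator bandwidths.
VOWEL_TARGETS = {
    "a": (800.0, 1200.0, 2800.0),
    "i": (300.0, 2300.0, 3000.0),
    "u": (350.0, 800.0, 2250.0),
}
_FORMANT_BW = (80.0, 120.0, 160.0)
_VOWEL_RUN_S = 0.30      # seconds per vowel before cycling to the next
_NOISE_FLOOR_DB = 50.0   # noise this many dB below speech RMS

PAUSE_MEDIAN_S = 0.5     # log-normal pause model
PAUSE_SIGMA_LOG = 0.5

CORPUS_SEED = 777        # the background corpus is a fixed artifact
CORPUS_N_DOCS = 500
CORPUS_DOC_LEN = 200

MANIFEST_COLUMNS = ("subject_id", "session", "condition", "task",
                    "audio_path", "transcript_path", "annotation_path")


@dataclass
class ConditionEffects:
    """Planted per-condition offsets on the generator parameters."""

    pitch_hz: float = 0.0
    jitter_pp: float = 0.0
    pause_rate_per_min: float = 0.0
    concept_weight: float = 0.0
    hapax_factor: float = 1.0

    def is_null(self) -> bool:
        return (self.pitch_hz == 0 and self.jitter_pp == 0
                and self.pause_rate_per_min == 0 and self.concept_weight == 0
                and self.hapax_factor == 1.0)


@dataclass
class SubjectProfile:
    """Between-speaker baseline parameters (the speaker's habitual voice)."""

    base_f0: float
    base_jitter: float
    base_shimmer: float
    base_pause_rate: float
    base_speech_rate: float
    base_concept_weight: float
    topic_preference: np.ndarray
    verbosity: float

    def __post_init__(self) -> None:
        for name in ("base_f0", "base_jitter", "base_shimmer",
                     "base_pause_rate", "base_speech_rate", "verbosity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        s = float(np.sum(self.topic_preference))
        if not np.isclose(s, 1.0):
            raise ValueError("topic_preference must sum to 1")


@dataclass
class CohortConfig:
    n_subjects: int
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    tasks: tuple[str, ...] = DEFAULT_TASKS
    duration_s: float = 300.0
    sample_rate: int = 22050
    seed: int = 0
    effect_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.duration_s <= 61:
            raise ValueError("duration_s must exceed 61 s "
                             "(30 s trimmed from each end)")
        if self.sample_rate < 16000:
            raise ValueError("sample_rate must be >= 16000 Hz")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be unique")

    def effects_for(self, condition: str, task: str) -> ConditionEffects:
        return self.effect_map.get((condition, task),
                                   self.effect_map.get(condition,
                                                       ConditionEffects()))


# ---------------------------------------------------------------------------
# voice synthesis
# ---------------------------------------------------------------------------

def _resonator_sos(freq: float, bw: float, sr: float) -> np.ndarray:
    r = np.exp(-np.pi * bw / sr)
    theta = 2 * np.pi * freq / sr
    # all-pole second-order section, unity numerator
    return np.array([[1.0, 0.0, 0.0, 1.0, -2 * r * np.cos(theta), r * r]])


def _vowel_filters(sr: float) -> dict[str, np.ndarray]:
    return {
        v: np.vstack([_resonator_sos(f, bw, sr)
                      for f, bw in zip(fs, _FORMANT_BW)])
        for v, fs in VOWEL_TARGETS.items()
    }


def _perturbation(rng: np.random.Generator, n: int, target_pct: float) -> np.ndarray:
    """i.i.d. fractional perturbations rescaled so the realized local
    cycle-to-cycle variation equals ``target_pct`` percent."""
    if target_pct <= 0 or n < 3:
        return np.zeros(n)
    eps = rng.standard_normal(n)
    realized = np.mean(np.abs(np.diff(eps)))
    if realized == 0:
        return np.zeros(n)
    out = eps * (target_pct / 100.0) / realized
    return np.clip(out, -0.45, 0.45)


def _render_phonation(n_samples: int, f0: float, jitter_pct: float,
                      shimmer_pct: float, syllable_rate: float, sr: int,
                      rng: np.random.Generator,
                      filters: dict[str, np.ndarray],
                      vowel_offset: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Render one continuous phonated span.

    Returns the waveform and the realized (sample-quantized) glottal period
    sequence in samples.
    """
    t0 = sr / f0
    n_cycles = int(np.ceil(n_samples / t0)) + 2
    delta = _perturbation(rng, n_cycles, jitter_pct)
    periods = t0 * (1.0 + delta)
    marks = np.concatenate([[0.0], np.cumsum(periods)])
    marks = marks[marks < n_samples - 1]
    periods_q = np.diff(marks)

    gamma = _perturbation(rng, len(marks), shimmer_pct)
    amps = 1.0 + gamma

    # fractional impulse placement: split each pulse over the two adjacent
    # samples so the laid-down period sequence is not quantized to the grid
    exc = np.zeros(n_samples)
    base = np.floor(marks).astype(int)
    frac = marks - base
    np.add.at(exc, base, amps * (1.0 - frac))
    np.add.at(exc, base + 1, amps * frac)

    out = np.empty(n_samples)
    vowels = list(filters)
    run = max(1, int(_VOWEL_RUN_S * sr))
    for k, start in enumerate(range(0, n_samples, run)):
        stop = min(start + run, n_samples)
        sos = filters[vowels[(k + vowel_offset) % len(vowels)]]
        out[start:stop] = sps.sosfilt(sos, exc[start:stop])

    if syllable_rate > 0:
        t = np.arange(n_samples) / sr
        env = 0.675 - 0.325 * np.cos(2 * np.pi * syllable_rate * t)
        out *= env
    rms = np.sqrt(np.mean(out ** 2))
    if rms > 0:
        out *= 0.15 / rms
    return out, periods_q.astype(float)


def synth_voice(profile: SubjectProfile, effects: ConditionEffects,
                duration_s: float, sample_rate: int,
                seed: int | np.random.SeedSequence) -> tuple[np.ndarray, dict]:
    """Synthesize one recording; returns (waveform, truth entry).

    The truth entry records the *realized* parameters: median f0 and local
    jitter computed from the sample-quantized period sequence actually laid
    down, and the planted pause intervals (all of which lie strictly inside
    the 30-s-trimmed analysis window).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if duration_s <= 61:
        raise ValueError("duration_s must exceed 61 s")
    f0 = profile.base_f0 + effects.pitch_hz
    if f0 <= 0:
        raise ValueError("f0 (base_f0 + pitch effect) must be positive")
    if sample_rate < 16000:
        raise ValueError("sample_rate must be >= 16000 Hz")

    jitter_pct = max(0.0, profile.base_jitter + effects.jitter_pp)
    pause_rate = max(0.0, profile.base_pause_rate + effects.pause_rate_per_min)
    rng = np.random.default_rng(seed)
    sr = int(sample_rate)
    filters = _vowel_filters(sr)

    total_n = int(round(duration_s * sr))
    head_end = TRIM_S + _EDGE_MARGIN_S
    tail_start = duration_s - TRIM_S - _EDGE_MARGIN_S

    # timeline: (is_speech, start_s, end_s); head/tail are pure phonation
    mean_pause = PAUSE_MEDIAN_S * np.exp(PAUSE_SIGMA_LOG ** 2 / 2)
    segments: list[tuple[bool, float, float]] = [(True, 0.0, head_end)]
    t = head_end
    if pause_rate > 0:
        mean_speech = max(60.0 / pause_rate - mean_pause, 0.8)
        while t < tail_start:
            sdur = float(np.exp(rng.normal(np.log(mean_speech) - 0.045, 0.3)))
            sdur = min(sdur, tail_start - t)
            segments.append((True, t, t + sdur))
            t += sdur
            if t >= tail_start:
                break
            pdur = float(np.exp(rng.normal(np.log(PAUSE_MEDIAN_S),
                                           PAUSE_SIGMA_LOG)))
            pdur = max(0.35, min(pdur, tail_start - t))
            if tail_start - t < 0.35:
                break
            segments.append((False, t, t + pdur))
            t += pdur
    else:
        segments.append((True, t, tail_start))
        t = tail_start
    segments.append((True, max(t, tail_start), duration_s))

    wave = np.zeros(total_n)
    all_periods: list[np.ndarray] = []
    pauses: list[tuple[float, float]] = []
    vowel_offset = 0
    for is_speech, s0, s1 in segments:
        i0, i1 = int(round(s0 * sr)), min(int(round(s1 * sr)), total_n)
        if i1 <= i0:
            continue
        if is_speech:
            seg, periods = _render_phonation(
                i1 - i0, f0, jitter_pct, profile.base_shimmer,
                profile.base_speech_rate, sr, rng, filters, vowel_offset)
            wave[i0:i1] = seg
            all_periods.append(periods)
            vowel_offset += int(np.ceil((i1 - i0) / (_VOWEL_RUN_S * sr)))
        else:
            pauses.append((s0, s1))

    speech_rms = np.sqrt(np.mean(wave[wave != 0] ** 2)) if np.any(wave) else 1.0
    noise_scale = speech_rms * 10 ** (-_NOISE_FLOOR_DB / 20)
    wave = wave + rng.standard_normal(total_n, dtype=np.float32) * noise_scale

    # realized parameters from the quantized periods
    sum_abs_diff = sum(float(np.sum(np.abs(np.diff(p))))
                       for p in all_periods if len(p) > 1)
    n_diffs = sum(len(p) - 1 for p in all_periods if len(p) > 1)
    all_p = np.concatenate(all_periods) if all_periods else np.array([1.0])
    mean_period = float(np.mean(all_p))
    truth = {
        "f0_target_hz": float(f0),
        "f0_realized_hz": float(sr / np.median(all_p)),
        "jitter_target_pct": float(jitter_pct),
        "jitter_realized_pct": (100.0 * sum_abs_diff / n_diffs / mean_period
                                if n_diffs else 0.0),
        "shimmer_target_pct": float(profile.base_shimmer),
        "pause_rate_per_min": float(pause_rate),
        "pause_intervals": [[round(a, 4), round(b, 4)] for a, b in pauses],
        "n_pauses": len(pauses),
        "speech_rate_target": float(profile.base_speech_rate),
    }
    return wave.astype(np.float32), truth


# ---------------------------------------------------------------------------
# transcripts and corpus
# ---------------------------------------------------------------------------

_FUNCTION_POOL = None


def _function_pool(lex: Lexicon):
    words = [w for w, p in lex.pos.items()
             if p in ("DT", "PRP", "IN", "CC", "MD") and w not in FILLER_WORDS]
    words.sort()
    weights = np.array([3.0 if lex.pos[w] in ("DT", "PRP") else 1.0
                        for w in words])
    return words, weights / weights.sum()


def _sample_topic_word(rng: np.random.Generator, lex: Lexicon, topic: str,
                       hapax_factor: float) -> str:
    words = lex.topics[topic]
    w = lex.topic_weights[topic]
    if hapax_factor != 1.0:
        w = w ** (1.0 / max(hapax_factor, 1e-3))
        w = w / w.sum()
    return words[int(rng.choice(len(words), p=w))]


def synth_transcript(profile: SubjectProfile, concept_weight: float,
                     concepts: tuple[str, ...] = CONCEPTS,
                     lexicon: Lexicon | None = None,
                     seed: int | np.random.SeedSequence = 0,
                     hapax_factor: float = 1.0) -> str:
    """Generate one transcript as raw text (with punctuation and fillers).

    Content words are drawn from the mixture
    ``(1 - w) * subject topic preference + w * concept-neighborhood topics``
    so that LSA proximity to the concept words rises with ``concept_weight``.
    """
    if not 0 <= concept_weight <= 1:
        raise ValueError("concept_weight must lie in [0, 1]")
    if not concepts:
        raise ValueError("concepts must be non-empty")
    lex = lexicon or default_lexicon()
    concept_topics = [lex.concept_topic(c) for c in concepts]
    bg = lex.background_topics
    if not bg:
        raise ValueError("lexicon has no background topics")
    pref = np.asarray(profile.topic_preference, dtype=float)
    if len(pref) != len(bg):
        raise ValueError("topic_preference length must match the number of "
                         f"background topics ({len(bg)})")

    rng = np.random.default_rng(seed)
    n_tokens = max(20, int(rng.poisson(profile.verbosity)))
    fwords, fweights = _function_pool(lex)
    fillers = sorted(FILLER_WORDS)

    out: list[str] = []
    sent_len = 0
    sent_target = 6 + int(rng.poisson(6))
    produced = 0
    while produced < n_tokens:
        r = rng.random()
        if r < 0.30:
            word = fwords[int(rng.choice(len(fwords), p=fweights))]
        elif r < 0.33:
            word = fillers[int(rng.integers(len(fillers)))]
        else:
            if rng.random() < concept_weight:
                topic = concept_topics[int(rng.integers(len(concept_topics)))]
            else:
                topic = bg[int(rng.choice(len(bg), p=pref))]
            word = _sample_topic_word(rng, lex, topic, hapax_factor)
        if sent_len == 0:
            word = word.capitalize()
        if rng.random() < 0.005:
            word = "#" + word
        out.append(word)
        produced += 1
        sent_len += 1
        if sent_len >= sent_target:
            out[-1] += "." if rng.random() < 0.85 else "!"
            sent_len = 0
            sent_target = 6 + int(rng.poisson(6))
        elif rng.random() < 0.06:
            out[-1] += ","
    if not out[-1][-1] in ".!":
        out[-1] += "."
    return " ".join(out)


def generate_corpus(lexicon: Lexicon | None = None,
                    n_docs: int = CORPUS_N_DOCS,
                    doc_len: int = CORPUS_DOC_LEN,
                    seed: int = CORPUS_SEED) -> list[list[str]]:
    """Seed-fixed background corpus (token lists) for the semantic model."""
    lex = lexicon or default_lexicon()
    rng = np.random.default_rng(seed)
    all_topics = sorted(lex.topics)
    fwords, fweights = _function_pool(lex)
    docs: list[list[str]] = []
    for _ in range(n_docs):
        k = 2
        topics = [all_topics[i] for i in rng.choice(len(all_topics), size=k,
                                                    replace=False)]
        mix = rng.dirichlet(np.ones(k))
        n = max(40, int(rng.poisson(doc_len)))
        doc: list[str] = []
        for _ in range(n):
            if rng.random() < 0.35:
                doc.append(fwords[int(rng.choice(len(fwords), p=fweights))])
            else:
                topic = topics[int(rng.choice(k, p=mix))]
                doc.append(_sample_topic_word(rng, lex, topic, 1.0))
        docs.append(doc)
    return docs


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def sample_profile(rng: np.random.Generator, n_background_topics: int,
                   verbosity: float = 350.0) -> SubjectProfile:
    return SubjectProfile(
        base_f0=float(rng.uniform(100, 220)),
        base_jitter=float(rng.uniform(0.8, 2.0)),
        base_shimmer=float(rng.uniform(2.0, 5.0)),
        base_pause_rate=float(rng.uniform(6.0, 12.0)),
        base_speech_rate=float(rng.uniform(3.5, 5.0)),
        base_concept_weight=float(rng.uniform(0.05, 0.20)),
        topic_preference=rng.dirichlet(np.full(n_background_topics, 0.6)),
        verbosity=float(rng.uniform(250, 450)),
    )


@dataclass
class CohortResult:
    manifest: pd.DataFrame
    truth: dict
    out_dir: Path
    lexicon: Lexicon

    @property
    def manifest_path(self) -> Path:
        return self.out_dir / "manifest.csv"


def _interviewer_annotations(rng: np.random.Generator, duration_s: float,
                             pauses: list) -> list[tuple[float, float]]:
    """Two interviewer intervals inside the analysis window, clear of the
    planted pauses."""
    out = []
    lo, hi = TRIM_S + 2.0, duration_s - TRIM_S - 10.0
    span = max(hi - lo, 4.0)
    for k in range(2):
        start = lo + span * (0.15 + 0.5 * k) + float(rng.uniform(0, 0.1 * span))
        dur = float(rng.uniform(1.5, 4.0))
        interval = (start, min(start + dur, duration_s - TRIM_S - 1.0))
        if all(interval[1] <= p0 or interval[0] >= p1
               for p0, p1 in [tuple(p) for p in pauses]) and interval[1] > interval[0]:
            out.append(interval)
    return out


def generate_cohort(config: CohortConfig, out_dir: str | Path,
                    lexicon: Lexicon | None = None,
                    write_corpus: bool = True) -> CohortResult:
    """Generate audio, transcripts, annotations, manifest, corpus, and truth.

    Fully determined by ``config`` (including its seed): re-running with the
    same configuration writes byte-identical artifacts.
    """
    out = Path(out_dir)
    (out / "audio").mkdir(parents=True, exist_ok=True)
    (out / "transcripts").mkdir(exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    lex = lexicon or default_lexicon()

    root = np.random.SeedSequence(config.seed)
    profile_seed, order_seed, row_root = root.spawn(3)
    prof_rng = np.random.default_rng(profile_seed)
    order_rng = np.random.default_rng(order_seed)

    n_bg = len(lex.background_topics)
    profiles = {f"S{idx:03d}": sample_profile(prof_rng, n_bg)
                for idx in range(1, config.n_subjects + 1)}
    session_order = {
        sid: list(order_rng.permutation(len(config.conditions)))
        for sid in profiles
    }

    rows = []
    truth: dict[str, dict] = {}
    row_seeds = row_root.spawn(config.n_subjects * len(config.conditions)
                               * len(config.tasks))
    i = 0
    for sid, profile in profiles.items():
        for c_idx, condition in enumerate(config.conditions):
            session = session_order[sid].index(c_idx) + 1
            for task in config.tasks:
                eff = config.effects_for(condition, task)
                seed_seq = row_seeds[i]
                i += 1
                wav_seq, txt_seq, ann_seq = seed_seq.spawn(3)
                wave, vtruth = synth_voice(profile, eff, config.duration_s,
                                           config.sample_rate, wav_seq)
                w = max(0.0, min(1.0, profile.base_concept_weight
                                 + eff.concept_weight))
                text = synth_transcript(profile, w, CONCEPTS, lex, txt_seq,
                                        hapax_factor=eff.hapax_factor)

                stem = f"{sid}_{condition}_{task}"
                audio_path = out / "audio" / f"{stem}.wav"
                wavfile.write(audio_path, config.sample_rate,
                              np.clip(wave * 32767, -32767, 32767).astype(np.int16))
                txt_path = out / "transcripts" / f"{stem}.txt"
                txt_path.write_text(text, encoding="utf-8")

                ann_path = ""
                if task == "Description":
                    ann_rng = np.random.default_rng(ann_seq)
                    ivs = _interviewer_annotations(ann_rng, config.duration_s,
                                                   vtruth["pause_intervals"])
                    p = out / "annotations" / f"{stem}.csv"
                    with open(p, "w", encoding="utf-8") as fh:
                        fh.write("start_s,end_s\n")
                        for a, b in ivs:
                            fh.write(f"{a:.3f},{b:.3f}\n")
                    ann_path = str(p)

                rows.append({
                    "subject_id": sid, "session": session,
                    "condition": condition, "task": task,
                    "audio_path": str(audio_path),
                    "transcript_path": str(txt_path),
                    "annotation_path": ann_path,
                })
                truth[stem] = {
                    **vtruth,
                    "concept_weight": w,
                    "hapax_factor": eff.hapax_factor,
                    "base_f0": profile.base_f0,
                    "n_tokens": len(text.split()),
                }

    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest.to_csv(out / "manifest.csv", index=False)
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    lex.to_tsv(out / "lexicon.tsv")
    if write_corpus:
        docs = generate_corpus(lex)
        with open(out / "corpus.txt", "w", encoding="utf-8") as fh:
            for doc in docs:
                fh.write(" ".join(doc) + "\n")
    return CohortResult(manifest=manifest, truth=truth, out_dir=out,
                        lexicon=lex)
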