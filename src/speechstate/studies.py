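"""Calibration and power studies on synthetic cohorts.

These drivers tie the generator, extractors, and classifier together into
the two standing experiments the package uses to validate itself:

* **Null calibration** — cohorts in which condition has no effect on any
  generator parameter are pushed through the full pipeline (synthesis ->
  feature extraction -> paired contrasts -> nested LOPO CV); the mean
  held-out accuracy over independent seeds must sit at the 50% chance
  level within Monte-Carlo error.
* **Power curve** — contrast samples with a planted class-mean shift on a
  few features quantify how CV accuracy grows with effect size.

Problem sizes default to desk scale: 70-s recordings at 16 kHz (the
analysis window after 30-s head/tail trimming is 10 s), which keeps a
20-seed calibration run in the minutes range on one CPU while exercising
every stage of the pipeline.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .audio import AcousticConfig
from .classify import (ContrastData, CVResult, make_contrasts, nested_lopo_cv)
from .features import build_feature_table
from .lexicon import default_lexicon
from .semantic import SemanticModel, build_semantic_model
from .synth import CohortConfig, generate_cohort, generate_corpus

log = logging.getLogger(__name__)

NULL_CONDITIONS = ("PBO", "MDMA1.5")
NULL_TASK = "Monologue"


def default_semantic_model(rank: int = 100) -> SemanticModel:
    """LSA model over the packaged (seed-fixed) background corpus."""
    return build_semantic_model(generate_corpus(), rank=rank)


@dataclass
class CalibrationResult:
    accuracies: list[float]
    n_subjects: int
    seeds: list[int]
    cv_results: list[CVResult] = field(repr=False, default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mc_halfwidth(self) -> float:
        """Half-width of the Monte-Carlo 95% band for the mean."""
        n = len(self.accuracies)
        return float(1.96 * np.std(self.accuracies, ddof=1) / np.sqrt(n))

    @property
    def within_chance_band(self) -> bool:
        return abs(self.mean_accuracy - 0.5) <= self.mc_halfwidth


def run_cohort_cv(cohort_seed: int, n_subjects: int,
                  conditions=NULL_CONDITIONS, task: str = NULL_TASK,
                  duration_s: float = 70.0, sample_rate: int = 16000,
                  effect_map: dict | None = None,
                  model: SemanticModel | None = None,
                  cv_seed: int | None = None) -> CVResult:
    """Generate one cohort, extract all 126 features, run nested LOPO CV."""
    model = model or default_semantic_model()
    lex = default_lexicon()
    config = CohortConfig(n_subjects=n_subjects, conditions=tuple(conditions),
                          tasks=(task,), duration_s=duration_s,
                          sample_rate=sample_rate, seed=cohort_seed,
                          effect_map=effect_map or {})
    with tempfile.TemporaryDirectory(prefix="speechstate_") as tmp:
        cohort = generate_cohort(config, tmp, lexicon=lex, write_corpus=False)
        table, _ = build_feature_table(cohort.manifest, model, lex)
    data = make_contrasts(table, conditions[0], conditions[1], task)
    return nested_lopo_cv(data, seed=cv_seed if cv_seed is not None
                          else cohort_seed)


def run_null_calibration(n_subjects: int = 30, n_seeds: int = 20,
                         seed: int = 0, duration_s: float = 70.0,
                         sample_rate: int = 16000,
                         model: SemanticModel | None = None,
                         progress: bool = False) -> CalibrationResult:
    """Null cohorts (no planted effects) through the full pipeline."""
    model = model or default_semantic_model()
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in root.spawn(n_seeds)]
    accs, results = [], []
    for i, s in enumerate(seeds):
        res = run_cohort_cv(s, n_subjects, duration_s=duration_s,
                            sample_rate=sample_rate, model=model)
        accs.append(res.accuracy)
        results.append(res)
        if progress:
            log.info("null seed %d/%d: accuracy %.3f", i + 1, n_seeds,
                     res.accuracy)
    return CalibrationResult(accuracies=accs, n_subjects=n_subjects,
                             seeds=seeds, cv_results=results)


# ---------------------------------------------------------------------------
# feature-level power simulation
# ---------------------------------------------------------------------------

def simulate_contrasts(n_subjects: int, n_features: int = 126,
                       effect: float = 0.0, n_signal: int = 5,
                       seed: int = 0) -> ContrastData:
    """Antisymmetric contrast samples with a planted class-mean shift.

    Each subject's difference vector is unit-variance noise; the first
    ``n_signal`` features get a mean shift of ``effect`` standard
    deviations for the (A-B) class.
    """
    rng = np.random.default_rng(seed)
    X, y, sids = [], [], []
    for i in range(n_subjects):
        d = rng.standard_normal(n_features)
        d[:n_signal] += effect
        X.extend([d, -d])
        y.extend([1, -1])
        sids.extend([f"S{i:03d}"] * 2)
    names = [f"f{i:03d}" for i in range(n_features)]
    return ContrastData(X=np.asarray(X), y=np.asarray(y),
                        subjects=np.asarray(sids), feature_names=names,
                        contrast=("A", "B"), task="sim")


def run_power_curve(effects=(0.0, 0.5, 1.0, 2.0), n_subjects: int = 30,
                    n_seeds: int = 3, seed: int = 0) -> dict[float, float]:
    """Mean nested-CV accuracy per planted effect size."""
    root = np.random.SeedSequence(seed)
    out: dict[float, float] = {}
    for ei, effect in enumerate(effects):
        accs = []
        for si, ss in enumerate(root.spawn(len(effects) * n_seeds)
                                [ei * n_seeds:(ei + 1) * n_seeds]):
            s = int(ss.generate_state(1)[0] % (2 ** 31))
            data = simulate_contrasts(n_subjects, effect=effect, seed=s)
            accs.append(nested_lopo_cv(data, seed=s).accuracy)
        out[float(effect)] = float(np.mean(accs))
    return out
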