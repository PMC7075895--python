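"""Configuration-driven pipeline: cohort -> features -> stats -> classification.

Stages write plain-text artifacts (CSV/JSON/markdown) into the run
directory, and a run record captures the configuration digest, per-stage
wall time, and SHA-256 digests of every artifact, so a re-run with the same
configuration is verifiably identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (make_contrasts, nested_lopo_cv, train_contrast_model,
                       transfer_evaluate, weight_profile)
from .features import META_COLUMNS, build_feature_table, feature_columns
from .lexicon import default_lexicon
from .semantic import build_semantic_model
from .stats import mds_embed, paired_feature_tests, partial_correlations
from .synth import (CohortConfig, ConditionEffects, MANIFEST_COLUMNS,
                    generate_cohort, generate_corpus)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    manifest_path: str | None = None      # use an existing cohort ...
    synth: dict | None = None             # ... or generate one
    domains: tuple[str, ...] = ("acoustic", "semantic", "psycholinguistic")
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("MDMA1.5", "PBO")])
    tasks: list[str] = field(default_factory=lambda: ["Monologue"])
    lsa_rank: int = 100
    fdr_q: float = 0.05
    network_features: list[str] | None = None   # override FDR-passing set
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        payload = yaml.safe_load(Path(path).read_text())
        payload["contrasts"] = [tuple(c) for c in payload.get("contrasts", [])] \
            or [("MDMA1.5", "PBO")]
        return cls(**payload)

    def cohort_config(self) -> CohortConfig:
        synth = dict(self.synth or {})
        effect_map = {}
        for key, eff in (synth.pop("effect_map", None) or {}).items():
            cond, _, task = key.partition("/")
            effect_map[(cond, task) if task else cond] = ConditionEffects(**eff)
        synth.setdefault("seed", self.seed)
        return CohortConfig(effect_map=effect_map, **synth)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunRecord:
    config_digest: str
    version: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    artifact_digests: dict[str, str] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def validate_manifest(path: str | Path,
                      conditions: tuple[str, ...] | None = None,
                      tasks: tuple[str, ...] | None = None) -> dict:
    """Schema, label, and design-completeness checks for a cohort manifest.

    Unknown condition/task labels are fatal; subjects with incomplete
    designs are flagged (they will be excluded at contrast time).
    """
    path = Path(path)
    try:
        manifest = pd.read_csv(path)
    except Exception as err:
        raise ValueError(f"{path}: malformed CSV ({err})") from err
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    conditions = conditions or tuple(sorted(manifest["condition"].unique()))
    tasks = tasks or tuple(sorted(manifest["task"].unique()))
    bad_cond = set(manifest["condition"]) - set(conditions)
    bad_task = set(manifest["task"]) - set(tasks)
    if bad_cond or bad_task:
        raise ValueError(f"{path}: unknown labels: "
                         f"conditions={sorted(bad_cond)} tasks={sorted(bad_task)}")
    expected = len(conditions) * len(tasks)
    incomplete = []
    for sid, grp in manifest.groupby("subject_id"):
        cells = set(zip(grp["condition"], grp["task"]))
        if len(cells) != expected or len(grp) != expected:
            incomplete.append(str(sid))
    report = {
        "n_rows": len(manifest), "n_subjects": manifest["subject_id"].nunique(),
        "conditions": list(conditions), "tasks": list(tasks),
        "incomplete_subjects": incomplete, "ok": True,
    }
    if incomplete:
        log.warning("subjects with incomplete designs: %s", incomplete)
    return report


def run_pipeline(config: RunConfig) -> RunRecord:
    """Execute every stage and write the output tree.

    Artifacts: manifest (if synthesized), feature table + missingness mask,
    per-contrast test tables, partial-correlation matrices, MDS
    coordinates, CV result JSONs, weight profiles, and a markdown report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = RunRecord(config_digest=config.digest(), version=__version__)
    lex = default_lexicon()

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.time()

            def __exit__(self, *exc):
                record.stage_seconds[stage] = round(time.time() - self.t0, 3)
        return _T()

    # -- cohort ------------------------------------------------------------
    with timed("synth"):
        if config.manifest_path:
            manifest = pd.read_csv(config.manifest_path)
            corpus_file = Path(config.manifest_path).parent / "corpus.txt"
        else:
            cohort = generate_cohort(config.cohort_config(), out / "cohort",
                                     lexicon=lex)
            manifest = cohort.manifest
            corpus_file = cohort.out_dir / "corpus.txt"

    with timed("validate"):
        mpath = config.manifest_path or out / "cohort" / "manifest.csv"
        validation = validate_manifest(mpath)
        (out / "manifest_validation.json").write_text(
            json.dumps(validation, indent=1))

    # -- semantic model ----------------------------------------------------
    with timed("semantic_model"):
        if corpus_file.exists():
            docs = [line.split() for line in
                    corpus_file.read_text(encoding="utf-8").splitlines()
                    if line.strip()]
        else:
            docs = generate_corpus(lex)
        model = build_semantic_model(docs, rank=config.lsa_rank)

    # -- features ----------------------------------------------------------
    with timed("features"):
        table, mask = build_feature_table(manifest, model, lex,
                                          domains=config.domains)
        table.to_csv(out / "features.csv", index=False)
        mask.to_csv(out / "missing_mask.csv", index=False)

    # -- group statistics --------------------------------------------------
    report_lines = [f"# Pipeline report (config {record.config_digest})", ""]
    with timed("stats"):
        all_tests = []
        for a, b in config.contrasts:
            for task in config.tasks:
                all_tests.append(paired_feature_tests(table, a, b, task,
                                                      q=config.fdr_q))
        tests = pd.concat(all_tests, ignore_index=True)
        tests.to_csv(out / "paired_tests.csv", index=False)
        n_sig = int(tests["reject"].sum())
        report_lines += [f"## Univariate tests",
                         f"{len(tests)} paired Wilcoxon tests; "
                         f"{n_sig} pass BH-FDR at q<{config.fdr_q}.", ""]

        selected = config.network_features or sorted(
            tests.loc[tests["reject"], "feature"].unique())
        if len(selected) >= 2:
            matrices, labels = [], []
            for cond in manifest["condition"].unique():
                for task in config.tasks:
                    rows = table[(table["condition"] == cond)
                                 & (table["task"] == task)]
                    data = rows[selected].to_numpy(dtype=float)
                    keep = data.std(axis=0, ddof=1) > 0
                    if len(rows) < 3 or keep.sum() < 2:
                        continue
                    names = [s for s, k in zip(selected, keep) if k]
                    pc = partial_correlations(data[:, keep],
                                              feature_names=names)
                    fn = out / f"partial_corr_{cond}_{task}.csv"
                    pc.to_csv(fn)
                    matrices.append(pc)
                    labels.append(f"{cond}/{task}")
            common = set.intersection(*(set(m.index) for m in matrices)) \
                if matrices else set()
            if len(matrices) >= 3 and len(common) >= 2:
                order = sorted(common)
                emb = mds_embed([m.loc[order, order] for m in matrices],
                                labels)
                pd.DataFrame(emb.coordinates, index=labels,
                             columns=["dim1", "dim2"]) \
                    .to_csv(out / "mds_coordinates.csv")
                report_lines += ["## Correlation structure",
                                 f"Partial correlations over "
                                 f"{len(order)} features; MDS stress "
                                 f"{emb.stress:.3f}.", ""]
        else:
            log.info("fewer than 2 FDR-passing features: network stage "
                     "skipped")

    # -- classification ----------------------------------------------------
    with timed("classify"):
        report_lines.append("## Classification")
        for a, b in config.contrasts:
            for task in config.tasks:
                data = make_contrasts(table, a, b, task)
                res = nested_lopo_cv(data, seed=config.seed)
                stem = f"cv_{a}_vs_{b}_{task}"
                (out / f"{stem}.json").write_text(
                    json.dumps(res.to_dict(), indent=1))
                marker = ("**" if res.p_value < 0.001 else
                          "*" if res.p_value < 0.05 else "")
                report_lines.append(
                    f"- {a} vs {b} ({task}): accuracy "
                    f"{100 * res.accuracy:.1f}%{marker} "
                    f"(binomial p={res.p_value:.3g}, "
                    f"n={res.n_total} samples)")
                final = train_contrast_model(data, seed=config.seed)
                if final.classifier_id == "svm":
                    w = weight_profile(final.classifier.coef_.ravel(),
                                       final.selected_features)
                    w.sort_values(ascending=False).to_csv(
                        out / f"weights_{stem}.csv",
                        header=["relative_contribution"])
                    top = w[w > 0.10]
                    if len(top):
                        report_lines.append(
                            "  top features (>10%): "
                            + ", ".join(f"{n} ({100 * v:.0f}%)"
                                        for n, v in
                                        top.sort_values(ascending=False)
                                        .items()))

    (out / "report.md").write_text("\n".join(report_lines) + "\n")
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.suffix in (".csv", ".json", ".md"):
            record.artifact_digests[str(f.relative_to(out))] = _sha256(f)
    record.save(out / "run_record.json")
    return record
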