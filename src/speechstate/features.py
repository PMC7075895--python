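"""Cohort feature-table assembly.

One row per (subject, condition, task) with 126 feature columns: 88
acoustic (prefix ``A-``), 21 semantic (``S-``), 17 psycholinguistic
(``P-``).  Records whose audio is unreadable are excluded with a logged
reason (the analysis assumes every retained subject has a complete set of
usable recordings).  Missing feature values are imputed with the cohort
median at assembly time and flagged in a companion missingness mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import audio as audio_mod
from .lexicon import CONCEPTS, Lexicon, default_lexicon
from .semantic import SemanticModel, extract_semantic
from .text import (PSYCHOLINGUISTIC_FEATURES, clean_and_tag,
                   extract_psycholinguistic)

log = logging.getLogger(__name__)

META_COLUMNS = ("subject_id", "session", "condition", "task")
DOMAINS = ("acoustic", "semantic", "psycholinguistic")


@dataclass
class SessionRecord:
    subject_id: str
    session: int
    condition: str
    task: str
    audio_path: str
    transcript_path: str
    annotation_path: str = ""


def feature_columns(domains=DOMAINS,
                    concepts: tuple[str, ...] = CONCEPTS) -> list[str]:
    """Prefixed column names for the requested feature domains."""
    cols: list[str] = []
    if "acoustic" in domains:
        cols += [f"A-{n}" for n in audio_mod.load_inventory()]
    if "semantic" in domains:
        cols += [f"S-{c.capitalize()}" for c in concepts]
    if "psycholinguistic" in domains:
        cols += [f"P-{n}" for n in PSYCHOLINGUISTIC_FEATURES]
    return cols


def records_from_manifest(manifest: pd.DataFrame) -> list[SessionRecord]:
    return [SessionRecord(subject_id=r.subject_id, session=int(r.session),
                          condition=r.condition, task=r.task,
                          audio_path=r.audio_path,
                          transcript_path=r.transcript_path,
                          annotation_path=(r.annotation_path
                                           if isinstance(r.annotation_path, str)
                                           else ""))
            for r in manifest.itertuples()]


def extract_record(record: SessionRecord, model: SemanticModel | None,
                   lexicon: Lexicon | None = None,
                   domains=DOMAINS,
                   concepts: tuple[str, ...] = CONCEPTS,
                   acoustic_config: audio_mod.AcousticConfig | None = None
                   ) -> dict[str, float]:
    """All requested features for one session recording/transcript."""
    lex = lexicon or default_lexicon()
    feats: dict[str, float] = {}
    if "acoustic" in domains:
        ac = audio_mod.extract_acoustic(record.audio_path,
                                        record.annotation_path or None,
                                        acoustic_config)
        feats.update({f"A-{k}": v for k, v in ac.items()})
    if "semantic" in domains or "psycholinguistic" in domains:
        raw = Path(record.transcript_path).read_text(encoding="utf-8")
        ct = clean_and_tag(raw, lex)
        if "semantic" in domains:
            if model is None:
                raise ValueError("semantic extraction requires a model")
            sem = extract_semantic(ct, model, concepts)
            feats.update({f"S-{k.capitalize()}": v for k, v in sem.items()})
        if "psycholinguistic" in domains:
            psy = extract_psycholinguistic(ct)
            feats.update({f"P-{k}": v for k, v in psy.items()})
    return feats


def build_feature_table(manifest: pd.DataFrame,
                        model: SemanticModel | None = None,
                        lexicon: Lexicon | None = None,
                        domains=DOMAINS,
                        concepts: tuple[str, ...] = CONCEPTS,
                        acoustic_config=None, impute: bool = True
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract features for every manifest row.

    Returns (table, missingness mask); both have the metadata columns and
    one column per feature.  Unreadable recordings exclude the record (not
    the run); missing values are imputed with the per-column cohort median.
    """
    cols = feature_columns(domains, concepts)
    rows, meta = [], []
    for rec in records_from_manifest(manifest):
        try:
            feats = extract_record(rec, model, lexicon, domains, concepts,
                                   acoustic_config)
        except (OSError, ValueError) as err:
            log.warning("excluding %s/%s/%s: %s", rec.subject_id,
                        rec.condition, rec.task, err)
            continue
        rows.append([feats.get(c, np.nan) for c in cols])
        meta.append([rec.subject_id, rec.session, rec.condition, rec.task])
    if not rows:
        raise ValueError("no usable records in manifest")
    values = np.asarray(rows, dtype=float)
    mask = ~np.isfinite(values)
    if impute and mask.any():
        med = np.nanmedian(values, axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        values = np.where(mask, med[None, :], values)
        log.info("imputed %d missing values with cohort medians",
                 int(mask.sum()))
    meta_df = pd.DataFrame(meta, columns=list(META_COLUMNS))
    table = pd.concat([meta_df, pd.DataFrame(values, columns=cols)], axis=1)
    mask_df = pd.concat([meta_df, pd.DataFrame(mask, columns=cols)], axis=1)
    return table, mask_df
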