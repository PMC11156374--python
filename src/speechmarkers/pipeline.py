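"""End-to-end orchestration: extract -> analyze -> classify -> generalize.

Ties the stages together around a single run configuration, stamps
every artifact with the configuration hash and seed, and reproduces the
full analysis recipe: per patient group, 2x2 mixed ANOVAs on the ratio
families with Tukey HSD post hocs, one-tailed t tests on the lexical
properties, FDR correction within each analysis block, outlier
screening, feature-cognition correlations, and the two binary SVM
classification tasks with optional hold-out generalizability.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify as clf
from . import stats as st
from .corpus import Transcript, load_corpus
from .features import (
    FEATURE_NAMES,
    EmbeddingTable,
    FeatureConfig,
    extract_features,
    features_table,
    load_property_lexicon,
)
from .tagging import TagLexicon, load_tag_lexicon

logger = logging.getLogger(__name__)

#: directional hypotheses for the one-tailed property tests: patients
#: are expected to use more frequent, better-connected, shorter and
#: semantically steadier vocabulary than controls.
DEFAULT_T_DIRECTIONS: dict[str, str] = {
    "mean_log_freq": "greater",
    "mean_phon_neighbors": "greater",
    "mean_length": "less",
    "semantic_variability": "less",
}

PROPERTY_FEATURES = list(DEFAULT_T_DIRECTIONS)


@dataclass
class RunConfig:
    manifest: str
    lexicon: str
    tag_lexicon: str
    embeddings: str
    outdir: str
    holdout_manifest: str | None = None
    suffix_rules: str | None = None
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    t_directions: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_T_DIRECTIONS))
    correlation_method: str = "spearman"
    folds: int = 5
    iterations: int = 1000
    svm_c: float = 1.0
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def extract_corpus_features(
    transcripts: Sequence[Transcript],
    tag_lexicon: TagLexicon,
    property_lexicon: Mapping,
    embeddings: EmbeddingTable,
    config: FeatureConfig | None = None,
    split: str | None = None,
) -> pd.DataFrame:
    rows = [
        extract_features(t, tag_lexicon, property_lexicon, embeddings, config)
        for t in transcripts
    ]
    return features_table(rows, split=split)


def _ratio_block(
    df: pd.DataFrame, patient_group: str, value_cols: tuple[str, str]
) -> dict:
    """Mixed ANOVA + FDR + Tukey post hocs for one ratio family."""
    sub = df[df.group.isin([patient_group, "HC"])].dropna(subset=list(value_cols))
    long = st.wide_to_long(sub, value_cols)
    aov = st.mixed_anova_2x2(long)
    results = st.apply_fdr([aov["group"], aov["within"], aov["interaction"]])
    # pooled-MSE convention for the post hocs: average of the two error
    # mean squares, error df = N - 2
    tukey = st.tukey_hsd(long, mse=aov.mse_pooled, df_error=aov.df_error)
    st.apply_fdr(tukey)
    return {
        "anova": {r.name: r.as_dict() for r in results},
        "tukey": [r.as_dict() for r in tukey],
        "mse": aov.mse_pooled,
        "df_error": aov.df_error,
    }


def _property_block(df: pd.DataFrame, patient_group: str, directions: Mapping[str, str]) -> dict:
    pat = df[df.group == patient_group]
    hc = df[df.group == "HC"]
    results = []
    for feat in PROPERTY_FEATURES:
        x = pat[feat].dropna().to_numpy(dtype=float)
        y = hc[feat].dropna().to_numpy(dtype=float)
        r = st.one_tailed_t(x, y, direction=directions.get(feat, "greater"))
        r.name = feat
        results.append(r)
    st.apply_fdr(results)
    return {r.name: r.as_dict() for r in results}


def _outlier_block(df: pd.DataFrame) -> dict:
    flagged: dict[str, list[str]] = {}
    for group, sub in df.groupby("group"):
        for feat in FEATURE_NAMES:
            vals = sub[feat].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            if ok.sum() >= 3:
                flags = st.outlier_screen(vals[ok])
                ids = sub.loc[sub.index[ok][flags], "participant_id"].tolist()
                if ids:
                    flagged.setdefault(f"{group}:{feat}", []).extend(ids)
    return flagged


def analyze_features(
    df: pd.DataFrame,
    *,
    t_directions: Mapping[str, str] | None = None,
    correlation_method: str = "spearman",
) -> dict:
    """The full group-level statistical report for a features table."""
    t_directions = t_directions or DEFAULT_T_DIRECTIONS
    report: dict = {"groups": sorted(df.group.unique().tolist()), "n": len(df)}
    score_cols = [c for c in ("MoCA", "IFS") if c in df.columns]
    for group in ("AD", "bvFTD"):
        if group not in set(df.group):
            continue
        block = {
            "word_class": _ratio_block(df, group, ("noun_ratio", "verb_ratio")),
            "person": _ratio_block(df, group, ("first_person_ratio", "third_person_ratio")),
            "properties": _property_block(df, group, t_directions),
        }
        if score_cols:
            pat_only = df[df.group == group]
            pooled = df[df.group.isin([group, "HC"])]
            block["correlations"] = {
                "patients_only": st.correlation_grid(
                    pat_only, FEATURE_NAMES, score_cols, method=correlation_method
                ).to_dict(orient="records"),
                "patients_plus_hc": st.correlation_grid(
                    pooled, FEATURE_NAMES, score_cols, method=correlation_method
                ).to_dict(orient="records"),
            }
        report[f"{group}_vs_HC"] = block
    report["outliers_3sd"] = _outlier_block(df)
    return report


def classification_matrix(df: pd.DataFrame, patient_group: str) -> tuple[pd.DataFrame, np.ndarray]:
    sub = df[df.group.isin([patient_group, "HC"])]
    X = sub[FEATURE_NAMES].astype(float)
    y = (sub.group == patient_group).to_numpy(dtype=int)
    return X, y


def classify_tasks(
    df: pd.DataFrame,
    *,
    folds: int = 5,
    iterations: int = 1000,
    C: float = 1.0,
    seed: int = 0,
) -> dict:
    """Both binary tasks (AD vs HC, bvFTD vs HC) with repeated CV."""
    out: dict = {}
    for i, group in enumerate(("AD", "bvFTD")):
        if group not in set(df.group):
            continue
        X, y = classification_matrix(df, group)
        report = clf.run_repeated_cv(
            X, y, k=folds, iterations=iterations, C=C, seed=seed + i
        )
        out[f"{group}_vs_HC"] = report.as_dict()
    return out


def generalizability_tasks(
    df_main: pd.DataFrame, df_holdout: pd.DataFrame, *, C: float = 1.0
) -> dict:
    out: dict = {}
    for group in ("AD", "bvFTD"):
        if group not in set(df_main.group) or group not in set(df_holdout.group):
            continue
        X_tr, y_tr = classification_matrix(df_main, group)
        X_te, y_te = classification_matrix(df_holdout, group)
        report = clf.generalizability_eval(
            X_tr, y_tr, X_te, y_te,
            train_ids=df_main.loc[X_tr.index, "participant_id"],
            test_ids=df_holdout.loc[X_te.index, "participant_id"],
            C=C,
        )
        out[f"{group}_vs_HC"] = report.as_dict()
    return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all stages and write the artifact bundle to ``outdir``.

    Outputs: features.csv (+ holdout_features.csv), stats.json,
    classification.json, generalizability.json when a hold-out manifest
    is given, and run.json with the configuration hash and seed.
    Identical configuration implies identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    tag_lex = load_tag_lexicon(config.tag_lexicon, config.suffix_rules)
    prop_lex = load_property_lexicon(config.lexicon)
    embeddings = EmbeddingTable.from_tsv(config.embeddings)

    transcripts = load_corpus(config.manifest)
    df = extract_corpus_features(
        transcripts, tag_lex, prop_lex, embeddings, config.feature_config, split="main"
    )
    artifacts: dict[str, Path] = {}
    df.to_csv(outdir / "features.csv", index=False)
    artifacts["features"] = outdir / "features.csv"

    stats_report = analyze_features(
        df, t_directions=config.t_directions, correlation_method=config.correlation_method
    )
    stats_report.update(stamp)
    (outdir / "stats.json").write_text(json.dumps(stats_report, indent=1, default=float))
    artifacts["stats"] = outdir / "stats.json"

    cls_report = classify_tasks(
        df, folds=config.folds, iterations=config.iterations, C=config.svm_c, seed=config.seed
    )
    cls_report.update(stamp)
    (outdir / "classification.json").write_text(json.dumps(cls_report, indent=1, default=float))
    artifacts["classification"] = outdir / "classification.json"

    if config.holdout_manifest:
        holdout = load_corpus(config.holdout_manifest)
        df_h = extract_corpus_features(
            holdout, tag_lex, prop_lex, embeddings, config.feature_config, split="holdout"
        )
        df_h.to_csv(outdir / "holdout_features.csv", index=False)
        artifacts["holdout_features"] = outdir / "holdout_features.csv"
        gen_report = generalizability_tasks(df, df_h, C=config.svm_c)
        gen_report.update(stamp)
        (outdir / "generalizability.json").write_text(
            json.dumps(gen_report, indent=1, default=float)
        )
        artifacts["generalizability"] = outdir / "generalizability.json"

    (outdir / "run.json").write_text(json.dumps(stamp, indent=1))
    logger.info("pipeline complete: %s", {k: str(v) for k, v in artifacts.items()})
    return artifacts
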