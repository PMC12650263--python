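"""End-to-end analysis pipeline: score all modalities, assemble the
participant x variable table, filter outliers, run the permutation
correlation matrix, sleep-group Mann-Whitney comparisons, and the
HVHA-deviation -> mean-score regression.

Every stage is also callable on its own; the pipeline adds no hidden
state, so composing the modules manually on the same inputs yields the
same outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .affect_space import hvha_deviation
from .blink_sebr import BlinkConfig, detect_blinks, summarize_sebr
from .errors import ValidationError
from .io import (
    read_art_ratings,
    read_eye_signals,
    read_questionnaires,
    read_wm_trials,
    write_table,
)
from .psychometrics import classify_sleeper, score_erq, score_psqi
from .sentiment_text import text_features
from .stats_validation import (
    CorrelationResult,
    GroupComparison,
    OutlierReport,
    RegressionReport,
    filter_outliers,
    mann_whitney,
    ols_fit,
    permutation_correlation_matrix,
)
from .wm_game import score_session

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "PAPER_VARIABLES",
    "FULL_VARIABLES",
    "assemble_cohort_table",
    "run_pipeline",
]

log = logging.getLogger("create_lab.pipeline")

#: Variable set used in the published analysis: three game metrics, the
#: three ER scores, six sleep components plus the global, the three blink
#: summaries, and all six narrative features.
PAPER_VARIABLES = (
    "num_correct_responses",
    "max_score",
    "mean_score",
    "er_total",
    "er_reappraisal",
    "er_suppression",
    "psqi_subjective_quality",
    "psqi_latency",
    "psqi_duration",
    "psqi_efficiency",
    "psqi_disturbances",
    "psqi_daytime_dysfunction",
    "psqi_global",
    "sebr_pre",
    "sebr_post",
    "sebr_diff",
    "polarity",
    "subjectivity",
    "avg_word_length",
    "token_count",
    "unique_tokens",
    "type_token_ratio",
)

FULL_VARIABLES = PAPER_VARIABLES + (
    "num_total_responses",
    "median_score",
    "count_above_0_25",
    "count_above_0_5",
    "successive_correct_count",
    "psqi_medication",
    "hvha_deviation",
)


@dataclass(frozen=True)
class AnalysisConfig:
    wm_trials: str
    art_ratings: str
    questionnaires: str
    eye_signals: str
    eye_sessions: str
    variables: str = "paper"  # "paper" | "full"
    n_perm: int = 2000
    alpha: float = 0.05
    outlier_k: float = 2.0
    psqi_threshold: int = 5
    seed: int = 0
    output_dir: str | None = None
    blink: BlinkConfig = field(default_factory=BlinkConfig)

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0,1)")
        if self.outlier_k <= 0:
            raise ValidationError("outlier_k must be > 0")
        if self.variables not in ("paper", "full"):
            raise ValidationError("variables must be 'paper' or 'full'")

    @classmethod
    def from_dir(cls, data_dir, **overrides) -> "AnalysisConfig":
        d = Path(data_dir)
        return cls(
            wm_trials=str(d / "wm_trials.csv"),
            art_ratings=str(d / "art_ratings.csv"),
            questionnaires=str(d / "questionnaires.csv"),
            eye_signals=str(d / "eye_signals.csv"),
            eye_sessions=str(d / "eye_sessions.csv"),
            **overrides,
        )

    def provenance(self) -> dict[str, object]:
        cfg = dataclasses.asdict(self)
        cfg["blink"] = dataclasses.asdict(self.blink)
        # the output location does not influence any computed value, so it
        # stays out of the reproducibility fingerprint
        cfg.pop("output_dir", None)
        blob = json.dumps(cfg, sort_keys=True).encode()
        return {
            "config": cfg,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": self.seed,
            "version": __version__,
        }


@dataclass(frozen=True)
class AnalysisReport:
    n_input: int
    n_analyzed: int
    exclusions: OutlierReport
    group_sizes: dict[str, int]
    correlations: CorrelationResult
    group_tests: list[GroupComparison]
    regression: RegressionReport | None
    regression_note: str
    cohort_table: pd.DataFrame
    filtered_table: pd.DataFrame
    provenance: dict


def assemble_cohort_table(config: AnalysisConfig) -> pd.DataFrame:
    """Score every modality and join into one participant x variable table."""
    trials = read_wm_trials(config.wm_trials)
    ratings = read_art_ratings(config.art_ratings)
    questionnaires = read_questionnaires(config.questionnaires)
    signals = read_eye_signals(config.eye_signals, config.eye_sessions)

    known = set(questionnaires)
    orphans = sorted(
        (set(trials) | set(ratings["participant_id"].astype(str)) | set(signals)) - known
    )
    if orphans:
        raise ValidationError(
            f"participants missing from questionnaires: {orphans}"
        )

    rows: dict[str, dict[str, object]] = {}
    for pid in sorted(known):
        row: dict[str, object] = {}
        if pid in trials:
            row.update(score_session(trials[pid]).as_dict())
        qs = questionnaires[pid]
        if "PSQI" in qs:
            row.update(score_psqi(qs["PSQI"], threshold=config.psqi_threshold).as_dict())
        if "ERQ" in qs:
            row.update(score_erq(qs["ERQ"]).as_dict())
        if pid in signals:
            phases = signals[pid]
            if {"pre", "post"} <= set(phases):
                pre = detect_blinks(phases["pre"].ratio, phases["pre"].fps, config.blink)
                post = detect_blinks(phases["post"].ratio, phases["post"].fps, config.blink)
                row.update(summarize_sebr(pre, post).as_dict())
        rows[pid] = row

    # per-participant means of the six narrative features
    feature_cols = (
        "polarity",
        "subjectivity",
        "avg_word_length",
        "token_count",
        "unique_tokens",
        "type_token_ratio",
    )
    feats = pd.DataFrame(
        [
            {"participant_id": str(r.participant_id), **text_features(str(r.comment)).as_dict()}
            for r in ratings.itertuples()
        ]
    )
    if len(feats):
        means = feats.groupby("participant_id")[list(feature_cols)].mean()
        for pid, vals in means.iterrows():
            rows.setdefault(str(pid), {}).update(vals.to_dict())

    dev = hvha_deviation(ratings)
    for pid, val in dev.items():
        rows.setdefault(str(pid), {})["hvha_deviation"] = float(val)

    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "participant_id"
    return table


def _selected_columns(config: AnalysisConfig, table: pd.DataFrame) -> list[str]:
    wanted = PAPER_VARIABLES if config.variables == "paper" else FULL_VARIABLES
    return [c for c in wanted if c in table.columns]


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    t0 = time.perf_counter()
    table = assemble_cohort_table(config)
    log.info("assembled cohort table: %d participants (%.2fs)", len(table), time.perf_counter() - t0)

    cols = _selected_columns(config, table)
    analysis = table[cols].astype(float)
    filtered, report = filter_outliers(analysis, k=config.outlier_k)
    log.info(
        "outlier filter: %d -> %d participants (excluded: %s)",
        report.n_before,
        report.n_after,
        sorted(report.excluded),
    )

    corr = permutation_correlation_matrix(
        filtered, n_perm=config.n_perm, alpha=config.alpha, seed=config.seed
    )

    groups = table.loc[filtered.index, "psqi_global"].map(
        lambda g: classify_sleeper(int(g), config.psqi_threshold)
    )
    group_sizes = groups.value_counts().to_dict()
    comparisons: list[GroupComparison] = []
    if groups.nunique() == 2:
        good_idx = groups[groups == "Good"].index
        poor_idx = groups[groups == "Poor"].index
        for col in filtered.columns:
            a = filtered.loc[good_idx, col].dropna()
            b = filtered.loc[poor_idx, col].dropna()
            if len(a) == 0 or len(b) == 0:
                continue
            comparisons.append(mann_whitney(a.to_numpy(), b.to_numpy(), variable=col))
    else:
        log.warning("only one sleep group present; skipping group comparisons")

    regression: RegressionReport | None = None
    note = ""
    if "hvha_deviation" in table.columns and "mean_score" in table.columns:
        sub = table.loc[filtered.index, ["hvha_deviation", "mean_score"]].dropna()
        try:
            regression = ols_fit(sub["hvha_deviation"], sub["mean_score"])
        except ValidationError as err:
            note = f"regression skipped: {err}"
            log.warning(note)
    else:
        note = "regression skipped: hvha_deviation or mean_score unavailable"

    result = AnalysisReport(
        n_input=len(table),
        n_analyzed=len(filtered),
        exclusions=report,
        group_sizes={str(k): int(v) for k, v in group_sizes.items()},
        correlations=corr,
        group_tests=comparisons,
        regression=regression,
        regression_note=note,
        cohort_table=table,
        filtered_table=filtered,
        provenance=config.provenance(),
    )
    if config.output_dir:
        write_report(result, config.output_dir)
    log.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return result


def write_report(report: AnalysisReport, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(report.cohort_table.reset_index(), outdir / "cohort_table.csv")
    write_table(report.filtered_table.reset_index(), outdir / "filtered_table.csv")
    write_table(report.correlations.to_long(), outdir / "correlations.csv")
    write_table(
        report.correlations.rho.reset_index(names="variable"), outdir / "rho_matrix.csv"
    )
    write_table(
        report.correlations.p_empirical.reset_index(names="variable"),
        outdir / "p_matrix.csv",
    )
    write_table(
        pd.DataFrame([gc.as_dict() for gc in report.group_tests]),
        outdir / "group_tests.csv",
    )
    with open(outdir / "regression_report.json", "w", encoding="utf-8") as fh:
        payload = report.regression.as_dict() if report.regression else {"note": report.regression_note}
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    summary = {
        "n_input": report.n_input,
        "n_analyzed": report.n_analyzed,
        "excluded": {str(k): v for k, v in report.exclusions.excluded.items()},
        "group_sizes": report.group_sizes,
        "n_significant_cells": int(report.correlations.mask.to_numpy().sum() // 2),
        "alpha": report.correlations.alpha,
        "n_perm": report.correlations.n_perm,
        "provenance": report.provenance,
    }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
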