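"""Supporting engineering: schemas, questionnaire scoring, validation,
run configuration and the end-to-end pipeline.

Conventions fixed here: all CSV interchange is UTF-8, comma-separated,
header row, '.' decimal, full double precision. Questionnaire scoring
keys (item sets, reverse-coded items, admissible ranges, subscales)
live in editable JSON files shipped under ``questionnaire_keys/``; the
package computes sum scores from a key rather than hard-coding any
instrument. Every random draw flows from the run's single seed through
named substreams, so two runs with equal configs are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import schema
from .schema import RATING_MAX, RATING_MIN, SENTIMENTS, TRAITS
from .cohort_analysis import (
    compare_cohorts,
    infer_stimulus_ids,
    sentiment_associations,
    sensitivity_boredom_link,
    summarize_ratings,
)
from .synthetic_data import (
    CohortGenConfig,
    StimulusGenConfig,
    default_clinical_config,
    default_control_config,
    generate_two_cohorts,
)
from .text_metrics import ComplexityProfile, profiles_to_frame
from .transmission_model import build_design, fit_cohort, shuffled_null

__all__ = [
    "QuestionnaireKey",
    "ScoreResult",
    "ValidationReport",
    "RunConfig",
    "load_questionnaire_key",
    "score_questionnaire",
    "validate_dataset",
    "load_profiles_csv",
    "run_pipeline",
]

logger = logging.getLogger("infotrans")


# ---------------------------------------------------------------------------
# questionnaire scoring

@dataclass(frozen=True)
class QuestionnaireKey:
    """Scoring key for a sum-score questionnaire.

    ``reverse_items`` are mapped as ``range_max + range_min - response``
    before summing. Subscales group items; a scale with no subscale
    structure uses a single subscale named after the scale.
    """

    name: str
    items: tuple[str, ...]
    response_range: tuple[float, float]
    reverse_items: tuple[str, ...] = ()
    subscales: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if not set(self.reverse_items) <= set(self.items):
            raise ValueError("reverse_items must be a subset of items")
        lo, hi = self.response_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("response_range must be finite with min < max")
        for sub, sub_items in self.subscales.items():
            if not set(sub_items) <= set(self.items):
                raise ValueError(f"subscale {sub!r} references unknown items")

    @property
    def effective_subscales(self) -> dict[str, tuple[str, ...]]:
        if self.subscales:
            return {k: tuple(v) for k, v in self.subscales.items()}
        return {self.name: self.items}

    @classmethod
    def from_json(cls, path: str | Path) -> "QuestionnaireKey":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            name=d["name"],
            items=tuple(d["items"]),
            response_range=tuple(d["response_range"]),
            reverse_items=tuple(d.get("reverse_items", ())),
            subscales={k: tuple(v) for k, v in d.get("subscales", {}).items()},
        )


def load_questionnaire_key(name: str) -> QuestionnaireKey:
    """Load one of the bundled key templates (bfi10, bps, msbs, stai_y, brs)."""
    ref = resources.files("infotrans").joinpath(f"questionnaire_keys/{name}.json")
    with resources.as_file(ref) as path:
        return QuestionnaireKey.from_json(path)


@dataclass(frozen=True)
class ScoreResult:
    scores: dict[str, float]       # subscale -> sum score (only complete ones)
    excluded: tuple[str, ...]      # subscales with skipped items


def score_questionnaire(responses: Mapping[str, float],
                        key: QuestionnaireKey) -> ScoreResult:
    """Sum-score a participant's item responses under a key.

    A missing item excludes only the affected subscale (flagged), not
    the participant; an out-of-range response is an error naming the
    item.
    """
    lo, hi = key.response_range
    coded: dict[str, float] = {}
    for item in key.items:
        v = responses.get(item)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        if not lo <= v <= hi:
            raise ValueError(
                f"response {v!r} for item {item!r} outside range [{lo}, {hi}]")
        coded[item] = hi + lo - v if item in key.reverse_items else float(v)
    scores: dict[str, float] = {}
    excluded: list[str] = []
    for sub, sub_items in key.effective_subscales.items():
        if all(i in coded for i in sub_items):
            scores[sub] = float(sum(coded[i] for i in sub_items))
        else:
            excluded.append(sub)
    return ScoreResult(scores=scores, excluded=tuple(excluded))


# ---------------------------------------------------------------------------
# dataset validation

@dataclass
class ValidationReport:
    violations: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, kind: str, message: str, row: int | None = None) -> None:
        self.violations.append({"kind": kind, "message": message, "row": row})

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.violations)


def validate_dataset(
    participants: pd.DataFrame,
    profiles: list[ComplexityProfile] | pd.DataFrame,
    known_cohorts: tuple[str, ...] | None = None,
) -> ValidationReport:
    """Check a participant table against the rating schema.

    Structural problems (missing required columns) raise; value-level
    problems (out-of-range ratings, incomplete texts, duplicate ids,
    unknown cohort labels) become report entries with row references.
    """
    report = ValidationReport()
    required = [schema.ID_COL, schema.COHORT_COL]
    missing = [c for c in required if c not in participants.columns]
    if missing:
        raise ValueError(f"participant table lacks required columns: {missing}")

    if isinstance(profiles, pd.DataFrame):
        stim_ids = profiles["stimulus_id"].tolist()
    else:
        stim_ids = [p.stimulus_id for p in profiles]

    dup = participants[schema.ID_COL][participants[schema.ID_COL].duplicated()]
    for idx, pid in dup.items():
        report.add("duplicate_id", f"participant id {pid!r} duplicated", row=int(idx))

    if known_cohorts is not None:
        bad = ~participants[schema.COHORT_COL].isin(known_cohorts)
        for idx in participants.index[bad]:
            report.add("unknown_cohort",
                       f"cohort {participants.loc[idx, schema.COHORT_COL]!r} "
                       f"not in {known_cohorts}", row=int(idx))

    for sent in SENTIMENTS:
        for sid in stim_ids:
            col = schema.rating_col(sent, sid)
            if col not in participants.columns:
                report.add("missing_rating_column", f"column {col!r} absent")
                continue
            vals = participants[col]
            for idx in participants.index[vals.isna()]:
                report.add("incomplete_ratings",
                           f"{col}: missing value (texts incomplete)", row=int(idx))
            out = vals.notna() & ((vals < RATING_MIN) | (vals > RATING_MAX))
            for idx in participants.index[out]:
                report.add(
                    "rating_out_of_bounds",
                    f"{col}={vals.loc[idx]} outside [{RATING_MIN}, {RATING_MAX}]",
                    row=int(idx))
    return report


def load_profiles_csv(path: str | Path) -> list[ComplexityProfile]:
    """Rehydrate minimal profiles (id, counts, H_cum) from a profiles CSV."""
    frame = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, row in frame.iterrows():
        out.append(ComplexityProfile(
            stimulus_id=str(row["stimulus_id"]),
            token_count=int(row.get("token_count", 0) or 0),
            unique_count=int(row.get("unique_count", 0) or 0),
            prefix_entropies=np.array([]),
            cumulated_entropy=float(row["H_cum"]),
            vocabulary=np.array([], dtype=np.intp),
            semantic_diversity=(float(row["semantic_diversity"])
                                if "semantic_diversity" in row and
                                pd.notna(row["semantic_diversity"]) else None),
        ))
    return out


# ---------------------------------------------------------------------------
# run configuration and pipeline

@dataclass(frozen=True)
class RunConfig:
    """One pipeline run, fully serializable.

    With ``simulate=True`` (default) the pipeline generates a two-cohort
    synthetic dataset at the configured sizes; otherwise it loads
    ``participants_csv`` and ``profiles_csv``.
    """

    seed: int = 0
    out_dir: str = "infotrans_run"
    lam: float = 0.2
    shuffle_scheme: str = "pooled"
    n_shuffle_reps: int = 1
    alpha: float = 0.05
    alternative: str = "two-sided"
    simulate: bool = True
    n_control: int = 142
    n_clinical: int = 19
    control_sensitivity: float = 1.0
    clinical_sensitivity: float = 0.6
    participants_csv: str | None = None
    profiles_csv: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _setup_logging(out: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr),
              logging.FileHandler(out / "run.log", encoding="utf-8")):
        h.setFormatter(fmt)
        logger.addHandler(h)


def _corr_dict(res) -> dict:
    return {"r": res.r, "n": res.n, "p": res.p,
            "ci": [res.ci_low, res.ci_high], "ci_defined": res.ci_defined}


def run_pipeline(config: RunConfig) -> Path:
    """Execute complexity scoring, simulation/loading, fitting, the
    shuffled null and the cohort analysis; write all outputs.

    Deterministic given the config (single seed, named substreams);
    rerunning with the same config rewrites byte-identical CSVs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    logger.info("run config hash %s", config.config_hash)
    (out / "run_config.json").write_text(config.to_json(), encoding="utf-8")

    stage = "load"
    try:
        if config.simulate:
            stage = "simulate"
            dataset = generate_two_cohorts(
                control_config=dataclasses.replace(
                    default_control_config(config.n_control, seed=config.seed),
                    sensitivity_mean=config.control_sensitivity),
                clinical_config=dataclasses.replace(
                    default_clinical_config(config.n_clinical,
                                            seed=config.seed + 1),
                    sensitivity_mean=config.clinical_sensitivity),
                stimulus_config=StimulusGenConfig(seed=config.seed),
            )
            dataset.save(out)
            participants = dataset.participants
            profiles = dataset.profiles
        else:
            if not config.participants_csv or not config.profiles_csv:
                raise ValueError("simulate=False requires participants_csv "
                                 "and profiles_csv")
            participants = pd.read_csv(config.participants_csv, float_precision="round_trip")
            profiles = load_profiles_csv(config.profiles_csv)

        stage = "validate"
        report = validate_dataset(participants, profiles)
        report.frame().to_csv(out / "validation.csv", index=False)
        if not report.ok:
            logger.warning("validation found %d issues", len(report.violations))

        stage = "fit"
        cohorts = dict(tuple(participants.groupby(schema.COHORT_COL, sort=False)))
        fits = {}
        nulls = {}
        for label, records in cohorts.items():
            design = build_design(records, profiles)
            logger.info("cohort %s: %d participants, %d excluded",
                        label, len(design.participant_ids), len(design.excluded))
            fits[label] = fit_cohort(design, lam=config.lam)
            nulls[label] = shuffled_null(design, lam=config.lam,
                                         scheme=config.shuffle_scheme,
                                         seed=config.seed,
                                         n_reps=config.n_shuffle_reps)
            fits[label].fits_frame.to_csv(out / f"fits_{label}.csv", index=False)
            fits[label].contributions_frame.to_csv(
                out / f"contributions_{label}.csv", index=False)
            nulls[label].frame.to_csv(out / f"null_{label}.csv", index=False)

        stage = "analyze"
        report_obj: dict = {
            "config_hash": config.config_hash,
            "seed": config.seed,
            "lambda": config.lam,
            "shuffle_scheme": config.shuffle_scheme,
            "regressor_order": list(("entropy",) + TRAITS),
            "cohorts": {},
        }
        for label, records in cohorts.items():
            summary = summarize_ratings(records, cohort=label)
            summary.table.to_csv(out / f"rating_summary_{label}.csv", index=False)
            entry: dict = {
                "n": int(len(records)),
                "pooled_r2": fits[label].pooled_r2,
                "mean_sensitivity": float(np.nanmean(
                    [f.information_sensitivity for f in fits[label].fits
                     if not f.degenerate])),
                "n_degenerate": fits[label].n_degenerate,
                "real_mse_mean": float(nulls[label].real_mse.mean()),
                "shuffled_mse_mean": float(nulls[label].shuffled_mse.mean()),
                "null_rank_sum_p": nulls[label].test.p,
                "kruskal_wallis": {k: list(v) for k, v in summary.kruskal.items()},
            }
            if len(records) >= 4:
                _, assoc = sentiment_associations(records, alpha=config.alpha)
                entry["bonferroni_threshold"] = assoc.threshold
                entry["sentiment_correlations"] = {
                    f"{a}~{b}": _corr_dict(r) for (a, b), r in assoc.pairs.items()}
                entry["sensitivity_boredom"] = _corr_dict(
                    sensitivity_boredom_link(fits[label], records))
            report_obj["cohorts"][label] = entry

        if {"control", "clinical"} <= set(cohorts):
            comparison = compare_cohorts(
                cohorts["control"], cohorts["clinical"],
                fits["control"], fits["clinical"],
                alternative=config.alternative)
            comparison.rating_tests.to_csv(out / "cohort_rating_tests.csv",
                                           index=False)
            comparison.psychometric.to_csv(out / "cohort_psychometric.csv",
                                           index=False)
            comparison.entropy_contribution.to_csv(
                out / "entropy_contribution.csv", index=False)
            report_obj["cohort_comparison"] = {
                "sensitivity_means": comparison.sensitivity_means,
                "entropy_contribution_signed_rank": {
                    "statistic": comparison.entropy_contribution_test.statistic,
                    "p": comparison.entropy_contribution_test.p,
                    "alternative": comparison.entropy_contribution_test.alternative,
                },
                "d_profiles": {k: list(v) for k, v in comparison.d_profiles.items()},
            }

        (out / "report.json").write_text(
            json.dumps(report_obj, indent=2, sort_keys=True), encoding="utf-8")
        logger.info("pipeline complete: %s", out)
        return out
    except Exception as exc:
        logger.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from exc
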