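"""Group-level result set: rating summaries, sentiment associations,
the sensitivity-boredom link, and control-vs-clinical contrasts.

This stage composes the other modules into the analyses a study of
perceived information runs end to end: descriptive statistics of the
1-7 ratings per text, Kruskal-Wallis across texts per sentiment,
Bonferroni-controlled correlations among per-participant mean ratings,
the Pearson link between fitted information sensitivity and mean
boredom, and the between-cohort contrasts (psychometric scales, per
text x sentiment rank-sum tests with Cohen's d, per-sentiment
effect-size profiles, and the signed-rank comparison of per-text mean
entropy contributions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .schema import SCALES, SENTIMENTS, TRAITS
from .stats_core import (
    CorrelationMatrixResult,
    CorrelationResult,
    SignedRankResult,
    TwoSampleResult,
    correlation_matrix,
    kruskal_wallis,
    pearson_ci,
    rank_sum,
    signed_rank,
)
from .transmission_model import CohortFitResult

__all__ = [
    "RatingSummary",
    "CohortComparison",
    "infer_stimulus_ids",
    "mean_ratings",
    "summarize_ratings",
    "sentiment_associations",
    "sensitivity_boredom_link",
    "compare_cohorts",
]


def infer_stimulus_ids(records: pd.DataFrame) -> list[str]:
    """Stimulus ids recoverable from the information_* rating columns."""
    prefix = "information_"
    ids = [c[len(prefix):] for c in records.columns if c.startswith(prefix)]
    if not ids:
        raise ValueError("no information rating columns found")
    return ids


def mean_ratings(records: pd.DataFrame,
                 stimulus_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-participant mean rating over texts, one column per sentiment."""
    sids = stimulus_ids or infer_stimulus_ids(records)
    out = {schema.ID_COL: records[schema.ID_COL]}
    for sent in SENTIMENTS:
        out[sent] = records[schema.rating_cols(sent, sids)].mean(axis=1)
    return pd.DataFrame(out)


@dataclass
class RatingSummary:
    """Descriptives per text x sentiment, with across-text Kruskal-Wallis.

    Dispersion is always exported as both SD and SEM (never a single
    ambiguous column); SEM is NaN for n = 1.
    """

    cohort: str
    table: pd.DataFrame                      # one row per text x sentiment
    kruskal: dict[str, tuple[float, float]]  # sentiment -> (H, p)


def summarize_ratings(records: pd.DataFrame, cohort: str = "") -> RatingSummary:
    if records.empty:
        raise ValueError("empty cohort")
    sids = infer_stimulus_ids(records)
    rows = []
    kw: dict[str, tuple[float, float]] = {}
    for sent in SENTIMENTS:
        groups = []
        for sid in sids:
            vals = records[schema.rating_col(sent, sid)].to_numpy(float)
            groups.append(vals)
            n = vals.size
            sd = float(np.std(vals, ddof=1)) if n > 1 else float("nan")
            rows.append({
                "sentiment": sent, "stimulus_id": sid, "n": n,
                "mean": float(np.mean(vals)), "sd": sd,
                "sem": sd / np.sqrt(n) if n > 1 else float("nan"),
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
            })
        kw[sent] = kruskal_wallis(groups)
    return RatingSummary(cohort=cohort, table=pd.DataFrame(rows), kruskal=kw)


def sentiment_associations(
    records: pd.DataFrame, alpha: float = 0.05,
) -> tuple[pd.DataFrame, CorrelationMatrixResult]:
    """Pairwise correlations of per-participant mean ratings.

    Five sentiments give C(5,2) = 10 pairs, hence a Bonferroni
    threshold of alpha/10 (0.005 at the 0.05 level).
    """
    if len(records) < 4:
        raise ValueError("need at least 4 participants")
    means = mean_ratings(records)
    result = correlation_matrix(means[list(SENTIMENTS)], alpha=alpha)
    return means, result


def sensitivity_boredom_link(fit: CohortFitResult,
                             records: pd.DataFrame) -> CorrelationResult:
    """Pearson + CI between information sensitivity and mean boredom.

    Degenerate fits are dropped; fewer than 4 usable fits is an error.
    """
    usable = {f.participant_id: f.information_sensitivity
              for f in fit.fits if not f.degenerate}
    sids = infer_stimulus_ids(records)
    boredom = records.set_index(schema.ID_COL)[
        schema.rating_cols("boredom", sids)].mean(axis=1)
    common = [pid for pid in usable if pid in boredom.index]
    if len(common) < 4:
        raise ValueError("fewer than 4 non-degenerate fits with boredom ratings")
    x = np.array([usable[p] for p in common])
    y = boredom.loc[common].to_numpy(float)
    return pearson_ci(x, y)


@dataclass
class CohortComparison:
    """Control-vs-clinical contrast bundle.

    ``d_profiles`` holds one Cohen's d per text per sentiment (control
    minus clinical convention); ``d_profile_tests`` compares the
    information profile against each other sentiment's profile by exact
    rank-sum on the two 5-vectors. ``entropy_contribution_test`` is the
    signed-rank over the per-text mean entropy contributions of the two
    cohorts, with its sidedness recorded.
    """

    psychometric: pd.DataFrame
    rating_tests: pd.DataFrame
    d_profiles: dict[str, np.ndarray]
    d_profile_tests: dict[tuple[str, str], TwoSampleResult]
    entropy_contribution: pd.DataFrame       # per text mean external per cohort
    entropy_contribution_test: SignedRankResult
    sensitivity_boredom: dict[str, CorrelationResult]
    sensitivity_means: dict[str, float]
    alternative: str


def compare_cohorts(
    control_records: pd.DataFrame,
    clinical_records: pd.DataFrame,
    control_fit: CohortFitResult,
    clinical_fit: CohortFitResult,
    alternative: str = "two-sided",
) -> CohortComparison:
    """Full between-cohort contrast on a shared stimulus set."""
    if control_fit.stimulus_ids != clinical_fit.stimulus_ids:
        raise ValueError("cohorts were fitted on different stimulus sets")
    sids = list(control_fit.stimulus_ids)

    # (i) psychometric scale contrasts (plus trait neuroticism, the
    # clinically loaded Big Five dimension)
    psych_rows = []
    for col in list(SCALES) + ["neuroticism"]:
        if col not in control_records.columns or col not in clinical_records.columns:
            continue
        res = rank_sum(control_records[col].dropna().to_numpy(float),
                       clinical_records[col].dropna().to_numpy(float))
        psych_rows.append({"scale": col, "statistic": res.statistic,
                           "p": res.p, "d": res.d,
                           "n_control": res.n1, "n_clinical": res.n2})
    psychometric = pd.DataFrame(psych_rows)

    # (ii) per text x sentiment rating contrasts
    rating_rows = []
    d_profiles: dict[str, np.ndarray] = {}
    for sent in SENTIMENTS:
        ds = []
        for sid in sids:
            col = schema.rating_col(sent, sid)
            res = rank_sum(control_records[col].to_numpy(float),
                           clinical_records[col].to_numpy(float))
            ds.append(res.d)
            rating_rows.append({"sentiment": sent, "stimulus_id": sid,
                                "statistic": res.statistic, "p": res.p,
                                "d": res.d, "method": res.method})
        d_profiles[sent] = np.asarray(ds)
    rating_tests = pd.DataFrame(rating_rows)

    # (iii) effect-size profile comparisons: information vs each other sentiment
    d_profile_tests = {
        ("information", sent): rank_sum(d_profiles["information"], d_profiles[sent])
        for sent in SENTIMENTS if sent != "information"
    }

    # (iv) per-text mean entropy contribution, signed-rank over texts
    contrib = pd.DataFrame({
        "stimulus_id": sids,
        "control": control_fit.group_external_mean,
        "clinical": clinical_fit.group_external_mean,
    })
    diffs = contrib["clinical"].to_numpy() - contrib["control"].to_numpy()
    contrib_test = signed_rank(diffs, alternative=alternative)

    sens_boredom = {
        "control": sensitivity_boredom_link(control_fit, control_records),
        "clinical": sensitivity_boredom_link(clinical_fit, clinical_records),
    }
    sens_means = {
        "control": float(np.nanmean([f.information_sensitivity
                                     for f in control_fit.fits if not f.degenerate])),
        "clinical": float(np.nanmean([f.information_sensitivity
                                      for f in clinical_fit.fits if not f.degenerate])),
    }
    return CohortComparison(
        psychometric=psychometric,
        rating_tests=rating_tests,
        d_profiles=d_profiles,
        d_profile_tests=d_profile_tests,
        entropy_contribution=contrib,
        entropy_contribution_test=contrib_test,
        sensitivity_boredom=sens_boredom,
        sensitivity_means=sens_means,
        alternative=alternative,
    )
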