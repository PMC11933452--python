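"""Per-participant information-transmission regression.

Each participant's information ratings over the stimulus set are fit,
without an intercept, as a linear combination of one external regressor
(the stimulus' cumulated entropy) and five internal regressors (the Big
Five trait scores, constant across a participant's rows):

    y_t = beta_H * H_t + sum_k beta_k * trait_k + e_t

The per-participant design (one row per text, five of six regressors
constant) is rank-deficient, so the squared loss carries a ridge
penalty ``lambda * n_rows * ||beta||^2`` with a closed-form solution;
at ``lambda = 0`` the minimum-norm least-squares solution is returned
and flagged. The default ``lambda = 0.2`` equals ``1/n_rows`` for the
five-text design.

The decomposition of a fit: for each regressor j and text t the
contribution is ``c_{j,t} = |x_{j,t} * beta_j|``, normalized per text to
relative contributions ``r_{j,t}`` summing to one. ``r_entropy,t`` is
the external contribution, the five trait terms sum to the internal
contribution (external + internal = 1 by construction), and the mean of
``r_entropy,t`` over texts is the participant's *information
sensitivity* — the index carried into all cohort contrasts.

The shuffled-data null refits every participant after permuting each
regressor column independently across all rows (pooled over
participants and texts, destroying the x-y pairing; a within-participant
entropy-only scheme exists for sensitivity analysis, since permuting a
constant trait column within a participant is a no-op).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .schema import TRAITS
from .stats_core import TwoSampleResult, rank_sum
from .text_metrics import ComplexityProfile

__all__ = [
    "REGRESSORS",
    "DesignMatrix",
    "TransmissionFit",
    "CohortFitResult",
    "NullComparison",
    "build_design",
    "fit_participant",
    "contributions",
    "fit_cohort",
    "shuffled_null",
]

REGRESSORS: tuple[str, ...] = ("entropy",) + TRAITS
ENTROPY_IDX = 0


@dataclass
class DesignMatrix:
    """Stacked per-(participant, text) observations.

    ``frame`` holds one row per participant x stimulus with the fixed
    column order ``REGRESSORS`` plus the response ``information``.
    Participants with incomplete traits or ratings are excluded up
    front and listed in ``excluded``.
    """

    frame: pd.DataFrame
    stimulus_ids: tuple[str, ...]
    excluded: list[str] = field(default_factory=list)
    columns: tuple[str, ...] = REGRESSORS

    @property
    def participant_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame[schema.ID_COL]))

    def participant_arrays(self, pid: str) -> tuple[np.ndarray, np.ndarray]:
        rows = self.frame[self.frame[schema.ID_COL] == pid]
        return rows[list(self.columns)].to_numpy(float), rows["information"].to_numpy(float)


def build_design(participants: pd.DataFrame,
                 profiles: list[ComplexityProfile]) -> DesignMatrix:
    """Assemble the regression design from a participant table + profiles.

    A participant missing any trait score or any information rating is
    excluded from the design (and reported), mirroring the convention
    that skipped questionnaire items drop a participant from the
    affected analysis only.
    """
    stim_ids = tuple(p.stimulus_id for p in profiles)
    hcum = {p.stimulus_id: p.cumulated_entropy for p in profiles}
    info_cols = schema.rating_cols("information", list(stim_ids))
    needed = list(TRAITS) + info_cols
    missing_cols = [c for c in needed if c not in participants.columns]
    if missing_cols:
        raise ValueError(f"participant table lacks columns: {missing_cols}")

    complete = participants[needed].notna().all(axis=1)
    excluded = participants.loc[~complete, schema.ID_COL].tolist()
    eligible = participants.loc[complete]
    if eligible.empty:
        raise ValueError("no participant has complete traits and ratings")

    rows = []
    for _, part in eligible.iterrows():
        for sid in stim_ids:
            row = {
                schema.ID_COL: part[schema.ID_COL],
                schema.COHORT_COL: part.get(schema.COHORT_COL, ""),
                "stimulus_id": sid,
                "entropy": hcum[sid],
                "information": part[schema.rating_col("information", sid)],
            }
            for t in TRAITS:
                row[t] = part[t]
            rows.append(row)
    frame = pd.DataFrame(rows)
    return DesignMatrix(frame=frame, stimulus_ids=stim_ids, excluded=excluded)


# ---------------------------------------------------------------------------
# fitting

def fit_participant(X: np.ndarray, y: np.ndarray,
                    lam: float = 0.2) -> tuple[np.ndarray, float, bool]:
    """Ridge-penalized no-intercept least squares, closed form.

    Minimizes ``||y - X b||^2 + lam * n_rows * ||b||^2``. Returns
    ``(beta, mse, min_norm_flag)``; the flag marks a rank-deficient
    ``lam = 0`` design solved by the minimum-norm pseudoinverse.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) and y length n")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if lam < 0:
        raise ValueError("ridge strength must be nonnegative")
    n, p = X.shape
    min_norm = False
    if lam > 0:
        beta = np.linalg.solve(X.T @ X + lam * n * np.eye(p), X.T @ y)
    else:
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        min_norm = rank < p
    resid = y - X @ beta
    return beta, float(np.mean(resid ** 2)), min_norm


@dataclass
class TransmissionFit:
    """One participant's fitted transmission model and its decomposition."""

    participant_id: str
    beta: np.ndarray                 # length 6, REGRESSORS order
    lam: float
    mse: float
    relative_contributions: np.ndarray  # (n_texts, 6); NaN rows are degenerate
    external_per_text: np.ndarray       # r_entropy per text
    information_sensitivity: float      # mean external over non-degenerate texts
    degenerate_texts: np.ndarray        # bool per text
    degenerate: bool                    # all texts degenerate
    min_norm: bool = False

    @property
    def internal_per_text(self) -> np.ndarray:
        return 1.0 - self.external_per_text


def contributions(beta: np.ndarray, X: np.ndarray) -> dict:
    """Decompose fitted weights into per-text relative contributions.

    ``c_{j,t} = |x_{j,t} beta_j|`` normalized per text. A text whose
    contributions sum to zero is flagged degenerate (NaN row) rather
    than divided through; the sensitivity mean skips such texts and is
    NaN only when every text is degenerate.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    c = np.abs(X * beta[None, :])            # (n_texts, p)
    denom = c.sum(axis=1)
    degenerate = denom == 0
    rel = np.full_like(c, np.nan)
    ok = ~degenerate
    rel[ok] = c[ok] / denom[ok, None]
    external = rel[:, ENTROPY_IDX]
    sensitivity = float(np.nanmean(external)) if ok.any() else math.nan
    return {
        "relative": rel,
        "external": external,
        "sensitivity": sensitivity,
        "degenerate_texts": degenerate,
        "degenerate": bool(degenerate.all()),
    }


def _fit_one(pid: str, X: np.ndarray, y: np.ndarray, lam: float) -> TransmissionFit:
    beta, mse, min_norm = fit_participant(X, y, lam)
    dec = contributions(beta, X)
    return TransmissionFit(
        participant_id=pid, beta=beta, lam=lam, mse=mse,
        relative_contributions=dec["relative"],
        external_per_text=dec["external"],
        information_sensitivity=dec["sensitivity"],
        degenerate_texts=dec["degenerate_texts"],
        degenerate=dec["degenerate"],
        min_norm=min_norm,
    )


@dataclass
class CohortFitResult:
    """All per-participant fits of one design plus group-level summaries."""

    fits: list[TransmissionFit]
    stimulus_ids: tuple[str, ...]
    lam: float
    pooled_r2: float                 # 1 - SSE/sum(y^2), no-intercept convention
    group_external_mean: np.ndarray  # per text, over non-degenerate fits
    group_external_sem: np.ndarray
    n_degenerate: int

    @property
    def fits_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            row = {"participant_id": f.participant_id, "lambda": f.lam,
                   "mse": f.mse, "information_sensitivity": f.information_sensitivity,
                   "degenerate": f.degenerate, "min_norm": f.min_norm}
            for name, b in zip(REGRESSORS, f.beta):
                row[f"beta_{name}"] = b
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def contributions_frame(self) -> pd.DataFrame:
        """Long format: participant_id, stimulus_id, regressor, relative_contribution."""
        rows = []
        for f in self.fits:
            for t, sid in enumerate(self.stimulus_ids):
                for j, name in enumerate(REGRESSORS):
                    rows.append({
                        "participant_id": f.participant_id,
                        "stimulus_id": sid,
                        "regressor": name,
                        "relative_contribution": f.relative_contributions[t, j],
                    })
        return pd.DataFrame(rows)

    def trait_contribution_distributions(self) -> pd.DataFrame:
        """Per participant, mean relative contribution of each trait over texts."""
        rows = []
        for f in self.fits:
            if f.degenerate:
                continue
            row = {"participant_id": f.participant_id}
            for j, name in enumerate(REGRESSORS[1:], start=1):
                row[name] = float(np.nanmean(f.relative_contributions[:, j]))
            rows.append(row)
        return pd.DataFrame(rows)


def fit_cohort(design: DesignMatrix, lam: float = 0.2) -> CohortFitResult:
    """Fit every participant in a design and summarize at the group level."""
    fits = []
    sse = 0.0
    sst = 0.0
    for pid in design.participant_ids:
        X, y = design.participant_arrays(pid)
        f = _fit_one(pid, X, y, lam)
        fits.append(f)
        resid = y - X @ f.beta
        sse += float(resid @ resid)
        sst += float(y @ y)  # SST about zero: no-intercept convention
    pooled_r2 = 1.0 - sse / sst if sst > 0 else math.nan
    ext = np.vstack([f.external_per_text for f in fits if not f.degenerate])
    mean = np.nanmean(ext, axis=0)
    with np.errstate(invalid="ignore"):
        counts = np.sum(~np.isnan(ext), axis=0)
        sem = np.nanstd(ext, axis=0, ddof=1) / np.sqrt(counts)
    return CohortFitResult(
        fits=fits, stimulus_ids=design.stimulus_ids, lam=lam,
        pooled_r2=pooled_r2, group_external_mean=mean, group_external_sem=sem,
        n_degenerate=sum(f.degenerate for f in fits),
    )


# ---------------------------------------------------------------------------
# shuffled-data null

SHUFFLE_SCHEMES = ("pooled", "within_participant_entropy")


@dataclass
class NullComparison:
    """Real-vs-shuffled fit errors under a recorded permutation scheme."""

    participant_ids: list[str]
    real_mse: np.ndarray
    shuffled_mse: np.ndarray   # mean over replicates per participant
    scheme: str
    seed: int
    n_reps: int
    lam: float
    test: TwoSampleResult      # rank-sum, shuffled vs real MSE distributions

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": self.participant_ids,
            "real_mse": self.real_mse,
            "shuffled_mse": self.shuffled_mse,
        })


def shuffled_null(design: DesignMatrix, lam: float = 0.2,
                  scheme: str = "pooled", seed: int = 0,
                  n_reps: int = 1) -> NullComparison:
    """Refit after permuting regressors; compare error distributions.

    ``pooled`` (default) permutes the entropy column across all rows,
    pooled over participants and texts, and permutes each trait
    regressor at the participant level — every participant's constant
    is swapped for another participant's. This destroys the entire x-y
    pairing while preserving the structural invariant that trait
    columns are constant within a participant. (A naive row-wise
    permutation of the trait columns would break that constancy and
    turn the 5-observation, 6-regressor system full-rank, letting the
    shuffled fit interpolate its five points to near-zero error — the
    null would then sit *below* the real fit, which is an artifact of
    the permutation scheme, not evidence about the model.)
    ``within_participant_entropy`` permutes only the entropy column and
    only within each participant's rows (permuting a constant trait
    column there is the identity). The shuffled MSE per participant is
    averaged over ``n_reps`` seeded replicates; the group test is a
    two-sided rank-sum of the shuffled versus real MSE distributions.
    """
    if scheme not in SHUFFLE_SCHEMES:
        raise ValueError(f"unknown shuffle scheme {scheme!r}; "
                         f"choose from {SHUFFLE_SCHEMES}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    pids = design.participant_ids
    base = design.frame
    Xfull = base[list(design.columns)].to_numpy(float)
    y = base["information"].to_numpy(float)
    pid_codes = base[schema.ID_COL].to_numpy()

    real_mse = np.empty(len(pids))
    for i, pid in enumerate(pids):
        m = pid_codes == pid
        _, real_mse[i], _ = fit_participant(Xfull[m], y[m], lam)

    shuf_acc = np.zeros(len(pids))
    n_rows, p = Xfull.shape
    for _ in range(n_reps):
        Xs = Xfull.copy()
        if scheme == "pooled":
            Xs[:, ENTROPY_IDX] = Xs[rng.permutation(n_rows), ENTROPY_IDX]
            blocks = [np.flatnonzero(pid_codes == pid) for pid in pids]
            for j in range(1, p):
                order = rng.permutation(len(blocks))
                col = Xs[:, j].copy()
                for dst, src in enumerate(order):
                    Xs[blocks[dst], j] = col[blocks[src][0]]
        else:
            for pid in pids:
                m = np.flatnonzero(pid_codes == pid)
                Xs[m, ENTROPY_IDX] = Xs[m[rng.permutation(m.size)], ENTROPY_IDX]
        for i, pid in enumerate(pids):
            m = pid_codes == pid
            _, mse, _ = fit_participant(Xs[m], y[m], lam)
            shuf_acc[i] += mse
    shuffled_mse = shuf_acc / n_reps
    test = rank_sum(shuffled_mse, real_mse, alternative="two-sided")
    return NullComparison(
        participant_ids=pids, real_mse=real_mse, shuffled_mse=shuffled_mse,
        scheme=scheme, seed=seed, n_reps=n_reps, lam=lam, test=test,
    )
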