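"""Synthetic stimulus sets and rating cohorts.

Real studies of text-based information transmission pair a small set of
~100-word stimuli spanning a gradient of entropy with cohorts of raters
who score each text on 1-7 scales (information, boredom, creativity,
affect, arousal) and complete trait questionnaires. This module
generates datasets with that structure so the full analysis pipeline is
testable without any deposited data:

* ``generate_stimulus_set`` builds texts of exactly ``words_per_text``
  tokens drawn from nested vocabularies of strictly increasing size,
  which yields a strictly increasing cumulated-entropy gradient across
  stimuli (checked, with seeded retries).
* ``generate_participants`` draws Big Five trait scores, psychometric
  sum scores, and a latent per-participant entropy sensitivity ``s_i``.
* ``generate_ratings`` fills in the texts x sentiments rating matrix
  from the generative model

      information(p, t) = s_p * g(h_t) + sum_k w_k * trait_{p,k} + eps

  where ``h_t`` is the stimulus entropy normalized by the set maximum,
  ``g`` is linear or a concave inverse-U peaking at ``inverse_u_peak``
  (the default, mirroring the empirical finding that perceived
  information peaks at intermediate complexity), and boredom is affine
  in minus the latent perceived information. All ratings are clipped to
  [1, 7]; the clipped fraction is reported in provenance.
* ``generate_two_cohorts`` produces a combined control + clinical
  dataset sharing one stimulus set, with the clinical cohort given a
  lower mean sensitivity and shifted psychometric means.

Ground truth (latent sensitivities, weights) is stored separately from
the observables. Identical configs and seeds regenerate datasets
bit-identically.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import schema
from .schema import TRAITS, SENTIMENTS, SCALES, RATING_MIN, RATING_MAX
from .text_metrics import (
    ComplexityProfile,
    EmbeddingProvider,
    HashEmbeddingProvider,
    TextStimulus,
    complexity_profile,
)

__all__ = [
    "StimulusGenConfig",
    "CohortGenConfig",
    "SyntheticDataset",
    "default_lexicon",
    "default_control_config",
    "default_clinical_config",
    "generate_stimulus_set",
    "generate_participants",
    "generate_ratings",
    "generate_dataset",
    "generate_two_cohorts",
]


def default_lexicon(n: int = 120) -> tuple[str, ...]:
    """Deterministic pseudo-word lexicon (syllable products, no semantics)."""
    syllables = ("ba", "do", "fi", "gu", "ka", "le", "mi", "no",
                 "pe", "ra", "su", "ti", "vo", "wu", "za", "ne")
    words = ["".join(pair) for pair in itertools.product(syllables, repeat=2)]
    if n > len(words):
        raise ValueError(f"lexicon capped at {len(words)} words")
    return tuple(words[:n])


# questionnaire-scale admissible ranges for the generated sum scores
_TRAIT_RANGE = (2.0, 10.0)  # BFI-10: two 1-5 items per dimension
_SCALE_RANGES = {
    "bps": (8.0, 56.0),     # 8 items, 1-7
    "msbs": (8.0, 56.0),    # 8 items, 1-7
    "stai_y": (20.0, 80.0),  # 20 items, 1-4
    "brs": (6.0, 30.0),     # 6 items, 1-5
}


@dataclass(frozen=True)
class StimulusGenConfig:
    """Stimulus-set design: nested vocabularies of increasing size.

    ``vocabulary_sizes`` must be strictly increasing; every word of a
    stimulus' vocabulary occurs at least once, so unique counts equal
    the budgets exactly.
    """

    n_stimuli: int = 5
    words_per_text: int = 100
    vocabulary_sizes: tuple[int, ...] = (2, 5, 12, 30, 70)
    seed: int = 0
    lexicon: tuple[str, ...] | None = None
    max_retries: int = 20

    def validate(self) -> None:
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be >= 1")
        if len(self.vocabulary_sizes) != self.n_stimuli:
            raise ValueError("vocabulary_sizes length must equal n_stimuli")
        sizes = self.vocabulary_sizes
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("vocabulary_sizes must be strictly increasing")
        lex = self.lexicon or default_lexicon()
        if max(sizes) > len(lex):
            raise ValueError("vocabulary budget exceeds lexicon size")
        if self.words_per_text < max(sizes):
            raise ValueError("words_per_text must cover the largest vocabulary")


@dataclass(frozen=True)
class CohortGenConfig:
    """Generative parameters of one rating cohort.

    Units: trait means/SDs in BFI-10 sum-score units (range 2-10);
    ``sensitivity_mean``/``sensitivity_sd`` are unitless weights on the
    normalized entropy response; ``entropy_gain`` converts the response
    to rating units; ``noise_sd`` is in rating units; ``boredom_coupling``
    is rating units of boredom per rating unit of latent perceived
    information (negative: more perceived information, less boredom).
    """

    n_participants: int = 142
    cohort_label: str = "control"
    trait_means: tuple[float, ...] = (6.9, 6.8, 6.0, 6.4, 5.2)
    trait_sds: tuple[float, ...] = (1.5, 1.5, 1.5, 1.5, 1.5)
    scale_means: tuple[float, ...] = (28.0, 24.0, 38.0, 21.0)  # bps, msbs, stai_y, brs
    scale_sds: tuple[float, ...] = (7.0, 8.0, 8.0, 4.0)
    sensitivity_mean: float = 1.0
    sensitivity_sd: float = 0.45
    trait_weights: tuple[float, ...] = (0.10, 0.05, 0.05, 0.05, 0.05)
    noise_sd: float = 0.25
    response_shape: str = "inverse_u"  # or "linear"
    entropy_gain: float = 2.5
    inverse_u_peak: float = 0.8    # in normalized-entropy units
    inverse_u_width: float = 0.77
    boredom_coupling: float = -0.9
    boredom_intercept: float = 7.0
    sentiment_intercepts: tuple[float, ...] = (2.0, 3.0, 2.5)  # creativity, affect, arousal
    sentiment_slopes: tuple[float, ...] = (0.7, 0.5, 0.4)      # per stimulus index step
    integer_ratings: bool = False
    rating_bounds: tuple[float, float] = (RATING_MIN, RATING_MAX)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if len(self.trait_means) != len(TRAITS) or len(self.trait_sds) != len(TRAITS):
            raise ValueError("trait parameter vectors must match the five traits")
        if len(self.trait_weights) != len(TRAITS):
            raise ValueError("trait_weights must match the five traits")
        if self.noise_sd < 0 or any(s < 0 for s in self.trait_sds):
            raise ValueError("standard deviations must be nonnegative")
        if self.response_shape not in ("linear", "inverse_u"):
            raise ValueError(f"unknown response_shape {self.response_shape!r}")
        if tuple(self.rating_bounds) != (RATING_MIN, RATING_MAX):
            raise ValueError("rating bounds are fixed at [1, 7]")


def default_control_config(n_participants: int = 142, seed: int = 0) -> CohortGenConfig:
    return CohortGenConfig(n_participants=n_participants, seed=seed)


def default_clinical_config(n_participants: int = 19, seed: int = 1) -> CohortGenConfig:
    """ADHD-like cohort: lower entropy sensitivity, higher boredom
    proneness / state boredom / anxiety / neuroticism, lower resilience."""
    return CohortGenConfig(
        n_participants=n_participants,
        cohort_label="clinical",
        trait_means=(6.9, 6.3, 6.0, 6.4, 6.5),
        scale_means=(38.0, 34.0, 50.0, 16.0),
        sensitivity_mean=0.6,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# stimuli

def generate_stimulus_set(
    config: StimulusGenConfig = StimulusGenConfig(),
    provider: EmbeddingProvider | None = None,
) -> tuple[list[TextStimulus], list[ComplexityProfile]]:
    """Generate texts with strictly increasing cumulated entropy.

    Stimulus k draws its tokens from the first ``vocabulary_sizes[k]``
    lexicon words: every vocabulary word once, the remainder uniform,
    then a seeded shuffle. The monotone H_cum gradient is verified and
    regenerated under derived seeds a bounded number of times (the
    uniform design makes a violation rare; the check makes it
    impossible to return one).
    """
    config.validate()
    lexicon = config.lexicon or default_lexicon()
    if provider is None:
        provider = HashEmbeddingProvider(dim=16, seed=0)
    last_hcum: list[float] = []
    for attempt in range(config.max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0, attempt]))
        stimuli: list[TextStimulus] = []
        profiles: list[ComplexityProfile] = []
        for k, vsize in enumerate(config.vocabulary_sizes):
            vocab = list(lexicon[:vsize])
            fill = rng.choice(vocab, size=config.words_per_text - vsize)
            tokens = np.array(vocab + list(fill))
            rng.shuffle(tokens)
            tokens = [str(t) for t in tokens]
            stim = TextStimulus(
                stimulus_id=f"text{k + 1}",
                raw_text=" ".join(tokens),
                tokens=tuple(tokens),
            )
            stimuli.append(stim)
            profiles.append(complexity_profile(stim, provider=provider))
        hcum = [p.cumulated_entropy for p in profiles]
        if all(b > a for a, b in zip(hcum, hcum[1:])):
            return stimuli, profiles
        last_hcum = hcum
    raise RuntimeError(
        f"could not achieve a monotone entropy gradient after "
        f"{config.max_retries} attempts (last H_cum: {last_hcum})")


# ---------------------------------------------------------------------------
# participants

def generate_participants(config: CohortGenConfig) -> pd.DataFrame:
    """Draw trait scores, psychometric sum scores and latent sensitivity.

    Returns one row per participant. Observable columns: id, cohort,
    the five traits, the four scale scores. The latent entropy
    sensitivity is carried in ``true_sensitivity`` (split out into the
    dataset's ground-truth table by the callers that assemble one).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_participants
    data: dict[str, object] = {
        schema.ID_COL: [f"{config.cohort_label}_{i:04d}" for i in range(n)],
        schema.COHORT_COL: [config.cohort_label] * n,
    }
    lo, hi = _TRAIT_RANGE
    for t, m, s in zip(TRAITS, config.trait_means, config.trait_sds):
        data[t] = np.clip(rng.normal(m, s, size=n), lo, hi)
    for sc, m, s in zip(SCALES, config.scale_means, config.scale_sds):
        slo, shi = _SCALE_RANGES[sc]
        data[sc] = np.clip(rng.normal(m, s, size=n), slo, shi)
    data["true_sensitivity"] = rng.normal(
        config.sensitivity_mean, config.sensitivity_sd, size=n)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# ratings

def _entropy_response(h_norm: np.ndarray, config: CohortGenConfig) -> np.ndarray:
    """g(h): rating-unit response to normalized entropy h in (0, 1]."""
    if config.response_shape == "linear":
        return config.entropy_gain * h_norm
    # concave quadratic, peak at inverse_u_peak, floored at zero
    g = 1.0 - ((h_norm - config.inverse_u_peak) / config.inverse_u_width) ** 2
    return config.entropy_gain * np.clip(g, 0.0, None)


def generate_ratings(
    participants: pd.DataFrame,
    profiles: Sequence[ComplexityProfile],
    config: CohortGenConfig,
) -> tuple[pd.DataFrame, dict]:
    """Fill the texts x sentiments rating matrix for every participant.

    Returns the participant table with rating columns appended, plus a
    provenance dict recording the clipped-rating fraction.
    """
    config.validate()
    if "true_sensitivity" not in participants.columns:
        raise ValueError("participants table lacks latent sensitivities")
    hcum = np.array([p.cumulated_entropy for p in profiles], dtype=float)
    if hcum.size == 0 or not np.isfinite(hcum).all():
        raise ValueError("profiles must carry finite cumulated entropies")
    stim_ids = [p.stimulus_id for p in profiles]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n, n_t = len(participants), len(profiles)
    h_norm = hcum / hcum.max()
    g = _entropy_response(h_norm, config)  # (n_t,)
    s = participants["true_sensitivity"].to_numpy()
    trait_mat = participants[list(TRAITS)].to_numpy()
    internal = trait_mat @ np.asarray(config.trait_weights)  # (n,)

    latent_info = s[:, None] * g[None, :] + internal[:, None]  # (n, n_t)
    lo, hi = config.rating_bounds
    raw: dict[str, np.ndarray] = {}
    raw["information"] = latent_info + rng.normal(0, config.noise_sd, (n, n_t))
    raw["boredom"] = (config.boredom_intercept
                      + config.boredom_coupling * latent_info
                      + rng.normal(0, config.noise_sd, (n, n_t)))
    idx = np.arange(n_t, dtype=float)
    for sent, b0, b1 in zip(("creativity", "affect", "arousal"),
                            config.sentiment_intercepts, config.sentiment_slopes):
        raw[sent] = b0 + b1 * idx[None, :] + rng.normal(0, config.noise_sd, (n, n_t))

    out = participants.copy()
    clipped = 0
    total = 0
    for sent in SENTIMENTS:
        vals = raw[sent]
        if config.integer_ratings:
            vals = np.rint(vals)
        clipped += int(np.sum((vals < lo) | (vals > hi)))
        total += vals.size
        vals = np.clip(vals, lo, hi)
        for j, sid in enumerate(stim_ids):
            out[schema.rating_col(sent, sid)] = vals[:, j]
    provenance = {
        "cohort_label": config.cohort_label,
        "clip_fraction": clipped / total,
        "n_ratings": total,
    }
    return out, provenance


# ---------------------------------------------------------------------------
# full datasets

@dataclass
class SyntheticDataset:
    """A complete simulated study: stimuli, profiles, observables, truth."""

    stimuli: list[TextStimulus]
    profiles: list[ComplexityProfile]
    participants: pd.DataFrame        # observables only
    ground_truth: pd.DataFrame        # participant_id, cohort, true_sensitivity
    provenance: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False)
        self.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        manifest = [{"stimulus_id": s.stimulus_id, "raw_text": s.raw_text}
                    for s in self.stimuli]
        (out / "stimuli.json").write_text(
            json.dumps(manifest, indent=2), encoding="utf-8")
        from .text_metrics import profiles_to_frame
        profiles_to_frame(self.profiles).to_csv(out / "profiles.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str), encoding="utf-8")


def _split_truth(filled: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    truth = filled[[schema.ID_COL, schema.COHORT_COL, "true_sensitivity"]].copy()
    observables = filled.drop(columns=["true_sensitivity"])
    return observables, truth


def generate_dataset(
    cohort_config: CohortGenConfig = CohortGenConfig(),
    stimulus_config: StimulusGenConfig = StimulusGenConfig(),
) -> SyntheticDataset:
    """One-cohort dataset: stimuli + participants + ratings + truth."""
    stimuli, profiles = generate_stimulus_set(stimulus_config)
    participants = generate_participants(cohort_config)
    filled, prov = generate_ratings(participants, profiles, cohort_config)
    observables, truth = _split_truth(filled)
    provenance = {
        "stimulus_config": asdict(stimulus_config),
        "cohort_configs": [asdict(cohort_config)],
        "rating_provenance": [prov],
    }
    return SyntheticDataset(stimuli, profiles, observables, truth, provenance)


def generate_two_cohorts(
    control_config: CohortGenConfig | None = None,
    clinical_config: CohortGenConfig | None = None,
    stimulus_config: StimulusGenConfig = StimulusGenConfig(),
) -> SyntheticDataset:
    """Combined control + clinical dataset over a shared stimulus set.

    Defaults follow the reference study design: 142 controls with mean
    sensitivity 1.0 versus 19 patients with mean sensitivity 0.6 and
    shifted psychometric means. The true sensitivity gap is recorded in
    provenance.
    """
    control_config = control_config or default_control_config()
    clinical_config = clinical_config or default_clinical_config()
    if control_config.cohort_label == clinical_config.cohort_label:
        raise ValueError("cohorts must carry distinct labels")
    stimuli, profiles = generate_stimulus_set(stimulus_config)
    parts = []
    provs = []
    for cfg in (control_config, clinical_config):
        filled, prov = generate_ratings(generate_participants(cfg), profiles, cfg)
        parts.append(filled)
        provs.append(prov)
    combined = pd.concat(parts, ignore_index=True)
    observables, truth = _split_truth(combined)
    provenance = {
        "stimulus_config": asdict(stimulus_config),
        "cohort_configs": [asdict(control_config), asdict(clinical_config)],
        "rating_provenance": provs,
        "true_sensitivity_gap": (control_config.sensitivity_mean
                                 - clinical_config.sensitivity_mean),
    }
    return SyntheticDataset(stimuli, profiles, observables, truth, provenance)
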