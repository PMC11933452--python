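"""Objective information-content measures for word sequences.

The central quantity is the cumulated empirical entropy of a text: at
every word position ``i`` (1-based), the Shannon entropy ``H_i`` of the
empirical word-frequency distribution of the prefix ending at — and
including — position ``i`` is computed, and ``H_cum`` is the sum of all
``H_i``. A text of constant repetitions has ``H_cum = 0``; a text of n
all-distinct words has ``H_cum = ln(n!)`` nats. ``H_cum`` thus grows
with both vocabulary size and the unpredictability of word use and
serves as a proxy for the objective information content of a stimulus.

Complementary measures: vocabulary trajectory (unique words among the
first i tokens), token/type counts, and semantic diversity — the mean
pairwise cosine distance between embedding vectors of the unique word
types. The embedding model is an adapter (``EmbeddingProvider``); the
package ships a deterministic hash-seeded unit-vector backend for
testing and a TSV file backend for real vectors, and never bundles
model weights.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats_core import one_sample_t

__all__ = [
    "TokenizerConfig",
    "TextStimulus",
    "ComplexityProfile",
    "EmbeddingProvider",
    "HashEmbeddingProvider",
    "FileEmbeddingProvider",
    "tokenize",
    "prefix_entropy",
    "cumulated_entropy",
    "lexical_counts",
    "semantic_diversity",
    "complexity_profile",
    "complexity_correlations",
    "load_stimuli",
    "profiles_to_frame",
]

_PUNCT_RE = re.compile(r"[^\w\s]|_", flags=re.UNICODE)


@dataclass(frozen=True)
class TokenizerConfig:
    """Normalization applied before whitespace splitting.

    Identical configs produce identical token sequences for identical
    input; the config round-trips through ``to_dict``/``from_dict`` so a
    run's provenance can record it.
    """

    case_folding: bool = True
    punctuation_stripping: bool = True

    def to_dict(self) -> dict:
        return {"case_folding": self.case_folding,
                "punctuation_stripping": self.punctuation_stripping}

    @classmethod
    def from_dict(cls, d: Mapping) -> "TokenizerConfig":
        return cls(**dict(d))


@dataclass(frozen=True)
class TextStimulus:
    """An ordered word-token sequence with identity; position i is 1-based."""

    stimulus_id: str
    raw_text: str
    tokens: tuple[str, ...]

    def __post_init__(self):
        if not self.tokens:
            raise ValueError(f"stimulus {self.stimulus_id!r}: empty token sequence")

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(raw_text: str, config: TokenizerConfig = TokenizerConfig(),
             stimulus_id: str = "stimulus") -> TextStimulus:
    """Normalize and whitespace-split ``raw_text`` into a TextStimulus.

    Default normalization lowercases and strips punctuation. Compound
    words are never split. An input that is empty after normalization
    raises a ValueError naming the stimulus.
    """
    text = raw_text
    if config.case_folding:
        text = text.lower()
    if config.punctuation_stripping:
        text = _PUNCT_RE.sub(" ", text)
    tokens = tuple(text.split())
    if not tokens:
        raise ValueError(
            f"stimulus {stimulus_id!r}: no tokens remain after normalization")
    return TextStimulus(stimulus_id=stimulus_id, raw_text=raw_text, tokens=tokens)


# ---------------------------------------------------------------------------
# entropy

def _as_tokens(stimulus) -> Sequence[str]:
    return stimulus.tokens if isinstance(stimulus, TextStimulus) else tuple(stimulus)


def prefix_entropy(stimulus, log_base: float = math.e) -> np.ndarray:
    """Shannon entropy of the word distribution of every prefix.

    Position i's prefix includes the current word, so H_1 = 0 always.
    Computed incrementally: with S = sum over words of c*ln(c) for
    counts c over the first N tokens, H = ln(N) - S/N, and a count
    update c -> c+1 changes S by (c+1)ln(c+1) - c*ln(c).
    """
    tokens = _as_tokens(stimulus)
    if not tokens:
        raise ValueError("empty token sequence")
    if log_base <= 0 or log_base == 1:
        raise ValueError(f"invalid log base {log_base}")
    counts: dict[str, int] = {}
    s = 0.0  # running sum of c*ln(c)
    out = np.empty(len(tokens))
    for i, tok in enumerate(tokens):
        c = counts.get(tok, 0)
        s += (c + 1) * math.log(c + 1) - (c * math.log(c) if c else 0.0)
        counts[tok] = c + 1
        n = i + 1
        # single word type: exactly zero, avoiding telescoped round-off
        out[i] = 0.0 if len(counts) == 1 else math.log(n) - s / n
    np.clip(out, 0.0, None, out=out)  # guard tiny negative round-off
    if log_base != math.e:
        out /= math.log(log_base)
    return out


def cumulated_entropy(stimulus, log_base: float = math.e) -> float:
    """H_cum: the sum of prefix entropies over all word positions."""
    return float(prefix_entropy(stimulus, log_base=log_base).sum())


def vocabulary_trajectory(stimulus) -> np.ndarray:
    """n_i: number of unique words among the first i tokens (nondecreasing)."""
    tokens = _as_tokens(stimulus)
    seen: set[str] = set()
    out = np.empty(len(tokens), dtype=np.intp)
    for i, tok in enumerate(tokens):
        seen.add(tok)
        out[i] = len(seen)
    return out


def prefix_frequencies(stimulus, i: int) -> dict[str, float]:
    """Relative word frequencies of the prefix ending at 1-based position i."""
    tokens = _as_tokens(stimulus)
    if not 1 <= i <= len(tokens):
        raise ValueError(f"position {i} outside 1..{len(tokens)}")
    prefix = tokens[:i]
    return {w: prefix.count(w) / i for w in set(prefix)}


def lexical_counts(stimulus) -> dict[str, int]:
    """Token count and unique-type count of a stimulus."""
    tokens = _as_tokens(stimulus)
    return {"token_count": len(tokens), "unique_count": len(set(tokens))}


# ---------------------------------------------------------------------------
# semantic diversity

class EmbeddingProvider:
    """Contract: deterministic token -> fixed-length vector mapping."""

    backend_id: str = "abstract"

    def vector(self, token: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class HashEmbeddingProvider(EmbeddingProvider):
    """Deterministic pseudo-random unit vectors seeded by a token hash.

    A test backend only: it carries no semantics, but is deterministic
    across processes and platforms (BLAKE2-based, not ``hash()``).
    """

    def __init__(self, dim: int = 16, seed: int = 0):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = dim
        self.seed = seed
        self.backend_id = f"stub-hash-d{dim}-s{seed}"

    def vector(self, token: str) -> np.ndarray:
        digest = hashlib.blake2b(
            f"{self.seed}\x00{token}".encode(), digest_size=8).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "big"))
        v = rng.standard_normal(self.dim)
        return v / np.linalg.norm(v)


class FileEmbeddingProvider(EmbeddingProvider):
    """Vectors from a TSV file: token<TAB>v1<TAB>v2..., one token per line."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.backend_id = f"file:{self.path.name}"
        self._table: dict[str, np.ndarray] = {}
        for line in self.path.read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            self._table[parts[0]] = np.asarray(parts[1:], dtype=float)

    def vector(self, token: str) -> np.ndarray:
        if token not in self._table:
            raise KeyError(token)
        return self._table[token]


def semantic_diversity(stimulus, provider: EmbeddingProvider) -> float:
    """Mean pairwise cosine distance over unique word types.

    Operates on the set of unique types (order-invariant); a single-type
    text has no pairs and is defined as 0. Unresolvable tokens raise a
    ValueError listing them.
    """
    types = sorted(set(_as_tokens(stimulus)))
    missing = []
    vecs = []
    for t in types:
        try:
            vecs.append(np.asarray(provider.vector(t), dtype=float))
        except KeyError:
            missing.append(t)
    if missing:
        raise ValueError(f"embedding backend cannot resolve tokens: {missing}")
    if len(vecs) < 2:
        return 0.0
    V = np.vstack(vecs)
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding vector")
    U = V / norms[:, None]
    cos = U @ U.T
    iu = np.triu_indices(len(vecs), k=1)
    return float(np.mean(1.0 - cos[iu]))


# ---------------------------------------------------------------------------
# profiles

@dataclass
class ComplexityProfile:
    """Per-stimulus complexity measures.

    ``prefix_entropies`` holds one H_i per position in the configured
    log-base units; ``cumulated_entropy`` is their sum; ``annotations``
    carries externally supplied counts (e.g. conjunctions, adjectives),
    never computed here.
    """

    stimulus_id: str
    token_count: int
    unique_count: int
    prefix_entropies: np.ndarray
    cumulated_entropy: float
    vocabulary: np.ndarray
    log_base: float = math.e
    semantic_diversity: float | None = None
    annotations: dict[str, float] = field(default_factory=dict)


def complexity_profile(
    stimulus: TextStimulus,
    log_base: float = math.e,
    provider: EmbeddingProvider | None = None,
    annotations: Mapping[str, float] | None = None,
) -> ComplexityProfile:
    """Compute the full ComplexityProfile of one stimulus."""
    h = prefix_entropy(stimulus, log_base=log_base)
    counts = lexical_counts(stimulus)
    return ComplexityProfile(
        stimulus_id=stimulus.stimulus_id,
        token_count=counts["token_count"],
        unique_count=counts["unique_count"],
        prefix_entropies=h,
        cumulated_entropy=float(h.sum()),
        vocabulary=vocabulary_trajectory(stimulus),
        log_base=log_base,
        semantic_diversity=(semantic_diversity(stimulus, provider)
                            if provider is not None else None),
        annotations=dict(annotations or {}),
    )


def profiles_to_frame(profiles: Iterable[ComplexityProfile]) -> pd.DataFrame:
    """One row per stimulus: counts, H_cum, diversity, annotation columns."""
    rows = []
    for p in profiles:
        row = {
            "stimulus_id": p.stimulus_id,
            "token_count": p.token_count,
            "unique_count": p.unique_count,
            "H_cum": p.cumulated_entropy,
            "log_base": p.log_base,
            "semantic_diversity": p.semantic_diversity,
        }
        row.update(p.annotations)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComplexityCorrelationSummary:
    n_pairs: int
    mean_r: float
    sd_r: float
    t: float
    p: float


def complexity_correlations(
    profiles: Sequence[ComplexityProfile] | pd.DataFrame,
    measures: Sequence[str],
) -> tuple[pd.DataFrame, ComplexityCorrelationSummary]:
    """Pairwise Pearson correlations of complexity measures across stimuli.

    Returns the symmetric correlation matrix over ``measures`` plus a
    summary: the mean and SD of the C(m,2) pairwise correlations and a
    one-sample t-test of those correlations against zero. (Small print:
    with few stimuli each individual correlation is noisy; the summary
    test asks whether the collection of pairwise correlations sits above
    zero, not whether any single one does.)
    """
    if isinstance(profiles, pd.DataFrame):
        frame = profiles
    else:
        frame = profiles_to_frame(profiles)
    if len(frame) < 3:
        raise ValueError("need at least 3 stimuli for cross-stimulus correlations")
    if len(measures) < 2:
        raise ValueError("need at least 2 measures")
    data = frame[list(measures)].astype(float)
    for m in measures:
        if np.ptp(data[m].to_numpy()) == 0:
            raise ValueError(f"measure {m!r} has zero variance across stimuli")
    mat = data.corr(method="pearson")
    rs = [mat.loc[a, b] for a, b in itertools.combinations(measures, 2)]
    rs = np.asarray(rs, dtype=float)
    t, p = one_sample_t(rs, 0.0)
    summary = ComplexityCorrelationSummary(
        n_pairs=len(rs), mean_r=float(rs.mean()),
        sd_r=float(rs.std(ddof=1)), t=t, p=p,
    )
    return mat, summary


# ---------------------------------------------------------------------------
# stimulus-set I/O

def load_stimuli(source: str | Path,
                 config: TokenizerConfig = TokenizerConfig()) -> list[TextStimulus]:
    """Load a stimulus set from a JSON manifest or a directory of .txt files.

    Manifest format: a JSON list of {"stimulus_id": ..., "raw_text": ...}.
    For a directory, each ``*.txt`` file becomes one stimulus named after
    its stem; files are taken in sorted order.
    """
    path = Path(source)
    if path.is_dir():
        out = []
        for f in sorted(path.glob("*.txt")):
            out.append(tokenize(f.read_text(encoding="utf-8"), config,
                                stimulus_id=f.stem))
        if not out:
            raise ValueError(f"no .txt stimuli found in {path}")
        return out
    entries = json.loads(path.read_text(encoding="utf-8"))
    return [tokenize(e["raw_text"], config, stimulus_id=e["stimulus_id"])
            for e in entries]
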