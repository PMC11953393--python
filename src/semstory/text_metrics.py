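"""Behavioural text metrics: semantic distance (novelty) and surprise
(appropriateness), plus MSE-based stimulus triplet selection.

Semantic distance of a story is the mean cosine distance between each of its
target words and every non-target content word:

    SD = (1/|phi_t|) sum_i (1/|phi_nt|) sum_j (1 - cos(w_i, w_j))

Surprise is the mean negative log-likelihood (natural log, nats) a masked
language model assigns to the target words in their story context:

    delta = (1/|phi_t|) sum_i -ln P(t_i | C(t_i))

Both are computed per embedding/LM model and averaged across models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ValidationError

__all__ = [
    "StoryTranscript", "EmbeddingLexicon", "MaskedLMTable", "SemanticScores",
    "TripletCandidate", "semantic_distance", "surprise",
    "aggregate_across_models", "select_triplets", "score_stories",
]


class MissingWordError(KeyError):
    """A required word is absent from a lexicon or LM table."""


@dataclass
class StoryTranscript:
    """Tokenised story with target / non-target content-word roles.

    Non-target content words default to all tokens minus targets and stop
    words, optionally passed through a lemma map.  Set semantics: repeated
    words are counted once.
    """

    tokens: list[str]
    target_words: list[str]
    condition_label: str = ""
    subject_id: int | str = ""
    trial_id: int | str = ""
    stop_words: frozenset[str] = frozenset()
    lemma_map: dict[str, str] = field(default_factory=dict)
    non_target_content_words: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(set(self.target_words)) != 3:
            raise ValidationError("exactly 3 distinct target words required")
        if not self.non_target_content_words:
            lemmas = (self.lemma_map.get(tok, tok) for tok in self.tokens)
            nt = {w for w in lemmas
                  if w not in self.stop_words and w not in set(self.target_words)}
            self.non_target_content_words = frozenset(nt)
        if set(self.target_words) & set(self.non_target_content_words):
            raise ValidationError("target and non-target sets must be disjoint")

    @property
    def story_id(self) -> str:
        return f"sub-{self.subject_id}_cond-{self.condition_label}_trial-{self.trial_id}"

    def to_dict(self) -> dict:
        return {"tokens": self.tokens, "targets": self.target_words,
                "condition": self.condition_label, "subject": self.subject_id,
                "trial": self.trial_id}

    @classmethod
    def from_dict(cls, d: dict, **kw) -> "StoryTranscript":
        return cls(tokens=d["tokens"], target_words=d["targets"],
                   condition_label=d.get("condition", ""),
                   subject_id=d.get("subject", ""), trial_id=d.get("trial", ""), **kw)


@dataclass
class EmbeddingLexicon:
    """word -> real vector lookup, word2vec text-format compatible."""

    vectors: dict[str, np.ndarray]
    dimension: int
    model_id: str = ""

    def __post_init__(self) -> None:
        for w, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (self.dimension,):
                raise ValidationError(
                    f"vector for {w!r} has length {v.shape}, expected {self.dimension}")
            self.vectors[w] = v

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        try:
            return self.vectors[word]
        except KeyError:
            raise MissingWordError(
                f"word {word!r} not in lexicon {self.model_id!r}") from None

    def write_word2vec(self, path: str | Path) -> None:
        """First line '<vocab> <dim>', then one word + values per line."""
        lines = [f"{len(self.vectors)} {self.dimension}"]
        for w, v in self.vectors.items():
            lines.append(w + " " + " ".join(f"{x:.8g}" for x in v))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_word2vec(cls, path: str | Path, model_id: str = "") -> "EmbeddingLexicon":
        lines = Path(path).read_text().strip().splitlines()
        n, dim = (int(x) for x in lines[0].split())
        vectors = {}
        for line in lines[1:n + 1]:
            parts = line.split()
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]], dtype=float)
        return cls(vectors=vectors, dimension=dim,
                   model_id=model_id or Path(path).stem)


@dataclass
class MaskedLMTable:
    """(story_id, mask_index) -> probability distribution over a vocabulary."""

    distributions: dict[tuple[str, int], dict[str, float]]
    model_id: str = ""

    def __post_init__(self) -> None:
        for key, dist in self.distributions.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"distribution at {key} sums to {total}, not 1")
            if any(p < 0 or p > 1 for p in dist.values()):
                raise ValidationError(f"probabilities at {key} outside [0, 1]")

    def probability(self, story_id: str, mask_index: int, word: str) -> float:
        key = (story_id, mask_index)
        if key not in self.distributions:
            raise MissingWordError(
                f"no distribution for story {story_id!r} mask {mask_index}")
        dist = self.distributions[key]
        if word not in dist:
            raise MissingWordError(
                f"word {word!r} not in distribution for {key}")
        return dist[word]

    def write_json(self, path: str | Path) -> None:
        payload = {"model_id": self.model_id,
                   "distributions": {f"{sid}::{idx}": dist
                                     for (sid, idx), dist in self.distributions.items()}}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def read_json(cls, path: str | Path) -> "MaskedLMTable":
        payload = json.loads(Path(path).read_text())
        dists = {}
        for key, dist in payload["distributions"].items():
            sid, idx = key.rsplit("::", 1)
            dists[(sid, int(idx))] = dist
        return cls(distributions=dists, model_id=payload.get("model_id", ""))


@dataclass
class SemanticScores:
    """Per-story semantic-distance and surprise values for one model
    (or the across-model mean)."""

    table: pd.DataFrame  # columns: story_id, subject, condition, trial, model, SD, delta

    def __post_init__(self) -> None:
        required = {"story_id", "model", "SD", "delta"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"scores table missing columns {missing}")

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Core metrics
# ---------------------------------------------------------------------------

def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("zero-norm embedding vector")
    return float(np.dot(a, b) / (na * nb))


def semantic_distance(story: StoryTranscript, lexicon: EmbeddingLexicon,
                      skip_oov_non_targets: bool = False) -> float:
    """Mean cosine distance between targets and non-target content words.

    Out-of-vocabulary words raise :class:`MissingWordError` by default;
    ``skip_oov_non_targets`` drops missing *non-target* words instead
    (targets must always resolve).
    """
    targets = [lexicon[w] for w in story.target_words]
    non_targets = []
    for w in sorted(story.non_target_content_words):
        if w in lexicon:
            non_targets.append(lexicon[w])
        elif not skip_oov_non_targets:
            raise MissingWordError(f"non-target word {w!r} not in lexicon")
    if not non_targets:
        raise ValidationError("no scoreable non-target content words")
    total = 0.0
    for wi in targets:
        for wj in non_targets:
            total += 1.0 - _cosine(wi, wj)
    return total / (len(targets) * len(non_targets))


def surprise(story: StoryTranscript, table: MaskedLMTable,
             probability_floor: float | None = None) -> float:
    """Mean negative log-likelihood (nats) of the target words under the LM.

    Mask index ``i`` refers to the i-th target word of the story.  A zero
    probability raises unless ``probability_floor`` is set, in which case
    probabilities are floored at that value.
    """
    nll = 0.0
    for i, word in enumerate(story.target_words):
        p = table.probability(story.story_id, i, word)
        if probability_floor is not None:
            p = max(p, probability_floor)
        if p <= 0:
            raise ValidationError(
                f"zero probability for target {word!r} (infinite surprise); "
                "set probability_floor to allow")
        nll += -math.log(p)
    return nll / len(story.target_words)


def score_stories(stories: list[StoryTranscript],
                  lexicons: list[EmbeddingLexicon],
                  lm_tables: list[MaskedLMTable],
                  **kw) -> list[SemanticScores]:
    """Score every story under every model; one SemanticScores per model.

    Semantic distance comes from the embedding lexicons, surprise from the
    LM tables; models of the two families are scored independently (their
    counts may differ) and rows are tagged with the model id.
    """
    out = []
    for lex in lexicons:
        rows = [{"story_id": s.story_id, "subject": s.subject_id,
                 "condition": s.condition_label, "trial": s.trial_id,
                 "model": lex.model_id,
                 "SD": semantic_distance(s, lex, **kw), "delta": np.nan}
                for s in stories]
        out.append(SemanticScores(pd.DataFrame(rows)))
    for table in lm_tables:
        rows = [{"story_id": s.story_id, "subject": s.subject_id,
                 "condition": s.condition_label, "trial": s.trial_id,
                 "model": table.model_id,
                 "SD": np.nan, "delta": surprise(s, table)}
                for s in stories]
        out.append(SemanticScores(pd.DataFrame(rows)))
    return out


def aggregate_across_models(per_model_scores: list[SemanticScores]) -> SemanticScores:
    """Per-story arithmetic mean of SD and delta across models.

    SD is averaged over the embedding models (rows where SD is present) and
    delta over the LM models; all inputs must cover the same story set.
    """
    if not per_model_scores:
        raise ValidationError("no scores to aggregate")
    story_sets = [set(s.table["story_id"]) for s in per_model_scores]
    if any(ss != story_sets[0] for ss in story_sets[1:]):
        raise ValidationError("mismatched story sets across models")
    combined = pd.concat([s.table for s in per_model_scores], ignore_index=True)
    meta_cols = [c for c in ("subject", "condition", "trial") if c in combined]
    agg = (combined.groupby("story_id", sort=False)
           .agg({**{c: "first" for c in meta_cols}, "SD": "mean", "delta": "mean"})
           .reset_index())
    agg["model"] = "mean"
    return SemanticScores(agg)


# ---------------------------------------------------------------------------
# Stimulus triplet selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TripletCandidate:
    """Three candidate target words with their pairwise similarities and
    normalised corpus frequencies."""

    words: tuple[str, str, str]
    categories: tuple[str, str, str]
    similarities: tuple[float, float, float]  # (w1,w2), (w1,w3), (w2,w3)
    frequencies: tuple[float, float, float]   # normalised to [0, 1]

    def __post_init__(self) -> None:
        if len(set(self.words)) != 3:
            raise ValidationError("triplet words must be distinct")
        if len(set(self.categories)) != 3:
            raise ValidationError("at most one word per category")
        if any(f < 0 or f > 1 for f in self.frequencies):
            raise ValidationError("frequencies must lie in [0, 1]")

    @property
    def mse_score(self) -> float:
        """Mean squared deviation of the 6 values from their ideals
        (similarity ideal 0, frequency ideal 0.5)."""
        dev = [s ** 2 for s in self.similarities]
        dev += [(f - 0.5) ** 2 for f in self.frequencies]
        return sum(dev) / 6.0


class TripletShortfallError(RuntimeError):
    def __init__(self, requested: int, selectable: int):
        super().__init__(
            f"only {selectable} admissible triplets for a request of {requested}")
        self.requested = requested
        self.selectable = selectable


def select_triplets(pool: list[TripletCandidate], k: int) -> list[TripletCandidate]:
    """Greedy lowest-MSE selection with word-reuse exclusion.

    Candidates are scanned in ascending MSE (ties keep input order); a
    candidate sharing any word with an already-selected triplet is skipped.
    """
    order = sorted(range(len(pool)), key=lambda i: (pool[i].mse_score, i))
    chosen: list[TripletCandidate] = []
    used: set[str] = set()
    for i in order:
        cand = pool[i]
        if used & set(cand.words):
            continue
        chosen.append(cand)
        used.update(cand.words)
        if len(chosen) == k:
            return chosen
    raise TripletShortfallError(k, len(chosen))
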