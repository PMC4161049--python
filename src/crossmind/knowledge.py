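"""Associative memories built from clue-answer pairs.

Two memories back the solver: a *semantic* store associating clue-text
features (words and adjacent word bigrams) with answers, and an
*orthographic* store associating answer-form features (a length marker,
positional letters and positional letter bigrams) with answers.  Both are
sparse feature -> answer co-occurrence tables; association strength is
monotone in co-occurrence frequency, following stimulus-sampling accounts
of associative learning in which strength grows with exposure and, in the
optional saturating mode, asymptotes to a finite level.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

log = logging.getLogger(__name__)

SEMANTIC = "semantic"
ORTHOGRAPHIC = "orthographic"

#: placeholder token for fill-in-the-blank runs in clue text
BLANK_TOKEN = "__blank__"

#: separator inside word-bigram feature keys
BIGRAM_SEP = "▸"  # '▸'

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_BLANK_RE = re.compile(r"_+")
_NON_ALPHA_RE = re.compile(r"[^A-Z]")


class CorpusError(ValueError):
    """Raised for records or corpus files that cannot be ingested."""


@dataclass(frozen=True)
class ClueAnswerRecord:
    """One observed pairing of a clue with its (normalized) answer."""

    clue_text: str
    answer: str


@dataclass(frozen=True)
class FeatureSet:
    """The feature multiset extracted from a clue or a letter pattern.

    ``features`` keeps duplicates (a token repeated in a clue contributes
    once per occurrence); ``n_features`` is the multiset cardinality and is
    the root order of the geometric-mean combination rule.
    """

    modality: str
    features: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return len(self.features)

    def __bool__(self) -> bool:
        return bool(self.features)


def normalize_answer(raw: str) -> str:
    """Uppercase ``raw`` and strip every non A-Z character.

    Multiword answers collapse to their concatenation, matching the
    crossword grid alphabet.  Raises :class:`CorpusError` if nothing
    remains.
    """
    if not raw:
        raise CorpusError("empty answer")
    out = _NON_ALPHA_RE.sub("", raw.upper())
    if not out:
        raise CorpusError(f"answer {raw!r} is empty after normalization")
    return out


def semantic_features(clue_text: str) -> FeatureSet:
    """Tokenize a clue into lowercase words plus adjacent word bigrams.

    Runs of underscores (fill-in-the-blank markers) map to a single
    placeholder token; punctuation is stripped; stopwords are retained
    because they carry signal in crossword clues ("of the litter").
    """
    lowered = _BLANK_RE.sub(f" {BLANK_TOKEN} ", clue_text.lower())
    tokens = [
        t if t == BLANK_TOKEN else m
        for t in lowered.split()
        for m in ([t] if t == BLANK_TOKEN else _TOKEN_RE.findall(t))
    ]
    bigrams = [f"{a}{BIGRAM_SEP}{b}" for a, b in zip(tokens, tokens[1:])]
    return FeatureSet(SEMANTIC, tuple(tokens + bigrams))


UNKNOWN = "?"


def orthographic_features(pattern: str) -> FeatureSet:
    """Features of a letter pattern: length, positional letters/bigrams.

    Unknown cells (``?``) contribute nothing; a fully unknown pattern
    reduces to its length marker.  Position coding keeps the probe
    discriminative: ``C?T`` activates words with C first and T third, not
    words merely containing those letters.
    """
    feats = [f"LEN:{len(pattern)}"]
    for i, ch in enumerate(pattern):
        if ch != UNKNOWN:
            feats.append(f"P{i}:{ch}")
    for i, (a, b) in enumerate(zip(pattern, pattern[1:])):
        if a != UNKNOWN and b != UNKNOWN:
            feats.append(f"P{i}{i + 1}:{a}{b}")
    return FeatureSet(ORTHOGRAPHIC, tuple(feats))


@dataclass
class AssociationStore:
    """Sparse feature -> answer co-occurrence strengths for one modality.

    ``counts[feature][answer]`` holds the association strength,
    ``feature_totals[feature]`` its sum over answers (the normalizer of the
    per-feature conditional probability), and ``vocabulary`` the set of
    answers with any positive strength.  ``by_length`` indexes vocabulary by
    word length for pattern-constrained probes.
    """

    modality: str
    counts: dict[str, dict[str, float]] = field(default_factory=dict)
    feature_totals: dict[str, float] = field(default_factory=dict)
    vocabulary: set[str] = field(default_factory=set)
    by_length: dict[int, set[str]] = field(default_factory=dict)

    def add(self, feature: str, answer: str, strength: float = 1.0) -> None:
        if strength < 0:
            raise ValueError("association strength must be non-negative")
        row = self.counts.setdefault(feature, {})
        row[answer] = row.get(answer, 0.0) + strength
        self.feature_totals[feature] = self.feature_totals.get(feature, 0.0) + strength
        if answer not in self.vocabulary:
            self.vocabulary.add(answer)
            self.by_length.setdefault(len(answer), set()).add(answer)

    def strength(self, feature: str, answer: str) -> float:
        return self.counts.get(feature, {}).get(answer, 0.0)

    def conditional(self, feature: str, answer: str) -> float:
        """Pr(answer | feature): strength over the feature's total (0 if unseen)."""
        total = self.feature_totals.get(feature, 0.0)
        if total <= 0.0:
            return 0.0
        return self.counts[feature].get(answer, 0.0) / total

    def candidates(self, features: Iterable[str]) -> set[str]:
        """Answers with positive strength on at least one of ``features``."""
        out: set[str] = set()
        for f in features:
            out.update(self.counts.get(f, ()))
        return out

    def saturated(self, theta: float) -> "AssociationStore":
        """Return a copy with counts c mapped through 1 - (1-theta)^c.

        The saturating map realizes strength that grows with co-occurrence
        but asymptotes; theta=1 degenerates to presence/absence.
        """
        if not 0.0 < theta <= 1.0:
            raise ValueError("theta must lie in (0, 1]")
        out = AssociationStore(self.modality)
        for feature, row in self.counts.items():
            for answer, c in row.items():
                out.add(feature, answer, 1.0 - (1.0 - theta) ** c)
        return out

    # -- serialization: JSON-lines, one (modality, key, answer, strength) per line

    def dump(self, fh: TextIO) -> None:
        for feature in sorted(self.counts):
            row = self.counts[feature]
            for answer in sorted(row):
                rec = {
                    "modality": self.modality,
                    "key": feature,
                    "answer": answer,
                    "strength": row[answer],
                }
                fh.write(json.dumps(rec) + "\n")

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            self.dump(fh)

    @classmethod
    def load(cls, path: str | Path, modality: str | None = None) -> "AssociationStore":
        store: AssociationStore | None = None
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                if store is None:
                    store = cls(modality or rec["modality"])
                store.add(rec["key"], rec["answer"], rec["strength"])
        return store if store is not None else cls(modality or SEMANTIC)


def ingest_corpus(
    records: Iterable[ClueAnswerRecord | tuple[str, str]],
    mode: str = "counts",
    theta: float = 0.1,
) -> tuple[AssociationStore, AssociationStore]:
    """Build the (semantic, orthographic) stores from clue-answer records.

    ``mode='counts'`` (default) accumulates raw co-occurrence counts, the
    simplest strength map that is monotone in frequency; ``mode='saturating'``
    post-transforms each count c to 1-(1-theta)^c.  Malformed records are
    skipped with a log line, not fatal.
    """
    if mode not in ("counts", "saturating"):
        raise ValueError(f"unknown ingest mode {mode!r}")
    sem = AssociationStore(SEMANTIC)
    orth = AssociationStore(ORTHOGRAPHIC)
    n_ok = n_bad = 0
    for i, rec in enumerate(records):
        if isinstance(rec, tuple):
            rec = ClueAnswerRecord(*rec)
        try:
            answer = normalize_answer(rec.answer)
            feats = semantic_features(rec.clue_text)
        except CorpusError as exc:
            log.warning("skipping record %d: %s", i, exc)
            n_bad += 1
            continue
        for f in feats.features:
            sem.add(f, answer)
        for f in orthographic_features(answer).features:
            orth.add(f, answer)
        n_ok += 1
    log.info("ingested %d records (%d skipped)", n_ok, n_bad)
    if mode == "saturating":
        sem = sem.saturated(theta)
        orth = orth.saturated(theta)
    return sem, orth


def read_corpus(path: str | Path) -> Iterator[ClueAnswerRecord]:
    """Stream a TSV corpus: one ``clue<TAB>answer`` per line, '#' comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                log.warning("skipping malformed corpus line %d: %r", lineno, line)
                continue
            yield ClueAnswerRecord(parts[0].strip(), parts[1].strip())


def write_corpus(records: Iterable[ClueAnswerRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec.clue_text}\t{rec.answer}\n")
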