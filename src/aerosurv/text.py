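"""Keyword pre-filter and pluggable post-relevance classification.

Surveillance from social text is a two-stage funnel: a cheap keyword/hashtag
match retrieves candidate posts, then a trained classifier removes posts
that merely share vocabulary with genuine symptom reports ("Gluten and
Allergy Free expo" passes the keyword stage but is irrelevant). The
classifier is a pluggable interface — anything with ``classify(text)`` —
with a seeded linear bag-of-words reference implementation suitable for
desk-scale corpora; a transformer-backed implementation can be dropped in
without changes elsewhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Protocol, Sequence, runtime_checkable

import numpy as np

from .base import ConfigError, DegenerateInputError, PostRecord, SchemaError

__all__ = [
    "TermList",
    "DEFAULT_TERMS",
    "keyword_match",
    "RelevanceClassifier",
    "BagOfWordsClassifier",
    "train_classifier",
    "FilterLog",
    "filter_posts",
    "ClassifierMetrics",
    "evaluate_classifier",
    "stratified_split",
]

RELEVANT = "relevant"
IRRELEVANT = "irrelevant"


@dataclass(frozen=True)
class TermList:
    """Case-folded search terms and hashtags used by the pre-filter."""

    terms: tuple[str, ...]
    hashtags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        terms = tuple(t.casefold().strip() for t in self.terms)
        hashtags = tuple(h.casefold().strip() for h in self.hashtags)
        if not terms and not hashtags:
            raise ConfigError("TermList: at least one term or hashtag required")
        if any(not t for t in terms) or any(h in ("", "#") for h in hashtags):
            raise ConfigError("TermList: empty term or hashtag")
        if any(not h.startswith("#") for h in hashtags):
            raise ConfigError("TermList: hashtags must begin with '#'")
        if len(set(terms)) != len(terms) or len(set(hashtags)) != len(hashtags):
            raise ConfigError("TermList: duplicate entries after case-folding")
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "hashtags", hashtags)


#: shipped default of obvious allergy terms; the real retrieval list is data,
#: not algorithm, and is supplied through configuration
DEFAULT_TERMS = TermList(
    terms=("allergies", "allergy", "pollen", "hay fever", "antihistamine", "sneezing", "sneeze"),
    hashtags=("#allergies", "#pollen"),
)

_HASHTAG_RE = re.compile(r"#\w+", re.UNICODE)


def keyword_match(text: str, terms: TermList = DEFAULT_TERMS) -> bool:
    """True iff any term matches on word boundaries (case-insensitive) or
    any hashtag equals a ``#``-token of the text exactly."""
    if not text:
        return False
    folded = text.casefold()
    for term in terms.terms:
        if re.search(rf"(?<!\w){re.escape(term)}(?!\w)", folded):
            return True
    if terms.hashtags:
        tags = {m.group(0) for m in _HASHTAG_RE.finditer(folded)}
        if tags.intersection(terms.hashtags):
            return True
    return False


@runtime_checkable
class RelevanceClassifier(Protocol):
    """Anything that labels a post text relevant/irrelevant."""

    def classify(self, text: str) -> str: ...

    def classify_batch(self, texts: Sequence[str]) -> list[str]: ...


class BagOfWordsClassifier:
    """Seeded linear (logistic-regression) bag-of-words reference classifier.

    Tokenization: unicode word boundaries, case-folded, '#' kept as a token
    prefix, no stemming. Deterministic given the training data and seed.
    """

    _TOKEN_RE = r"#?\w+"

    def __init__(self, seed: int = 0, min_df: int = 1, C: float = 1.0) -> None:
        from sklearn.feature_extraction.text import CountVectorizer
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import Pipeline

        self.seed = int(seed)
        self._pipe = Pipeline(
            [
                (
                    "bow",
                    CountVectorizer(
                        lowercase=True,
                        token_pattern=self._TOKEN_RE,
                        min_df=min_df,
                    ),
                ),
                ("clf", LogisticRegression(C=C, max_iter=1000, random_state=self.seed)),
            ]
        )
        self._fitted = False

    def fit(self, texts: Sequence[str], labels: Sequence[str]) -> "BagOfWordsClassifier":
        labels = list(labels)
        classes = set(labels)
        if classes - {RELEVANT, IRRELEVANT}:
            raise SchemaError(f"label: unknown labels {sorted(classes - {RELEVANT, IRRELEVANT})}")
        if len(classes) < 2:
            raise DegenerateInputError("training data must contain both labels")
        self._pipe.fit(list(texts), labels)
        self._fitted = True
        return self

    def classify(self, text: str) -> str:
        return self.classify_batch([text])[0]

    def classify_batch(self, texts: Sequence[str]) -> list[str]:
        if not self._fitted:
            raise RuntimeError("classifier is not trained")
        if len(texts) == 0:
            return []
        return list(self._pipe.predict(list(texts)))


def train_classifier(
    posts: Iterable[PostRecord], seed: int = 0, min_df: int = 1, C: float = 1.0
) -> BagOfWordsClassifier:
    """Train the reference bag-of-words classifier on labeled posts."""
    texts, labels = [], []
    for p in posts:
        if p.label is None:
            raise SchemaError(f"label: post {p.post_id} is unlabeled")
        texts.append(p.text)
        labels.append(p.label)
    if not texts:
        raise DegenerateInputError("no labeled posts supplied")
    return BagOfWordsClassifier(seed=seed, min_df=min_df, C=C).fit(texts, labels)


@dataclass
class FilterLog:
    """Stage-by-stage accounting of the post-filtering funnel."""

    n_input: int = 0
    n_keyword_pass: int = 0
    n_classified_relevant: int = 0

    @property
    def n_keyword_fail(self) -> int:
        return self.n_input - self.n_keyword_pass

    @property
    def n_classified_irrelevant(self) -> int:
        return self.n_keyword_pass - self.n_classified_relevant


def filter_posts(
    posts: Iterable[PostRecord],
    terms: TermList,
    classifier: RelevanceClassifier,
) -> tuple[list[PostRecord], FilterLog]:
    """Keyword pre-filter then classifier; returns retained posts and a log.

    Stage order is fixed: a post failing the keyword match never reaches the
    classifier. Output is a subset of keyword-matching posts.
    """
    log = FilterLog()
    candidates: list[PostRecord] = []
    for post in posts:
        log.n_input += 1
        if keyword_match(post.text, terms):
            log.n_keyword_pass += 1
            candidates.append(post)
    if not candidates:
        return [], log
    preds = classifier.classify_batch([p.text for p in candidates])
    kept = [p for p, lab in zip(candidates, preds) if lab == RELEVANT]
    log.n_classified_relevant = len(kept)
    return kept, log


@dataclass(frozen=True)
class ClassifierMetrics:
    """Confusion counts and derived proportions; undefined ratios are None,
    never silently zero."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def accuracy(self) -> Optional[float]:
        n = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / n if n else None

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None


def evaluate_classifier(
    predictions: Sequence[str], truth: Sequence[str]
) -> ClassifierMetrics:
    """Confusion-matrix metrics with ``relevant`` as the positive class."""
    if len(predictions) != len(truth):
        raise SchemaError(
            f"predictions/truth length mismatch: {len(predictions)} vs {len(truth)}"
        )
    tp = fp = fn = tn = 0
    for pred, true in zip(predictions, truth):
        if pred == RELEVANT and true == RELEVANT:
            tp += 1
        elif pred == RELEVANT and true == IRRELEVANT:
            fp += 1
        elif pred == IRRELEVANT and true == RELEVANT:
            fn += 1
        elif pred == IRRELEVANT and true == IRRELEVANT:
            tn += 1
        else:
            raise SchemaError(f"label: unknown label pair ({pred!r}, {true!r})")
    return ClassifierMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


def stratified_split(
    posts: Sequence[PostRecord], test_fraction: float = 0.3, seed: int = 0
) -> tuple[list[PostRecord], list[PostRecord]]:
    """Seeded stratified train/test split on the ground-truth label."""
    if not 0.0 < test_fraction < 1.0:
        raise ConfigError("test_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train: list[PostRecord] = []
    test: list[PostRecord] = []
    by_label: dict[Optional[str], list[PostRecord]] = {}
    for p in posts:
        by_label.setdefault(p.label, []).append(p)
    for label in sorted(by_label, key=str):
        group = by_label[label]
        order = rng.permutation(len(group))
        n_test = int(round(test_fraction * len(group)))
        test.extend(group[i] for i in order[:n_test])
        train.extend(group[i] for i in order[n_test:])
    return train, test
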