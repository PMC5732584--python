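"""The four feature representations of a post: Set1, Set2, Set3, combined.

Set 1 holds lexical/structural features (part-of-speech tag frequencies,
negations, first-person use, URL/mention flags), general and affective
lexical-domain counts, summed token polarity scores, and one binary per
curated keyword phrase plus a global any-keyword binary.  Set 2 is the
per-category word counts of a psychological category lexicon (an open
stand-in with the classic category names: death, health, cognitive
mechanisms, affect, social words, ...).  Set 3 is binary pattern features
from a cleaned rule file of class-typical regular expressions and short
word lists for noisy social-media language.  The combined set is the
group-prefixed union, optionally compressed with PCA.
"""

from __future__ import annotations

import csv
import re
import warnings
from collections import Counter, OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.decomposition import PCA

from .corpus import ClassLabel, Post
from .lexicon import KeywordLexicon
from .tagging import PENN_TAGS, Tagger
from .tokenizer import MENTION_TOKEN, URL_TOKEN, ngrams, normalize_phrase, tokenize

CategoryLexicon = Mapping[str, Set[str]]

_FIRST_PERSON = {"i", "me", "my", "mine", "myself", "we", "us", "our", "ours", "ourselves"}


@dataclass
class FeatureVector:
    """Named numeric features for one post, grouped by feature set."""

    values: "OrderedDict[str, float]"
    group: str

    def __post_init__(self) -> None:
        if self.group not in ("set1", "set2", "set3", "text", "combined"):
            raise ValueError(f"unknown feature group: {self.group!r}")
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite feature value for {name!r}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RegexRule:
    """One class-typical pattern rule; patterns are case-insensitive."""

    id: str
    class_hint: ClassLabel
    pattern: str
    description: str = ""

    @property
    def compiled(self) -> "re.Pattern[str]":
        return re.compile(self.pattern, re.IGNORECASE)


def load_regex_rules(path: "str | Path") -> List[RegexRule]:
    """Read the rule file (CSV: id, class_hint, pattern, description)."""
    rules: List[RegexRule] = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            rule = RegexRule(
                id=row["id"],
                class_hint=ClassLabel.from_code(row["class_hint"]),
                pattern=row["pattern"],
                description=row.get("description", ""),
            )
            rule.compiled  # compile now so a bad pattern fails at load time
            rules.append(rule)
    if len({r.id for r in rules}) != len(rules):
        raise ValueError(f"{path}: duplicate rule ids")
    return rules


def _category_counts(tokens: Sequence[str], categories: CategoryLexicon, prefix: str) -> "OrderedDict[str, float]":
    out: "OrderedDict[str, float]" = OrderedDict()
    for name in sorted(categories):
        patterns = categories[name]
        stems = tuple(p[:-1] for p in patterns if p.endswith("*"))
        exact = {p for p in patterns if not p.endswith("*")}
        count = 0
        for tok in tokens:
            t = tok.lower()
            if t in exact or (stems and t.startswith(stems)):
                count += 1
        out[f"{prefix}.{name}"] = float(count)
    return out


def _keyword_hits(tokens: Sequence[str], lexicon: KeywordLexicon) -> "OrderedDict[str, float]":
    joined = " " + " ".join(tokens) + " "
    out: "OrderedDict[str, float]" = OrderedDict()
    any_hit = 0.0
    for phrase in lexicon:
        norm = normalize_phrase(phrase)
        hit = 1.0 if norm and f" {norm} " in joined else 0.0
        out[f"kw.{norm.replace(' ', '_')}"] = hit
        any_hit = max(any_hit, hit)
    out["kw.any"] = any_hit
    return out


def extract_set1(
    post: Post,
    lexicon: KeywordLexicon,
    tagger: Tagger,
    domains: CategoryLexicon,
    affect: CategoryLexicon,
    sentiment: Mapping[str, Tuple[float, float]],
    negations: Optional[Set[str]] = None,
) -> FeatureVector:
    """Lexical, structural, domain, affect, sentiment and keyword features."""
    if negations is None:
        from .resources import default_negations

        negations = default_negations()
    tokens = tokenize(post.text)
    try:
        tags = list(tagger(tokens))
    except Exception as exc:
        raise RuntimeError(f"POS tagger failed on post {post.id!r}: {exc}") from exc
    if len(tags) != len(tokens):
        raise RuntimeError(
            f"POS tagger returned {len(tags)} tags for {len(tokens)} tokens on post {post.id!r}"
        )

    values: "OrderedDict[str, float]" = OrderedDict()
    tag_counts = Counter(tags)
    for tag in PENN_TAGS:
        values[f"pos.{tag}"] = float(tag_counts.get(tag, 0))

    values["struct.negations"] = float(sum(1 for t in tokens if t in negations))
    values["struct.first_person"] = 1.0 if any(t in _FIRST_PERSON for t in tokens) else 0.0
    values["struct.url"] = 1.0 if URL_TOKEN in tokens else 0.0
    values["struct.mention"] = 1.0 if MENTION_TOKEN in tokens else 0.0

    values.update(_category_counts(tokens, domains, "domain"))
    values.update(_category_counts(tokens, affect, "affect"))

    pos_sum = sum(sentiment[t][0] for t in tokens if t in sentiment)
    neg_sum = sum(sentiment[t][1] for t in tokens if t in sentiment)
    values["senti.positive_sum"] = float(pos_sum)
    values["senti.negative_sum"] = float(neg_sum)

    values.update(_keyword_hits(tokens, lexicon))
    return FeatureVector(values, "set1")


def extract_set2(post: Post, categories: CategoryLexicon) -> FeatureVector:
    """Per-category token-match counts against a category lexicon."""
    tokens = tokenize(post.text)
    return FeatureVector(_category_counts(tokens, categories, "cat"), "set2")


def _normalize_for_rules(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip().lower())


def extract_set3(post: Post, rules: Sequence[RegexRule]) -> FeatureVector:
    """One binary per rule: does the pattern match the normalised text?"""
    text = _normalize_for_rules(post.text)
    values: "OrderedDict[str, float]" = OrderedDict()
    for rule in rules:
        values[f"rule.{rule.id}"] = 1.0 if rule.compiled.search(text) else 0.0
    return FeatureVector(values, "set3")


class TextVectorizer:
    """Raw n-gram count vectors over a vocabulary frozen at fit time.

    The vocabulary is the ``vocab_size`` most frequent n-grams by total
    corpus count (ties broken lexicographically); transforming unseen posts
    uses the frozen vocabulary, so out-of-vocabulary n-grams are ignored.
    """

    def __init__(self, ngram_min: int = 1, ngram_max: int = 3, vocab_size: int = 500) -> None:
        if vocab_size <= 0:
            raise ValueError("vocab_size must be positive")
        if ngram_min < 1 or ngram_max < ngram_min:
            raise ValueError("invalid n-gram range")
        self.ngram_min = ngram_min
        self.ngram_max = ngram_max
        self.vocab_size = vocab_size
        self.vocabulary_: Optional[List[str]] = None

    @staticmethod
    def _texts(corpus: Sequence["Post | str"]) -> List[str]:
        return [p.text if isinstance(p, Post) else str(p) for p in corpus]

    def fit(self, corpus: Sequence["Post | str"]) -> "TextVectorizer":
        if not corpus:
            raise ValueError("corpus must be non-empty")
        totals: Counter = Counter()
        for text in self._texts(corpus):
            totals.update(ngrams(tokenize(text), self.ngram_min, self.ngram_max))
        ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
        self.vocabulary_ = [term for term, _ in ranked[: self.vocab_size]]
        return self

    def transform(self, corpus: Sequence["Post | str"]) -> np.ndarray:
        if self.vocabulary_ is None:
            raise RuntimeError("vectorizer is not fitted")
        index = {t: j for j, t in enumerate(self.vocabulary_)}
        X = np.zeros((len(corpus), len(self.vocabulary_)), dtype=int)
        for i, text in enumerate(self._texts(corpus)):
            for gram in ngrams(tokenize(text), self.ngram_min, self.ngram_max):
                j = index.get(gram)
                if j is not None:
                    X[i, j] += 1
        return X

    def fit_transform(self, corpus: Sequence["Post | str"]) -> np.ndarray:
        return self.fit(corpus).transform(corpus)

    def feature_vector(self, post: Post) -> FeatureVector:
        row = self.transform([post])[0]
        values = OrderedDict(
            (f"ng.{t.replace(' ', '_')}", float(v)) for t, v in zip(self.vocabulary_, row)
        )
        return FeatureVector(values, "text")


def vectorize_text(
    corpus: Sequence["Post | str"],
    ngram_min: int = 1,
    ngram_max: int = 3,
    vocab_size: int = 500,
) -> Tuple[List[str], np.ndarray]:
    """Fit a vocabulary on ``corpus`` and return (vocabulary, count matrix)."""
    vec = TextVectorizer(ngram_min, ngram_max, vocab_size)
    X = vec.fit_transform(corpus)
    return list(vec.vocabulary_ or []), X


def combine(vectors: Sequence[FeatureVector]) -> FeatureVector:
    """Concatenate feature vectors with group-prefixed names."""
    if not vectors:
        raise ValueError("combine requires at least one feature vector")
    values: "OrderedDict[str, float]" = OrderedDict()
    for vec in vectors:
        for name, v in vec.values.items():
            key = f"{vec.group}.{name}"
            if key in values:
                raise ValueError(f"feature name collision: {key!r}")
            values[key] = v
    return FeatureVector(values, "combined")


def features_to_matrix(vectors: Sequence[FeatureVector]) -> Tuple[List[str], np.ndarray]:
    """Stack equally-named feature vectors into (names, dense matrix)."""
    if not vectors:
        raise ValueError("no feature vectors")
    names = list(vectors[0].values.keys())
    for v in vectors[1:]:
        if list(v.values.keys()) != names:
            raise ValueError("feature vectors have differing feature names")
    X = np.array([[v.values[n] for n in names] for v in vectors], dtype=float)
    return names, X


def pca_reduce(
    matrix: np.ndarray, variance_kept: float = 0.95
) -> Tuple[np.ndarray, np.ndarray]:
    """Centre the matrix and project it onto its leading principal components.

    Keeps the smallest prefix of components whose cumulative explained
    variance share reaches ``variance_kept``.  Returns ``(components,
    transformed)`` where ``components`` has one orthonormal component per
    row.  A constant matrix has no variance to explain: it yields zero
    components with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("pca_reduce needs a 2-D matrix with at least 2 rows")
    if not 0 < variance_kept <= 1:
        raise ValueError("variance_kept must be in (0, 1]")
    if np.allclose(X, X[0]):
        warnings.warn("constant matrix: no principal components retained")
        return np.zeros((0, X.shape[1])), np.zeros((X.shape[0], 0))
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    shares = pca.explained_variance_ratio_
    n_keep = int(np.searchsorted(np.cumsum(shares), variance_kept - 1e-12) + 1)
    n_keep = min(n_keep, scores.shape[1])
    return pca.components_[:n_keep], scores[:, :n_keep]
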