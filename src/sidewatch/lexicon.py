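"""Induction and curation of the ranked suicide-related keyword lexicon.

The lexicon is induced from a binary-labelled corpus (ideation vs not) by a
tf-idf contrast: per-document tf-idf uses raw term counts and
``idf = ln(N/df)`` with no smoothing, and a term's score is its mean tf-idf
over positive-label documents minus its mean over negative-label documents
(method ``"difference"``, the default).  The alternative reading — ranking
by the ratio of the two means — is available as method ``"ratio"``.  The
top-ranked terms are then manually curated (duplicates and non-specific
terms removed) into the final keyword lexicon used as Set 1 features and as
collection search terms.
"""

from __future__ import annotations

import csv
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .tokenizer import ngrams, normalize_phrase, tokenize


@dataclass(frozen=True)
class ScoredTerm:
    """A ranked n-gram with its contrast score and document frequency."""

    term: str
    score: float
    df: int


@dataclass
class KeywordLexicon:
    """An ordered, curated list of keyword phrases."""

    terms: List[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("keyword lexicon must be non-empty")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("keyword lexicon terms must be unique")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)


def score_terms(
    corpus: Sequence[Tuple[str, int]],
    ngram_min: int = 1,
    ngram_max: int = 5,
    top_k: int = 500,
    method: str = "difference",
) -> List[ScoredTerm]:
    """Rank n-gram terms by their tf-idf contrast between the two classes.

    ``corpus`` is a sequence of ``(text, label)`` with binary labels (truthy
    = ideation class).  Terms are n-grams of ``ngram_min``..``ngram_max``
    tokens from the canonical tokenizer.  Returns the ``top_k`` terms by
    descending score, ties broken lexicographically; the ranking is
    invariant under document order.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if method not in ("difference", "ratio"):
        raise ValueError(f"unknown contrast method: {method!r}")
    labels = [bool(lbl) for _, lbl in corpus]
    if not labels or all(labels) or not any(labels):
        raise ValueError("corpus must contain both a positive and a negative class")

    doc_grams: List[Counter] = []
    df: Counter = Counter()
    for text, _ in corpus:
        grams = Counter(ngrams(tokenize(text), ngram_min, ngram_max))
        doc_grams.append(grams)
        df.update(grams.keys())

    n_docs = len(corpus)
    n_pos = sum(labels)
    n_neg = n_docs - n_pos
    idf = {t: math.log(n_docs / d) for t, d in df.items()}

    pos_sum: Dict[str, float] = {t: 0.0 for t in df}
    neg_sum: Dict[str, float] = {t: 0.0 for t in df}
    for grams, is_pos in zip(doc_grams, labels):
        target = pos_sum if is_pos else neg_sum
        for term, tf in grams.items():
            target[term] += tf * idf[term]

    scored = []
    for term in df:
        mean_pos = pos_sum[term] / n_pos
        mean_neg = neg_sum[term] / n_neg
        if method == "difference":
            score = mean_pos - mean_neg
        else:
            score = mean_pos / mean_neg if mean_neg > 0 else math.inf
        scored.append(ScoredTerm(term, score, df[term]))
    scored.sort(key=lambda st: (-st.score, st.term))
    return scored[:top_k]


def curate(ranked: Sequence[ScoredTerm | str], removals: Iterable[str]) -> KeywordLexicon:
    """Curate a ranked term list into the final keyword lexicon.

    Removes the ``removals`` (warning about removals not present in the
    ranked list) and case/tokenization duplicates, preserving rank order.
    """
    terms = [st.term if isinstance(st, ScoredTerm) else str(st) for st in ranked]
    norm_removals = {normalize_phrase(r) for r in removals}
    present = {normalize_phrase(t) for t in terms}
    missing = norm_removals - present
    if missing:
        warnings.warn(f"removals not present in ranked list: {sorted(missing)}")
    out: List[str] = []
    seen = set()
    for t in terms:
        norm = normalize_phrase(t)
        if norm in norm_removals or norm in seen:
            continue
        seen.add(norm)
        out.append(t)
    if not out:
        raise ValueError("curation removed every term")
    return KeywordLexicon(out, provenance=f"curated {len(terms)} ranked terms -> {len(out)}")


def load_keyword_lexicon(path: "str | Path", provenance: Optional[str] = None) -> KeywordLexicon:
    """Load a keyword lexicon file (one phrase per line, ``#`` comments)."""
    path = Path(path)
    terms = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.append(line)
    return KeywordLexicon(terms, provenance=provenance or str(path))


def default_keyword_lexicon() -> KeywordLexicon:
    """The bundled reconstructed 62-phrase keyword lexicon.

    Built by curating the shipped ranked list with the shipped removal
    file.  The list is a reconstruction: it contains every phrase the
    original curated lexicon is known to include, topped up with
    closely-related ideation phrasing to the documented size of 62.
    """
    from .resources import default_keyword_files

    ranked_path, removals_path = default_keyword_files()
    ranked = load_keyword_lexicon(ranked_path).terms
    removals = load_keyword_lexicon(removals_path).terms
    lex = curate(ranked, removals)
    lex.provenance = "bundled reconstructed keyword lexicon"
    return lex


def export_ranked_terms(ranked: Sequence[ScoredTerm], path: "str | Path") -> None:
    """Write a ranked term list as CSV (term, score, df)."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["term", "score", "df"])
        for st in ranked:
            writer.writerow([st.term, f"{st.score:.6g}", st.df])
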