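"""Canonical tokenizer shared by the lexicon and feature modules.

Short social-media posts are lowercased, URLs are collapsed to the
placeholder token ``URL`` and @-mentions to ``MENTION`` (returned uppercase
so they cannot collide with the ordinary words "url"/"mention"), and
apostrophes are kept inside tokens so contractions like "don't" stay single
tokens.  Everything else that is not a word character is a separator.
"""

from __future__ import annotations

import re
from typing import Iterable, List

URL_TOKEN = "URL"
MENTION_TOKEN = "MENTION"

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_TOKEN_RE = re.compile(r"[a-z0-9_\x00]+(?:'[a-z0-9_]+)*")

# \x00-wrapped sentinels survive lowercasing and cannot occur in user text
_URL_SENTINEL = "\x00url\x00"
_MENTION_SENTINEL = "\x00mention\x00"


def tokenize(text: str) -> List[str]:
    """Split ``text`` into lowercase tokens with URL/mention placeholders."""
    text = _URL_RE.sub(" " + _URL_SENTINEL + " ", text)
    text = _MENTION_RE.sub(" " + _MENTION_SENTINEL + " ", text)
    out: List[str] = []
    for tok in _TOKEN_RE.findall(text.lower()):
        tok = tok.strip("'")
        if not tok:
            continue
        if "\x00" in tok:
            if tok.strip("\x00") == "url":
                out.append(URL_TOKEN)
            elif tok.strip("\x00") == "mention":
                out.append(MENTION_TOKEN)
            continue
        out.append(tok)
    return out


def ngrams(tokens: Iterable[str], n_min: int, n_max: int) -> List[str]:
    """All space-joined n-grams of ``tokens`` with n_min <= n <= n_max."""
    toks = list(tokens)
    grams: List[str] = []
    for n in range(n_min, n_max + 1):
        grams.extend(" ".join(toks[i:i + n]) for i in range(len(toks) - n + 1))
    return grams


def normalize_phrase(phrase: str) -> str:
    """Canonical form of a keyword phrase: its token stream re-joined."""
    return " ".join(tokenize(phrase))
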