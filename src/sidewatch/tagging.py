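"""A small deterministic part-of-speech tagger over the 36-tag newswire tagset.

Feature extraction only needs per-tag frequency counts, so the bundled
tagger is a lexicon + suffix-rule tagger: tokens found in the bundled word
list get their listed tag, otherwise a handful of morphological suffix
rules apply, and everything else is tagged as a singular noun.  It needs no
model download and is reproducible; any callable with the same contract
(tokens in, one tag per token out) can be plugged in instead, e.g. a
wrapper around a production statistical tagger.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence

from .tokenizer import MENTION_TOKEN, URL_TOKEN

# the standard 36-tag newswire tagset
PENN_TAGS = (
    "CC CD DT EX FW IN JJ JJR JJS LS MD NN NNS NNP NNPS PDT POS PRP PRP$ "
    "RB RBR RBS RP SYM TO UH VB VBD VBG VBN VBP VBZ WDT WP WP$ WRB"
).split()

Tagger = Callable[[Sequence[str]], List[str]]


class SimpleTagger:
    """Deterministic lexicon + suffix tagger.

    Parameters
    ----------
    lexicon:
        token -> tag mapping; defaults to the bundled word list.
    """

    def __init__(self, lexicon: Optional[Dict[str, str]] = None) -> None:
        if lexicon is None:
            from .resources import resource_path

            lexicon = {}
            with resource_path("postag_lexicon.csv").open(encoding="utf-8", newline="") as fh:
                for row in csv.DictReader(fh):
                    lexicon[row["word"].lower()] = row["tag"]
        bad = set(lexicon.values()) - set(PENN_TAGS)
        if bad:
            raise ValueError(f"tags outside the tagset: {sorted(bad)}")
        self.lexicon = dict(lexicon)

    def __call__(self, tokens: Sequence[str]) -> List[str]:
        return [self.tag_token(t) for t in tokens]

    def tag_token(self, token: str) -> str:
        if token in (URL_TOKEN, MENTION_TOKEN):
            return "NNP"
        tok = token.lower()
        if tok in self.lexicon:
            return self.lexicon[tok]
        if tok.isdigit():
            return "CD"
        if tok.startswith("#"):
            return "NN"
        # morphological fallbacks, most specific first
        if tok.endswith("ing") and len(tok) > 4:
            return "VBG"
        if tok.endswith("ed") and len(tok) > 3:
            return "VBD"
        if tok.endswith("ly") and len(tok) > 3:
            return "RB"
        if tok.endswith("est") and len(tok) > 4:
            return "JJS"
        if tok.endswith("s") and not tok.endswith(("ss", "us", "is")) and len(tok) > 3:
            return "NNS"
        return "NN"
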