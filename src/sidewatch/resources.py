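"""Loaders for the resource files bundled with the package.

Everything here is plain text: word lists (one entry per line, ``#``
comments), LIWC-dictionary-style category lexicons, CSV tables, and the
bundled reference tables used by the worked examples.  Paths default to the
files shipped under ``sidewatch/data`` but every loader accepts an
explicit path so callers can substitute their own resources.
"""

from __future__ import annotations

import csv
import hashlib
import json
from importlib import resources as _ilr
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import numpy as np


def resource_path(name: str) -> Path:
    """Filesystem path of a bundled resource file."""
    return Path(str(_ilr.files("sidewatch.data").joinpath(name)))


def resource_checksum(path: "str | Path") -> str:
    """SHA-256 hex digest of a resource file (used by run manifests)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_wordlist(path: "str | Path") -> List[str]:
    """One entry per line; blank lines and ``#`` comment lines skipped."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_category_lexicon(path: "str | Path") -> Dict[str, Set[str]]:
    """Parse a LIWC-dictionary-style category lexicon.

    The format is a ``%``-delimited header mapping numeric ids to category
    names, followed by ``word<TAB>id [id ...]`` lines; word entries ending
    in ``*`` are prefix (stem) patterns.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].strip() != "%":
        raise ValueError(f"{path}: expected '%' header delimiter")
    idx = {}
    i = 1
    while i < len(lines) and lines[i].strip() != "%":
        parts = lines[i].split()
        if len(parts) >= 2:
            idx[parts[0]] = parts[1]
        i += 1
    if i >= len(lines):
        raise ValueError(f"{path}: missing closing '%' delimiter")
    categories: Dict[str, Set[str]] = {name: set() for name in idx.values()}
    for line in lines[i + 1:]:
        parts = line.split()
        if len(parts) < 2:
            continue
        word = parts[0].lower()
        for cid in parts[1:]:
            if cid not in idx:
                raise ValueError(f"{path}: unknown category id {cid!r} for {word!r}")
            categories[idx[cid]].add(word)
    return categories


def read_sentiment_lexicon(path: "str | Path") -> Dict[str, Tuple[float, float]]:
    """token -> (positive, negative) scores, each in [0, 1]."""
    out: Dict[str, Tuple[float, float]] = {}
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            tok = row["token"].lower()
            if tok not in out:  # first-listed sense wins
                out[tok] = (float(row["positive"]), float(row["negative"]))
    return out


def read_name_lexicon(path: "str | Path") -> Dict[str, str]:
    """name -> gender category in {male, female, unisex}, lowercased."""
    out: Dict[str, str] = {}
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            gender = row["gender"].strip().lower()
            if gender not in ("male", "female", "unisex"):
                raise ValueError(f"{path}: bad gender {gender!r}")
            out[row["name"].strip().lower()] = gender
    return out


# -- default bundled resources -------------------------------------------

def default_keyword_files() -> Tuple[Path, Path]:
    return resource_path("keywords_ranked.txt"), resource_path("keywords_removals.txt")


def default_regex_rules_path() -> Path:
    return resource_path("regex_rules.csv")


def default_category_lexicon() -> Dict[str, Set[str]]:
    return read_category_lexicon(resource_path("categories.dic"))


def default_domain_lexicon() -> Dict[str, Set[str]]:
    return read_category_lexicon(resource_path("domains.dic"))


def default_affect_lexicon() -> Dict[str, Set[str]]:
    return read_category_lexicon(resource_path("affect.dic"))


def default_sentiment_lexicon() -> Dict[str, Tuple[float, float]]:
    return read_sentiment_lexicon(resource_path("sentiment.csv"))


def default_negations() -> Set[str]:
    return set(read_wordlist(resource_path("negations.txt")))


def default_name_lexicon() -> Dict[str, str]:
    return read_name_lexicon(resource_path("names.csv"))


def default_counties() -> List[str]:
    return read_wordlist(resource_path("counties.txt"))


def default_us_ambiguous() -> List[str]:
    return read_wordlist(resource_path("us_ambiguous.txt"))


def default_age_filters() -> List[str]:
    return read_wordlist(resource_path("age_filters.txt"))


def default_fillers() -> List[str]:
    return read_wordlist(resource_path("fillers.txt"))


def load_reference_confusion(path: Optional["str | Path"] = None) -> "np.ndarray":
    """Bundled 7x7 reference confusion matrix (rows true, columns predicted).

    A published benchmark grid for a seven-class suicide-communication
    classifier evaluated on 601 annotated posts; used by the worked
    examples and as an exact oracle input for the metrics layer.
    """
    path = Path(path) if path is not None else resource_path("reference_confusion_7class.csv")
    with path.open(encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    grid = np.array([[int(v) for v in row[1:]] for row in rows[1:]], dtype=int)
    if grid.shape != (7, 7):
        raise ValueError(f"{path}: expected a 7x7 grid, got {grid.shape}")
    return grid


def load_case_study_counts() -> dict:
    """Bundled summary counts from a published 12-month monitoring study."""
    return json.loads(resource_path("case_study_counts.json").read_text(encoding="utf-8"))
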