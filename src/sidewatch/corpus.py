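"""Data model, readers/writers, annotation-agreement resolution and filters.

A corpus is a list of :class:`AnnotatedPost`: one short text plus the
label-sets assigned by (at least four) independent human annotators.  Each
annotator may select several of the seven communication classes; the unit's
*agreement* is the fraction of annotators whose label-set contains the modal
label, and units below a 75% agreement threshold carry no resolved label and
are dropped before training.
"""

from __future__ import annotations

import csv
import enum
import json
import math
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Set, Tuple


class ClassLabel(enum.Enum):
    """The seven suicide-related communication classes."""

    c1 = "Evidence of possible suicidal intent"
    c2 = "Campaigning (i.e. petitions etc.)"
    c3 = "Flippant reference to suicide"
    c4 = "Information or support"
    c5 = "Memorial or condolence"
    c6 = "Reporting of suicide (not bombing)"
    c7 = "None of the above"

    @property
    def code(self) -> str:
        return self.name

    @property
    def description(self) -> str:
        return self.value

    @property
    def index(self) -> int:
        """0-based class index (c1 -> 0)."""
        return int(self.name[1]) - 1

    @classmethod
    def from_code(cls, code: str) -> "ClassLabel":
        code = code.strip().lower()
        try:
            return cls[code]
        except KeyError:
            raise ValueError(f"unknown class label code: {code!r}") from None


CLASS_LABELS: Tuple[ClassLabel, ...] = tuple(ClassLabel)


@dataclass(frozen=True)
class Post:
    """One short text with optional author/profile metadata."""

    id: str
    text: str
    timestamp: Optional[datetime] = None
    profile_name: Optional[str] = None
    profile_location: Optional[str] = None
    time_zone: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(f"post {self.id!r}: text empty after whitespace strip")


@dataclass
class AnnotatedPost:
    """A post plus per-annotator label-sets and the resolved majority label."""

    post: Post
    annotator_labels: List[Set[ClassLabel]]
    agreement: float = 0.0
    resolved_label: Optional[ClassLabel] = None

    @classmethod
    def from_labels(
        cls,
        post: Post,
        annotator_labels: Sequence[Set[ClassLabel]],
        min_annotators: int = 4,
        threshold: float = 0.75,
    ) -> "AnnotatedPost":
        resolved, agreement = resolve_majority(
            annotator_labels, min_annotators=min_annotators, threshold=threshold
        )
        return cls(post, [set(s) for s in annotator_labels], agreement, resolved)


def resolve_majority(
    annotator_labels: Sequence[Set[ClassLabel]],
    min_annotators: int = 4,
    threshold: float = 0.75,
) -> Tuple[Optional[ClassLabel], float]:
    """Majority resolution of multi-label annotations with agreement filter.

    The modal label is the class appearing in most annotator label-sets
    (multi-label entries count toward every listed class; ties broken by
    lowest class index).  An annotator *agrees* when the modal label is a
    member of its label-set.  The modal label is returned only when there
    are at least ``min_annotators`` annotators and the agreement fraction
    reaches ``threshold``; otherwise ``None`` is returned together with the
    agreement value.
    """
    if not annotator_labels:
        raise ValueError("at least one annotator is required")
    if any(not s for s in annotator_labels):
        raise ValueError("empty annotator label-set")
    counts = {lbl: 0 for lbl in CLASS_LABELS}
    for label_set in annotator_labels:
        for lbl in label_set:
            counts[lbl] += 1
    modal = max(CLASS_LABELS, key=lambda l: (counts[l], -l.index))
    n = len(annotator_labels)
    agreement = sum(1 for s in annotator_labels if modal in s) / n
    if n >= min_annotators and agreement >= threshold:
        return modal, agreement
    return None, agreement


def _parse_label_sets(raw: str) -> List[Set[ClassLabel]]:
    """Decode ``"c1|c1,c3|c5"`` into one label-set per annotator."""
    sets: List[Set[ClassLabel]] = []
    for part in raw.split("|"):
        part = part.strip()
        if not part:
            raise ValueError("empty annotator label-set")
        sets.append({ClassLabel.from_code(c) for c in part.split(",")})
    return sets


def _parse_timestamp(raw: object) -> Optional[datetime]:
    if raw in (None, "", float("nan")):
        return None
    if isinstance(raw, datetime):
        dt = raw
    else:
        dt = datetime.fromisoformat(str(raw))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def read_corpus(
    path: "str | Path",
    format: Optional[str] = None,
    min_annotators: int = 4,
    threshold: float = 0.75,
) -> List[AnnotatedPost]:
    """Read an annotated corpus from a JSONL or CSV file.

    JSONL records carry ``id``, ``text``, optional metadata fields, and
    ``labels`` as a list of per-annotator lists of class codes.  CSV files
    use the columns ``id,text,timestamp,profile_name,profile_location,
    time_zone,labels`` with label-sets pipe-and-comma encoded
    (``"c1|c1,c3|c5"``).  Duplicate ids and unknown class codes are errors
    naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format: {format!r}")

    out: List[AnnotatedPost] = []
    seen_ids: Set[str] = set()

    def add(record: dict, label_sets: List[Set[ClassLabel]], lineno: int) -> None:
        pid = str(record["id"])
        if pid in seen_ids:
            raise ValueError(f"{path}:{lineno}: duplicate post id {pid!r}")
        seen_ids.add(pid)
        post = Post(
            id=pid,
            text=str(record["text"]),
            timestamp=_parse_timestamp(record.get("timestamp")),
            profile_name=record.get("profile_name") or None,
            profile_location=record.get("profile_location") or None,
            time_zone=record.get("time_zone") or None,
        )
        out.append(
            AnnotatedPost.from_labels(
                post, label_sets, min_annotators=min_annotators, threshold=threshold
            )
        )

    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                    if "id" not in rec or "text" not in rec or "labels" not in rec:
                        raise ValueError("missing required key (id, text, labels)")
                    label_sets = [
                        {ClassLabel.from_code(c) for c in ann} for ann in rec["labels"]
                    ]
                    if any(not s for s in label_sets):
                        raise ValueError("empty annotator label-set")
                except (json.JSONDecodeError, ValueError, TypeError, KeyError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
                add(rec, label_sets, lineno)
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"id", "text", "labels"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ValueError(f"{path}: CSV must have columns {sorted(required)}")
            for lineno, rec in enumerate(reader, start=2):
                try:
                    label_sets = _parse_label_sets(rec["labels"])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
                add(rec, label_sets, lineno)
    return out


def write_corpus(records: Iterable[AnnotatedPost], path: "str | Path", format: str = "jsonl") -> None:
    """Write a corpus in the same JSONL/CSV layout :func:`read_corpus` reads."""
    path = Path(path)
    rows = []
    for ap in records:
        p = ap.post
        rows.append(
            {
                "id": p.id,
                "text": p.text,
                "timestamp": p.timestamp.isoformat() if p.timestamp else "",
                "profile_name": p.profile_name or "",
                "profile_location": p.profile_location or "",
                "time_zone": p.time_zone or "",
                "labels": [sorted(l.code for l in s) for s in ap.annotator_labels],
            }
        )
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(
                fh,
                fieldnames=[
                    "id", "text", "timestamp", "profile_name",
                    "profile_location", "time_zone", "labels",
                ],
            )
            writer.writeheader()
            for row in rows:
                row = dict(row)
                row["labels"] = "|".join(",".join(s) for s in row["labels"])
                writer.writerow(row)
    else:
        raise ValueError(f"unknown corpus format: {format!r}")


def filter_long_posts(posts: Sequence[Post]) -> List[Post]:
    """Drop posts more than five percent longer than the collection mean.

    Length is measured in characters and the cutoff 1.05 x mean is computed
    on the input collection, so re-applying the filter to its own output can
    tighten the cutoff further; it is applied once per source collection.
    """
    if not posts:
        raise ValueError("filter_long_posts requires a non-empty list")
    mean_len = sum(len(p.text) for p in posts) / len(posts)
    cutoff = 1.05 * mean_len
    return [p for p in posts if len(p.text) <= cutoff]


_WORD_RE = re.compile(r"[a-z]+")


def filter_geography(
    posts: Sequence[Post],
    counties: Sequence[str],
    timezone_name: str = "London",
    us_ambiguous: Sequence[str] = (),
) -> List[Post]:
    """Keep posts plausibly originating from the target region.

    A post is kept iff its profile time zone equals ``timezone_name`` or its
    profile location contains a county name (case-insensitive token-sequence
    match) that is not on the ``us_ambiguous`` exclusion list of place names
    with US equivalents.
    """
    ambiguous = {c.strip().lower() for c in us_ambiguous}
    county_tokens = [
        tuple(_WORD_RE.findall(c.lower()))
        for c in counties
        if c.strip() and c.strip().lower() not in ambiguous
    ]
    kept: List[Post] = []
    for p in posts:
        if p.time_zone and p.time_zone.strip().lower() == timezone_name.strip().lower():
            kept.append(p)
            continue
        if p.profile_location:
            toks = tuple(_WORD_RE.findall(p.profile_location.lower()))
            ok = False
            for ct in county_tokens:
                n = len(ct)
                if n and any(toks[i:i + n] == ct for i in range(len(toks) - n + 1)):
                    ok = True
                    break
            if ok:
                kept.append(p)
    return kept
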