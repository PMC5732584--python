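"""Synthetic labelled corpora with the statistical structure the classifier assumes.

The generator emits short posts (<= 140 characters) built from class-typical
template phrases embedded in neutral filler text, with configurable rates
of URLs, @-mentions, character typos and — crucially — *shared phrases*:
suicidal-ideation phrasing injected into flippant-class posts, emulating
the real confusion between genuine ideation (c1) and flippant usage (c3).
Class proportions default to the annotated-corpus distribution (c1 13%,
c2 5%, c3 30%, c4 6%, c5 5%, c6 15%, c7 26%).  A companion operation
simulates noisy multi-annotator labels for the agreement-filter pipeline.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta, timezone
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .corpus import CLASS_LABELS, AnnotatedPost, ClassLabel, Post

# class-typical phrases; each c1 template fires at least one class-1 pattern
# rule and no c3 template fires any (the shared-phrase mechanism is the only
# designed route for ideation phrasing into flippant posts)
DEFAULT_TEMPLATES: Dict[str, List[str]] = {
    "c1": [
        "i want to die",
        "i don't want to exist",
        "asleep and never wake",
        "i want to end it all",
        "i can't take it anymore",
        "i can't go on",
        "suicidal thoughts again",
        "i don't want to be alive",
        "wanna die in my sleep",
        "never want to wake up",
    ],
    "c2": [
        "sign the petition and call for help",
        "we need help to shut this site down",
        "stop the bullying now",
        "a plea to offer help",
        "ask for help and stop this",
    ],
    "c3": [
        "might as well kill myself",
        "i hate myself for that",
        "school is killing me",
        "ugh work again kill me now",
        "just missed the bus like kill me",
        "my boyfriend watched it without me kill me",
        "throw myself out the window if school runs late",
    ],
    "c4": [
        "talk to someone if you are struggling",
        "speak to somebody you trust",
        "mental health advice on our blog",
        "find support on the web",
        "good advice if you need to talk to anyone",
    ],
    "c5": [
        "miss you so much every single morning",
        "you were killed a year ago rip",
        "a month since you died rip",
        "still miss him terribly rip",
        "miss her more every single morning",
    ],
    "c6": [
        "actor took his own life reports say",
        "she has taken her own life aged 40",
        "man found hanged local news reports",
        "overdose confirmed by the coroner",
        "news reports he took his own life",
    ],
    "c7": [
        "nothing much happening this morning",
        "another quiet evening with tea",
        "the train was late again",
        "watching the same series again tonight",
        "lovely sunny morning for a stroll",
    ],
}

# ideation phrases injected into flippant posts by shared_phrase_rate
SHARED_PHRASES = [
    "i want to die",
    "i can't take it anymore",
    "i want to end it all",
    "suicidal thoughts",
]

DEFAULT_PROPORTIONS: Dict[str, float] = {
    "c1": 0.13, "c2": 0.05, "c3": 0.30, "c4": 0.06,
    "c5": 0.05, "c6": 0.15, "c7": 0.26,
}


@dataclass
class GeneratorConfig:
    n_posts: int = 1000
    class_proportions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    phrase_templates: Dict[str, List[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_TEMPLATES.items()}
    )
    url_rate: float = 0.10
    mention_rate: float = 0.15
    typo_rate: float = 0.05
    shared_phrase_rate: float = 0.0
    n_annotators: int = 4
    annotator_error_rate: float = 0.0
    start_date: date = date(2014, 2, 1)
    n_days: int = 365
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        for name in ("url_rate", "mention_rate", "typo_rate", "shared_phrase_rate",
                     "annotator_error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_posts < 1:
            raise ValueError("n_posts must be positive")
        for code, frac in self.class_proportions.items():
            if frac > 0 and not self.phrase_templates.get(code):
                raise ValueError(f"class {code} has proportion {frac} but no templates")


def _fillers() -> List[str]:
    from .resources import default_fillers

    return default_fillers()


def _typo(word: str, rng: np.random.Generator) -> str:
    if len(word) < 4:
        return word
    i = int(rng.integers(1, len(word) - 2))
    return word[:i] + word[i + 1] + word[i] + word[i + 2:]


def generate_corpus(config: GeneratorConfig) -> List[Tuple[Post, ClassLabel]]:
    """Generate a labelled synthetic corpus (deterministic given seed)."""
    rng = np.random.default_rng(config.seed)
    fillers = _fillers()
    codes = [l.code for l in CLASS_LABELS]
    probs = np.array([config.class_proportions.get(c, 0.0) for c in codes])
    counts = rng.multinomial(config.n_posts, probs)
    labels: List[str] = []
    for code, n in zip(codes, counts):
        labels.extend([code] * n)
    rng.shuffle(labels)

    out: List[Tuple[Post, ClassLabel]] = []
    for i, code in enumerate(labels):
        templates = config.phrase_templates[code]
        phrase = templates[int(rng.integers(len(templates)))]
        lead = [fillers[int(j)] for j in rng.integers(len(fillers), size=int(rng.integers(0, 4)))]
        tail = [fillers[int(j)] for j in rng.integers(len(fillers), size=int(rng.integers(0, 4)))]
        if config.typo_rate > 0:
            lead = [_typo(w, rng) if rng.random() < config.typo_rate else w for w in lead]
            tail = [_typo(w, rng) if rng.random() < config.typo_rate else w for w in tail]
        parts = lead + [phrase] + tail
        if code == "c3" and config.shared_phrase_rate > 0 and rng.random() < config.shared_phrase_rate:
            parts.append(SHARED_PHRASES[int(rng.integers(len(SHARED_PHRASES)))])
        if config.mention_rate > 0 and rng.random() < config.mention_rate:
            parts.insert(0, f"@user{int(rng.integers(1000))}")
        if config.url_rate > 0 and rng.random() < config.url_rate:
            parts.append(f"http://t.example/{int(rng.integers(10000))}")
        text = " ".join(parts)
        while len(text) > 140 and len(parts) > 1:
            # drop filler from the edges, never the class phrase itself
            drop = 0 if parts[0] != phrase else len(parts) - 1
            if parts[drop] == phrase:
                break
            parts.pop(drop)
            text = " ".join(parts)
        text = text[:140]
        day = int(rng.integers(config.n_days))
        second = int(rng.integers(86400))
        ts = datetime.combine(
            config.start_date + timedelta(days=day), datetime.min.time(), timezone.utc
        ) + timedelta(seconds=second)
        post = Post(
            id=f"s{i}",
            text=text,
            timestamp=ts,
            profile_name=None,
            time_zone="London",
        )
        out.append((post, ClassLabel.from_code(code)))
    return out


def generate_annotations(
    corpus: Sequence[Tuple[Post, ClassLabel]],
    n_annotators: int = 4,
    error_rate: float = 0.0,
    seed: int = 0,
    min_annotators: int = 4,
    threshold: float = 0.75,
) -> List[AnnotatedPost]:
    """Simulate noisy multi-annotator labels over a true-labelled corpus.

    Each annotator reports the true label with probability ``1 -
    error_rate`` and otherwise a uniformly random *other* class.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out: List[AnnotatedPost] = []
    all_labels = list(CLASS_LABELS)
    for post, true_label in corpus:
        label_sets = []
        for _ in range(n_annotators):
            if rng.random() < error_rate:
                others = [l for l in all_labels if l is not true_label]
                label_sets.append({others[int(rng.integers(len(others)))]})
            else:
                label_sets.append({true_label})
        out.append(
            AnnotatedPost.from_labels(
                post, label_sets, min_annotators=min_annotators, threshold=threshold
            )
        )
    return out
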