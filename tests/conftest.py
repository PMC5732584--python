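"""Shared fixtures: bundled resources and small synthetic corpora."""

from __future__ import annotations

import pytest

from sidewatch.pipeline import ResourceBundle
from sidewatch.synth import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def resources() -> ResourceBundle:
    return ResourceBundle.default()


@pytest.fixture(scope="session")
def separable_corpus():
    """A clean 7-class synthetic corpus: no shared phrases, no label noise."""
    config = GeneratorConfig(n_posts=280, seed=3, shared_phrase_rate=0.0)
    return generate_corpus(config)


@pytest.fixture(scope="session")
def separable_posts_labels(separable_corpus):
    posts = [p for p, _ in separable_corpus]
    labels = [l.code for _, l in separable_corpus]
    return posts, labels
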