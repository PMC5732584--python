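"""End-to-end classifier pipelines: posts -> features -> labels.

A :class:`TextClassifierPipeline` bundles the resources, the chosen feature
sets, an optional PCA step and either a single base learner or the Rotation
Forest ensemble behind the simple fit/predict contract the cross-validation
harness expects.  Everything data-dependent (text vocabulary, PCA basis,
probability calibration) is fitted in :meth:`fit` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from . import resources as res
from .classify import (
    BaseLearnerSpec,
    RotationForestModel,
    predict,
    train_base,
    train_rotation_forest,
)
from .corpus import Post
from .features import (
    FeatureVector,
    TextVectorizer,
    combine,
    extract_set1,
    extract_set2,
    extract_set3,
    features_to_matrix,
    load_regex_rules,
)
from .lexicon import KeywordLexicon, default_keyword_lexicon
from .tagging import SimpleTagger

FEATURE_SETS = ("set1", "set2", "set3", "text", "combined", "combined+pca")


@dataclass
class ResourceBundle:
    """The static lexical resources the feature extractors need."""

    keywords: KeywordLexicon
    tagger: object
    domains: Mapping[str, Set[str]]
    affect: Mapping[str, Set[str]]
    categories: Mapping[str, Set[str]]
    sentiment: Mapping[str, Tuple[float, float]]
    negations: Set[str]
    rules: list

    @classmethod
    def default(cls) -> "ResourceBundle":
        return cls(
            keywords=default_keyword_lexicon(),
            tagger=SimpleTagger(),
            domains=res.default_domain_lexicon(),
            affect=res.default_affect_lexicon(),
            categories=res.default_category_lexicon(),
            sentiment=res.default_sentiment_lexicon(),
            negations=res.default_negations(),
            rules=load_regex_rules(res.default_regex_rules_path()),
        )


class TextClassifierPipeline:
    """Posts-in, labels-out classifier over a chosen feature representation.

    Parameters
    ----------
    feature_set:
        One of ``set1 | set2 | set3 | text | combined | combined+pca``.
        The combined sets always append the text n-gram counts, mirroring
        the experimental design in which the word-vector features accompany
        every configuration.
    classifier:
        ``"rotation_forest"`` or one of the base kinds
        (``naive_bayes | decision_tree | max_margin``).
    """

    def __init__(
        self,
        feature_set: str = "combined",
        classifier: str = "rotation_forest",
        resources: Optional[ResourceBundle] = None,
        base_specs: Optional[Sequence[BaseLearnerSpec]] = None,
        L: int = 10,
        K_size: int = 3,
        bootstrap_fraction: float = 0.75,
        variance_kept: float = 0.95,
        ngram_min: int = 1,
        ngram_max: int = 3,
        vocab_size: int = 500,
        seed: int = 0,
    ) -> None:
        if feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set: {feature_set!r}")
        self.feature_set = feature_set
        self.classifier = classifier
        self.resources = resources or ResourceBundle.default()
        # the final ensemble configuration: probabilistic + margin learners
        self.base_specs = list(base_specs) if base_specs else [
            BaseLearnerSpec("naive_bayes"),
            BaseLearnerSpec("max_margin"),
        ]
        self.L = L
        self.K_size = K_size
        self.bootstrap_fraction = bootstrap_fraction
        self.variance_kept = variance_kept
        self.ngram_min = ngram_min
        self.ngram_max = ngram_max
        self.vocab_size = vocab_size
        self.seed = seed
        self.vectorizer_: Optional[TextVectorizer] = None
        self.feature_names_: Optional[List[str]] = None
        self.pca_mean_: Optional[np.ndarray] = None
        self.pca_components_: Optional[np.ndarray] = None
        self.model_ = None

    # -- featurization ----------------------------------------------------

    def _static_vector(self, post: Post) -> List[FeatureVector]:
        r = self.resources
        vecs: List[FeatureVector] = []
        wanted = self.feature_set
        if wanted in ("set1", "combined", "combined+pca"):
            vecs.append(
                extract_set1(post, r.keywords, r.tagger, r.domains, r.affect,
                             r.sentiment, r.negations)
            )
        if wanted in ("set2", "combined", "combined+pca"):
            vecs.append(extract_set2(post, r.categories))
        if wanted in ("set3", "combined", "combined+pca"):
            vecs.append(extract_set3(post, r.rules))
        return vecs

    def featurize(self, posts: Sequence[Post]) -> np.ndarray:
        """Feature matrix for ``posts`` using the frozen fitted state."""
        rows: List[FeatureVector] = []
        use_text = self.feature_set in ("text", "combined", "combined+pca")
        for post in posts:
            vecs = self._static_vector(post)
            if use_text:
                if self.vectorizer_ is None:
                    raise RuntimeError("pipeline is not fitted")
                vecs.append(self.vectorizer_.feature_vector(post))
            rows.append(combine(vecs) if len(vecs) != 1 else vecs[0])
        names, X = features_to_matrix(rows)
        if self.feature_names_ is None:
            self.feature_names_ = names
        elif names != self.feature_names_:
            raise RuntimeError("feature names changed between fit and predict")
        if self.feature_set == "combined+pca":
            if self.pca_components_ is None:
                raise RuntimeError("pipeline is not fitted")
            X = (X - self.pca_mean_) @ self.pca_components_.T
        return X

    # -- fit / predict -----------------------------------------------------

    def fit(self, posts: Sequence[Post], labels: Sequence[str]) -> "TextClassifierPipeline":
        if len(posts) != len(labels):
            raise ValueError("posts and labels differ in length")
        y = np.array([str(l) for l in labels])
        if self.feature_set in ("text", "combined", "combined+pca"):
            self.vectorizer_ = TextVectorizer(
                self.ngram_min, self.ngram_max, self.vocab_size
            ).fit(posts)
        self.feature_names_ = None
        if self.feature_set == "combined+pca":
            from .features import pca_reduce

            # fit the basis on the training matrix without PCA applied
            saved = self.feature_set
            self.feature_set = "combined"
            X_raw = self.featurize(posts)
            self.feature_set = saved
            self.pca_mean_ = X_raw.mean(axis=0)
            components, X = pca_reduce(X_raw, self.variance_kept)
            self.pca_components_ = components
        else:
            X = self.featurize(posts)

        if self.classifier == "rotation_forest":
            self.model_ = train_rotation_forest(
                X, y, self.base_specs,
                L=self.L, K_size=min(self.K_size, X.shape[1]),
                bootstrap_fraction=self.bootstrap_fraction, seed=self.seed,
            )
        else:
            self.model_ = train_base(
                BaseLearnerSpec(self.classifier), X, y, random_state=self.seed
            )
        return self

    def predict(self, posts: Sequence[Post]) -> List[str]:
        if self.model_ is None:
            raise RuntimeError("pipeline is not fitted")
        X = self.featurize(posts)
        if isinstance(self.model_, RotationForestModel):
            return [str(l) for l in predict(self.model_, X)]
        return [str(l) for l in self.model_.predict(X)]
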