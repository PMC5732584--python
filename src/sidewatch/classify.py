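"""Base learners and the Rotation Forest ensemble with max-probability voting.

The ensemble follows the Rotation Forest recipe: for each of ``L`` members
the feature indices are randomly partitioned into subsets of size ~``K``;
for every subset a random sample of classes and instances is drawn and PCA
is fitted on the sampled rows restricted to that subset; the per-subset
loadings are assembled into a block rotation matrix; and every base learner
is trained on the fully rotated (full-dimensional) data.  At prediction
time each (member, learner) pair produces a class distribution, and the
metaclassifier returns the single distribution whose maximum probability is
highest across the whole ensemble — the maximum-probability voting rule —
with probability averaging available as an alternative.

Randomness protocol (bit-reproducible given ``seed``): member ``m`` uses
``numpy.random.default_rng([seed, m])`` and draws, in order, (1) a feature
permutation, then per subset (2) one uniform variate per class for the
class sample (a class is kept when its variate is < 0.5; if none survives,
all classes are used) and (3) a without-replacement instance sample of
``ceil(bootstrap_fraction * n_candidates)`` rows.  When
``bootstrap_fraction >= 1`` the class and instance draws are skipped and
all rows are used, which makes the degenerate configuration (L=1, one
subset spanning all features) coincide exactly with plain PCA followed by
the base learner.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.decomposition import PCA
from sklearn.naive_bayes import GaussianNB, MultinomialNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .corpus import ClassLabel

BASE_LEARNER_KINDS = ("naive_bayes", "decision_tree", "max_margin")


@dataclass(frozen=True)
class BaseLearnerSpec:
    """Which base learner to build and with which hyperparameters."""

    kind: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in BASE_LEARNER_KINDS:
            raise ValueError(f"unsupported base learner kind: {self.kind!r}")


def build_learner(spec: BaseLearnerSpec, X: np.ndarray, random_state: int = 0):
    """Instantiate an unfitted probabilistic learner for ``spec``.

    Naive Bayes uses add-one-smoothed multinomial likelihoods when the
    training matrix is non-negative and integral (count features) and
    Gaussian likelihoods otherwise.  The margin learner is a linear SVM
    whose class probabilities come from pairwise-coupled sigmoid (Platt)
    calibration fitted on training folds.
    """
    params = dict(spec.hyperparameters)
    if spec.kind == "naive_bayes":
        X = np.asarray(X)
        if X.size and np.all(X >= 0) and np.allclose(X, np.round(X)):
            return MultinomialNB(alpha=params.pop("alpha", 1.0), **params)
        return GaussianNB(**params)
    if spec.kind == "decision_tree":
        params.setdefault("random_state", random_state)
        return DecisionTreeClassifier(**params)
    params.setdefault("kernel", "linear")
    params.setdefault("C", 1.0)
    return SVC(probability=True, random_state=random_state, **params)


def train_base(spec: BaseLearnerSpec, X: np.ndarray, y: np.ndarray, random_state: int = 0):
    """Fit one base learner with a predict_proba contract."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    learner = build_learner(spec, X, random_state=random_state)
    with warnings.catch_warnings():
        # libsvm's built-in pairwise-coupled Platt calibration is the
        # documented probability model for the margin learner
        warnings.filterwarnings(
            "ignore", message=".*probability.*", category=FutureWarning
        )
        learner.fit(X, y)
    return learner


@dataclass
class Prediction:
    """A predicted label together with the winning class distribution."""

    label: object
    distribution: Dict[object, float]

    def __post_init__(self) -> None:
        total = sum(self.distribution.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.distribution.values()):
            raise ValueError("negative probability")


@dataclass
class _Member:
    """One rotation-forest member: its rotation and fitted learners."""

    subsets: List[np.ndarray]
    rotation: np.ndarray
    center: np.ndarray
    learners: List[object]


@dataclass
class RotationForestModel:
    members: List[_Member]
    classes_: np.ndarray
    n_features: int
    base_specs: List[BaseLearnerSpec]
    L: int
    K_size: int
    bootstrap_fraction: float
    seed: int
    voting: str = "max_probability"

    def rotate(self, member: _Member, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - member.center) @ member.rotation


def _member_rotation(
    rng: np.random.Generator,
    X: np.ndarray,
    y: np.ndarray,
    classes: np.ndarray,
    K_size: int,
    bootstrap_fraction: float,
) -> Tuple[List[np.ndarray], np.ndarray]:
    """Draw one member's feature partition and block rotation matrix."""
    n, d = X.shape
    perm = rng.permutation(d)
    subsets = [perm[i: i + K_size] for i in range(0, d, K_size)]
    rotation = np.zeros((d, d))
    for subset in subsets:
        if bootstrap_fraction >= 1.0:
            rows = np.arange(n)
        else:
            keep = rng.random(len(classes)) < 0.5
            if not keep.any():
                keep[:] = True
            candidates = np.flatnonzero(np.isin(y, classes[keep]))
            n_take = max(2, math.ceil(bootstrap_fraction * len(candidates)))
            n_take = min(n_take, len(candidates))
            rows = rng.choice(candidates, size=n_take, replace=False)
        block = np.eye(len(subset))
        sample = X[np.ix_(rows, subset)]
        # PCA needs more rows than block width and some variance; otherwise
        # the block degenerates to the identity (a no-op rotation)
        if len(rows) > len(subset) and not np.allclose(sample, sample[0]):
            pca = PCA(n_components=len(subset), svd_solver="full")
            pca.fit(sample)
            block = pca.components_.T
        rotation[np.ix_(subset, subset)] = block
    return subsets, rotation


def train_rotation_forest(
    X: np.ndarray,
    y: Sequence[object],
    base_specs: Sequence[BaseLearnerSpec],
    L: int = 10,
    K_size: int = 3,
    bootstrap_fraction: float = 0.75,
    seed: int = 0,
    voting: str = "max_probability",
) -> RotationForestModel:
    """Train the Rotation Forest ensemble (deterministic given ``seed``)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not base_specs:
        raise ValueError("at least one base learner spec is required")
    if L < 1:
        raise ValueError("L must be at least 1")
    if K_size > X.shape[1]:
        raise ValueError(f"K_size={K_size} exceeds feature count {X.shape[1]}")
    if not 0 < bootstrap_fraction <= 1:
        raise ValueError("bootstrap_fraction must be in (0, 1]")
    if voting not in ("max_probability", "average"):
        raise ValueError(f"unknown voting rule: {voting!r}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")

    center = X.mean(axis=0)
    members: List[_Member] = []
    for m in range(L):
        rng = np.random.default_rng([seed, m])
        subsets, rotation = _member_rotation(rng, X, y, classes, K_size, bootstrap_fraction)
        rotated = (X - center) @ rotation
        learners = []
        for j, spec in enumerate(base_specs):
            rs = int(np.random.SeedSequence([seed, m, j]).generate_state(1)[0] % (2**31))
            learners.append(train_base(spec, rotated, y, random_state=rs))
        members.append(_Member(subsets, rotation, center.copy(), learners))
    return RotationForestModel(
        members=members,
        classes_=classes,
        n_features=X.shape[1],
        base_specs=list(base_specs),
        L=L,
        K_size=K_size,
        bootstrap_fraction=bootstrap_fraction,
        seed=seed,
        voting=voting,
    )


def _ensemble_distributions(model: RotationForestModel, X: np.ndarray) -> np.ndarray:
    """All (member, learner) class distributions, aligned to model.classes_.

    Returns an array of shape (n_rows, n_member_learners, n_classes).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"input has {X.shape[1]} features, model expects {model.n_features}"
        )
    class_pos = {c: k for k, c in enumerate(model.classes_)}
    stacks = []
    for member in model.members:
        rotated = model.rotate(member, X)
        for learner in member.learners:
            proba = learner.predict_proba(rotated)
            aligned = np.zeros((X.shape[0], len(model.classes_)))
            for k, c in enumerate(learner.classes_):
                aligned[:, class_pos[c]] = proba[:, k]
            stacks.append(aligned)
    return np.stack(stacks, axis=1)


def predict_vote(model: RotationForestModel, x: np.ndarray) -> Prediction:
    """Predict one instance with the ensemble's voting metaclassifier.

    Under maximum-probability voting the returned distribution is the single
    (member, learner) distribution with the highest peak probability; ties
    go to the earlier-registered learner and then the lowest class index.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    dists = _ensemble_distributions(model, x)[0]
    if model.voting == "average":
        dist = dists.mean(axis=0)
    else:
        peaks = dists.max(axis=1)
        dist = dists[int(np.argmax(peaks))]  # argmax keeps the first on ties
    dist = dist / dist.sum()
    label = model.classes_[int(np.argmax(dist))]
    return Prediction(label, {c: float(p) for c, p in zip(model.classes_, dist)})


def predict(model: RotationForestModel, X: np.ndarray) -> np.ndarray:
    """Vectorised voting prediction for a matrix of instances."""
    dists = _ensemble_distributions(model, X)
    if model.voting == "average":
        avg = dists.mean(axis=1)
        idx = avg.argmax(axis=1)
    else:
        peaks = dists.max(axis=2)
        winner = peaks.argmax(axis=1)
        chosen = dists[np.arange(dists.shape[0]), winner]
        idx = chosen.argmax(axis=1)
    return model.classes_[idx]


# -- serialization --------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(
    model: RotationForestModel,
    path: "str | Path",
    resource_checksums: Optional[Mapping[str, str]] = None,
) -> None:
    """Serialize a fitted model to a single versioned archive."""
    import joblib

    payload = {
        "format_version": _FORMAT_VERSION,
        "model": model,
        "resource_checksums": dict(resource_checksums or {}),
    }
    joblib.dump(payload, path)


def load_model(
    path: "str | Path",
    expected_checksums: Optional[Mapping[str, str]] = None,
) -> RotationForestModel:
    """Load a model archive, refusing on version or checksum mismatch."""
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version: {payload.get('format_version')}")
    if expected_checksums:
        stored = payload.get("resource_checksums", {})
        for name, digest in expected_checksums.items():
            if stored.get(name) != digest:
                raise ValueError(f"resource checksum mismatch for {name!r}")
    return payload["model"]
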