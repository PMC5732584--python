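"""Base learners, Rotation Forest training and the voting metaclassifier."""

from __future__ import annotations

import math

import numpy as np
import pytest
from sklearn.datasets import make_blobs
from sklearn.decomposition import PCA
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from sidewatch.classify import (
    BaseLearnerSpec,
    Prediction,
    RotationForestModel,
    _Member,
    load_model,
    predict,
    predict_vote,
    save_model,
    train_base,
    train_rotation_forest,
)


@pytest.fixture(scope="module")
def blobs():
    X, y = make_blobs(n_samples=60, n_features=9, centers=3, cluster_std=1.0,
                      random_state=42)
    return X, y


class TestTrainBase:
    @pytest.mark.parametrize("kind", ["naive_bayes", "decision_tree", "max_margin"])
    def test_separable_clouds_are_learned_perfectly(self, kind):
        X, y = make_blobs(n_samples=40, centers=2, cluster_std=0.3, random_state=0)
        learner = train_base(BaseLearnerSpec(kind), X, y)
        assert (learner.predict(X) == y).mean() == 1.0
        proba = learner.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_multinomial_posterior_matches_hand_bayes_with_addone_smoothing(self):
        # class 0 docs put both counts on feature 1, class 1 on feature 2;
        # with add-one smoothing theta = (3/4, 1/4) vs (1/4, 3/4), so the
        # posterior for [1, 0] is 0.75 / (0.75 + 0.25) = 0.75
        X = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        y = np.array([0, 0, 1, 1])
        learner = train_base(BaseLearnerSpec("naive_bayes"), X, y)
        proba = learner.predict_proba([[1, 0]])[0]
        assert proba[0] == pytest.approx(0.75)
        assert proba[1] == pytest.approx(0.25)

    def test_decision_tree_solves_xor_with_depth_two(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 1, 1, 0])
        learner = train_base(BaseLearnerSpec("decision_tree"), X, y)
        assert learner.get_depth() >= 2
        assert (learner.predict(X) == y).all()

    def test_single_class_labels_are_an_error(self):
        with pytest.raises(ValueError):
            train_base(BaseLearnerSpec("naive_bayes"), np.eye(3), np.zeros(3))

    def test_unknown_kind_is_an_error(self):
        with pytest.raises(ValueError):
            BaseLearnerSpec("random_forest")


# -- clean-room reference implementation of the rotation forest -----------
#
# Written against the documented randomness protocol only; PCA is done via
# an eigendecomposition of the sample covariance rather than the package's
# SVD path.  Base-learner predictions are invariant to component sign and
# order, so agreement here checks the partition/sampling/rotation logic.

def _oracle_rotation_forest(X, y, specs, L, K, frac, seed):
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, d = X.shape
    classes = np.unique(y)
    center = X.mean(axis=0)
    members = []
    for m in range(L):
        rng = np.random.default_rng([seed, m])
        perm = rng.permutation(d)
        chunks = [perm[i:i + K] for i in range(0, d, K)]
        R = np.zeros((d, d))
        for chunk in chunks:
            if frac >= 1.0:
                rows = np.arange(n)
            else:
                keep = rng.random(len(classes)) < 0.5
                if not keep.any():
                    keep[:] = True
                cand = np.flatnonzero(np.isin(y, classes[keep]))
                n_take = min(max(2, math.ceil(frac * len(cand))), len(cand))
                rows = rng.choice(cand, size=n_take, replace=False)
            block = np.eye(len(chunk))
            sample = X[np.ix_(rows, chunk)]
            if len(rows) > len(chunk) and not np.allclose(sample, sample[0]):
                sc = sample - sample.mean(axis=0)
                evals, evecs = np.linalg.eigh(sc.T @ sc)
                block = evecs[:, np.argsort(evals)[::-1]]
            R[np.ix_(chunk, chunk)] = block
        rotated = (X - center) @ R
        fitted = []
        for j, spec in enumerate(specs):
            rs = int(np.random.SeedSequence([seed, m, j]).generate_state(1)[0] % (2**31))
            if spec.kind == "naive_bayes":
                learner = GaussianNB()
            else:
                learner = SVC(kernel="linear", probability=True, random_state=rs)
            fitted.append(learner.fit(rotated, y))
        members.append((R, fitted))
    return center, members, classes


def _oracle_predict(center, members, classes, X):
    X = np.asarray(X, float)
    out = []
    for x in X:
        best = None
        for R, fitted in members:
            z = (x - center) @ R
            for learner in fitted:
                proba = np.zeros(len(classes))
                p = learner.predict_proba([z])[0]
                for k, c in enumerate(learner.classes_):
                    proba[np.searchsorted(classes, c)] = p[k]
                if best is None or proba.max() > best.max():
                    best = proba
        out.append(classes[int(np.argmax(best))])
    return np.array(out)


class TestRotationForest:
    def test_degenerate_single_member_equals_pca_plus_learner(self, blobs):
        X, y = blobs
        spec = BaseLearnerSpec("naive_bayes")
        model = train_rotation_forest(X, y, [spec], L=1, K_size=9,
                                      bootstrap_fraction=1.0, seed=5)
        rf_pred = predict(model, X)
        pca = PCA(n_components=9, svd_solver="full").fit(X)
        scores = pca.transform(X)
        learner = GaussianNB().fit(scores, y)
        assert (rf_pred == learner.predict(scores)).all()

    def test_rotation_blocks_are_orthonormal(self, blobs):
        X, y = blobs
        model = train_rotation_forest(X, y, [BaseLearnerSpec("naive_bayes")],
                                      L=4, K_size=3, seed=1)
        for member in model.members:
            for subset in member.subsets:
                block = member.rotation[np.ix_(subset, subset)]
                gram = block.T @ block
                assert np.allclose(gram, np.eye(len(subset)), atol=1e-8)
            # full rotation is block-diagonal up to permutation: off-subset
            # entries are exactly zero
            mask = np.zeros_like(member.rotation, dtype=bool)
            for subset in member.subsets:
                mask[np.ix_(subset, subset)] = True
            assert (member.rotation[~mask] == 0).all()

    def test_matches_clean_room_reference_implementation(self, blobs):
        X, y = blobs
        specs = [BaseLearnerSpec("naive_bayes"), BaseLearnerSpec("max_margin")]
        model = train_rotation_forest(X, y, specs, L=3, K_size=3,
                                      bootstrap_fraction=0.75, seed=17)
        rng = np.random.default_rng(0)
        X_new = X + rng.normal(scale=0.2, size=X.shape)
        mine = predict(model, X_new)
        center, members, classes = _oracle_rotation_forest(
            X, y, specs, L=3, K=3, frac=0.75, seed=17)
        theirs = _oracle_predict(center, members, classes, X_new)
        assert (mine == theirs).all()

    def test_same_seed_is_reproducible_and_seeds_differ(self, blobs):
        X, y = blobs
        specs = [BaseLearnerSpec("naive_bayes")]
        a = train_rotation_forest(X, y, specs, L=3, K_size=3, seed=9)
        b = train_rotation_forest(X, y, specs, L=3, K_size=3, seed=9)
        for ma, mb in zip(a.members, b.members):
            assert np.array_equal(ma.rotation, mb.rotation)
        assert (predict(a, X) == predict(b, X)).all()
        c = train_rotation_forest(X, y, specs, L=3, K_size=3, seed=10)
        assert any(
            not np.array_equal(ma.rotation, mc.rotation)
            for ma, mc in zip(a.members, c.members)
        )
        # accuracy on the separable set stays high for any seed
        assert (predict(c, X) == y).mean() >= (GaussianNB().fit(X, y).predict(X) == y).mean() - 0.05

    def test_parameter_validation(self, blobs):
        X, y = blobs
        with pytest.raises(ValueError):
            train_rotation_forest(X, y, [], L=1, K_size=3)
        with pytest.raises(ValueError):
            train_rotation_forest(X, y, [BaseLearnerSpec("naive_bayes")], K_size=99)
        with pytest.raises(ValueError):
            train_rotation_forest(X, np.zeros(len(y)), [BaseLearnerSpec("naive_bayes")])


class _StubLearner:
    def __init__(self, proba):
        self.proba = np.asarray(proba, float)
        self.classes_ = np.arange(self.proba.shape[-1])

    def predict_proba(self, X):
        return np.tile(self.proba, (len(X), 1))


def _stub_model(probas, n_features=2, voting="max_probability"):
    member = _Member(
        subsets=[np.arange(n_features)],
        rotation=np.eye(n_features),
        center=np.zeros(n_features),
        learners=[_StubLearner(p) for p in probas],
    )
    return RotationForestModel(
        members=[member], classes_=np.arange(len(probas[0])), n_features=n_features,
        base_specs=[], L=1, K_size=n_features, bootstrap_fraction=1.0, seed=0,
        voting=voting,
    )


class TestPredictVote:
    def test_peak_probability_wins(self):
        model = _stub_model([[0.6, 0.4], [0.9, 0.1]])
        pred = predict_vote(model, np.zeros(2))
        assert pred.label == 0
        assert pred.distribution[0] == pytest.approx(0.9)

    def test_uniform_tie_returns_lowest_class_index(self):
        model = _stub_model([[0.25, 0.25, 0.25, 0.25], [0.25, 0.25, 0.25, 0.25]])
        assert predict_vote(model, np.zeros(2)).label == 0

    def test_single_learner_ensemble_is_that_learner(self, blobs):
        X, y = blobs
        model = train_rotation_forest(X, y, [BaseLearnerSpec("naive_bayes")],
                                      L=1, K_size=9, bootstrap_fraction=1.0, seed=2)
        lone = model.members[0].learners[0]
        rotated = model.rotate(model.members[0], X)
        assert (predict(model, X) == lone.predict(rotated)).all()

    def test_invariant_under_learner_duplication(self):
        model = _stub_model([[0.7, 0.3], [0.2, 0.8]])
        base = predict_vote(model, np.zeros(2))
        dup = _stub_model([[0.7, 0.3], [0.2, 0.8], [0.2, 0.8]])
        again = predict_vote(dup, np.zeros(2))
        assert again.label == base.label
        assert again.distribution == base.distribution

    def test_dimension_mismatch_is_an_error(self):
        model = _stub_model([[0.5, 0.5]])
        with pytest.raises(ValueError):
            predict_vote(model, np.zeros(5))

    def test_distribution_is_a_probability(self):
        with pytest.raises(ValueError):
            Prediction(0, {0: 0.6, 1: 0.6})


class TestSerialization:
    def test_roundtrip_and_checksum_guard(self, blobs, tmp_path):
        X, y = blobs
        model = train_rotation_forest(X, y, [BaseLearnerSpec("naive_bayes")],
                                      L=2, K_size=3, seed=4)
        path = tmp_path / "model.joblib"
        save_model(model, path, resource_checksums={"lexicon": "abc"})
        loaded = load_model(path, expected_checksums={"lexicon": "abc"})
        assert (predict(loaded, X) == predict(model, X)).all()
        with pytest.raises(ValueError, match="checksum"):
            load_model(path, expected_checksums={"lexicon": "zzz"})
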