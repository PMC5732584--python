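"""Feature extraction: Set1/Set2/Set3, text n-grams, combination, PCA."""

from __future__ import annotations

import random
import warnings
from collections import Counter

import numpy as np
import pytest

from sidewatch.corpus import Post
from sidewatch.features import (
    TextVectorizer,
    combine,
    extract_set1,
    extract_set2,
    extract_set3,
    features_to_matrix,
    load_regex_rules,
    pca_reduce,
    vectorize_text,
)
from sidewatch.lexicon import KeywordLexicon
from sidewatch.resources import default_regex_rules_path
from sidewatch.tokenizer import ngrams, tokenize


def _post(text, i="p1"):
    return Post(id=str(i), text=text)


@pytest.fixture(scope="module")
def rules():
    return load_regex_rules(default_regex_rules_path())


class TestSet1:
    def test_keyword_and_first_person_flags(self, resources):
        lex = KeywordLexicon(["want to die", "end it all"])
        fv = extract_set1(
            _post("I want to die"), lex, resources.tagger, resources.domains,
            resources.affect, resources.sentiment, resources.negations,
        )
        assert fv["kw.want_to_die"] == 1.0
        assert fv["kw.end_it_all"] == 0.0
        assert fv["kw.any"] == 1.0
        assert fv["struct.first_person"] == 1.0

    def test_tokenless_text_yields_all_zero_counts(self, resources):
        fv = extract_set1(
            _post("..."), resources.keywords, resources.tagger,
            resources.domains, resources.affect, resources.sentiment,
            resources.negations,
        )
        assert all(v == 0.0 for v in fv.values.values())

    def test_polarity_sums_are_token_sums(self, resources):
        sentiment = {"glum": (0.0, 0.5), "gleam": (0.5, 0.0), "shine": (0.5, 0.0)}
        fv = extract_set1(
            _post("gleam and shine and glum"), KeywordLexicon(["x y"]),
            resources.tagger, {}, {}, sentiment, resources.negations,
        )
        assert fv["senti.positive_sum"] == pytest.approx(1.0)
        assert fv["senti.negative_sum"] == pytest.approx(0.5)

    def test_negation_count_and_url_mention_flags(self, resources):
        fv = extract_set1(
            _post("I can't and won't stop @you http://a.io"),
            KeywordLexicon(["zz"]), resources.tagger, {}, {},
            resources.sentiment, resources.negations,
        )
        assert fv["struct.negations"] == 2.0
        assert fv["struct.url"] == 1.0
        assert fv["struct.mention"] == 1.0

    def test_global_keyword_binary_is_or_of_individuals(self, resources, separable_corpus):
        for post, _ in separable_corpus[:60]:
            fv = extract_set1(
                post, resources.keywords, resources.tagger, resources.domains,
                resources.affect, resources.sentiment, resources.negations,
            )
            individual = [v for k, v in fv.values.items()
                          if k.startswith("kw.") and k != "kw.any"]
            assert fv["kw.any"] == float(any(individual))

    def test_extraction_is_pure(self, resources):
        post = _post("i feel so alone tonight")
        a = extract_set1(post, resources.keywords, resources.tagger,
                         resources.domains, resources.affect,
                         resources.sentiment, resources.negations)
        b = extract_set1(post, resources.keywords, resources.tagger,
                         resources.domains, resources.affect,
                         resources.sentiment, resources.negations)
        assert a.values == b.values

    def test_tagger_failure_names_the_post(self, resources):
        def broken(tokens):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="p9"):
            extract_set1(_post("hello", i="p9"), resources.keywords, broken,
                         {}, {}, {}, resources.negations)


class TestSet2:
    def test_stem_pattern_matches_prefix(self):
        fv = extract_set2(_post("my anxiety is killing me"), {"anxiety": {"anxi*"}})
        assert fv["cat.anxiety"] == 1.0

    def test_no_hits_is_a_zero_vector(self):
        fv = extract_set2(_post("zzz qqq"), {"anxiety": {"anxi*"}, "death": {"die*"}})
        assert all(v == 0.0 for v in fv.values.values())

    def test_counts_equal_brute_force_membership_scan(self, resources):
        text = "i worry my family and friends will grieve and cry when i die"
        fv = extract_set2(_post(text), resources.categories)
        tokens = tokenize(text)
        for name, patterns in resources.categories.items():
            expected = 0
            for tok in tokens:
                for pat in patterns:
                    if (pat.endswith("*") and tok.startswith(pat[:-1])) or tok == pat:
                        expected += 1
                        break
            assert fv[f"cat.{name}"] == expected, name


class TestSet3:
    @pytest.mark.parametrize(
        "text, rule_id",
        [
            ("i just can't take it anymore", "c1_r4"),
            ("miss you so much", "c5_r1"),
            ("i keep having suicidal thoughts", "c1_r1"),
            ("he took his own life", "c6_r1"),
        ],
    )
    def test_class_rules_fire_on_their_phrases(self, rules, text, rule_id):
        fv = extract_set3(_post(text), rules)
        assert fv[f"rule.{rule_id}"] == 1.0

    def test_neutral_text_fires_nothing(self, rules):
        fv = extract_set3(_post("nice weather today"), rules)
        assert all(v == 0.0 for v in fv.values.values())

    def test_invariant_to_case_and_surrounding_whitespace(self, rules):
        a = extract_set3(_post("MISS YOU so much"), rules)
        b = extract_set3(_post("   miss you so much \n"), rules)
        assert a.values == b.values


class TestTextVectorizer:
    def test_counts_tiny_corpus(self):
        vocab, X = vectorize_text(["a a b"], ngram_min=1, ngram_max=1, vocab_size=2)
        assert set(vocab) == {"a", "b"}
        counts = dict(zip(vocab, X[0]))
        assert counts == {"a": 2, "b": 1}

    def test_unseen_post_with_no_vocab_ngrams_is_zero(self):
        vec = TextVectorizer(1, 2, 10).fit(["a b c"])
        assert vec.transform(["z z z"]).sum() == 0

    def test_matches_brute_force_counter_on_synthetic_corpus(self, separable_corpus):
        posts = [p for p, _ in separable_corpus[:20]]
        vec = TextVectorizer(1, 3, 50).fit(posts)
        X = vec.transform(posts)
        # oracle: total-count ranking with lexicographic ties, raw counts
        totals = Counter()
        for p in posts:
            totals.update(ngrams(tokenize(p.text), 1, 3))
        expected_vocab = [t for t, _ in sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))[:50]]
        assert vec.vocabulary_ == expected_vocab
        for i, p in enumerate(posts):
            grams = Counter(ngrams(tokenize(p.text), 1, 3))
            for j, term in enumerate(expected_vocab):
                assert X[i, j] == grams.get(term, 0)

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            TextVectorizer(vocab_size=0)
        with pytest.raises(ValueError):
            TextVectorizer(1, 3, 10).fit([])


class TestCombine:
    def test_prefixes_disjoint_groups(self):
        from collections import OrderedDict

        from sidewatch.features import FeatureVector

        a = FeatureVector(OrderedDict(a=1.0), "set1")
        b = FeatureVector(OrderedDict(b=2.0), "set2")
        merged = combine([a, b])
        assert merged.values == OrderedDict({"set1.a": 1.0, "set2.b": 2.0})

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            combine([])

    def test_collision_is_an_error(self):
        from collections import OrderedDict

        from sidewatch.features import FeatureVector

        a = FeatureVector(OrderedDict(x=1.0), "set1")
        with pytest.raises(ValueError, match="collision"):
            combine([a, a])


class TestPcaReduce:
    def test_rank_one_matrix_needs_one_component(self):
        base = np.outer(np.arange(6, dtype=float), np.array([1.0, 2.0, 3.0]))
        components, scores = pca_reduce(base, variance_kept=0.95)
        assert components.shape[0] == 1
        assert scores.shape == (6, 1)

    def test_projection_decorrelates_columns(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 6)) @ rng.normal(size=(6, 6))
        _, scores = pca_reduce(X, variance_kept=0.99)
        cov = np.cov(scores.T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_components_match_eigendecomposition_up_to_sign(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 6))
        components, _ = pca_reduce(X, variance_kept=1.0)
        cov = np.cov(X.T, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order]
        for i in range(components.shape[0]):
            dot = abs(np.dot(components[i], evecs[:, i]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_retained_share_reaches_threshold_and_reconstruction_improves(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 8)) * np.array([5, 4, 3, 2, 1, 0.5, 0.2, 0.1])
        Xc = X - X.mean(axis=0)
        total = (Xc ** 2).sum()
        for kept in (0.5, 0.8, 0.95):
            components, scores = pca_reduce(X, variance_kept=kept)
            recon = scores @ components
            explained = (recon ** 2).sum() / total
            assert explained >= kept - 1e-9
        errs = []
        for k in range(1, 8):
            comps, _ = pca_reduce(X, variance_kept=1.0)
            comps = comps[:k]
            recon = Xc @ comps.T @ comps
            errs.append(((Xc - recon) ** 2).sum())
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_constant_matrix_warns_and_returns_nothing(self):
        with pytest.warns(UserWarning, match="constant"):
            components, scores = pca_reduce(np.ones((5, 3)))
        assert components.shape == (0, 3)
        assert scores.shape == (5, 0)


def test_features_to_matrix_requires_aligned_names(resources):
    a = extract_set2(_post("my anxiety"), {"anxiety": {"anxi*"}})
    b = extract_set2(_post("ok"), {"death": {"die*"}})
    with pytest.raises(ValueError):
        features_to_matrix([a, b])
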