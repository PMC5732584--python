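# Methods

`sidewatch` implements an end-to-end system for multi-class classification
of suicide-related short social-media texts and for aggregate surveillance
of the resulting class streams. This note documents the models and
procedures, the parameters that matter, the synthetic data the tests rely
on, and the design choices made where the design was genuinely open.

## The classification problem

Posts are assigned to one of seven communication classes: evidence of
possible suicidal intent (c1), campaigning (c2), flippant reference to
suicide (c3), information or support (c4), memorial or condolence (c5),
reporting of a suicide (c6), and none of the above (c7). The central
difficulty is c1 vs c3: flippant posts use the same surface phrasing
("kill myself") about trivial matters, so the two classes share much of
their vocabulary and are the dominant source of confusion.

## Annotation model and agreement filtering

Each post carries at least four independent annotator label-sets
(annotators may select several classes). The modal label is the class
contained in the most label-sets, with multi-label entries counting toward
every listed class; ties break to the lowest class index (deterministic,
and with four annotators a tied unit fails the threshold anyway). The
agreement score is the fraction of annotators whose set contains the modal
label; a unit resolves only when there are >= `min_annotators` (default 4)
annotators and agreement >= `threshold` (default 0.75). Whether agreement
should be computed before or after multi-label expansion is not settled;
this package computes the mode over expanded labels and agreement over
annotators, one defensible reading, and documents it as the contract.

Two corpus filters are provided. The long-post filter drops posts whose
character length exceeds 1.05x the mean length of the source collection
(read as "more than five percent longer than the average"; characters
rather than words, computed once per collection). Note the cutoff is a
function of the input, so the filter is *not* idempotent in general:
re-filtering the filtered output can tighten the cutoff further (e.g.
lengths [80, 100, 100, 106]). It is intended to be applied once per
collection. The geography filter keeps a post when its profile time zone
equals the target zone (e.g. "London") or its profile location contains a
county name, token-sequence matched case-insensitively, excluding names
with US equivalents (Lincoln, Boston, ...); no geocoding is attempted.

## Keyword-lexicon induction

Given a binary-labelled corpus (ideation vs not), every 1-5-token n-gram
is scored by a tf-idf contrast: per document tf is the raw count, idf =
ln(N/df) with no smoothing, and the score is the mean tf-idf over
positive-label documents minus the mean over negative-label documents.
The mean-difference contrast is the package's defined behaviour (the
choice between a difference and a ratio is open; the ratio is available as
`method="ratio"`). Ranking is deterministic: descending score, ties
lexicographic. The canonical tokenizer lowercases, collapses URLs and
@-mentions to placeholder tokens, and keeps apostrophes inside tokens.

The bundled 62-phrase keyword lexicon is a *reconstruction*: the original
curated list was never published in full, so the shipped ranked list
contains every phrase known to be in it plus closely related ideation
phrasing, and the shipped removal file curates it to the documented size
of 62.

## Feature sets

* **Set 1** — part-of-speech tag frequencies over the standard 36-tag
  newswire tagset; structural features (negation count from a bundled
  negation list, a first-person-pronoun flag, URL and mention flags);
  per-category counts against a general lexical-domain lexicon and an
  affective-category lexicon; positive and negative polarity sums (each
  token's [0,1] scores summed over the post; where a polarity resource
  lists multiple senses the first-listed sense is used); and one binary
  per keyword phrase plus a global any-keyword binary.
* **Set 2** — per-category token counts against a psychological category
  lexicon with the classic category names (death, health, money, religion,
  occupation, achievement, senses, cognitive mechanisms, affect, social,
  family, friends, humans, anxiety, anger, sadness, positive/negative
  emotion, certainty, inhibition, insight, causal, inclusive, exclusive).
  The well-known commercial dictionary of this kind is proprietary; the
  bundled lexicon is an original, much smaller stand-in with the same
  category structure, adequate for exercising the pipeline but not a
  substitute for the full resource on real data.
* **Set 3** — one binary per rule in a versioned file of class-typical
  regular expressions plus short word lists ("trigger warning", "self
  harm", ...). Printed sources for such rules are typographically fragile,
  so the rule file is the normative artifact: each pattern is written to
  match the example phrases its rule is meant to cover, every rule carries
  exactly one class hint (phrases like "hate myself" are deliberately
  assigned to the flippant class, "want to die" to the ideation class),
  and matching is case-insensitive on whitespace-normalised text.
* **Text** — raw n-gram counts (default 1-3-grams) over a vocabulary of
  the `vocab_size` (default 500) most frequent n-grams in the training
  corpus, ties lexicographic; the vocabulary is frozen at fit time.
* **Combined** — the group-prefixed union of the above; `combined+pca`
  additionally centres the matrix and projects it onto the smallest
  prefix of principal components reaching `variance_kept` (default 0.95)
  of the variance.

Domain/affect features are counts rather than binaries (consistent with
treating per-tag and per-category frequencies as features). The POS tagger
is a pluggable contract; the bundled tagger is a deterministic
lexicon+suffix tagger so that tests need no model download, and a
production statistical tagger can be plugged in unchanged.

## The ensemble

Base learners are naive Bayes (add-one-smoothed multinomial likelihoods on
non-negative integral matrices, Gaussian likelihoods otherwise), a
decision tree, and a linear SVM whose class probabilities come from
pairwise-coupled sigmoid (Platt) calibration fitted on training folds.
The ensemble default pairs naive Bayes with the SVM; the tree is available
but not in the default configuration (it is the weakest of the three on
this task shape).

Rotation Forest: for each of `L` (default 10) members, the feature indices
are randomly partitioned into subsets of size ~`K` (default 3); for each
subset a random half of the classes is selected and a without-replacement
sample of `bootstrap_fraction` (default 0.75) of their instances drawn;
PCA is fitted on the sampled rows restricted to the subset; all loadings
are assembled into a block rotation matrix; and every base learner is
trained on the *fully* rotated data (all features, full-dimensional).
Prediction uses the maximum-probability voting metaclassifier: each
(member, learner) pair emits a class distribution on the rotated input,
and the single distribution with the highest peak wins; its argmax is the
label, with ties resolved by learner registration order then lowest class
index. Probability averaging is available (`voting="average"`) for
comparison.

Numerical choices worth recording:

* The rotation is applied to mean-centred data (the full-training-data
  mean), so the degenerate configuration (one member, one subset spanning
  all features, `bootstrap_fraction=1`) coincides *exactly* with plain PCA
  followed by the base learner — a reduction the tests assert.
* `bootstrap_fraction >= 1` is defined to mean "use all instances and skip
  the class-subset draw", which is what makes the reduction above exact.
* A subset whose sample has fewer rows than features, or no variance,
  keeps an identity block (a no-op rotation) rather than failing.
* The randomness protocol is documented in `classify.py` and is part of
  the model's contract: member `m` draws from
  `numpy.random.default_rng([seed, m])` in a fixed order, making training
  bit-reproducible given the seed and independently re-implementable (the
  test suite contains such a clean-room reference implementation).

## Evaluation

Stratified K-fold cross-validation (default 10 folds; stratified because
the class distribution is heavily skewed) with fold assignment fixed by a
seed. All data-dependent fitting — text vocabulary, PCA basis, SVM
calibration — happens inside the training fold. The headline numbers are
computed from the pooled out-of-fold confusion matrix; per-fold metrics
and their mean are also reported. Precision for a never-predicted class is
defined as 0 with a warning; report display rounds half-up to 3 decimals
while raw values are retained. Weighted recall equals the micro accuracy
(trace over total) exactly, which the tests assert.

The package bundles a published seven-class benchmark confusion grid (601
posts) as a worked-example input. One cell-level note: the published
per-class table for that grid prints an F of 0.631 for the campaigning
class where the exact harmonic mean of the grid's precision and recall is
0.6316 (rounds to 0.632) — a truncation artifact in the original table.
The grid's total (601) is also smaller than the full annotated corpus it
came from (816); the discrepancy is unexplained at source, and the metrics
here are computed from the printed grid as-is. The bundled 12-month
validation table is reduced to its unambiguous ideation row (111 correct
of 170), from which the published 65.29% recall follows.

## Surveillance analytics

* **Time series** — per-UTC-day, per-class counts over a contiguous date
  range with explicit zeros; out-of-range or timestamp-less posts are
  excluded and counted.
* **Gender inference** — the first whitespace token of the profile name,
  lowercased, is matched by *containment* against a name-gender lexicon
  (the token must be a substring of a lexicon name); the gender with the
  greatest count among matches wins, ties map to unisex. Containment
  over-matches short tokens badly, so tokens under 3 characters are sent
  to unknown — a deliberate deviation to control noise. The bundled name
  list is a small original sample; a production deployment would use a
  large name database.
* **Age extraction** — three patterns in order ("I am X years old",
  "born in X", bare "X years old"), X a two-digit number or a year/date;
  ages from years are reference-year minus birth-year, adjusted by
  month/day when present. A configurable false-positive filter file
  (patterns like "years ago", "when I was", "felt ... years old") vetoes
  matches in a +-25-character window. Ages are clamped to [0, 99]; bands
  follow the reporting scheme 13-20 / 21-30 / ... / 60+, with under-13
  counted separately (the published under-13 percentage uses an
  inconsistent denominator at source, so this package reports raw counts
  and leaves the denominator to the caller).
* **Mortality correlation** — Spearman rank correlation (mid-rank ties,
  two-sided p) between a daily death series and the daily ideation-post
  series; the 24h window pairs deaths(d) with posts(d), the 48h window
  with posts(d) + posts(d+1) ("the 48 hours following"), and a signed
  `lag_days` parameter provides alternative alignments. Constant series
  make the coefficient undefined and are flagged rather than raised.

Only aggregate-level analytics are implemented. Identifying or flagging
individual accounts, and any alerting or intervention feature, are
deliberately out of scope on ethical grounds.

## Synthetic data

The generator emulates the statistical structure the classifier assumes,
not realistic distress language. Class proportions default to the
annotated-corpus distribution (c1 13%, c2 5%, c3 30%, c4 6%, c5 5%,
c6 15%, c7 26%). Each post is a class-typical template phrase wrapped in
neutral filler words (a fixed 500-word list chosen so that no filler fires
any rule or keyword — reproducibility over realism), with URLs (10%),
mentions (15%) and character-swap typos (5%) at configurable rates, capped
at 140 characters. Every ideation template fires at least one
ideation-class pattern rule and no flippant template fires any; the
`shared_phrase_rate` parameter injects ideation phrasing into
flippant-class posts and is the designed route for c1/c3 confusion, so
raising it measurably raises the pooled c1<->c3 confusion count (a
monotonicity the acceptance tests check on average over seeds). The
annotation simulator gives each annotator the true label with probability
1 - `annotator_error_rate` and otherwise a uniform other class.

Because the synthetic classes are separable by construction, a
cross-validated micro accuracy >= 0.9 on clean synthetic corpora shows the
pipeline wiring, feature extraction and ensemble are sound — it says
nothing about performance on real, noisy, label-ambiguous data, where the
published benchmark numbers (weighted F around 0.73) are the realistic
reference point.

Default experiment sizes used by the test suite and the acceptance script
(280-post corpora, 5 folds, 300-word text vocabulary, L=10 members) were
chosen as the smallest sizes at which the properties under test are
stable across seeds.

## Known limitations

* The bundled category/affect/domain/polarity lexicons and the name list
  are small original stand-ins: sufficient to exercise and test every code
  path, far smaller than the production resources they emulate.
* The bundled POS tagger is rule-based; on real text a statistical tagger
  should be plugged in.
* Naive Bayes with multinomial likelihoods is weak on sparse binary rule
  features under heavy class imbalance (empty feature vectors inherit the
  majority prior); the ensemble's SVM arm and the rotation to dense
  real-valued features mitigate this.
* The serialized model archive embeds fitted scikit-learn estimators and
  is therefore sensitive to the scikit-learn version; the archive carries
  a format version and optional resource checksums and refuses to load on
  mismatch.
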