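"""Induce a ranked suicide-phrase lexicon with the tf-idf contrast score.

Terms are ranked by mean tf-idf in ideation-labelled documents minus the
mean in non-ideation documents, so phrases concentrated in the ideation
class float to the top; curation then removes non-specific terms.
"""

from sidewatch import curate, default_keyword_lexicon, score_terms

corpus = [
    ("i want to kill myself i really do", 1),
    ("asleep and never wake that is all i want", 1),
    ("kill myself before another monday", 1),
    ("the bus was late again this morning", 0),
    ("lovely weather for a walk in the park", 0),
    ("watching the match with friends tonight", 0),
]

ranked = score_terms(corpus, ngram_min=1, ngram_max=4, top_k=10)
print("top contrast-ranked terms (score = ideation mean tf.idf - other mean):")
for st in ranked[:8]:
    print(f"  {st.term:28s} score={st.score:+.3f} df={st.df}")

lexicon = curate(ranked, removals=["i", "i want", "all i"])
print(f"\ncurated lexicon keeps {len(lexicon)} terms in rank order.")

bundled = default_keyword_lexicon()
print(f"the bundled curated lexicon has {len(bundled)} phrases, e.g. "
      f"{bundled.terms[:3]}")
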