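"""Resolve noisy multi-annotator labels with the 75% agreement filter.

Each post gets at least four annotator label-sets (annotators may pick
several classes); the modal label is kept only when at least 75% of
annotators endorse it.
"""

from sidewatch import ClassLabel, resolve_majority

C = ClassLabel.from_code

examples = [
    ("unanimous", [{C("c1")}, {C("c1")}, {C("c1")}, {C("c1")}]),
    ("3-of-4 boundary", [{C("c1")}, {C("c1")}, {C("c1")}, {C("c3")}]),
    ("split 2-2", [{C("c1")}, {C("c1")}, {C("c3")}, {C("c3")}]),
    ("multi-label annotator", [{C("c1"), C("c3")}, {C("c1")}, {C("c1")}, {C("c5")}]),
]

for name, label_sets in examples:
    label, agreement = resolve_majority(label_sets)
    print(f"{name:22s} -> resolved={label.code if label else 'dropped':8s} "
          f"agreement={agreement:.2f}")

print()
print("A unit is kept for training only when it resolves: the 2-2 split is")
print("discarded, while 3-of-4 (agreement 0.75) just passes the filter.")
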