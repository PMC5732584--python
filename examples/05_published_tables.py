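"""Reproduce the published evaluation numbers from the bundled tables.

The metrics layer is exactly reproducible from printed inputs: the bundled
7x7 benchmark confusion grid yields the published per-class and weighted
precision/recall/F, and the bundled case-study counts yield the published
surveillance percentages.
"""

import numpy as np

from sidewatch import ConfusionMatrix, metrics_from_confusion, summarise_from_counts
from sidewatch.resources import load_case_study_counts, load_reference_confusion

labels = tuple(f"c{i}" for i in range(1, 8))
rep = metrics_from_confusion(ConfusionMatrix(load_reference_confusion(), labels)).rounded()
print("per-class precision / recall / F from the benchmark grid (601 posts):")
for code, (p, r, f, s) in rep.per_class.items():
    print(f"  {code}: {p:.3f} / {r:.3f} / {f:.3f}")
print(f"weighted: P={rep.weighted[0]:.3f} R={rep.weighted[1]:.3f} F={rep.weighted[2]:.3f}")

counts = load_case_study_counts()
binary = counts["binary_validation"]
print(f"\nbinary validation accuracy: "
      f"{100 * binary['confirmed_positive'] / binary['classifier_positive']:.1f}% "
      f"({binary['confirmed_positive']}/{binary['classifier_positive']})")
row = np.array(counts["twelve_month_confusion_c1_row"])
print(f"12-month ideation recall:   {100 * row[0] / row.sum():.2f}% ({row[0]}/{row.sum()})")
gender = counts["gender"]
print(f"profiles matched to a name: {100 * gender['matched'] / gender['total_users']:.1f}%")
print(f"female share of matched:    {100 * gender['female'] / gender['matched']:.1f}%")
flippant = next(r for r in summarise_from_counts(counts["category_counts"], 365)
                if r.class_code == "c3")
print(f"flippant share of stream:   {flippant.percent:.1f}% "
      f"(mean {flippant.mean_daily_rate}/day)")
ages = counts["age_groups"]
print(f"13-20 share of aged users:  {100 * ages['13-20'] / sum(ages.values()):.1f}%")
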