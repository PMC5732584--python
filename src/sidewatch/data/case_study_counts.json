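{
  "description": "Published summary counts from a 12-month national Twitter suicide-communication monitoring study, bundled as worked-example inputs for the case-study arithmetic.",
  "binary_validation": {
    "sample": 2000,
    "agreed_units": 1731,
    "classifier_positive": 282,
    "confirmed_positive": 240
  },
  "twelve_month_confusion_c1_row": [111, 0, 15, 3, 0, 39, 2],
  "gender": {
    "total_users": 43185,
    "matched": 22742,
    "male": 6846,
    "female": 10394,
    "unisex": 5502
  },
  "category_counts": {
    "c1": 108195,
    "c2": 3699,
    "c3": 904373,
    "c4": 59204,
    "c5": 34588,
    "c6": 106741,
    "c7": 667448
  },
  "n_days": 365,
  "age_groups": {
    "13-20": 345,
    "21-30": 71,
    "31-40": 7,
    "41-50": 2,
    "51-60": 0,
    "60+": 0
  },
  "under_13": 38
}
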