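"""The manual-review evaluation arithmetic on a worked example.

Reviewers confirm a subset of the flagged messages per topic (precision),
a 20% sample of the unflagged messages is read to estimate recall, two
annotators double-review 20% of the flags (Cohen kappa), and the corpus
noncompliance rate is the confirmed count over all topic-assigned posts.
"""

from adhermine import (cohen_kappa, noncompliance_rate, precision, recall,
                       sample_for_review)
from adhermine.evaluation import macro_average

# per-topic review outcomes: (confirmed, flagged)
review = {
    "dosage variation (corpus A)": (54, 187),
    "treatment cessation (corpus A)": (100, 216),
    "dosage variation (corpus B)": (56, 176),
    "treatment cessation (corpus B)": (62, 265),
}
per_topic = {}
for topic, (tp, n) in review.items():
    per_topic[topic] = precision(tp, n)
    print(f"precision {topic}: {per_topic[topic]}% ({tp}/{n})")
print(f"headline precision (macro-average): "
      f"{macro_average(list(per_topic.values()))}%")

# recall: the 20% sample of unflagged posts surfaced 4 missed cases,
# all in one subset
recalls = [recall(54, 0), recall(100, 0), recall(56, 0), recall(62, 4)]
print(f"per-subset recalls: {recalls} -> headline {macro_average(recalls)}%")

n_sample = len(sample_for_review([f"m{i}" for i in range(3246)], 0.20, seed=4))
print(f"20% review sample of 3246 unflagged posts: {n_sample} messages")

kappa = cohen_kappa([[40, 5], [10, 45]])
print(f"inter-annotator agreement on a double-reviewed 2x2 table: "
      f"kappa = {kappa:.2f}")

rate = noncompliance_rate(276, 4469)
print(f"corpus noncompliance rate: {rate}% (276 confirmed / 4469 assigned)")
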