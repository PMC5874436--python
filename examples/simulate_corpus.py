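"""Generate a labeled synthetic forum corpus and look at what it contains.

The generator draws posts from the LDA generative process with five
planted themes, two of which model noncompliance behaviors (treatment
cessation, dosage variation), then renders noisy French-like text with a
drug name in every post, literal dosage strings, stopwords and
punctuation.  Ground truth (which posts are really noncompliant) comes
from the generative topic weights, not from the text.
"""

from adhermine import SimConfig, generate_corpus

config = SimConfig(D=200, seed=7)
messages, gold = generate_corpus(config)

print(f"generated {len(messages)} posts; "
      f"{int(gold.flags.sum())} are gold noncompliant "
      f"(topic mass >= {config.flag_threshold} on a noncompliance theme)")
print()
print("an ordinary post:")
print(" ", messages[int(gold.flags.argmin())].text[:160], "...")
print()
flagged_idx = int(gold.flags.argmax())
print("a gold noncompliance post (note dosage strings / cessation words):")
print(" ", messages[flagged_idx].text[:160], "...")
print()
print("its true topic weights:",
      [round(float(w), 2) for w in gold.theta[flagged_idx]])
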