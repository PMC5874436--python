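"""Walk one forum post through the six preprocessing steps.

Dosage mentions ("10 mg", "2,5mg") are standardized to the neutral token
"dosemilligrams" before tokenization; text is lowercased and split on
punctuation (French elisions split at the apostrophe); stopwords and the
corpus-defining drug name are removed; the remaining words are stemmed
with the French Snowball stemmer; unigrams and adjacent bigrams form the
final tokens.
"""

from adhermine import (Message, RunConfig, preprocess_message,
                       standardize_dosage, tokenize)

text = "J'ai arrêté le Seroplex 10 mg, trop d'effets secondaires !"
print("raw:          ", text)
print("dosage step:  ", standardize_dosage(text))
print("tokenized:    ", tokenize(standardize_dosage(text)))

config = RunConfig(drug_names=["seroplex"])
doc = preprocess_message(Message("m1", "2011-06-01", "doctissimo", text),
                         config)
print("final tokens: ", list(doc.tokens))
print()
print("note: the drug name and stopwords (j, ai, le, trop, d) are gone,")

print("'effets secondaires' survives both as stems and as the bigram")
print("'effet_secondair', and the dosage is the single token"
      " 'dosemilligrams'.")
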