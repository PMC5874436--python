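"""Build a document-term matrix, choose the number of topics, inspect them.

The vocabulary is pruned by scanning per-term sparsity thresholds
(99.95% down to 80% by 0.025%) until the matrix reaches the 97% overall
sparsity target.  LDA is fitted by MAP-EM for each candidate K and the
log Bayes factor against the one-topic model picks the winner; each topic
is then summarized by its 15 highest-probability terms — the reading a
human labeler uses.
"""

from adhermine import (RunConfig, SimConfig, build_dtm, drop_empty_documents,
                       generate_corpus, preprocess_corpus, select_num_topics,
                       select_vocabulary)

messages, _ = generate_corpus(SimConfig(seed=1))  # 500 posts, 5 themes
config = RunConfig(drug_names=["seroplex"], K_grid=list(range(1, 7)), seed=1)

docs = preprocess_corpus(messages, config)
dtm = build_dtm(docs)
print(f"raw DTM: {dtm.n_docs} docs x {dtm.n_terms} terms, "
      f"sparsity {100 * dtm.sparsity:.2f}%")

threshold, dtm = select_vocabulary(dtm, config)
dtm, removed = drop_empty_documents(dtm)
print(f"kept {dtm.n_terms} terms at per-term sparsity threshold "
      f"{100 * threshold:.3f}% -> overall sparsity {100 * dtm.sparsity:.2f}%"
      f" ({len(removed)} emptied doc(s) dropped)")

selection = select_num_topics(dtm, config)
print("\nlog Bayes factor vs the one-topic model:")
print(selection.table().to_string(index=False))
print(f"\nselected K = {selection.selected_K}")
for k in range(selection.selected_model.K):
    print(f"topic {k}: {' '.join(selection.selected_model.top_terms(k, 15))}")
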