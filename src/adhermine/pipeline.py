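"""End-to-end orchestration: raw messages → preprocessing → DTM →
model selection → topic assignment."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .assign import TopicAssignment, assign_corpus
from .corpus import Message, RunConfig
from .dtm import (DocumentTermMatrix, build_dtm, drop_empty_documents,
                  select_vocabulary, tfidf_weight)
from .lda import ModelSelection, TopicModel, select_num_topics
from .preprocess import TokenizedDocument, preprocess_corpus

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything one analysis run produces."""

    docs: list[TokenizedDocument]
    dtm: DocumentTermMatrix            # after vocabulary selection
    sparsity_threshold: float          # winning per-term sparsity candidate
    removed_doc_ids: list[str]         # emptied by vocabulary filtering
    selection: ModelSelection
    assignments: list[TopicAssignment] = field(default_factory=list)

    @property
    def model(self) -> TopicModel:
        return self.selection.selected_model


def run_pipeline(messages: Sequence[Message],
                 config: RunConfig) -> PipelineResult:
    """Run the whole study pipeline on a corpus.

    Preprocesses every message, builds the document-term matrix, prunes
    the vocabulary by the sparsity scan, drops emptied documents, fits
    LDA over the configured K grid (on counts, or TF-IDF pseudo-counts
    when ``config.weighting == "tfidf"``), selects K by log Bayes factor
    and assigns messages to topics at the configured token-fraction
    threshold.
    """
    docs = preprocess_corpus(messages, config)
    dtm = build_dtm(docs)
    threshold, dtm = select_vocabulary(dtm, config)
    dtm, removed = drop_empty_documents(dtm)
    fit_input = tfidf_weight(dtm) if config.weighting == "tfidf" else dtm
    selection = select_num_topics(fit_input, config)
    assignments = assign_corpus(selection.selected_model, docs,
                                config.association_threshold)
    return PipelineResult(
        docs=docs, dtm=dtm, sparsity_threshold=threshold,
        removed_doc_ids=removed, selection=selection,
        assignments=assignments,
    )
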