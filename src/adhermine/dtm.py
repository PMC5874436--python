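"""Document-term matrix construction, sparsity-scan vocabulary selection,
TF-IDF weighting.

The vocabulary is pruned by scanning per-term sparsity thresholds from
99.95% down to 80% in steps of 0.025%: at each candidate every term rarer
than the candidate allows is dropped, and the first (largest) candidate
whose reduced matrix reaches the overall-sparsity target (default 97%)
wins.  This removes misspellings and rare abbreviations while keeping the
vocabulary patients actually use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .corpus import RunConfig
from .preprocess import TokenizedDocument

__all__ = [
    "DocumentTermMatrix",
    "WeightedMatrix",
    "build_dtm",
    "term_sparsity",
    "select_vocabulary",
    "tfidf_weight",
    "drop_empty_documents",
    "export_mtx",
]


@dataclass
class DocumentTermMatrix:
    """Docs × terms occurrence counts with vocabulary bookkeeping."""

    doc_ids: list[str]
    vocabulary: list[str]
    counts: sp.csr_matrix  # integer occurrence counts

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.doc_ids), len(self.vocabulary)):
            raise ValueError("counts shape does not match doc_ids/vocabulary")

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    @property
    def n_terms(self) -> int:
        return len(self.vocabulary)

    @property
    def doc_freq(self) -> np.ndarray:
        """Number of documents containing each term."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    @property
    def sparsity(self) -> float:
        """Fraction of zero cells."""
        cells = self.n_docs * self.n_terms
        return 1.0 - (self.counts > 0).nnz / cells if cells else 0.0

    def term_index(self, term: str) -> int:
        try:
            return self.vocabulary.index(term)
        except ValueError:
            raise KeyError(f"term {term!r} not in vocabulary") from None


@dataclass
class WeightedMatrix:
    """TF-IDF-weighted matrix, same shape/bookkeeping as the count DTM."""

    doc_ids: list[str]
    vocabulary: list[str]
    values: sp.csr_matrix  # nonnegative reals


def build_dtm(docs: Sequence[TokenizedDocument]) -> DocumentTermMatrix:
    """Count term occurrences per document.

    Vocabulary is the sorted set of distinct tokens across all documents.
    Raises if every document is empty.
    """
    vocab = sorted({t for d in docs for t in d.tokens})
    if not vocab:
        raise ValueError("all documents are empty; nothing to count")
    index = {t: j for j, t in enumerate(vocab)}
    rows: list[int] = []
    cols: list[int] = []
    for i, d in enumerate(docs):
        for t in d.tokens:
            rows.append(i)
            cols.append(index[t])
    counts = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(docs), len(vocab)),
    ).tocsr()
    counts.sum_duplicates()
    return DocumentTermMatrix(
        doc_ids=[d.message_id for d in docs], vocabulary=vocab, counts=counts
    )


def term_sparsity(dtm: DocumentTermMatrix, term: str) -> float:
    """Fraction of documents lacking ``term``: 1 − doc_freq/n_docs."""
    j = dtm.term_index(term)
    return 1.0 - dtm.doc_freq[j] / dtm.n_docs


def _subset_terms(dtm: DocumentTermMatrix, keep: np.ndarray) -> DocumentTermMatrix:
    return DocumentTermMatrix(
        doc_ids=list(dtm.doc_ids),
        vocabulary=[t for t, k in zip(dtm.vocabulary, keep) if k],
        counts=dtm.counts[:, np.flatnonzero(keep)].tocsr(),
    )


def select_vocabulary(
    dtm: DocumentTermMatrix, config: RunConfig
) -> tuple[float, DocumentTermMatrix]:
    """Scan per-term sparsity thresholds and prune the vocabulary.

    Candidates descend from ``start`` to ``stop`` by ``step`` (config
    ``sparsity_scan``).  At each candidate, terms whose per-term sparsity
    exceeds the candidate are dropped; the first candidate whose reduced
    matrix has overall sparsity ≤ ``sparsity_target`` is returned with
    that matrix.  If no candidate reaches the target the last candidate
    wins, with a warning.
    """
    start, stop, step = config.sparsity_scan
    if step <= 0 or start < stop:
        raise ValueError("invalid sparsity scan grid")
    n_steps = int(np.floor((start - stop) / step + 1e-9)) + 1
    candidates = np.round(start - step * np.arange(n_steps), 10)
    if candidates.size == 0:
        raise ValueError("empty sparsity scan grid")

    df = dtm.doc_freq.astype(np.int64)
    ts = 1.0 - df / dtm.n_docs  # per-term sparsity
    order = np.argsort(ts, kind="stable")
    ts_sorted = ts[order]
    df_cum = np.concatenate([[0], np.cumsum(df[order])])

    chosen = None
    for c in candidates:
        k = int(np.searchsorted(ts_sorted, c + 1e-12, side="right"))
        if k == 0:
            continue  # candidate would empty the vocabulary
        overall = 1.0 - df_cum[k] / (dtm.n_docs * k)
        if overall <= config.sparsity_target:
            chosen = (float(c), k)
            break
    if chosen is None:
        k = int(np.searchsorted(ts_sorted, candidates[-1] + 1e-12, side="right"))
        k = max(k, 1)
        warnings.warn(
            "no sparsity-scan candidate reached the overall-sparsity target; "
            "returning the last candidate's vocabulary",
            stacklevel=2,
        )
        chosen = (float(candidates[-1]), k)

    threshold, k = chosen
    keep = np.zeros(dtm.n_terms, dtype=bool)
    keep[order[:k]] = True
    return threshold, _subset_terms(dtm, keep)


def tfidf_weight(dtm: DocumentTermMatrix) -> WeightedMatrix:
    """Term-frequency × log2 inverse-document-frequency weighting.

    ``weight[d, t] = counts[d, t] / row_total[d] × log2(n_docs / doc_freq[t])``.
    A term present in every document weighs 0 everywhere.  Rows with no
    retained tokens must be dropped first (:func:`drop_empty_documents`).
    """
    row_tot = np.asarray(dtm.counts.sum(axis=1)).ravel()
    if (row_tot == 0).any():
        raise ValueError(
            "matrix has empty rows; call drop_empty_documents first"
        )
    tf = sp.diags(1.0 / row_tot) @ dtm.counts
    df = dtm.doc_freq
    idf = np.zeros(dtm.n_terms)
    present = df > 0
    idf[present] = np.log2(dtm.n_docs / df[present])
    values = (tf @ sp.diags(idf)).tocsr()
    return WeightedMatrix(doc_ids=list(dtm.doc_ids),
                          vocabulary=list(dtm.vocabulary), values=values)


def drop_empty_documents(
    dtm: DocumentTermMatrix,
) -> tuple[DocumentTermMatrix, list[str]]:
    """Remove rows whose retained-vocabulary token total is zero.

    Returns the reduced matrix and the removed document ids (for logging;
    in practice these are messages whose entire text was filtered away,
    e.g. severely misspelled posts).
    """
    row_tot = np.asarray(dtm.counts.sum(axis=1)).ravel()
    keep = row_tot > 0
    removed = [d for d, k in zip(dtm.doc_ids, keep) if not k]
    if not removed:
        return dtm, []
    reduced = DocumentTermMatrix(
        doc_ids=[d for d, k in zip(dtm.doc_ids, keep) if k],
        vocabulary=list(dtm.vocabulary),
        counts=dtm.counts[np.flatnonzero(keep), :].tocsr(),
    )
    return reduced, removed


def export_mtx(dtm: DocumentTermMatrix, prefix: str | Path) -> None:
    """Write MatrixMarket counts plus vocabulary/doc-id sidecar files."""
    from scipy.io import mmwrite

    prefix = Path(prefix)

    mmwrite(str(prefix.with_suffix(".mtx")), dtm.counts)
    prefix.with_suffix(".terms.txt").write_text(
        "\n".join(dtm.vocabulary) + "\n", encoding="utf-8")
    prefix.with_suffix(".docs.txt").write_text(
        "\n".join(dtm.doc_ids) + "\n", encoding="utf-8")
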