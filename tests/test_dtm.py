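import numpy as np
import pytest
import scipy.sparse as sp

from adhermine import (RunConfig, TokenizedDocument, build_dtm,
                       drop_empty_documents, select_vocabulary, term_sparsity,
                       tfidf_weight)
from adhermine.dtm import DocumentTermMatrix


class TestBuildDtm:
    def test_hand_counts(self, toy_docs):
        dtm = build_dtm(toy_docs)
        assert dtm.vocabulary == ["a", "b", "c"]
        assert dtm.counts.toarray().tolist() == [[2, 1, 0], [0, 1, 1]]
        assert dtm.sparsity == pytest.approx(2 / 6)
        assert dtm.counts.sum() == 5  # conservation of token occurrences

    def test_single_doc_single_term(self):
        dtm = build_dtm([TokenizedDocument("d", ("a",))])
        assert dtm.counts.shape == (1, 1)
        assert dtm.sparsity == 0.0

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            build_dtm([TokenizedDocument("d", ())])

    def test_doc_freq_definition(self, toy_docs):
        dtm = build_dtm(toy_docs)
        assert dtm.doc_freq.tolist() == [1, 2, 1]


class TestTermSparsity:
    def test_ubiquitous_term_zero(self, toy_docs):
        dtm = build_dtm(toy_docs)
        assert term_sparsity(dtm, "b") == 0.0

    def test_rare_term(self):
        docs = ([TokenizedDocument(f"d{i}", ("common",)) for i in range(199)]
                + [TokenizedDocument("d199", ("common", "rare"))])
        dtm = build_dtm(docs)
        assert term_sparsity(dtm, "rare") == pytest.approx(0.995)

    def test_unknown_term_errors(self, toy_docs):
        with pytest.raises(KeyError):
            term_sparsity(build_dtm(toy_docs), "zz")


def _brute_force_scan(dtm: DocumentTermMatrix, config: RunConfig):
    """Independent enumeration of the sparsity scan (oracle)."""
    start, stop, step = config.sparsity_scan
    c = start
    last = None
    while c >= stop - 1e-12:
        keep = [t for t in dtm.vocabulary if term_sparsity(dtm, t) <= c + 1e-12]
        if keep:
            sub = dtm.counts[:, [dtm.vocabulary.index(t) for t in keep]]
            zeros = (sub.toarray() == 0).sum()
            overall = zeros / (dtm.n_docs * len(keep))
            last = (round(c, 10), keep)
            if overall <= config.sparsity_target:
                return round(c, 10), keep
        c -= step
    return last


class TestSelectVocabulary:
    def test_dense_matrix_returned_at_first_candidate(self):
        docs = [TokenizedDocument(f"d{i}", ("a", "b")) for i in range(4)]
        dtm = build_dtm(docs)
        threshold, reduced = select_vocabulary(dtm, RunConfig())
        assert threshold == pytest.approx(0.9995)
        assert reduced.vocabulary == ["a", "b"]
        assert reduced.sparsity == 0.0

    def test_matches_brute_force_enumeration(self):
        # 10 docs: one term in a single doc, others in >= 9 docs
        docs = []
        for i in range(10):
            toks = ["u", "v"] if i else ["u", "v", "rare"]
            if i < 9:
                toks.append("w")
            docs.append(TokenizedDocument(f"d{i}", tuple(toks)))
        dtm = build_dtm(docs)
        cfg = RunConfig(sparsity_target=0.05,
                        sparsity_scan=(0.9995, 0.80, 0.00025))
        expect_threshold, expect_vocab = _brute_force_scan(dtm, cfg)
        threshold, reduced = select_vocabulary(dtm, cfg)
        assert threshold == pytest.approx(expect_threshold)
        assert reduced.vocabulary == sorted(expect_vocab)
        # the rare term (sparsity 0.9) is dropped exactly when candidate < 0.9
        assert "rare" not in reduced.vocabulary

    def test_rare_term_dropped_below_its_sparsity(self):
        docs = []
        for i in range(10):
            toks = ("u", "rare") if i == 0 else ("u",)
            docs.append(TokenizedDocument(f"d{i}", toks))
        dtm = build_dtm(docs)
        # target reachable only after dropping the rare term
        cfg = RunConfig(sparsity_target=0.01)
        threshold, reduced = select_vocabulary(dtm, cfg)
        assert reduced.vocabulary == ["u"]
        assert threshold < 0.9

    def test_vocabulary_monotone_in_candidate(self, rng):
        from tests.conftest import random_count_matrix
        x = random_count_matrix(rng, d=30, v=40, density=0.3)
        dtm = DocumentTermMatrix([f"d{i}" for i in range(30)],
                                 [f"t{j}" for j in range(40)], x)
        sizes = []
        for c in np.arange(0.999, 0.0, -0.05):
            keep = [t for t in dtm.vocabulary if term_sparsity(dtm, t) <= c]
            sizes.append(len(keep))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_order_independence(self, rng):
        docs = [TokenizedDocument(f"d{i}",
                                  tuple(rng.choice(list("abcdef"),
                                                   size=rng.integers(1, 6))))
                for i in range(20)]
        cfg = RunConfig(sparsity_target=0.9)
        t1, r1 = select_vocabulary(build_dtm(docs), cfg)
        t2, r2 = select_vocabulary(build_dtm(docs[::-1]), cfg)
        assert t1 == t2
        assert r1.vocabulary == r2.vocabulary


class TestTfidf:
    def test_hand_computed_weight(self):
        # 4 docs; term "x" in one doc with count 2, row total 4
        docs = [
            TokenizedDocument("d0", ("x", "x", "y", "y")),
            TokenizedDocument("d1", ("y", "z")),
            TokenizedDocument("d2", ("y", "z")),
            TokenizedDocument("d3", ("y", "z")),
        ]
        wm = tfidf_weight(build_dtm(docs))
        x_col = wm.vocabulary.index("x")
        assert wm.values[0, x_col] == pytest.approx(0.5 * np.log2(4))  # 1.0

    def test_ubiquitous_term_weighs_zero(self, toy_docs):
        docs = toy_docs + [TokenizedDocument("d3", ("b",))]
        wm = tfidf_weight(build_dtm(docs))
        b_col = wm.vocabulary.index("b")
        assert np.allclose(wm.values.toarray()[:, b_col], 0.0)

    def test_weights_nonnegative(self, rng):
        from tests.conftest import random_count_matrix
        x = random_count_matrix(rng)
        dtm = DocumentTermMatrix([f"d{i}" for i in range(x.shape[0])],
                                 [f"t{j}" for j in range(x.shape[1])], x)
        assert (tfidf_weight(dtm).values.toarray() >= 0).all()

    def test_empty_row_rejected(self):
        dtm = DocumentTermMatrix(["d0", "d1"], ["a"],
                                 sp.csr_matrix(np.array([[1], [0]])))
        with pytest.raises(ValueError, match="drop_empty_documents"):
            tfidf_weight(dtm)


class TestDropEmptyDocuments:
    def test_identity_when_no_empty_rows(self, toy_docs):
        dtm = build_dtm(toy_docs)
        reduced, removed = drop_empty_documents(dtm)
        assert removed == []
        assert reduced is dtm

    def test_emptied_doc_removed_and_reported(self):
        dtm = DocumentTermMatrix(
            ["d0", "d1", "d2"], ["a", "b"],
            sp.csr_matrix(np.array([[1, 0], [0, 0], [0, 2]])))
        reduced, removed = drop_empty_documents(dtm)
        assert removed == ["d1"]
        assert reduced.n_docs == 2
        # doc_freq stays consistent after row removal
        assert reduced.doc_freq.tolist() == [1, 1]
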