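"""Synthetic forum-corpus generator with planted noncompliance topics.

Real patient-forum corpora cannot be redistributed, so every other module
is exercised on corpora drawn from the LDA generative process itself:
topic-term distributions φ_k ~ Dirichlet over a synthetic content
vocabulary (``w000`` …), per-document topic weights θ_d ~ Dirichlet,
Poisson document lengths, and topic-then-word token sampling.  Two
planted topics model the behaviors of interest: a *treatment cessation*
topic and a *dosage variation* topic, each putting a configurable share
of its mass on a small French seed vocabulary (stop/arrêter/diminuer/
dose …); the dosage topic additionally emits literal dosage strings such
as ``10 mg``.  Rendered text inserts the drug name once per message,
sprinkles stopwords and sentence punctuation, so preprocessing is
exercised end to end while ground truth stays exact: a document is gold
noncompliant iff its generative mass on a noncompliance topic reaches the
flag threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from ._snowball import stem_word
from .corpus import Message
from .preprocess import DOSE_TOKEN

__all__ = [
    "SimConfig",
    "SyntheticGold",
    "GoldConfusion",
    "CESSATION_SEED_WORDS",
    "DOSAGE_SEED_WORDS",
    "generate_corpus",
    "gold_confusion",
    "marker_stems",
    "label_topics_by_markers",
]

#: Surface French vocabulary seeded into the planted treatment-cessation topic.
CESSATION_SEED_WORDS = (
    "arrêter", "arrêté", "stopper", "cesser", "abandonner", "interrompre",
    "quitter", "terminer", "sevrage", "rechute",
)
#: Surface French vocabulary seeded into the planted dosage-variation topic.
DOSAGE_SEED_WORDS = (
    "dose", "dosage", "diminuer", "réduire", "augmenter", "baisser",
    "demi", "comprimé", "posologie", "palier",
)
#: Pseudo-word of the dosage topic rendered as a literal dosage string.
_DOSE_WORD = "__DOSE__"

_DOSAGE_STRINGS = (
    "10 mg", "5 mg", "2,5 mg", "15 mg", "20 mg", "0,5 mg",
    "7,5mg", "25mg", "1 g", "50 ml",
)
# must be a subset of the bundled French stopword list
_FILLER_STOPWORDS = (
    "je", "le", "la", "de", "et", "un", "pour", "avec", "mais", "pas",
    "que", "sur", "en", "du",
)
_FORUMS = ("doctissimo", "atoute", "sante-medecine")


@dataclass
class SimConfig:
    """Study-shaped generator settings.

    Defaults emulate the forum corpora the pipeline targets at desk
    scale: a few hundred short, noisy posts mixing a handful of themes,
    two of which are the planted noncompliance topics.
    """

    D: int = 500
    V: int = 200
    K_true: int = 5
    alpha_doc: float = 0.15
    topic_peakedness: float = 0.08
    mean_doc_length: float = 60.0
    noncompliance_topics: tuple[int, ...] = (0, 1)  # 0=cessation, 1=dosage
    marker_mass: float = 0.5
    dosage_string_prob: float = 0.25
    drug_name: str = "seroplex"
    stopword_rate: float = 0.25
    flag_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 0 or self.V < 1 or self.K_true < 1:
            raise ValueError("D must be >= 0, V and K_true >= 1")
        for r in (self.marker_mass, self.dosage_string_prob,
                  self.stopword_rate, self.flag_threshold):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if any(not (0 <= k < self.K_true) for k in self.noncompliance_topics):
            raise ValueError("noncompliance_topics must index planted topics")


@dataclass
class SyntheticGold:
    """Ground truth of a generated corpus."""

    vocabulary: list[str]        # surface words, incl. markers
    phi: np.ndarray              # K_true × V_total true topic-term probs
    theta: np.ndarray            # D × K_true true document-topic weights
    flags: np.ndarray            # bool, gold noncompliance per document
    dominant_topic: np.ndarray   # int, argmax theta per document
    doc_ids: list[str] = field(default_factory=list)


class GoldConfusion(NamedTuple):
    tp: int
    fp: int
    fn: int
    tn: int

    def as_table(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


def _planted_phi(config: SimConfig, rng: np.random.Generator
                 ) -> tuple[list[str], np.ndarray]:
    content = [f"w{j:03d}" for j in range(config.V)]
    cess_idx = config.noncompliance_topics[0] if config.noncompliance_topics else None
    dose_idx = (config.noncompliance_topics[1]
                if len(config.noncompliance_topics) > 1 else None)
    markers: list[str] = []
    if cess_idx is not None:
        markers += list(CESSATION_SEED_WORDS)
    if dose_idx is not None:
        markers += list(DOSAGE_SEED_WORDS) + [_DOSE_WORD]
    vocab = content + markers
    phi = np.zeros((config.K_true, len(vocab)))
    for k in range(config.K_true):
        phi[k, : config.V] = rng.dirichlet(
            np.full(config.V, config.topic_peakedness))
    if cess_idx is not None:
        base = config.V + 0
        w = rng.dirichlet(np.full(len(CESSATION_SEED_WORDS), 1.0))
        phi[cess_idx, : config.V] *= 1 - config.marker_mass
        phi[cess_idx, base: base + len(CESSATION_SEED_WORDS)] = (
            config.marker_mass * w)
    if dose_idx is not None:
        base = config.V + (len(CESSATION_SEED_WORDS) if cess_idx is not None
                           else 0)
        w = rng.dirichlet(np.full(len(DOSAGE_SEED_WORDS), 1.0))
        word_mass = config.marker_mass * (1 - config.dosage_string_prob)
        phi[dose_idx, : config.V] *= 1 - config.marker_mass
        phi[dose_idx, base: base + len(DOSAGE_SEED_WORDS)] = word_mass * w
        phi[dose_idx, base + len(DOSAGE_SEED_WORDS)] = (
            config.marker_mass * config.dosage_string_prob)
    phi /= phi.sum(axis=1, keepdims=True)
    return vocab, phi


def _render(words: Sequence[str], drug_name: str, stopword_rate: float,
            rng: np.random.Generator) -> str:
    """Join sampled words into noisy forum-like text: the drug name once,
    filler stopwords, sentence punctuation, literal dosage strings."""
    surface: list[str] = []
    for w in words:
        if stopword_rate and rng.random() < stopword_rate:
            surface.append(str(rng.choice(_FILLER_STOPWORDS)))
        surface.append(str(rng.choice(_DOSAGE_STRINGS)) if w == _DOSE_WORD
                       else w)
    pos = int(rng.integers(0, len(surface) + 1))
    surface.insert(pos, drug_name.capitalize())
    # sentence segmentation with '.' and occasional ','
    out: list[str] = []
    sent_len = 0
    next_break = int(rng.integers(6, 14))
    for i, w in enumerate(surface):
        out.append(w)
        sent_len += 1
        if sent_len >= next_break and i < len(surface) - 1:
            out[-1] += "." if rng.random() < 0.7 else ","
            sent_len = 0
            next_break = int(rng.integers(6, 14))
    return " ".join(out) + "."


def generate_corpus(config: SimConfig
                    ) -> tuple[list[Message], SyntheticGold]:
    """Draw a labeled corpus from the planted LDA process.

    Deterministic per seed: the same config yields byte-identical
    messages.
    """
    rng = np.random.default_rng(config.seed)
    vocab, phi = _planted_phi(config, rng)
    D, K = config.D, config.K_true
    theta = (rng.dirichlet(np.full(K, config.alpha_doc), size=D)
             if D else np.zeros((0, K)))
    messages: list[Message] = []
    nc = list(config.noncompliance_topics)
    flags = (theta[:, nc].max(axis=1) >= config.flag_threshold
             if (D and nc) else np.zeros(D, dtype=bool))
    dominant = theta.argmax(axis=1) if D else np.zeros(0, dtype=int)
    base_date = np.datetime64("2004-01-01")
    for d in range(D):
        length = max(1, int(rng.poisson(config.mean_doc_length)))
        topics = rng.choice(K, size=length, p=theta[d])
        words = [vocab[rng.choice(len(vocab), p=phi[k])] for k in topics]
        text = _render(words, config.drug_name, config.stopword_rate, rng)
        date = str(base_date + int(rng.integers(0, 3650)))
        messages.append(Message(
            id=f"msg-{d:05d}", date=date,
            forum=_FORUMS[d % len(_FORUMS)], text=text,
        ))
    gold = SyntheticGold(
        vocabulary=vocab, phi=phi, theta=theta, flags=flags,
        dominant_topic=dominant, doc_ids=[m.id for m in messages],
    )
    return messages, gold


def sample_count_matrix(config: SimConfig):
    """Draw a document-term count matrix straight from the planted process.

    Bypasses text rendering and preprocessing: the returned
    :class:`~adhermine.dtm.DocumentTermMatrix` holds the sampled
    token counts over the generator vocabulary (content words plus
    markers), giving the estimation modules a clean LDA-distributed test
    bed with exact ground truth.
    """
    import scipy.sparse as sp

    from .dtm import DocumentTermMatrix

    rng = np.random.default_rng(config.seed)
    vocab, phi = _planted_phi(config, rng)
    D, K = config.D, config.K_true
    theta = (rng.dirichlet(np.full(K, config.alpha_doc), size=D)
             if D else np.zeros((0, K)))
    X = np.zeros((D, len(vocab)), dtype=np.int64)
    for d in range(D):
        length = max(1, int(rng.poisson(config.mean_doc_length)))
        n_k = rng.multinomial(length, theta[d])
        for k in np.flatnonzero(n_k):
            X[d] += rng.multinomial(n_k[k], phi[k])
    doc_ids = [f"msg-{d:05d}" for d in range(D)]
    nc = list(config.noncompliance_topics)
    flags = (theta[:, nc].max(axis=1) >= config.flag_threshold
             if (D and nc) else np.zeros(D, dtype=bool))
    gold = SyntheticGold(
        vocabulary=vocab, phi=phi, theta=theta, flags=flags,
        dominant_topic=theta.argmax(axis=1) if D else np.zeros(0, dtype=int),
        doc_ids=doc_ids,
    )
    dtm = DocumentTermMatrix(doc_ids=doc_ids, vocabulary=list(vocab),
                             counts=sp.csr_matrix(X))
    return dtm, gold


def gold_confusion(flagged_ids: Iterable[str],
                   gold: SyntheticGold) -> GoldConfusion:
    """Confusion counts of pipeline flags against gold flags."""
    flagged = set(flagged_ids)
    unknown = flagged - set(gold.doc_ids)
    if unknown:
        raise ValueError(f"flagged ids not in the gold corpus: "
                         f"{sorted(unknown)[:5]}")
    tp = fp = fn = tn = 0
    for mid, is_gold in zip(gold.doc_ids, gold.flags):
        hit = mid in flagged
        if hit and is_gold:
            tp += 1
        elif hit:
            fp += 1
        elif is_gold:
            fn += 1
        else:
            tn += 1
    return GoldConfusion(tp, fp, fn, tn)


def marker_stems(words: Iterable[str] | None = None,
                 label: str | None = None) -> set[str]:
    """Stems of a marker vocabulary, as they appear in the fitted model."""
    if words is None:
        words = (CESSATION_SEED_WORDS if label == "treatment_cessation"
                 else DOSAGE_SEED_WORDS)
    stems = {stem_word(w.lower()) for w in words}
    if words is DOSAGE_SEED_WORDS or label == "dosage_variation":
        stems.add(DOSE_TOKEN)
    return stems


def label_topics_by_markers(model, top_n: int = 15, min_hits: int = 2
                            ) -> dict[int, str]:
    """Label fitted topics from their top terms — a synthetic stand-in
    for the manual labeling step.

    A topic is labeled ``treatment_cessation`` or ``dosage_variation``
    when at least ``min_hits`` of its ``top_n`` highest-probability terms
    are marker stems of that behavior (the same first-terms reading a
    human labeler performs); when both marker sets hit, the larger count
    wins, ties going to the dosage label.
    """
    from .assign import CESSATION_LABEL, DOSAGE_LABEL

    cess = marker_stems(CESSATION_SEED_WORDS)
    dose = marker_stems(DOSAGE_SEED_WORDS) | {DOSE_TOKEN}
    labels: dict[int, str] = {}
    for k in range(model.K):
        terms = model.top_terms(k, top_n)
        unigram_parts = set(terms) | {p for t in terms for p in t.split("_")}
        c_hits = len(unigram_parts & cess)
        d_hits = len(unigram_parts & dose)
        if max(c_hits, d_hits) < min_hits:
            continue
        labels[k] = DOSAGE_LABEL if d_hits >= c_hits else CESSATION_LABEL
    return labels
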