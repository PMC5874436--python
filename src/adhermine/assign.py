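"""Message-topic assignment via the 25%-of-tokens rule and extraction of
messages flagged by noncompliance-labeled topics.

Each token occurrence of a fitted document is associated with its MAP
topic (argmax_k θ_{dk} φ_{kv}); a message is associated with every topic
that accounts for at least a fraction τ (default 25%) of its
in-vocabulary token occurrences.  Messages assigned to a topic manually
labeled ``dosage_variation`` or ``treatment_cessation`` form the
noncompliance candidate set handed to human review.
"""

from __future__ import annotations

import csv
import statistics
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .lda import TopicModel
from .preprocess import TokenizedDocument

__all__ = [
    "TopicAssignment",
    "DOSAGE_LABEL",
    "CESSATION_LABEL",
    "token_topic",
    "assign_document",
    "assign_corpus",
    "assignment_stats",
    "extract_flagged",
    "read_label_map",
]

#: Distinguished labels for the two noncompliance behaviors.
DOSAGE_LABEL = "dosage_variation"
CESSATION_LABEL = "treatment_cessation"


@dataclass(frozen=True)
class TopicAssignment:
    """Per-document topic token-fractions and the ≥ τ assigned-topic set."""

    message_id: str
    token_fractions: tuple[float, ...]
    assigned: frozenset[int]


def token_topic(model: TopicModel, d: int, v: int | str) -> int:
    """MAP topic of term ``v`` within document ``d``:
    argmax_k θ[d,k]·φ[k,v], ties to the lowest topic index."""
    if isinstance(v, str):
        try:
            v = model.vocabulary.index(v)
        except ValueError:
            raise KeyError(f"term {v!r} not in model vocabulary") from None
    elif not (0 <= v < model.n_terms):
        raise KeyError(f"term index {v} out of range")
    scores = model.theta[d, :] * model.phi[:, v]
    return int(np.argmax(scores))  # argmax returns the first (lowest) maximum


def assign_document(
    model: TopicModel,
    doc: TokenizedDocument,
    tau: float = 0.25,
    doc_index: int | None = None,
) -> TopicAssignment:
    """Assign one fitted document to topics by the token-fraction rule.

    ``f[k]`` is the fraction of the document's in-vocabulary token
    occurrences whose MAP topic is k (repeated terms count multiply;
    out-of-vocabulary tokens are excluded from the denominator); the
    assigned set is ``{k : f[k] ≥ tau}``.  A document with no
    in-vocabulary tokens gets all-zero fractions and no topics.
    """
    if doc_index is None:
        try:
            doc_index = model.doc_ids.index(doc.message_id)
        except ValueError:
            raise KeyError(
                f"document {doc.message_id!r} was not part of the fit"
            ) from None
    vocab_index = {t: j for j, t in enumerate(model.vocabulary)}
    counts = np.zeros(model.K)
    total = 0
    for tok in doc.tokens:
        j = vocab_index.get(tok)
        if j is None:
            continue
        counts[token_topic(model, doc_index, j)] += 1
        total += 1
    if total == 0:
        fractions = np.zeros(model.K)
    else:
        fractions = counts / total
    assigned = frozenset(int(k) for k in np.flatnonzero(fractions >= tau))
    return TopicAssignment(
        message_id=doc.message_id,
        token_fractions=tuple(float(f) for f in fractions),
        assigned=assigned,
    )


def assign_corpus(
    model: TopicModel,
    docs: Sequence[TokenizedDocument],
    tau: float = 0.25,
) -> list[TopicAssignment]:
    """Assign every fitted document; documents dropped before the fit
    (absent from the model) are skipped."""
    pos = {mid: i for i, mid in enumerate(model.doc_ids)}
    out = []
    for doc in docs:
        i = pos.get(doc.message_id)
        if i is None:
            continue
        out.append(assign_document(model, doc, tau, doc_index=i))
    return out


def assignment_stats(assignments: Sequence[TopicAssignment]) -> dict:
    """Summary of an assignment run.

    Per-topic message counts and proportions (against the total message
    count), the number of unassigned messages, and the mean and median of
    topics-per-message over the assigned messages (None when no message
    is assigned).
    """
    n = len(assignments)
    k_max = max((max(a.assigned) for a in assignments if a.assigned),
                default=-1)
    topic_counts = {k: 0 for k in range(k_max + 1)}
    sizes = []
    for a in assignments:
        for k in a.assigned:
            topic_counts[k] += 1
        if a.assigned:
            sizes.append(len(a.assigned))
    return {
        "n_messages": n,
        "topic_counts": topic_counts,
        "topic_proportions": {k: (c / n if n else 0.0)
                              for k, c in topic_counts.items()},
        "n_unassigned": sum(1 for a in assignments if not a.assigned),
        "mean_topics_per_message": statistics.mean(sizes) if sizes else None,
        "median_topics_per_message": (statistics.median(sizes)
                                      if sizes else None),
    }


def extract_flagged(
    assignments: Sequence[TopicAssignment],
    labels: Mapping[int, str],
) -> dict:
    """Collect the messages flagged by the noncompliance topics.

    Returns, per noncompliance label, the set of message ids assigned to
    any topic carrying that label, plus the intersection of the two sets
    (messages flagged for both behaviors).  A label absent from the map
    yields an empty set with a warning.
    """
    out: dict = {}
    for label in (DOSAGE_LABEL, CESSATION_LABEL):
        topics = {k for k, lab in labels.items() if lab == label}
        if not topics:
            warnings.warn(f"no topic labeled {label!r}", stacklevel=2)
        out[label] = {a.message_id for a in assignments
                      if a.assigned & topics}
    out["intersection"] = out[DOSAGE_LABEL] & out[CESSATION_LABEL]
    out["union"] = out[DOSAGE_LABEL] | out[CESSATION_LABEL]
    return out


def read_label_map(path: str | Path) -> dict[int, str]:
    """Load a topic→label map from YAML (mapping) or CSV
    (``topic_id,label`` header)."""
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        with path.open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return {int(k): str(v) for k, v in data.items()}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        return {int(r["topic_id"]): r["label"] for r in reader}
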