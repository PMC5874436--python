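"""Corpus, lexicon and configuration I/O.

A corpus is an ordered collection of forum posts (:class:`Message`), read
from JSON-lines (one object per line with ``id``, ``date``, ``forum``,
``text`` keys) or CSV with the same columns.  Lexicons (drug names,
stopwords, dosage units) are plain-text files, one entry per line, with
``#`` comments.  Run parameters live in :class:`RunConfig`, loadable from
YAML.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "Message",
    "RunConfig",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "read_lexicon",
    "default_stopwords",
    "write_topic_report",
]

_REQUIRED_FIELDS = ("id", "date", "forum", "text")


class CorpusFormatError(ValueError):
    """Raised when a corpus file violates the record contract."""


@dataclass(frozen=True)
class Message:
    """One forum post: identifier, publication date, source forum, raw text.

    Dates are carried as ISO-8601 strings; the pipeline treats them as
    opaque metadata.
    """

    id: str
    date: str
    forum: str
    text: str


def _check_record(rec: dict, lineno: int, allow_empty_text: bool) -> Message:
    for f in _REQUIRED_FIELDS:
        if f not in rec or rec[f] is None:
            raise CorpusFormatError(
                f"record at line {lineno} is missing required field {f!r}"
            )
    msg = Message(
        id=str(rec["id"]), date=str(rec["date"]),
        forum=str(rec["forum"]), text=str(rec["text"]),
    )
    if not allow_empty_text and msg.text.strip() == "":
        raise CorpusFormatError(f"record at line {lineno} has empty text")
    return msg


def read_corpus(
    path: str | Path,
    format: str | None = None,
    allow_empty_text: bool = False,
) -> list[Message]:
    """Read a corpus file, preserving record order.

    ``format`` is ``"jsonl"`` or ``"csv"``; when omitted it is inferred
    from the file suffix.  Duplicate ids and missing fields raise
    :class:`CorpusFormatError` naming the offending line.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format {format!r}")

    messages: list[Message] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(
                        f"invalid JSON at line {lineno}: {exc}"
                    ) from exc
                messages.append(_check_record(rec, lineno, allow_empty_text))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise CorpusFormatError("CSV corpus has no header row")
            missing = [f for f in _REQUIRED_FIELDS if f not in reader.fieldnames]
            if missing:
                raise CorpusFormatError(
                    f"CSV header is missing required field(s) {missing}"
                )
            for rec in reader:
                messages.append(
                    _check_record(rec, reader.line_num, allow_empty_text)
                )

    seen: set[str] = set()
    for m in messages:
        if m.id in seen:
            raise CorpusFormatError(f"duplicate message id {m.id!r}")
        seen.add(m.id)
    return messages


def write_corpus(messages: Iterable[Message], path: str | Path,
                 format: str | None = None) -> None:
    """Write messages to JSON-lines or CSV (inverse of :func:`read_corpus`)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for m in messages:
                fh.write(json.dumps(dataclasses.asdict(m), ensure_ascii=False))
                fh.write("\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(_REQUIRED_FIELDS),
                                    quoting=csv.QUOTE_ALL)
            writer.writeheader()
            for m in messages:
                writer.writerow(dataclasses.asdict(m))
    else:
        raise ValueError(f"unknown corpus format {format!r}")


def read_lexicon(path: str | Path) -> list[str]:
    """Read a plain-text lexicon: one entry per line, ``#`` comments, UTF-8."""
    entries: list[str] = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                entries.append(line)
    return entries


def default_stopwords() -> list[str]:
    """The bundled French stopword list (fully overridable via config)."""
    text = resources.files("adhermine").joinpath(
        "data/stopwords_fr.txt").read_text(encoding="utf-8")
    return [w for w in (ln.split("#", 1)[0].strip() for ln in text.splitlines()) if w]


@dataclass
class RunConfig:
    """Parameters of one analysis run.

    Thresholds default to the study protocol: per-term sparsity scanned
    from 99.95% down to 80% in steps of 0.025% against an overall-sparsity
    target of 97%; messages count as associated with a topic when at least
    25% of their in-vocabulary tokens map to it; topics are summarized by
    their first 15 terms; 20% of non-flagged messages are sampled for the
    recall review.
    """

    drug_names: list[str] = field(default_factory=list)
    stopword_path: str | None = None
    sparsity_target: float = 0.97
    sparsity_scan: tuple[float, float, float] = (0.9995, 0.80, 0.00025)
    association_threshold: float = 0.25
    K_grid: list[int] = field(default_factory=lambda: list(range(1, 9)))
    top_n_terms: int = 15
    review_fraction: float = 0.20
    seed: int = 0
    weighting: str = "counts"
    # estimation knobs
    alpha_theta: float = 1.1
    alpha_phi: float = 1.1
    max_iter: int = 300
    tol: float = 1e-6
    n_restarts: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.association_threshold <= 1):
            raise ValueError("association_threshold must be in (0, 1]")
        if not (0 < self.sparsity_target < 1):
            raise ValueError("sparsity_target must be in (0, 1)")
        if not self.K_grid or any(k < 1 for k in self.K_grid):
            raise ValueError("K_grid must be nonempty with all K >= 1")
        if self.weighting not in ("counts", "tfidf"):
            raise ValueError("weighting must be 'counts' or 'tfidf'")
        if not (0 < self.review_fraction <= 1):
            raise ValueError("review_fraction must be in (0, 1]")
        self.drug_names = [d.lower() for d in self.drug_names]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from YAML; keyword arguments override file values."""
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "sparsity_scan" in data:
            data["sparsity_scan"] = tuple(data["sparsity_scan"])
        data.update(overrides)
        return cls(**data)

    def stopwords(self) -> set[str]:
        """Resolve the stopword set: the configured file or the bundled list."""
        if self.stopword_path is not None:
            return {w.lower() for w in read_lexicon(self.stopword_path)}
        return {w.lower() for w in default_stopwords()}


def write_topic_report(model, assignments: Sequence, outdir: str | Path,
                       config: RunConfig | None = None) -> dict[str, Path]:
    """Write the fitted-model report.

    Emits ``topic_terms.tsv`` (topic, rank, term, probability),
    ``doc_topics.tsv`` (message id, per-topic token fraction, assigned
    topic set) and ``summary.json`` (K, log marginal, config echo).
    Returns the paths written.  Decimal separator is ``.``; topic sets are
    comma-joined, empty string when no topic reaches the threshold.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "topic_terms": outdir / "topic_terms.tsv",
        "doc_topics": outdir / "doc_topics.tsv",
        "summary": outdir / "summary.json",
    }

    with paths["topic_terms"].open("w", encoding="utf-8") as fh:
        fh.write("topic\trank\tterm\tprobability\n")
        for k in range(model.K):
            order = sorted(range(len(model.vocabulary)),
                           key=lambda v: (-model.phi[k, v], model.vocabulary[v]))
            for rank, v in enumerate(order, start=1):
                fh.write(f"{k}\t{rank}\t{model.vocabulary[v]}\t"
                         f"{model.phi[k, v]:.10g}\n")

    with paths["doc_topics"].open("w", encoding="utf-8") as fh:
        header = "\t".join(["message_id"]
                           + [f"f_topic_{k}" for k in range(model.K)]
                           + ["assigned"])
        fh.write(header + "\n")
        for a in assignments:
            fracs = "\t".join(f"{f:.6f}" for f in a.token_fractions)
            assigned = ",".join(str(k) for k in sorted(a.assigned))
            fh.write(f"{a.message_id}\t{fracs}\t{assigned}\n")

    summary = {
        "K": int(model.K),
        "log_marginal": None if model.log_marginal is None
        else float(model.log_marginal),
        "converged": bool(model.converged),
        "seed": model.seed,
        "config": None if config is None else dataclasses.asdict(config),
    }
    with paths["summary"].open("w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, ensure_ascii=False)
    return paths
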