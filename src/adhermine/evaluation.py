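"""Evaluation protocol: per-topic precision from manual review, recall from
a 20% sample of the non-noncompliance messages, Cohen kappa agreement, and
the corpus noncompliance rate.

Truth labels always come from human review (a reviewed-outcomes CSV); the
module only does the arithmetic.  Percentages are rounded half away from
zero: one decimal for precision/recall, two for corpus rates, matching how
such results are conventionally reported.
"""

from __future__ import annotations

import csv
import decimal
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ReviewOutcome",
    "precision",
    "recall",
    "cohen_kappa",
    "sample_for_review",
    "noncompliance_rate",
    "macro_average",
    "read_review_outcomes",
]


@dataclass(frozen=True)
class ReviewOutcome:
    """One annotator's verdict on one flagged message."""

    message_id: str
    flagged_label: str
    annotator_id: str
    verdict: bool  # True = describes a noncompliant behavior


def _round_half_away(x: float, ndigits: int) -> float:
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


def _truncate(x: float, ndigits: int) -> float:
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(
        q, rounding=decimal.ROUND_DOWN))


def precision(tp: int, flagged_n: int) -> float | None:
    """Percentage of flagged messages confirmed by review, 1-decimal.

    ``None`` when nothing was flagged.
    """
    if tp < 0 or flagged_n < 0 or tp > flagged_n:
        raise ValueError("need 0 <= tp <= flagged_n")
    if flagged_n == 0:
        return None
    return _round_half_away(100.0 * tp / flagged_n, 1)


def recall(tp: int, fn: int) -> float | None:
    """Percentage of true noncompliance messages that were flagged,
    1-decimal.  ``None`` when no positives exist."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fn == 0:
        return None
    return _round_half_away(100.0 * tp / (tp + fn), 1)


def cohen_kappa(agreement_table) -> float:
    """Cohen's chance-corrected agreement for a 2×2 table.

    κ = (p_o − p_e) / (1 − p_e) with observed agreement
    p_o = (a + d)/n and expected agreement from the marginal products.
    Perfect agreement with degenerate marginals (p_e = 1) returns 1.
    """
    t = np.asarray(agreement_table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("agreement table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    n = t.sum()
    if n == 0:
        raise ValueError("agreement table is empty")
    p_o = (t[0, 0] + t[1, 1]) / n
    p_e = (t[0, :].sum() * t[:, 0].sum() + t[1, :].sum() * t[:, 1].sum()) / n**2
    if p_e == 1.0:
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def sample_for_review(
    message_ids: Sequence[str], fraction: float, seed: int
) -> list[str]:
    """Seeded simple random sample (without replacement) of
    ``ceil(fraction × n)`` message ids.

    The ceiling reproduces the protocol's printed sample sizes
    (20% of 1723 → 345, 20% of 3246 → 650).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = len(message_ids)
    if n == 0:
        return []
    size = math.ceil(round(fraction * n, 9))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=size, replace=False)
    return [message_ids[i] for i in sorted(idx)]


def noncompliance_rate(confirmed: int, assigned_total: int) -> float | None:
    """Corpus-level noncompliance percentage, truncated to 2 decimals.

    Two-decimal corpus rates are reported truncated toward zero (e.g.
    276/4469 → 6.17, 62/2164 → 2.86), so this helper truncates rather
    than rounds.
    """
    if confirmed < 0 or assigned_total < 0:
        raise ValueError("counts must be nonnegative")
    if assigned_total == 0:
        return None
    return _truncate(100.0 * confirmed / assigned_total, 2)


def macro_average(percentages: Sequence[float]) -> float:
    """Unweighted mean of per-topic percentages, 1-decimal rounding.

    Headline precision/recall over several topics and corpora are the
    macro-averages of the per-topic scores (e.g. per-topic precisions
    28.9, 46.3, 31.8, 23.4 average to 32.6), not the pooled ratios.
    """
    if not percentages:
        raise ValueError("no percentages to average")
    return _round_half_away(sum(percentages) / len(percentages), 1)


def read_review_outcomes(path: str | Path) -> list[ReviewOutcome]:
    """Read a reviewed-outcomes CSV:
    ``message_id,label,annotator_id,verdict`` (verdict in 1/0/true/false)."""
    out: list[ReviewOutcome] = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(ReviewOutcome(
                message_id=row["message_id"],
                flagged_label=row["label"],
                annotator_id=row["annotator_id"],
                verdict=row["verdict"].strip().lower() in ("1", "true", "yes"),
            ))
    return out
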