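"""Latent Dirichlet allocation fitted by MAP expectation-maximization, with
log-Bayes-factor selection of the number of topics.

The model: each document d mixes K topics with proportions θ_d; each topic
k is a distribution φ_k over the vocabulary.  With symmetric Dirichlet
priors Dir(α_θ) on θ and Dir(α_φ) on φ (both concentrations > 1 so the
posterior mode is interior), the MAP objective is

    L(θ, φ) = Σ_{d,v} x_{dv} log Σ_k θ_{dk} φ_{kv}
              + (α_θ−1) Σ log θ + (α_φ−1) Σ log φ

maximized by EM: responsibilities r_{dvk} ∝ θ_{dk} φ_{kv}, then
θ_{dk} ∝ Σ_v x_{dv} r_{dvk} + (α_θ−1) and φ_{kv} ∝ Σ_d x_{dv} r_{dvk}
+ (α_φ−1).  Each EM sweep cannot decrease L, which the per-iteration
trace records.

The number of topics is compared against the one-topic model with an
approximate log marginal likelihood: the maximized log posterior minus a
BIC-style dimensionality penalty (df/2)·log N, df = K(V−1) + D(K−1),
N = total token count.  BF(K) = log m(K) − log m(1); the grid argmax wins,
falling back to K = 1 when no multi-topic model beats the null.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .corpus import RunConfig
from .dtm import DocumentTermMatrix, WeightedMatrix

__all__ = [
    "TopicModel",
    "ModelSelection",
    "fit_lda_map",
    "log_marginal_approx",
    "select_num_topics",
    "top_terms",
]

_FLOOR = 1e-12
#: TF-IDF weights are mapped to pseudo-counts as round(10 × weight); the
#: multinomial likelihood needs count-like data.
TFIDF_COUNT_SCALE = 10


@dataclass
class TopicModel:
    """A fitted LDA model (MAP point estimates)."""

    K: int
    phi: np.ndarray          # K × V topic-term probabilities
    theta: np.ndarray        # D × K document-topic probabilities
    alpha_theta: float
    alpha_phi: float
    log_posterior_trace: list[float]
    seed: int
    n_restarts: int
    converged: bool
    vocabulary: list[str]
    doc_ids: list[str]
    n_tokens: float
    log_marginal: float | None = None

    @property
    def log_posterior(self) -> float:
        return self.log_posterior_trace[-1]

    @property
    def n_docs(self) -> int:
        return self.theta.shape[0]

    @property
    def n_terms(self) -> int:
        return self.phi.shape[1]

    def top_terms(self, k: int, n: int = 15) -> list[str]:
        return top_terms(self, k, n)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "K": self.K,
            "phi": self.phi.tolist(),
            "theta": self.theta.tolist(),
            "alpha_theta": self.alpha_theta,
            "alpha_phi": self.alpha_phi,
            "log_posterior_trace": self.log_posterior_trace,
            "seed": self.seed,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
            "vocabulary": self.vocabulary,
            "doc_ids": self.doc_ids,
            "n_tokens": self.n_tokens,
            "log_marginal": self.log_marginal,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "TopicModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        d["phi"] = np.asarray(d["phi"], dtype=float)
        d["theta"] = np.asarray(d["theta"], dtype=float)
        return cls(**d)


def _as_fit_input(
    x: DocumentTermMatrix | WeightedMatrix | np.ndarray | sp.spmatrix,
) -> tuple[sp.coo_matrix, list[str] | None, list[str] | None]:
    if isinstance(x, DocumentTermMatrix):
        return x.counts.tocoo(), x.vocabulary, x.doc_ids
    if isinstance(x, WeightedMatrix):
        dense = np.rint(x.values.toarray() * TFIDF_COUNT_SCALE)
        return sp.coo_matrix(dense), x.vocabulary, x.doc_ids
    return sp.coo_matrix(np.asarray(x) if not sp.issparse(x) else x), None, None


def fit_lda_map(
    dtm_or_weighted,
    K: int,
    alpha_theta: float = 1.1,
    alpha_phi: float = 1.1,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_restarts: int = 2,
) -> TopicModel:
    """Fit a K-topic LDA model by MAP-EM.

    Accepts a count DTM, a TF-IDF :class:`WeightedMatrix` (converted to
    pseudo-counts), or a raw nonnegative matrix.  ``n_restarts`` seeded
    initializations are run (φ rows drawn from a symmetric Dirichlet,
    θ started uniform so that reordering documents merely reorders θ) and
    the best log posterior kept.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if alpha_theta <= 1 or alpha_phi <= 1:
        raise ValueError("Dirichlet hyperparameters must exceed 1 "
                         "(interior MAP)")
    X, vocabulary, doc_ids = _as_fit_input(dtm_or_weighted)
    if (X.data < 0).any():
        raise ValueError("input matrix must be nonnegative")
    D, V = X.shape
    row_tot = np.zeros(D)
    np.add.at(row_tot, X.row, X.data)
    if (row_tot == 0).any():
        raise ValueError(
            "input has all-zero rows; call drop_empty_documents first"
        )
    if K > V:
        warnings.warn(f"K={K} exceeds vocabulary size {V}", stacklevel=2)

    rows, cols = X.row, X.col
    x = X.data.astype(float)
    n_tokens = float(x.sum())
    at, ap = alpha_theta - 1.0, alpha_phi - 1.0

    best: tuple[float, np.ndarray, np.ndarray, list[float], bool] | None = None
    for restart in range(n_restarts):
        rng = np.random.default_rng(seed + restart)
        theta = np.full((D, K), 1.0 / K)
        phi = rng.gamma(1.5, size=(K, V))
        phi /= phi.sum(axis=1, keepdims=True)

        trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            P = theta[rows, :] * phi[:, cols].T  # nnz × K
            s = P.sum(axis=1)
            lp = (float(x @ np.log(s))
                  + at * float(np.log(theta).sum())
                  + ap * float(np.log(phi).sum()))
            if trace and abs(lp - trace[-1]) <= tol * (abs(trace[-1]) + _FLOOR):
                trace.append(lp)
                converged = True
                break
            trace.append(lp)
            R = (P / s[:, None]) * x[:, None]
            theta = np.stack(
                [np.bincount(rows, weights=R[:, k], minlength=D)
                 for k in range(K)], axis=1) + at
            theta = np.maximum(theta, _FLOOR)
            theta /= theta.sum(axis=1, keepdims=True)
            phi = np.stack(
                [np.bincount(cols, weights=R[:, k], minlength=V)
                 for k in range(K)], axis=0) + ap
            phi = np.maximum(phi, _FLOOR)
            phi /= phi.sum(axis=1, keepdims=True)
        else:
            # evaluate the objective at the final parameters
            s = (theta[rows, :] * phi[:, cols].T).sum(axis=1)
            trace.append(float(x @ np.log(s))
                         + at * float(np.log(theta).sum())
                         + ap * float(np.log(phi).sum()))

        if best is None or trace[-1] > best[0]:
            best = (trace[-1], theta, phi, trace, converged)

    _, theta, phi, trace, converged = best
    return TopicModel(
        K=K, phi=phi, theta=theta,
        alpha_theta=alpha_theta, alpha_phi=alpha_phi,
        log_posterior_trace=trace, seed=seed, n_restarts=n_restarts,
        converged=converged,
        vocabulary=list(vocabulary) if vocabulary is not None
        else [f"t{j}" for j in range(V)],
        doc_ids=list(doc_ids) if doc_ids is not None
        else [f"d{i}" for i in range(D)],
        n_tokens=n_tokens,
    )


def log_marginal_approx(model: TopicModel, dtm=None) -> float:
    """BIC-style approximate log marginal likelihood.

    Maximized log posterior minus (df/2)·log N with
    df = K(V−1) + D(K−1) and N the total token count.  Stored on the
    model and returned.
    """
    if not model.log_posterior_trace:
        raise ValueError("model is not fitted")
    n_tokens = model.n_tokens
    if dtm is not None:
        counts = dtm.counts if isinstance(dtm, DocumentTermMatrix) else dtm
        n_tokens = float(np.asarray(counts.sum()))
    D, V, K = model.n_docs, model.n_terms, model.K
    df = K * (V - 1) + D * (K - 1)
    model.log_marginal = model.log_posterior - 0.5 * df * np.log(n_tokens)
    return model.log_marginal


@dataclass
class ModelSelection:
    """Per-K log Bayes factors against the one-topic null and the winner."""

    K_grid: list[int]
    log_bf: dict[int, float]
    selected_K: int
    models: dict[int, TopicModel] = field(repr=False, default_factory=dict)
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def selected_model(self) -> TopicModel:
        return self.models[self.selected_K]

    def table(self) -> pd.DataFrame:
        rows = [
            {"K": k, "log_marginal": self.models[k].log_marginal,
             "log_bayes_factor": self.log_bf[k]}
            for k in sorted(self.log_bf)
        ]
        return pd.DataFrame(rows)


def select_num_topics(dtm, config: RunConfig) -> ModelSelection:
    """Fit every K in the grid and pick the best by log Bayes factor.

    All fits share the run seed.  The one-topic model is always fitted as
    the comparison baseline, so BF(1) = 0 exactly.  Per-K fit failures
    are recorded and selection runs over the successful fits; if every
    BF ≤ 0 the one-topic model is selected.
    """
    if not config.K_grid:
        raise ValueError("K_grid is empty")
    grid = sorted(set(config.K_grid) | {1})
    models: dict[int, TopicModel] = {}
    failures: dict[int, str] = {}
    for k in grid:
        try:
            m = fit_lda_map(
                dtm, k,
                alpha_theta=config.alpha_theta, alpha_phi=config.alpha_phi,
                seed=config.seed, tol=config.tol, max_iter=config.max_iter,
                n_restarts=config.n_restarts,
            )
            log_marginal_approx(m)
            models[k] = m
        except Exception as exc:  # noqa: BLE001 — per-K failures are recorded
            failures[k] = str(exc)
    if 1 not in models:
        raise RuntimeError("the one-topic baseline failed to fit: "
                           + failures.get(1, "unknown error"))
    base = models[1].log_marginal
    log_bf = {k: m.log_marginal - base for k, m in models.items()}
    in_grid = [k for k in config.K_grid if k in log_bf]
    best = max(in_grid, key=lambda k: (log_bf[k], -k))
    selected = best if log_bf[best] > 0 else 1
    return ModelSelection(
        K_grid=list(config.K_grid), log_bf=log_bf,
        selected_K=selected, models=models, failures=failures,
    )


def top_terms(model: TopicModel, k: int, n: int = 15) -> list[str]:
    """The ``n`` highest-probability terms of topic ``k`` (0-based),
    descending; ties break alphabetically."""
    if not (0 <= k < model.K):
        raise IndexError(f"topic index {k} out of range [0, {model.K})")
    if n < 1:
        raise ValueError("n must be >= 1")
    order = sorted(range(model.n_terms),
                   key=lambda v: (-model.phi[k, v], model.vocabulary[v]))
    return [model.vocabulary[v] for v in order[:n]]
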