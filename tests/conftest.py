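import numpy as np
import pytest
import scipy.sparse as sp

from adhermine import Message, RunConfig, TokenizedDocument
from adhermine.lda import TopicModel


@pytest.fixture
def tiny_messages() -> list[Message]:
    return [
        Message(id="m1", date="2010-05-01", forum="doctissimo",
                text="Je prends du Seroplex 10 mg depuis un mois."),
        Message(id="m2", date="2011-02-14", forum="atoute",
                text="J'ai arrêté le traitement, trop d'effets secondaires !"),
        Message(id="m3", date="2012-08-30", forum="sante-medecine",
                text="Mon médecin a réduit la dose à 2,5mg ; le Seroplex me convient."),
    ]


@pytest.fixture
def tiny_config() -> RunConfig:
    return RunConfig(drug_names=["seroplex"], K_grid=[1, 2], seed=7)


@pytest.fixture
def toy_docs() -> list[TokenizedDocument]:
    return [
        TokenizedDocument("d1", ("a", "b", "a")),
        TokenizedDocument("d2", ("b", "c")),
    ]


def make_model(theta: np.ndarray, phi: np.ndarray,
               vocabulary: list[str] | None = None,
               doc_ids: list[str] | None = None) -> TopicModel:
    """Build a TopicModel with prescribed parameters (for assignment tests)."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    K, V = phi.shape
    return TopicModel(
        K=K, phi=phi, theta=theta, alpha_theta=1.1, alpha_phi=1.1,
        log_posterior_trace=[0.0], seed=0, n_restarts=1, converged=True,
        vocabulary=vocabulary or [f"t{j}" for j in range(V)],
        doc_ids=doc_ids or [f"d{i}" for i in range(theta.shape[0])],
        n_tokens=float(theta.shape[0]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_count_matrix(rng: np.random.Generator, d: int = 8, v: int = 12,
                        density: float = 0.5) -> sp.csr_matrix:
    x = rng.poisson(1.5, size=(d, v)) * (rng.random((d, v)) < density)
    # guarantee no all-zero rows
    for i in range(d):
        if x[i].sum() == 0:
            x[i, rng.integers(v)] = 1
    return sp.csr_matrix(x)
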