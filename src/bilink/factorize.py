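"""Low-rank scoring: truncated SVD, PLSA fitted by EM, and NNMF.

All three methods assign a K-dimensional vector ``r_u`` to each drug and
``s_v`` to each disease and score a candidate pair by the inner product
``r_u . s_v`` -- for SVD and NNMF this is the entry of a low-rank
approximation to the incidence matrix, for PLSA it is a model probability
for the pair.  Defaults K = 60 (SVD), 90 (PLSA), 80 (NNMF) follow where
each method performs best on the real drug-disease network; on small
synthetic networks much smaller K suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import svds

from .network import BipartiteNetwork
from .similarity import ScoreTable

__all__ = [
    "Embedding",
    "score_svd",
    "fit_plsa",
    "score_plsa",
    "fit_and_score_nnmf",
    "nnmf_factors",
]

_N_RESTARTS = 5  # EM / multiplicative updates are local optimisers


@dataclass(frozen=True)
class Embedding:
    """Per-node latent vectors with the model flavor that produced them.

    ``drug_vectors[u] . disease_vectors[v]`` is the pair score.  For the
    ``plsa`` flavor the vectors are non-negative and the implied pair
    distribution sums to one; for ``nnmf`` they are non-negative.
    """

    drug_vectors: np.ndarray
    disease_vectors: np.ndarray
    flavor: str
    log_likelihoods: tuple[float, ...] = ()  # PLSA: per-iteration trajectory
    objectives: tuple[float, ...] = ()  # NNMF: per-iteration Frobenius^2

    @property
    def K(self) -> int:
        return self.drug_vectors.shape[1]

    def __post_init__(self) -> None:
        if self.drug_vectors.shape[1] != self.disease_vectors.shape[1]:
            raise ValueError("drug and disease vectors have different dimension")
        if self.flavor in ("plsa", "nnmf"):
            if (self.drug_vectors < 0).any() or (self.disease_vectors < 0).any():
                raise ValueError(f"{self.flavor} vectors must be non-negative")

    def score_matrix(self) -> np.ndarray:
        return self.drug_vectors @ self.disease_vectors.T


# ---------------------------------------------------------------------------
# Truncated singular value decomposition
# ---------------------------------------------------------------------------

def score_svd(net: BipartiteNetwork, K: int = 60) -> ScoreTable:
    """Rank-K truncation of the incidence matrix as prediction scores.

    ``B' = U S' V^T`` with all but the K largest singular values zeroed;
    larger (more positive) entries of ``B'`` mean higher prediction
    certainty.  By the Eckart-Young theorem ``B'`` is the best rank-K
    approximation to ``B`` in Frobenius norm.
    """
    nd, nz = net.n_drugs, net.n_diseases
    if not 1 <= K <= min(nd, nz):
        raise ValueError(f"K must be in [1, {min(nd, nz)}], got {K}")
    B = net.incidence_matrix()
    if K < min(nd, nz) - 1 and min(nd, nz) > 300:
        U, s, Vt = svds(B, k=K)
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]
    else:
        U, s, Vt = np.linalg.svd(B, full_matrices=False)
        U, s, Vt = U[:, :K], s[:K], Vt[:K]
    approx = (U * s) @ Vt
    return ScoreTable.from_matrix(approx, net)


# ---------------------------------------------------------------------------
# Probabilistic latent semantic analysis
# ---------------------------------------------------------------------------

def _plsa_em(
    eu: np.ndarray,
    ev: np.ndarray,
    nd: int,
    nz: int,
    K: int,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """One EM run of the aspect model on the edge multiset.

    Model: P(u, v) = sum_k P(k) P(u|k) P(v|k).  E-step computes the
    posterior over components for each observed edge; M-step renormalises
    the expected counts.  The log-likelihood never decreases.
    """
    m = len(eu)
    pk = rng.random(K) + 0.5
    pk /= pk.sum()
    pu = rng.random((nd, K)) + 0.5
    pu /= pu.sum(axis=0)
    pv = rng.random((nz, K)) + 0.5
    pv /= pv.sum(axis=0)

    lls: list[float] = []
    for _ in range(max_iter):
        # E-step: responsibilities per edge
        q = pk[None, :] * pu[eu] * pv[ev]  # (m, K)
        row = q.sum(axis=1)
        lls.append(float(np.log(np.maximum(row, 1e-300)).sum()))
        q /= np.maximum(row, 1e-300)[:, None]
        # M-step: closed-form renormalisation of expected counts
        pk = q.sum(axis=0) / m
        pu = np.zeros((nd, K))
        np.add.at(pu, eu, q)
        pv = np.zeros((nz, K))
        np.add.at(pv, ev, q)
        colu = pu.sum(axis=0)
        colv = pv.sum(axis=0)
        pu /= np.maximum(colu, 1e-300)
        pv /= np.maximum(colv, 1e-300)
        if len(lls) >= 2 and lls[-1] - lls[-2] < tol:
            break
    q = pk[None, :] * pu[eu] * pv[ev]
    lls.append(float(np.log(np.maximum(q.sum(axis=1), 1e-300)).sum()))
    return pk, pu, pv, lls


def fit_plsa(
    net: BipartiteNetwork,
    K: int = 90,
    max_iter: int = 300,
    tol: float = 1e-8,
    seed: int = 0,
    n_restarts: int = _N_RESTARTS,
) -> Embedding:
    """Fit the PLSA aspect model by expectation-maximization.

    Each observed edge is one count of the pair ``(u, v)``; EM maximises
    the multinomial likelihood of the edge multiset.  Several random
    restarts are run from the seeded stream and the best log-likelihood
    kept, since EM only finds local optima.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if net.m < 1:
        raise ValueError("network has no edges to fit")
    edges = net.edge_array()
    eu, ev = edges[:, 0], edges[:, 1]
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_restarts, 1)):
        pk, pu, pv, lls = _plsa_em(
            eu, ev, net.n_drugs, net.n_diseases, K, max_iter, tol, rng
        )
        if best is None or lls[-1] > best[3][-1]:
            best = (pk, pu, pv, lls)
    pk, pu, pv, lls = best
    # absorb the component weights into the drug vectors: r_u[k] = P(k) P(u|k)
    return Embedding(pu * pk[None, :], pv, "plsa", log_likelihoods=tuple(lls))


def score_plsa(model: Embedding, net: BipartiteNetwork) -> ScoreTable:
    """Pair probabilities ``r_u . s_v`` of a fitted PLSA model as scores.

    Scores are non-negative and sum to one over all (u, v) pairs.
    """
    if model.flavor != "plsa":
        raise ValueError(f"expected a plsa embedding, got flavor {model.flavor!r}")
    return ScoreTable.from_matrix(model.score_matrix(), net)


# ---------------------------------------------------------------------------
# Non-negative matrix factorization
# ---------------------------------------------------------------------------

def _nnmf_mu(
    B: np.ndarray,
    K: int,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Multiplicative updates for ||B - WH||_F^2 (Lee-Seung rules).

    The objective is non-increasing under the updates; iteration stops at
    ``max_iter`` or when the relative objective change drops below ``tol``.
    """
    nd, nz = B.shape
    eps = 1e-12
    scale = np.sqrt(B.mean() / K) if B.mean() > 0 else 1.0
    W = rng.uniform(0.1, 1.0, size=(nd, K)) * scale
    H = rng.uniform(0.1, 1.0, size=(K, nz)) * scale
    objs = [float(((B - W @ H) ** 2).sum())]
    for _ in range(max_iter):
        H *= (W.T @ B) / np.maximum(W.T @ W @ H, eps)
        W *= (B @ H.T) / np.maximum(W @ (H @ H.T), eps)
        obj = float(((B - W @ H) ** 2).sum())
        prev = objs[-1]
        objs.append(obj)
        if prev > 0 and (prev - obj) / prev < tol:
            break
    return W, H, objs


def nnmf_factors(
    net: BipartiteNetwork,
    K: int = 80,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
    n_restarts: int = _N_RESTARTS,
) -> Embedding:
    """Non-negative factors ``B ~ W H`` minimising mean-squared error."""
    nd, nz = net.n_drugs, net.n_diseases
    if not 1 <= K <= min(nd, nz):
        raise ValueError(f"K must be in [1, {min(nd, nz)}], got {K}")
    B = net.incidence_matrix()
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_restarts, 1)):
        W, H, objs = _nnmf_mu(B, K, max_iter, tol, rng)
        if best is None or objs[-1] < best[2][-1]:
            best = (W, H, objs)
    W, H, objs = best
    return Embedding(W, H.T, "nnmf", objectives=tuple(objs))


def fit_and_score_nnmf(
    net: BipartiteNetwork,
    K: int = 80,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
    n_restarts: int = _N_RESTARTS,
) -> ScoreTable:
    """Fit NNMF and score each candidate pair by ``(W H)_{uv}``."""
    model = nnmf_factors(net, K, max_iter, tol, seed, n_restarts)
    return ScoreTable.from_matrix(model.score_matrix(), net)
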