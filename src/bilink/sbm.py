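"""Bayesian degree-corrected stochastic block model link prediction.

Drugs and diseases are each divided into groups and edges are modelled as
Poisson counts with rate ``theta_u * theta_v * omega[g_u, g_v]``: the
group-pair factor ``omega`` captures community structure (therapeutic
classes) while the per-node propensities ``theta`` absorb the broad degree
distribution, so that popular drugs are not forced into their own groups.
Within a fixed partition the rate parameters are profiled out at their
maximum-likelihood values, leaving a log-likelihood that depends only on
sufficient statistics -- group degree totals and edge counts between group
pairs.  Partitions are sampled by a single-node Metropolis chain, a
candidate pair is scored by the likelihood gain from adding that one edge,
and scores are averaged over the posterior samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import BipartiteNetwork
from .similarity import ScoreTable

logger = logging.getLogger("bilink")

__all__ = [
    "BlockState",
    "dcsbm_log_likelihood",
    "sample_partitions",
    "score_dcsbm",
]


def _xlogx(x: np.ndarray | float) -> np.ndarray | float:
    """x log x with the 0 log 0 = 0 convention."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BlockState:
    """A bipartite partition: one group set per side.

    Within-side group pairs are structurally empty (edges only ever connect
    a drug group to a disease group).
    """

    drug_groups: np.ndarray
    disease_groups: np.ndarray
    k_drug: int
    k_disease: int

    def __post_init__(self) -> None:
        if self.k_drug < 1 or self.k_disease < 1:
            raise ValueError("group counts must be at least 1")
        for g, k, name in (
            (self.drug_groups, self.k_drug, "drug"),
            (self.disease_groups, self.k_disease, "disease"),
        ):
            g = np.asarray(g)
            if g.size and (g.min() < 0 or g.max() >= k):
                raise ValueError(f"{name} group index out of range")

    def sufficient_stats(
        self, net: BipartiteNetwork
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(cell edge counts M[r, s], drug-group degree totals, disease-group
        degree totals) for this partition of ``net``."""
        if len(self.drug_groups) != net.n_drugs or len(
            self.disease_groups
        ) != net.n_diseases:
            raise ValueError("state size does not match the network")
        M = np.zeros((self.k_drug, self.k_disease))
        for u, v in net.edges:
            M[self.drug_groups[u], self.disease_groups[v]] += 1
        kappa_d = M.sum(axis=1)
        kappa_z = M.sum(axis=0)
        return M, kappa_d, kappa_z


def dcsbm_log_likelihood(net: BipartiteNetwork, state: BlockState) -> float:
    """Profile log-likelihood of the Poisson degree-corrected block model.

    With maximum-likelihood rates substituted in, the log-likelihood is

        sum_u d_u log d_u + sum_v d_v log d_v
        - sum_r kappa_r log kappa_r - sum_s kappa_s log kappa_s
        + sum_rs M_rs log M_rs - m

    (0 log 0 = 0), a function of the degrees and the partition's
    sufficient statistics alone.  Nodes of degree zero contribute nothing,
    and permuting group labels leaves the value unchanged.
    """
    M, kappa_d, kappa_z = state.sufficient_stats(net)
    deg_d = net.drug_degrees()
    deg_z = net.disease_degrees()
    return float(
        _xlogx(deg_d).sum()
        + _xlogx(deg_z).sum()
        - _xlogx(kappa_d).sum()
        - _xlogx(kappa_z).sum()
        + _xlogx(M).sum()
        - net.m
    )


def _move_delta(
    deg: int,
    e: np.ndarray,
    M_from: np.ndarray,
    M_to: np.ndarray,
    kappa_from: float,
    kappa_to: float,
) -> float:
    """Log-likelihood change from moving one node between groups.

    ``e`` is the node's edge count into each opposite-side group; ``M_from``
    / ``M_to`` the affected rows (or columns) of the cell-count matrix.
    """
    nz = e > 0
    return float(
        -_xlogx(kappa_from - deg)
        - _xlogx(kappa_to + deg)
        + _xlogx(kappa_from)
        + _xlogx(kappa_to)
        + (_xlogx(M_from[nz] - e[nz]) - _xlogx(M_from[nz])).sum()
        + (_xlogx(M_to[nz] + e[nz]) - _xlogx(M_to[nz])).sum()
    )


def sample_partitions(
    net: BipartiteNetwork,
    k_drug: int = 30,
    k_disease: int = 30,
    sweeps: int = 2000,
    burn_in: int = 500,
    thin: int = 10,
    seed: int = 0,
) -> list[BlockState]:
    """Sample partitions by single-node Metropolis moves.

    One sweep proposes one move per node: a uniformly chosen node is
    offered a uniformly chosen group on its own side and the move is
    accepted with probability ``min(1, exp(delta log-likelihood))`` (flat
    prior over partitions).  States are recorded every ``thin`` sweeps
    after ``burn_in``; the chain is reproducible given the seed.
    """
    if k_drug < 1 or k_disease < 1:
        raise ValueError("group counts must be at least 1")
    if not sweeps > burn_in >= 0:
        raise ValueError("need sweeps > burn_in >= 0")
    rng = np.random.default_rng(seed)
    nd, nz = net.n_drugs, net.n_diseases

    gd = rng.integers(k_drug, size=nd)
    gz = rng.integers(k_disease, size=nz)
    edges = net.edge_array()
    adj_d: list[list[int]] = [[] for _ in range(nd)]
    adj_z: list[list[int]] = [[] for _ in range(nz)]
    for u, v in edges:
        adj_d[u].append(v)
        adj_z[v].append(u)
    nbr_d = [np.array(a, dtype=np.int64) for a in adj_d]
    nbr_z = [np.array(a, dtype=np.int64) for a in adj_z]
    deg_d = np.array([len(a) for a in adj_d])
    deg_z = np.array([len(a) for a in adj_z])

    state = BlockState(gd.copy(), gz.copy(), k_drug, k_disease)
    M, kappa_d, kappa_z = state.sufficient_stats(net)

    samples: list[BlockState] = []
    n_nodes = nd + nz
    accepted = proposed = 0
    for sweep in range(sweeps):
        picks = rng.integers(n_nodes, size=n_nodes)
        props_d = rng.integers(k_drug, size=n_nodes)
        props_z = rng.integers(k_disease, size=n_nodes)
        accs = rng.random(n_nodes)
        for step in range(n_nodes):
            i = picks[step]
            if i < nd:
                u, r, rp = i, gd[i], props_d[step]
                if rp == r or deg_d[u] == 0:
                    if rp != r and deg_d[u] == 0:
                        gd[u] = rp  # isolated node: flat likelihood
                    continue
                proposed += 1
                e = np.bincount(gz[nbr_d[u]], minlength=k_disease).astype(float)
                delta = _move_delta(
                    deg_d[u], e, M[r], M[rp], kappa_d[r], kappa_d[rp]
                )
                if delta >= 0 or accs[step] < np.exp(delta):
                    accepted += 1
                    M[r] -= e
                    M[rp] += e
                    kappa_d[r] -= deg_d[u]
                    kappa_d[rp] += deg_d[u]
                    gd[u] = rp
            else:
                v = i - nd
                s, sp = gz[v], props_z[step]
                if sp == s or deg_z[v] == 0:
                    if sp != s and deg_z[v] == 0:
                        gz[v] = sp
                    continue
                proposed += 1
                e = np.bincount(gd[nbr_z[v]], minlength=k_drug).astype(float)
                delta = _move_delta(
                    deg_z[v], e, M[:, s], M[:, sp], kappa_z[s], kappa_z[sp]
                )
                if delta >= 0 or accs[step] < np.exp(delta):
                    accepted += 1
                    M[:, s] -= e
                    M[:, sp] += e
                    kappa_z[s] -= deg_z[v]
                    kappa_z[sp] += deg_z[v]
                    gz[v] = sp
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            samples.append(BlockState(gd.copy(), gz.copy(), k_drug, k_disease))
    if proposed:
        logger.info(
            "MCMC acceptance rate %.3f (%d/%d non-trivial proposals)",
            accepted / proposed,
            accepted,
            proposed,
        )
    return samples


def score_dcsbm(
    net: BipartiteNetwork,
    samples: list[BlockState],
    max_states: int = 150,
) -> ScoreTable:
    """Average likelihood-gain scores over posterior partition samples.

    For each sampled partition, a candidate pair ``(u, v)`` is scored by
    the change in the profile log-likelihood when that single edge is
    added; the final score is the mean over (at most ``max_states``)
    samples.  With ``f(x) = (x+1) log(x+1) - x log x`` the per-sample
    score decomposes into node, group and cell terms:

        f(d_u) + f(d_v) - f(kappa_{g_u}) - f(kappa_{g_v})
        + f(M[g_u, g_v]) - 1.
    """
    if not samples:
        raise ValueError("need at least one sampled partition")
    if len(samples) > max_states:
        idx = np.linspace(0, len(samples) - 1, max_states).round().astype(int)
        samples = [samples[i] for i in np.unique(idx)]
    deg_d = net.drug_degrees().astype(float)
    deg_z = net.disease_degrees().astype(float)

    def f(x):
        return _xlogx(np.asarray(x, dtype=float) + 1) - _xlogx(x)

    fd = f(deg_d)[:, None]
    fz = f(deg_z)[None, :]
    total = np.zeros((net.n_drugs, net.n_diseases))
    for st in samples:
        M, kappa_d, kappa_z = st.sufficient_stats(net)
        total += (
            fd
            + fz
            - f(kappa_d)[st.drug_groups][:, None]
            - f(kappa_z)[st.disease_groups][None, :]
            + f(M)[np.ix_(st.drug_groups, st.disease_groups)]
            - 1.0
        )
    return ScoreTable.from_matrix(total / len(samples), net)
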