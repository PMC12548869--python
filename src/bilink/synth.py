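"""Synthetic bipartite networks with planted block structure.

The generator draws from a degree-corrected planted-partition model: drugs
and diseases are assigned to groups, each pair ``(u, v)`` receives an edge
independently with probability ``min(1, theta_u * theta_v * omega[g_u, g_v])``
where ``omega`` is a group-mixing rate matrix and the ``theta`` are per-node
degree propensities with mean one inside each group.  This emulates the
features the real drug-disease network is believed to have -- sparse
(density ~2e-3), a few tens of therapeutic classes per side, heavy-tailed
degrees -- and provides a ground truth (group memberships and a set of
deliberately hidden edges) that predictors and bounds can be validated
against without any download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import BipartiteNetwork

logger = logging.getLogger("bilink")

__all__ = [
    "PlantedTruth",
    "generate_planted_network",
    "plant_missing_edges",
    "planted_mixing",
    "paper_like_preset",
]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth behind a generated network.

    Attributes
    ----------
    drug_groups, disease_groups
        Planted group index per node.
    mixing
        Per-pair edge rate ``omega[r, s]`` for a drug in group ``r`` and a
        disease in group ``s``.
    drug_propensities, disease_propensities
        Degree propensities ``theta``; mean one within each group
        (identifiability convention).
    """

    drug_groups: np.ndarray
    disease_groups: np.ndarray
    mixing: np.ndarray
    drug_propensities: np.ndarray
    disease_propensities: np.ndarray

    def __post_init__(self) -> None:
        kd, kz = self.mixing.shape
        if self.drug_groups.min(initial=0) < 0 or self.drug_groups.max(initial=0) >= kd:
            raise ValueError("drug group index out of range")
        if (
            self.disease_groups.min(initial=0) < 0
            or self.disease_groups.max(initial=0) >= kz
        ):
            raise ValueError("disease group index out of range")
        if (self.mixing < 0).any():
            raise ValueError("mixing entries must be non-negative")


def _balanced_groups(n: int, k: int) -> np.ndarray:
    """Contiguous near-equal blocks: node i -> group floor(i*k/n)."""
    return (np.arange(n) * k) // n


def _group_propensities(
    n: int, groups: np.ndarray, k: int, shape: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma(shape) draws renormalised to mean one within each group.

    ``shape = inf`` gives homogeneous propensities (theta = 1 exactly);
    small shapes give heavy-tailed degree heterogeneity.
    """
    if not np.isfinite(shape):
        return np.ones(n)
    if shape <= 0:
        raise ValueError("propensity_shape must be positive")
    theta = rng.gamma(shape, 1.0 / shape, size=n)
    theta = np.maximum(theta, 1e-12)
    for g in range(k):
        mask = groups == g
        if mask.any():
            theta[mask] /= theta[mask].mean()
    return theta


def planted_mixing(
    n_drugs: int,
    n_diseases: int,
    k_drug_groups: int,
    k_disease_groups: int,
    target_m: float,
    contrast: float = 10.0,
) -> np.ndarray:
    """Diagonal-dominant mixing matrix scaled to an expected edge count.

    Cells with ``r % k_disease_groups == s % k_drug_groups`` ("on-pattern"
    cells; the diagonal when the group counts are equal) get ``contrast``
    times the rate of the remaining cells, and the whole matrix is scaled
    so the expected number of edges (ignoring the probability cap) equals
    ``target_m``.
    """
    if contrast < 1:
        raise ValueError("contrast must be >= 1")
    gd = _balanced_groups(n_drugs, k_drug_groups)
    gz = _balanced_groups(n_diseases, k_disease_groups)
    size_d = np.bincount(gd, minlength=k_drug_groups).astype(float)
    size_z = np.bincount(gz, minlength=k_disease_groups).astype(float)
    r = np.arange(k_drug_groups)[:, None]
    s = np.arange(k_disease_groups)[None, :]
    omega = np.where((r % k_disease_groups) == (s % k_drug_groups), contrast, 1.0)
    expected = float(size_d @ omega @ size_z)
    return omega * (target_m / expected)


def generate_planted_network(
    n_drugs: int,
    n_diseases: int,
    k_drug_groups: int,
    k_disease_groups: int,
    mixing: np.ndarray,
    propensity_shape: float = 2.0,
    seed: int = 0,
) -> tuple[BipartiteNetwork, PlantedTruth]:
    """Sample a bipartite network from the degree-corrected planted model.

    Each pair gets an edge independently with probability
    ``min(1, theta_u * theta_v * omega[g_u, g_v])`` (Bernoulli, so the
    result is a simple graph like the observed data).  The same seed
    reproduces the identical network.  If the probability cap is hit for
    more than 1% of pairs a warning flags the degenerate regime.
    """
    mixing = np.asarray(mixing, dtype=float)
    if mixing.shape != (k_drug_groups, k_disease_groups):
        raise ValueError(
            f"mixing shape {mixing.shape} != ({k_drug_groups}, {k_disease_groups})"
        )
    if (mixing < 0).any():
        raise ValueError("mixing entries must be non-negative")
    rng = np.random.default_rng(seed)
    gd = _balanced_groups(n_drugs, k_drug_groups)
    gz = _balanced_groups(n_diseases, k_disease_groups)
    theta_d = _group_propensities(n_drugs, gd, k_drug_groups, propensity_shape, rng)
    theta_z = _group_propensities(n_diseases, gz, k_disease_groups, propensity_shape, rng)

    rate = np.outer(theta_d, theta_z) * mixing[np.ix_(gd, gz)]
    n_capped = int((rate > 1).sum())
    if n_capped > 0.01 * rate.size:
        logger.warning(
            "probability cap hit for %d of %d pairs (degenerate regime)",
            n_capped,
            rate.size,
        )
    prob = np.minimum(rate, 1.0)
    B = rng.random(prob.shape) < prob
    net = BipartiteNetwork.from_incidence(B)
    truth = PlantedTruth(gd, gz, mixing, theta_d, theta_z)
    return net, truth


def plant_missing_edges(
    net: BipartiteNetwork, mu: float, seed: int = 0
) -> tuple[BipartiteNetwork, frozenset[tuple[int, int]]]:
    """Hide a uniform random subset of edges to emulate data incompleteness.

    ``mu`` is the fraction of the *observed* network's unconnected pairs
    that are truly edges.  Hiding ``h`` of the ``m`` input edges leaves
    ``U0 + h`` unconnected pairs (``U0`` of the input network), so ``h``
    solves ``h = mu * (U0 + h)``, i.e. ``h = round(mu * U0 / (1 - mu))``.
    """
    if net.m == 0:
        raise ValueError("network has no edges")
    if not 0 <= mu < 1:
        raise ValueError("mu must be in [0, 1)")
    u0 = net.unconnected_pair_count()
    h = int(np.rint(mu * u0 / (1.0 - mu)))
    if h > net.m:
        raise ValueError(
            f"mu={mu} requires hiding {h} edges but the network has only {net.m}"
        )
    if h == 0:
        return net, frozenset()
    rng = np.random.default_rng(seed)
    edges = net.edge_array()
    pick = rng.choice(len(edges), size=h, replace=False)
    hidden = frozenset(map(tuple, edges[pick]))
    return net.remove_edges(hidden), hidden


def paper_like_preset(seed: int = 0, scale: float = 1.0):
    """A network resembling the published drug-disease data in the large:
    2620 x 1669 nodes, 30 planted groups per side, ~8946 edges, with
    ``scale`` shrinking all three counts proportionally for quick runs.
    """
    n_drugs = max(int(round(2620 * scale)), 30)
    n_diseases = max(int(round(1669 * scale)), 30)
    target_m = max(int(round(8946 * scale)), 60)
    k = 30 if min(n_drugs, n_diseases) >= 120 else max(min(n_drugs, n_diseases) // 4, 1)
    omega = planted_mixing(n_drugs, n_diseases, k, k, target_m, contrast=10.0)
    return generate_planted_network(
        n_drugs, n_diseases, k, k, omega, propensity_shape=2.0, seed=seed
    )
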