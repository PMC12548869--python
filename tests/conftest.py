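import numpy as np
import pytest

from bilink import BipartiteNetwork


@pytest.fixture
def toy_t1() -> BipartiteNetwork:
    """Three drugs, three diseases, six edges; degrees (2,3,1) / (2,2,2)."""
    return BipartiteNetwork.from_labeled_edges(
        [
            ("u1", "v1"),
            ("u1", "v2"),
            ("u2", "v1"),
            ("u2", "v2"),
            ("u2", "v3"),
            ("u3", "v3"),
        ]
    )


@pytest.fixture(scope="session")
def full_scale_net() -> BipartiteNetwork:
    """A network with the full data set's node and edge counts.

    2620 drug labels, 1669 disease labels and 8946 distinct edges sampled
    uniformly -- the counts of the real drug-disease network, used to check
    count arithmetic at scale without any download.
    """
    rng = np.random.default_rng(20251016)
    nd, nz, m = 2620, 1669, 8946
    flat = rng.choice(nd * nz, size=m, replace=False)
    edges = frozenset(zip((flat // nz).tolist(), (flat % nz).tolist()))
    return BipartiteNetwork(
        tuple(f"D{i:04d}" for i in range(nd)),
        tuple(f"Z{j:04d}" for j in range(nz)),
        edges,
    )


def random_bipartite(nd: int, nz: int, p: float, seed: int) -> BipartiteNetwork:
    rng = np.random.default_rng(seed)
    return BipartiteNetwork.from_incidence(rng.random((nd, nz)) < p)
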