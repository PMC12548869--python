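"""Bipartite network data model and edge-list I/O.

A drug-disease network is an unweighted bipartite graph: nodes are of two
types (drugs and diseases) and an edge means the drug is indicated for
treatment of the disease.  Every predictor in this package consumes the
:class:`BipartiteNetwork` container defined here, usually through its dense
incidence matrix ``B`` with ``B[u, v] = 1`` iff drug ``u`` treats disease
``v``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("bilink")

__all__ = [
    "BipartiteNetwork",
    "read_edge_list",
    "write_edge_list",
    "network_summary",
]


class BipartitenessError(ValueError):
    """A label was used both as a drug and as a disease."""


class EdgeListParseError(ValueError):
    """A line of an edge-list file could not be parsed."""


@dataclass(frozen=True)
class BipartiteNetwork:
    """An unweighted bipartite network of drugs and diseases.

    Node identity is by string label; internally nodes carry dense integer
    indices in first-appearance order so that matrix layouts are
    deterministic for a given input.  Isolated nodes are representable:
    labels may exist with no incident edge (holdout removal can isolate a
    node, and predictors must not assume minimum degree one).

    Parameters
    ----------
    drug_labels, disease_labels
        Ordered unique identifiers for the two node types.
    edges
        Set of ``(drug_index, disease_index)`` pairs.
    """

    drug_labels: tuple[str, ...]
    disease_labels: tuple[str, ...]
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.drug_labels)) != len(self.drug_labels):
            raise ValueError("duplicate drug labels")
        if len(set(self.disease_labels)) != len(self.disease_labels):
            raise ValueError("duplicate disease labels")
        overlap = set(self.drug_labels) & set(self.disease_labels)
        if overlap:
            raise BipartitenessError(
                f"labels appear on both sides: {sorted(overlap)[:5]}"
            )
        nd, nz = len(self.drug_labels), len(self.disease_labels)
        for u, v in self.edges:
            if not (0 <= u < nd and 0 <= v < nz):
                raise ValueError(f"edge ({u}, {v}) references an invalid node index")

    # -- basic counts ----------------------------------------------------
    @property
    def n_drugs(self) -> int:
        return len(self.drug_labels)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_labels)

    @property
    def m(self) -> int:
        """Number of edges."""
        return len(self.edges)

    @property
    def density(self) -> float:
        pairs = self.n_drugs * self.n_diseases
        return self.m / pairs if pairs else 0.0

    def unconnected_pair_count(self) -> int:
        """Number of drug-disease pairs not connected by an observed edge.

        For the full drug-disease network of 2620 drugs, 1669 diseases and
        8946 indications this is about 4.36 million pairs -- the candidate
        pool for repurposing predictions.
        """
        return self.n_drugs * self.n_diseases - self.m

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_labeled_edges(
        cls,
        pairs: Iterable[tuple[str, str]],
        drug_labels: Sequence[str] = (),
        disease_labels: Sequence[str] = (),
    ) -> "BipartiteNetwork":
        """Build a network from (drug label, disease label) pairs.

        Labels get dense indices in first-appearance order; ``drug_labels``
        / ``disease_labels`` may pre-declare nodes (including isolated
        ones) ahead of the edges.  Duplicate pairs collapse to one edge.
        """
        drugs: dict[str, int] = {d: i for i, d in enumerate(drug_labels)}
        diseases: dict[str, int] = {z: i for i, z in enumerate(disease_labels)}
        edges: set[tuple[int, int]] = set()
        n_dup = 0
        for d, z in pairs:
            if d in diseases:
                raise BipartitenessError(f"label {d!r} already used as a disease")
            if z in drugs:
                raise BipartitenessError(f"label {z!r} already used as a drug")
            u = drugs.setdefault(d, len(drugs))
            v = diseases.setdefault(z, len(diseases))
            if (u, v) in edges:
                n_dup += 1
            else:
                edges.add((u, v))
        if n_dup:
            logger.warning("collapsed %d duplicate edge(s)", n_dup)
        return cls(tuple(drugs), tuple(diseases), frozenset(edges))

    @classmethod
    def from_incidence(cls, B: np.ndarray) -> "BipartiteNetwork":
        """Build a network from a binary incidence matrix (synthetic use)."""
        B = np.asarray(B)
        nd, nz = B.shape
        us, vs = np.nonzero(B)
        return cls(
            tuple(f"d{i}" for i in range(nd)),
            tuple(f"z{j}" for j in range(nz)),
            frozenset(zip(us.tolist(), vs.tolist())),
        )

    # -- matrix views ----------------------------------------------------
    def incidence_matrix(self, dtype=np.float64) -> np.ndarray:
        """Dense incidence matrix ``B`` (n_drugs x n_diseases, 0/1 entries).

        Row sums are drug degrees, column sums disease degrees, and the
        grand total equals ``m``.
        """
        B = np.zeros((self.n_drugs, self.n_diseases), dtype=dtype)
        if self.edges:
            idx = np.array(sorted(self.edges))
            B[idx[:, 0], idx[:, 1]] = 1
        return B

    def edge_array(self) -> np.ndarray:
        """Edges as a sorted ``(m, 2)`` integer array (deterministic order)."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(self.edges), dtype=np.int64)

    def drug_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_drugs, dtype=np.int64)
        for u, _ in self.edges:
            deg[u] += 1
        return deg

    def disease_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_diseases, dtype=np.int64)
        for _, v in self.edges:
            deg[v] += 1
        return deg

    def remove_edges(self, removed: Iterable[tuple[int, int]]) -> "BipartiteNetwork":
        """Copy of the network with the given edges removed (labels kept)."""
        removed = set(removed)
        missing = removed - set(self.edges)
        if missing:
            raise ValueError(f"cannot remove non-existent edges: {sorted(missing)[:5]}")
        return BipartiteNetwork(
            self.drug_labels, self.disease_labels, frozenset(self.edges - removed)
        )

    def add_edges(self, added: Iterable[tuple[int, int]]) -> "BipartiteNetwork":
        return BipartiteNetwork(
            self.drug_labels, self.disease_labels, frozenset(self.edges) | set(added)
        )


def read_edge_list(path: str | Path, delimiter: str = "\t") -> BipartiteNetwork:
    """Read a network from a two-column edge list.

    Format: one ``drug_id<delimiter>disease_id`` pair per line, UTF-8,
    ``#``-prefixed comment lines ignored.  A comment line of the form
    ``#drugs: a,b,c`` or ``#diseases: x,y`` pre-declares labels so that
    isolated nodes survive a round-trip.  Duplicate data lines collapse to
    a single edge with a logged warning.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    pre_drugs: list[str] = []
    pre_diseases: list[str] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("drugs:"):
                    pre_drugs += [s for s in body[6:].strip().split(",") if s]
                elif body.startswith("diseases:"):
                    pre_diseases += [s for s in body[9:].strip().split(",") if s]
                continue
            fields = line.split(delimiter)
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected two {delimiter!r}-delimited fields, "
                    f"got {line!r}"
                )
            pairs.append((fields[0], fields[1]))
    return BipartiteNetwork.from_labeled_edges(pairs, pre_drugs, pre_diseases)


def write_edge_list(
    net: BipartiteNetwork, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a network as an edge list; inverse of :func:`read_edge_list`.

    Isolated nodes are recorded in ``#drugs:`` / ``#diseases:`` header
    comments so the round-trip preserves them.
    """
    path = Path(path)
    deg_d = net.drug_degrees()
    deg_z = net.disease_degrees()
    iso_d = [net.drug_labels[i] for i in np.nonzero(deg_d == 0)[0]]
    iso_z = [net.disease_labels[j] for j in np.nonzero(deg_z == 0)[0]]
    with path.open("w", encoding="utf-8") as fh:
        if iso_d:
            fh.write("#drugs: " + ",".join(iso_d) + "\n")
        if iso_z:
            fh.write("#diseases: " + ",".join(iso_z) + "\n")
        for u, v in net.edge_array():
            fh.write(f"{net.drug_labels[u]}{delimiter}{net.disease_labels[v]}\n")


def network_summary(net: BipartiteNetwork) -> str:
    """JSON one-liner with the headline counts, for logging."""
    return json.dumps(
        {
            "n_drugs": net.n_drugs,
            "n_diseases": net.n_diseases,
            "m": net.m,
            "density": net.density,
        }
    )
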