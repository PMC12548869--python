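"""Edge-holdout cross-validation, ranking metrics, and missing-edge bounds.

The benchmark removes a random fraction of edges (default 10%) from the
network, hands the remaining training network to each predictor, and
measures how well the removed edges (positives) are ranked above the pairs
that were never connected (negatives).  Four metrics are reported per
repetition and aggregated over repetitions with standard errors: AUROC,
AUPR (as a percentage), AUPR normalised by prevalence, and top-k
precision.  All predictors see the same sequence of splits so comparisons
are paired.

The same AUROC drives the bound calculus: if a fraction ``mu`` of the
observed non-edges are truly edges, and an algorithm is equally good at
finding them as it is at finding deliberately removed edges, the measured
AUROC cannot exceed ``1 - mu/2``.  Inverting, ``mu <= 2 (1 - A)`` -- an
upper limit on the interactions waiting to be discovered -- and the same
quantity bounds the fraction ``nu`` of recorded edges that are wrong.
Measured precision is diluted by the factor ``1 - mu``, so the true
precision lies between the measured value and measured ``/ (1 - mu)``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .network import BipartiteNetwork
from .similarity import ScoreTable

__all__ = [
    "HoldoutSplit",
    "EvaluationReport",
    "BoundEstimates",
    "make_holdout",
    "never_connected_pairs",
    "roc_auc",
    "pr_metrics",
    "run_benchmark",
    "missing_edge_bound",
    "precision_correction",
    "extrapolate_auroc",
    "uniform_random_scores",
    "Predictor",
]

#: A predictor adapter: any callable mapping (training network, seed) to a
#: ScoreTable covering the training network's unconnected pairs.  External
#: methods plug into the benchmark through this signature.
Predictor = Callable[[BipartiteNetwork, int], ScoreTable]


@dataclass(frozen=True)
class HoldoutSplit:
    """One cross-validation split.

    Positives are the removed edges; negatives the pairs never connected
    in the *original* network, so removed edges compete only with true
    non-edges.  Training edges are excluded from ranking.  Pair sets are
    stored as sorted ``(n, 2)`` index arrays; the negatives array is
    typically shared between the splits of one benchmark run.
    """

    training: BipartiteNetwork
    _positives: np.ndarray
    _negatives: np.ndarray

    @property
    def positives(self) -> frozenset[tuple[int, int]]:
        return frozenset(map(tuple, self._positives.tolist()))

    @property
    def negatives(self) -> frozenset[tuple[int, int]]:
        return frozenset(map(tuple, self._negatives.tolist()))

    @property
    def prevalence(self) -> float:
        return len(self._positives) / (len(self._positives) + len(self._negatives))

    def positive_array(self) -> np.ndarray:
        return self._positives

    def negative_array(self) -> np.ndarray:
        return self._negatives


def never_connected_pairs(net: BipartiteNetwork) -> np.ndarray:
    """All unconnected pairs of ``net`` as a sorted ``(n, 2)`` array."""
    mask = net.incidence_matrix(dtype=bool) == 0
    us, vs = np.nonzero(mask)
    return np.column_stack([us, vs]).astype(np.int64)


def make_holdout(
    net: BipartiteNetwork,
    fraction: float = 0.10,
    seed: int = 0,
    negatives: np.ndarray | None = None,
) -> HoldoutSplit:
    """Remove ``round(fraction * m)`` edges uniformly at random.

    ``negatives`` may be passed in (precomputed once per network) when
    building many splits of the same network.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_remove = int(np.rint(fraction * net.m))
    if n_remove < 1:
        raise ValueError(
            f"fraction {fraction} of {net.m} edges rounds to zero removals"
        )
    rng = np.random.default_rng(seed)
    edges = net.edge_array()
    pick = np.sort(rng.choice(len(edges), size=n_remove, replace=False))
    positives = edges[pick]
    training = net.remove_edges(map(tuple, positives.tolist()))
    if negatives is None:
        negatives = never_connected_pairs(net)
    return HoldoutSplit(training, positives, negatives)


def _test_arrays(
    scores: ScoreTable, split: HoldoutSplit
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scores for positives and negatives plus flat pair indices (tie-break)."""
    pos = split.positive_array()
    neg = split.negative_array()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one positive and one negative pair")
    s = np.concatenate([scores.scores_at(pos), scores.scores_at(neg)])
    nz = split.training.n_diseases
    flat = np.concatenate([pos[:, 0] * nz + pos[:, 1], neg[:, 0] * nz + neg[:, 1]])
    is_pos = np.zeros(len(s), dtype=bool)
    is_pos[: len(pos)] = True
    return s, is_pos, flat


def roc_auc(scores: ScoreTable, split: HoldoutSplit) -> float:
    """Area under the ROC curve by the Mann-Whitney rank statistic.

    Equals the probability that a uniformly random positive outscores a
    uniformly random negative, ties counted one half.
    """
    s, is_pos, _ = _test_arrays(scores, split)
    ranks = rankdata(s)  # average ranks handle ties at 1/2
    p = int(is_pos.sum())
    n = len(s) - p
    return float((ranks[is_pos].sum() - p * (p + 1) / 2) / (p * n))


def pr_metrics(
    scores: ScoreTable, split: HoldoutSplit, k: int = 100
) -> tuple[float, float, float]:
    """(AUPR %, normalised AUPR, top-k precision %).

    AUPR is average precision: the mean of the precision at each recalled
    positive, scanning candidates in descending score order (ties broken
    by pair index).  Normalised AUPR divides by the prevalence -- the
    precision of a no-skill classifier, which guesses correctly with
    probability equal to the positive density -- so 1 means no better than
    chance.  Top-k precision is the fraction of the k best-ranked
    candidates that are true positives.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    s, is_pos, flat = _test_arrays(scores, split)
    if k > len(s):
        raise ValueError(f"k={k} exceeds the {len(s)} ranked candidates")
    order = np.lexsort((flat, -s))
    hits = is_pos[order]
    cum = np.cumsum(hits)
    precision_at = cum / np.arange(1, len(hits) + 1)
    ap = float(precision_at[hits].mean())
    prevalence = split.prevalence
    return 100.0 * ap, ap / prevalence, 100.0 * float(cum[k - 1] / k)


@dataclass
class EvaluationReport:
    """Per-repetition metrics and their aggregation for one predictor."""

    predictor: str
    per_rep: pd.DataFrame  # columns: rep, auroc, aupr_pct, npr, topk_pct, seconds
    holdout_fraction: float
    k: int
    n_reps: int
    failures: list[tuple[int, str]] = field(default_factory=list)

    _METRICS = ("auroc", "aupr_pct", "npr", "topk_pct")

    def mean(self, metric: str) -> float:
        return float(self.per_rep[metric].mean())

    def se(self, metric: str) -> float:
        """Standard error of the mean: sample SD / sqrt(n_reps)."""
        n = len(self.per_rep)
        if n < 2:
            return float("nan")
        return float(self.per_rep[metric].std(ddof=1) / np.sqrt(n))

    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {"n_reps": len(self.per_rep)}
        for met in self._METRICS:
            out[met] = self.mean(met)
            out[met + "_se"] = self.se(met)
        out["seconds"] = float(self.per_rep["seconds"].mean())
        return out


def _derive_seed(master: int, *counters: int) -> int:
    """Deterministic sub-seed from a master seed and a fixed counter path."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(counters))
    return int(ss.generate_state(1)[0] % (2**31))


def run_benchmark(
    net: BipartiteNetwork,
    predictors: Mapping[str, Predictor],
    fraction: float = 0.10,
    n_reps: int = 50,
    k: int = 100,
    seed: int = 0,
) -> dict[str, EvaluationReport]:
    """Paired cross-validation of several predictors on one network.

    Every predictor is evaluated on the same sequence of splits (seeds are
    derived from the master seed by a fixed counter scheme), so metric
    differences between predictors are paired.  A predictor failure on a
    split is recorded and excluded from that predictor's means.
    """
    if not predictors:
        raise ValueError("need at least one predictor")
    reports: dict[str, EvaluationReport] = {}
    negatives = never_connected_pairs(net)
    splits = [
        make_holdout(net, fraction, _derive_seed(seed, 0, rep), negatives=negatives)
        for rep in range(n_reps)
    ]
    for name, predictor in predictors.items():
        rows = []
        failures: list[tuple[int, str]] = []
        for rep, split in enumerate(splits):
            pred_seed = _derive_seed(seed, 1, rep)
            t0 = time.perf_counter()
            try:
                table = predictor(split.training, pred_seed)
                a = roc_auc(table, split)
                aupr, npr, topk = pr_metrics(table, split, k)
            except Exception as exc:  # noqa: BLE001 - surfaced in the report
                failures.append((rep, f"{type(exc).__name__}: {exc}"))
                continue
            rows.append(
                {
                    "rep": rep,
                    "auroc": a,
                    "aupr_pct": aupr,
                    "npr": npr,
                    "topk_pct": topk,
                    "seconds": time.perf_counter() - t0,
                }
            )
        reports[name] = EvaluationReport(
            predictor=name,
            per_rep=pd.DataFrame(
                rows, columns=["rep", "auroc", "aupr_pct", "npr", "topk_pct", "seconds"]
            ),
            holdout_fraction=fraction,
            k=k,
            n_reps=n_reps,
            failures=failures,
        )
    return reports


# ---------------------------------------------------------------------------
# Bounds on missing edges, false positives, and precision
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundEstimates:
    """Upper bounds implied by a measured (or extrapolated) AUROC ``A``.

    ``mu_max = nu_max = 2 (1 - A)`` bound the fraction of missing edges
    among unconnected pairs and of false positives among recorded edges;
    the pair counts convert these fractions to absolute numbers, and the
    precision interval brackets the true precision of a measured value.
    """

    auroc: float
    mu_max: float
    nu_max: float
    max_missing_pairs: int
    max_false_positives: int
    precision_interval: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        out = {
            "auroc": self.auroc,
            "mu_max": self.mu_max,
            "nu_max": self.nu_max,
            "max_missing_pairs": self.max_missing_pairs,
            "max_false_positives": self.max_false_positives,
        }
        if self.precision_interval is not None:
            out["precision_interval"] = list(self.precision_interval)
        return out


def missing_edge_bound(
    A: float,
    unconnected_pairs: int,
    m: int,
    measured_precision: float | None = None,
) -> BoundEstimates:
    """Bound the number of missing edges and false positives from an AUROC.

    ``mu_max = 2 (1 - A)`` (clamped to [0, 1]); the maximum number of
    undiscovered interactions is ``round(mu_max * unconnected_pairs)`` and
    the maximum number of erroneous recorded edges ``round(mu_max * m)``.
    Optionally brackets a measured precision (in %) by the dilution factor.
    """
    if not 0.5 <= A <= 1.0:
        raise ValueError(f"AUROC must be in [0.5, 1], got {A}")
    mu = min(max(2.0 * (1.0 - A), 0.0), 1.0)
    interval = None
    if measured_precision is not None:
        interval = precision_correction(measured_precision, mu)
    return BoundEstimates(
        auroc=A,
        mu_max=mu,
        nu_max=mu,
        max_missing_pairs=int(np.rint(mu * unconnected_pairs)),
        max_false_positives=int(np.rint(mu * m)),
        precision_interval=interval,
    )


def precision_correction(measured: float, mu_max: float) -> tuple[float, float]:
    """Interval for the true precision given the missing-edge bound.

    Missing edges dilute measured precision by ``1 - mu``: the truth lies
    between the measured value and ``measured / (1 - mu_max)``.
    """
    if not 0 <= mu_max < 1:
        raise ValueError("mu_max must be in [0, 1)")
    return measured, measured / (1.0 - mu_max)


def extrapolate_auroc(
    fractions: Sequence[float],
    auroc_means: Sequence[float],
    auroc_ses: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Extrapolate AUROC to zero holdout fraction by a weighted line fit.

    Performance improves as less of the network is held out; a straight
    line in the holdout fraction, weighted by ``1/se^2`` when standard
    errors are given, estimates the AUROC that a predictor would attain on
    the full network.  Returns the intercept and its standard error.
    """
    x = np.asarray(fractions, dtype=float)
    y = np.asarray(auroc_means, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need at least two (fraction, auroc) points")
    if np.ptp(x) == 0:
        raise ValueError("all holdout fractions are equal; cannot extrapolate")
    if auroc_ses is not None:
        se = np.asarray(auroc_ses, dtype=float)
        if (se <= 0).any():
            raise ValueError("standard errors must be positive")
        w = 1.0 / se**2
    else:
        w = np.ones_like(x)
    X = np.column_stack([np.ones_like(x), x])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ y)
    if auroc_ses is None:
        # no measurement errors given: scale by residual mean square
        resid = y - X @ beta
        dof = len(x) - 2
        scale = float(resid @ resid / dof) if dof > 0 else 0.0
        cov = cov * scale
    return float(beta[0]), float(np.sqrt(cov[0, 0]))


def uniform_random_scores(net: BipartiteNetwork, seed: int = 0) -> ScoreTable:
    """No-skill reference predictor: independent uniform scores per pair."""
    rng = np.random.default_rng(seed)
    return ScoreTable.from_matrix(
        rng.random((net.n_drugs, net.n_diseases)), net
    )
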