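"""bilink: link prediction on bipartite drug-disease networks.

Score unconnected drug-disease pairs as repurposing candidates with
similarity, matrix-factorization or block-model predictors, benchmark them
by edge-holdout cross-validation, and bound the number of missing edges
and false positives implied by the measured AUROC.
"""

from .network import (
    BipartiteNetwork,
    network_summary,
    read_edge_list,
    write_edge_list,
)
from .synth import (
    PlantedTruth,
    generate_planted_network,
    paper_like_preset,
    plant_missing_edges,
    planted_mixing,
)
from .similarity import (
    MEASURES,
    ScoreTable,
    katz_alpha_max,
    same_type_similarity,
    score_degree_product,
    score_katz,
    score_similarity_sum,
)
from .factorize import (
    Embedding,
    fit_and_score_nnmf,
    fit_plsa,
    nnmf_factors,
    score_plsa,
    score_svd,
)
from .sbm import BlockState, dcsbm_log_likelihood, sample_partitions, score_dcsbm
from .evaluate import (
    BoundEstimates,
    EvaluationReport,
    HoldoutSplit,
    Predictor,
    extrapolate_auroc,
    make_holdout,
    missing_edge_bound,
    never_connected_pairs,
    pr_metrics,
    precision_correction,
    roc_auc,
    run_benchmark,
    uniform_random_scores,
)

__version__ = "0.1.0"


def get_predictor(name: str, **params) -> Predictor:
    """Build a named predictor adapter ``(network, seed) -> ScoreTable``.

    Known names: ``degree``, ``cn``, ``cosine``, ``jaccard``, ``dice``,
    ``hub``, ``katz``, ``svd``, ``plsa``, ``nnmf``, ``dcsbm``, ``random``.
    ``params`` forward to the underlying method (``K`` for the
    factorizations, ``alpha`` for Katz, ``k_drug``/``k_disease``/``sweeps``
    etc. for the block model).  Any other callable with the
    :data:`~bilink.evaluate.Predictor` signature plugs into the benchmark
    the same way.
    """
    measure_alias = {
        "cn": "common_neighbors",
        "cosine": "cosine",
        "jaccard": "jaccard",
        "dice": "dice",
        "hub": "hub_suppressed",
    }
    if name == "degree":
        return lambda net, seed: score_degree_product(net)
    if name in measure_alias:
        measure = measure_alias[name]
        direction = params.get("direction", "disease_side")
        return lambda net, seed: score_similarity_sum(net, measure, direction)
    if name == "katz":
        alpha = params.get("alpha")
        return lambda net, seed: score_katz(net, alpha)
    if name == "svd":
        K = params.get("K", 60)
        return lambda net, seed: score_svd(net, K)
    if name == "plsa":
        kw = {k: params[k] for k in ("K", "max_iter", "tol", "n_restarts") if k in params}
        return lambda net, seed: score_plsa(fit_plsa(net, seed=seed, **kw), net)
    if name == "nnmf":
        kw = {k: params[k] for k in ("K", "max_iter", "tol", "n_restarts") if k in params}
        return lambda net, seed: fit_and_score_nnmf(net, seed=seed, **kw)
    if name == "dcsbm":
        kw = {
            k: params[k]
            for k in ("k_drug", "k_disease", "sweeps", "burn_in", "thin")
            if k in params
        }

        def _dcsbm(net, seed):
            samples = sample_partitions(net, seed=seed, **kw)
            return score_dcsbm(net, samples)

        return _dcsbm
    if name == "random":
        return uniform_random_scores
    raise ValueError(f"unknown predictor {name!r}")


PREDICTOR_NAMES = (
    "degree",
    "cn",
    "cosine",
    "jaccard",
    "dice",
    "hub",
    "katz",
    "svd",
    "plsa",
    "nnmf",
    "dcsbm",
    "random",
)
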