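# Methods

This note documents the models, the synthetic data, and the numerical
choices behind `bilink`, in the order the pipeline runs.

## Data model

A network is a pair of ordered label lists (drugs, diseases) plus a set of
index edges. Node identity is the string label; indices are dense
integers in first-appearance order, so every matrix derived from a given
file has a deterministic layout. Isolated nodes are representable
(edge-list headers `#drugs:` / `#diseases:` declare them) because holdout
removal can isolate a node; no predictor assumes minimum degree one. The
TSV edge list is the only on-disk graph format.

## Synthetic networks

`generate_planted_network` draws from a degree-corrected planted-partition
model: each side is split into contiguous near-equal groups, each node
gets a propensity θ drawn from a Gamma(shape, 1/shape) distribution and
renormalized to mean 1 within its group, and each pair (u, v) receives an
edge independently with probability `min(1, θ_u θ_v ω[g_u, g_v])`.
Bernoulli rather than Poisson sampling keeps the graph simple, matching
the observed data model; cap events beyond 1% of pairs are logged as a
degenerate regime. `planted_mixing` builds ω with on-pattern cells
`contrast` times off-pattern cells, scaled so the uncapped expected edge
count hits a target.

Defaults emulate the gross features of a curated drug–indication network:
the `paper_like_preset` uses 2620×1669 nodes, 30 groups per side, ~8946
expected edges (density ≈ 2×10⁻³), Gamma shape 2 for moderately
heavy-tailed degrees, and contrast 10. The generator does **not**
reproduce a real network's exact degree sequence, nestedness, or
overlapping therapeutic categories, so passing tests demonstrate
correctness of the algorithms and protocol, not clinical performance.
`plant_missing_edges` hides a uniform subset of edges sized so the hidden
edges are a fraction μ of the *observed* network's unconnected pairs
(`h = round(μ·U₀/(1−μ))`, error if `h > m`), giving a ground truth for
the bound experiments. One master seed drives every operation;
sub-streams are derived deterministically (`SeedSequence` spawn keys), so
identical seeds give byte-identical networks, splits, and chains.

## Predictors

**Similarity sums.** All five same-type similarity measures are functions
of the shared-neighbor count `n_uv` and the degrees; 0/0 (a degree-zero
node) is defined as 0, and self-similarity is excluded from the sum. The
disease-side sum (similarity of the target disease to the diseases the
drug already treats) is the default direction; the drug-side mirror is
kept behind a flag because it performs clearly worse in practice. Path
counting uses the dense incidence-matrix product; no sampling.

**Katz.** The same-type Katz similarity is the geometric series
`Σ_{ℓ≥1} α^ℓ C^ℓ` with `C = BᵀB`, evaluated in closed form by solving
`(I − αC) S = αC`. The series converges iff `α < 1/σ_max(B)²`; the
default `α = 0.5/σ_max(B)²` sits safely inside, a convergence heuristic
rather than a tuned value. Non-convergent α raises an error that reports
the threshold.

**SVD.** Rank-K truncation of B; dense LAPACK SVD for small problems,
ARPACK partial SVD (`scipy.sparse.linalg.svds`) when the smaller
dimension exceeds 300 and K is well below it. Agreement across backends
is tolerance-level (~1e-8 on scores), not bit-exact. Default K = 60.

**PLSA.** The classic aspect model fitted by untempered EM on the edge
multiset (each observed edge one count): E-step responsibilities
`q_k(u,v) ∝ P(k)P(u|k)P(v|k)`, M-step closed-form renormalization. The
component weights are absorbed into the drug vectors, so
`r_u · s_v = P(u,v)` and scores sum to one over all pairs. Default K =
90, tol 1e-8 on the log-likelihood gain, 5 restarts from strictly
positive seeded uniform initializations (EM finds local optima; the best
final likelihood is kept). No smoothing or tempering is applied.

**NNMF.** Lee–Seung multiplicative updates for ‖B − WH‖²_F, the simplest
scheme whose objective is provably non-increasing; ε = 1e-12 guards the
denominators. Defaults K = 80, tol 1e-5 on relative objective change,
max 500 iterations, 5 restarts.

**Degree-corrected SBM.** Poisson likelihood with maximum-likelihood rate
parameters profiled out inside each partition, leaving
`ℓ = Σ_u d_u log d_u + Σ_v d_v log d_v − Σ_r κ_r log κ_r − Σ_s κ_s log κ_s
+ Σ_rs M_rs log M_rs − m` (0·log 0 = 0), a function of sufficient
statistics only. Profiling keeps the single-edge score closed-form; full
conjugate-prior marginalization would be the Bayesian-purist alternative
and is noted, not implemented. Group counts are fixed per run (default
30 + 30; no model selection over K), the two sides have separate group
sets, and within-side cells are structurally empty. Sampling is
single-node Metropolis under a flat partition prior: one sweep proposes
one move per node, with isolated nodes reassigned freely (their
likelihood contribution is flat). Default schedule 2000 sweeps, 500
burn-in, thinning 10; scoring uses at most 150 retained states. The edge
score averages, over sampled states, the likelihood change
`f(d_u) + f(d_v) − f(κ_{g_u}) − f(κ_{g_v}) + f(M_{g_u g_v}) − 1` with
`f(x) = (x+1)log(x+1) − x log x`. In the one-group limit this is an
increasing function of each degree and so tracks — but is not identical
to — the degree-product ranking: `f(a)+f(b)` is not monotone in the
product `ab` (degrees (1,8) and (3,3) reorder), which is why the
equivalence is tested as a rank correlation rather than exact equality.

## Evaluation protocol

A holdout removes `round(fraction·m)` edges uniformly (default 10%);
negatives are all never-connected pairs of the *original* network, so
removed edges compete only with true non-edges, and training edges are
excluded from every ranking. AUROC is computed by the Mann–Whitney rank
statistic (ties ½), which equals trapezoidal ROC integration. AUPR is
average precision — the mean of precision at each recalled positive —
rather than trapezoidal PR interpolation, the standard convention when
positives are sparse; it is quoted in percent, and the normalized variant
divides by prevalence (the precision of a no-skill classifier).
Ranking ties are broken by the flat pair index, deterministically: a
random tie-break would change top-k precision run to run. All predictors
see the same sequence of splits (per-repetition seeds from a fixed
counter scheme), so comparisons are paired; standard errors are sample
SD / √n_reps. Predictor failures on a split are recorded, excluded from
means, and surfaced in the report.

A caveat the test suite accounts for: average precision of a *random*
ranking is upward-biased when few positives are recalled (the first
recalled positive has precision 1/rank, a heavy-tailed term). The bias is
roughly 0.4 of the per-repetition SD at ~300 held-out positives and well
under Monte-Carlo noise by ~3000, so the no-skill calibration check
("normalized AUPR ≈ 1") is run on holdouts with thousands of positives.
AUROC has no such bias.

`extrapolate_auroc` fits a straight line in the holdout fraction,
weighted by 1/SE² when standard errors are supplied; the intercept
estimates the AUROC attainable with no edges removed. The linear form is
a modeling choice — performance varies slowly and smoothly over small
holdout fractions — not a derived law. With measurement errors given,
the intercept SE comes from error propagation; without them, from the
residual mean square (zero for two points).

`missing_edge_bound` clamps `2(1−A)` to [0, 1] and converts to counts by
nearest-integer rounding, the same rounding used for removal counts. The
bound's derivation assumes the predictor treats deliberately removed and
genuinely missing edges exchangeably; the bound-validity experiment in
the test suite constructs exactly that situation (hidden edges drawn
uniformly from the same pool) and checks `A ≤ 1 − μ/2 + 3·SE` for every
predictor family.

## Problem sizes in the test suite

Tests run on synthetic networks of roughly 150–500 nodes per side with
900–30 000 edges, MCMC chains of 40–300 sweeps, and 10–50 cross-validation
repetitions — sizes chosen so the full suite exercises every claim,
including the 20-seed paired-ordering and bound-validity experiments, in
about a minute. The qualitative predictor ordering (similarity and block
model above the degree heuristic) reproduces at these sizes; absolute
metric values on synthetic data are not comparable to values on any real
network and are never asserted.

## Known limitations

- The microcanonical SBM variant (hard edge-count constraints, non-local
  cluster moves) is not implemented; the Bayesian degree-corrected model
  covers the family's prediction mechanics.
- No model selection over the number of groups or embedding dimension;
  defaults are documented above and overridable.
- External embedding methods (node2vec-style) are supported only through
  the predictor-adapter interface, not bundled.
- The single-node MCMC is pure Python/NumPy; at hundreds of thousands of
  nodes a compiled sampler would be needed.
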