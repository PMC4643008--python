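# Methods

## Model and likelihood

`outclust` fits a joint Gaussian random-effects model for an N × J
column-centered expression matrix Y and an optional length-N continuous
outcome Z. Conditional on the membership map k(j), feature values are
Y_ij = c_{i,k(j)} + ε_ij with cluster effects c_ik ~ N(0, τ²) and errors
ε_ij ~ N(0, σ²); the outcome is Z_i = Σ_k β_k c_ik + ξ_i with ξ_i ~
N(0, γ²). The latent c are never instantiated during inference: per
sample, X_i = (Y_i, Z_i) is multivariate normal with covariance

    Σ = D + τ² A Aᵀ,   D = diag(σ², …, σ², γ²),   A = [Φ; βᵀ],

where Φ is the J × K one-hot membership matrix. Within a cluster the
feature block is compound symmetric (off-diagonal τ²), between clusters
zero, the feature–outcome covariances are τ²β_{k(j)}, and
Var(Z) = τ²Σβ_k² + γ².

The likelihood is evaluated in closed form. With the Woodbury identity
the (J+1)-dimensional solve reduces to the K × K capacity matrix
M = diag(1/τ² + n_k/σ²) + (β/γ)(β/γ)ᵀ, which is diagonal plus rank one,
so Sherman–Morrison and the matrix-determinant lemma finish the job.
Given cached sufficient statistics — cluster sizes n_k, per-sample
cluster sums T_ik = Σ_{j∈S_k} Y_ij, and the total sum of squares — a
full evaluation costs O(N·K) and never forms the dense matrix. The
dense construction (`build_joint_covariance` + a generic multivariate
normal density) is retained purely as the independent oracle in the test
suite; agreement is asserted to 1e-8 relative on random small instances,
including instances with empty clusters.

If a cluster k is empty, only the combination τ²β_k² + γ² enters Σ, so
(β_k, γ²) is not identifiable along that ridge; the tests assert this
invariance numerically, and empty-cluster β draws are excluded from
reported estimates.

Moving one feature between clusters changes two columns of T and two
entries of n; `move_delta` computes the log-likelihood change as the
difference of two closed-form evaluations on the updated statistics, so
it equals a pair of full evaluations exactly (asserted to 1e-9). A
consistency audit re-derives the statistics and the cached
log-likelihood from scratch every 100 sweeps (tolerance 1e-6) and raises
if they drift.

## Priors and MCMC

Priors: σ, τ, γ uniform on (0, A) with A = 100 by default; each β_k
uniform on [−B, B] with B = 1000; weights ω symmetric Dirichlet(α) with
α = 1; memberships multinomial(ω). Because updates operate on the
variance scale, the uniform-on-SD prior contributes a v^{−1/2} density
factor, which is included in the acceptance ratio together with the
support check.

Each sweep:

1. **Variance components.** One MH update each for σ², τ², γ². The
   proposal is inverse-gamma with shape s and scale s·(current value),
   so the proposal mean sits near the current value and s (default 50)
   controls step size; the asymmetric-proposal correction is included.
   Proposals below 1e-10 or with SD above A are rejected outright.
2. **Memberships and β.** For every feature in index order, the K
   candidate log-likelihoods are computed via the sufficient statistics,
   combined with log ω_k, normalized by log-sum-exp, and the new label is
   drawn from the resulting multinomial. All K probabilities are strictly
   positive, so clusters can empty and refill; K is a fixed maximum, not
   an estimate. After each accepted membership change, β for the old and
   new clusters gets a Gaussian random-walk MH update (step SD 0.25 by
   default); after the full pass, all K β's are updated. The model gives
   no simple conditional for β, so random-walk MH against the
   marginalized likelihood was chosen; a data-augmentation Gibbs step
   (re-instantiating c) would be a valid alternative but would abandon
   the marginalized likelihood that makes the sampler cheap.
3. **Weights.** ω ~ Dirichlet(α + n_1, …, α + n_K), its conjugate
   conditional.

Initialization is over-dispersed but scale-aware: uniform random labels,
σ² and γ² at half the empirical variances of Y and Z, τ² = σ², β = 0,
ω uniform. Chains are deterministic given the seed; multi-chain runs
derive child seeds from a `SeedSequence` so each chain starts from a
different random partition. Convergence is judged the pragmatic way: run
two chains and correlate their concordance matrices pair by pair
(`chain_agreement`); automated stopping rules are out of scope.

The outcome vector is used as given (no centering or scaling) by
default; `--center-outcome` subtracts its mean. Missing values are
rejected with an error naming the offending cell — the model has no
missing-data mechanism.

## Summaries

The concordance matrix C (fraction of post-burn-in iterations in which
features i and j share a label) is invariant to per-iteration
relabeling, which is the point: it is the label-switching-proof posterior
summary. Heat maps order features by average-linkage hierarchical
clustering on 1 − C with optimal leaf ordering (deterministic;
reproduces exact block structure as contiguous blocks — the ordering
algorithm is our choice, any seriation that groups high-concordance
features would do) and render 16 discrete gray shades with bin edges at
i/16, white 0 → black 1.

β is summarized by the stable-iteration procedure: take the modal
partition (most frequent sampled partition after canonical relabeling),
and for each of its clusters use only iterations in which exactly that
feature set shares one label, matching the label per iteration by set
identity. The reported `beta_se` is the SD of those draws. Clusters with
no usable iterations are reported as missing rather than erroring.

The **correct-pairing proportion** against a known truth is the
iteration-averaged fraction of feature pairs whose same/different-
cluster status matches the truth — i.e. the mean Rand index between the
sampled partitions and the truth. The metric admits other readings
(e.g. restricting to truly co-clustered pairs, available as
`mode="true_pairs"`); the all-pairs form was chosen as the default
because it is symmetric, bounded in [0, 1], and equals 1 exactly when
every stored partition matches the truth up to relabeling.

## Prediction

Conditioning the joint Gaussian yields, for a profile y centered with
the *training* column means,

    E[Z|y]   = τ² Σ_k β_k/(σ² + n_k τ²) · Σ_{j∈S_k} y_j
    Var[Z|y] = τ²σ² Σ_k β_k²/(σ² + n_k τ²) + γ²,

homoscedastic in y. Training column means are persisted with the fit so
new samples are centered consistently. The default prediction averages
these moments over the post-burn-in draws and combines them by the law
of total variance; a plug-in mode (posterior-mean parameters, modal
partition) reproduces the formulas above verbatim. Both agree with the
Schur-complement conditional of the dense joint covariance to 1e-9 on
random instances.

## Synthetic data and the study harness

The generator draws directly from the generative model and returns the
uncentered matrix plus the latent truth (used only for scoring). Default
design: N = 80 samples, J = 50 features in three clusters, σ = γ = 1,
β = (−5, 0, 5), variance ratio τ²/σ² = 4 (τ = 2). Cluster sizes default
to 17/17/16 (an even split of 50 into three). A 27-feature preset
(9/9/9) serves the low-ratio pairing comparison, with "variance ratio
0.15" implemented as τ = σ·√0.15. Fitting uses K = 5 and 1000 iterations
with 500 discarded — deliberately larger than the true cluster count, so
cluster-number inference is exercised.

`run_simulation_study` repeats simulate-then-fit over replicates and
tabulates, per parameter: the mean estimate, the SD of estimates across
replicates ("se") and the mean of the per-replicate posterior SDs
("mean_of_se"). Replicate data seeds derive only from the simulation
seed, so with- and without-outcome studies fit the *same* datasets —
pairing the comparison that matters for the directional claim that
outcome information improves clustering at a low variance ratio. The
recovery table reports the cluster-effect variance on both scales (τ and
τ²); the τ² row is the one comparable to reference tabulations of the
variance component. Matching of recovered clusters to true clusters uses
maximal Jaccard overlap with the modal partition. The studies run at 20
replicates by default — enough for cross-replicate standard errors a
few times smaller than the effects being checked — and complete in a few
minutes on one CPU.

What the simulations do not emulate: real microarray data's heavy-tailed
noise, probe-level artifacts, correlated measurement error across genes
in *different* clusters, and features that belong to no cluster.
Passing the recovery tests therefore demonstrates correctness of the
inference machinery under the model's own assumptions, not robustness to
their violation.

## Numerical choices and limitations

- Variance proposals below 1e-10 are rejected, keeping Σ non-singular.
- Label draws use cumulative-sum inversion of the normalized multinomial
  (log-sum-exp stabilized); Dirichlet draws are clipped away from exact
  zero to keep ω strictly positive.
- Modal-partition ties break by first occurrence; seriation ties break
  by feature index; Jaccard-matching ties break by smaller cluster index.
- Heterogeneous per-cluster τ_k, categorical or survival outcomes,
  longitudinal clustering, and split/merge partition moves are not
  implemented (deliberate non-goals).
- With a single filled cluster plus empties, the expression-only model
  can confound τ² with overall scale for small N; the sampler handles it
  but expect wide posteriors.
- For K ≫ true cluster count and a low variance ratio, chains mix among
  near-equivalent partitions; the concordance matrix (not the modal
  partition) is the trustworthy summary there.
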