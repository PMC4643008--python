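# outclust — outcome-driven Bayesian clustering of correlated features

`outclust` clusters features (typically genes measured on microarrays or
RNA-seq, after log transformation) so that features in a cluster are
*correlated with each other* and, optionally, *share a common effect on a
continuous clinical outcome*. It is aimed at analysts who want
model-based gene clusters that are informed by a phenotype — e.g. groups
of inflammation genes whose shared expression level predicts organ
failure after trauma — rather than clusters found blind to the outcome.

## The model

For samples *i* = 1..*N* and features *j* = 1..*J* with (column-centered)
values *Y*ᵢⱼ, each feature belongs to one of at most *K* clusters. With
per-sample, per-cluster Gaussian random effects *c*ᵢₖ:

```
Y_ij = c_{i,k(j)} + ε_ij          c_ik ~ N(0, τ²),  ε_ij ~ N(0, σ²)
Z_i  = Σ_k β_k c_ik + ξ_i         ξ_i ~ N(0, γ²)
```

so two features in the same cluster have covariance τ² within a sample,
features in different clusters are independent, and the outcome *Z* is a
linear combination of the latent cluster levels. The ratio τ²/σ² (the
**variance ratio**) governs how separable the clusters are.

Inference marginalizes the random effects: each sample's vector
(*Y*ᵢ, *Z*ᵢ) is multivariate normal with a block-plus-rank-one covariance
whose inverse and determinant have closed forms (Woodbury /
Sherman–Morrison), so likelihood evaluation costs O(N·K) given cached
cluster sums instead of a (J+1)³ factorization. An MCMC sampler cycles
through Metropolis–Hastings updates of σ², τ², γ², multinomial Gibbs
reassignment of every feature (weighted by cluster weights ω times the
marginal likelihood), random-walk updates of β, and a conjugate
Dirichlet draw of ω. *K* is a maximum: clusters may empty and refill, so
the number of occupied clusters is inferred implicitly.

Because cluster labels switch along the chain, results are summarized by
the **concordance matrix** — the proportion of iterations in which each
feature pair shares a cluster — plus label-switching-robust β estimates
computed only from iterations whose sampled clusters exactly match the
modal gene sets. For a new sample, the predictive law of its outcome
given its profile is Gaussian with closed-form mean and variance.

## Worked example

```bash
outclust simulate --out-dir demo            # 80 samples, 50 genes, 3 clusters
outclust fit demo/expression.csv --outcome demo/outcome.csv \
    --k-max 5 --iterations 1000 --burn-in 500 --seed 1 --out-dir demo/fit
outclust summarize demo/fit --truth demo/truth.json
```

The `summarize` step prints the stable-iteration β table and the pairing
score against the simulated truth:

```
 cluster  size           features  beta_mean  beta_se  n_iterations
       0    17   [0, 1, ..., 16]   -5.008993 0.137595           500
       1    17  [17, 18, ..., 33]   0.104615 0.184978           500
       2    16  [34, 35, ..., 49]   5.015845 0.168437           500
correct-pairing proportion vs truth: 1.0000
```

Here every post-burn-in iteration reproduced the true three-cluster
partition (pairing 1.0), and the recovered coefficients are close to the
generating values β = (−5, 0, 5): the first cluster's shared expression
level lowers the outcome, the second is unrelated to it, the third
raises it. `demo/fit/concordance.csv` and `concordance.png` hold the
co-clustering heat map (white 0% → black 100%, 16 shades), and
`outclust predict demo/fit new_expression.csv --out preds.csv` yields
per-sample predictive means and SDs for new profiles.

The same workflows are available as library functions (`run_chain`,
`concordance_matrix`, `stable_beta_summary`, `posterior_predict`, ...).

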