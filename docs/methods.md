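# Methods

## Model

A sample is a symmetric nonnegative adjacency matrix `A_i` over the union of
`V` taxa plus a scalar phenotype `y_i`.  The regression is
`y_i = mu + <A_i, B>_F + eps_i`, `eps_i ~ N(0, tau2)`, with symmetric
coefficient matrix `B`.  Writing `x_i` for the vectorized upper triangle of
`A_i` (including the diagonal; `q = V(V+1)/2` columns in row-major order)
this is `y ~ N(mu 1 + X gamma, tau2 I)` with `b_kl = gamma_kl / 2` for
`k != l` and `b_kk = gamma_kk` — the diagonal appears once in the Frobenius
sum, so halving it would break the identity `<A, B>_F = x . gamma`.  The
networks are taken as known without error; propagating network-estimation
uncertainty is out of scope.

Priors (all conjugate):

- `gamma_kl ~ N(u_k' Lambda u_l, tau2 s_kl)`, `s_kl ~ Exp(theta/2)`,
  `theta ~ Gamma(zeta, iota)`.  The scale mixture makes the marginal prior
  of each coefficient a heavy-tailed double exponential.
- `u_k ~ N(0, M)` if `xi_k = 1`, else the point mass at zero;
  `xi_k ~ Bernoulli(Delta)`, `Delta ~ Beta(a_Delta, b_Delta)`,
  `M ~ InvWishart(nu, I_R)`.  A node whose factor is zero contributes zero
  prior mean to every incident coefficient, so `xi` is a node-influence
  indicator and its posterior mean the node's probability of influence.
- `lambda_r in {-1, 0, 1}` with `P(lambda_r = 0 | pi_r)` etc. given by a
  `Dirichlet(r eta, 1, 1)` hyperprior (`eta > 1`), increasingly biased
  toward zero for higher `r` so the effective latent dimension is learned.
- `pi(mu, tau2) ∝ 1/tau2` (flat/Jeffreys-type, improper but with proper
  posterior for `n >= 2`).

## Gibbs sweep

One generation updates, in order: `tau2` (inverse-gamma) → `(xi_k, u_k)` for
`k = 1..V` → `gamma` (q-variate normal through a Cholesky solve of
`X'X + D^-1`) → all `s_kl` (generalized inverse Gaussian) → `theta` (gamma,
summing all q scales so the shape `zeta + q` matches the number of
observations) → `Delta` (beta, from the just-updated `xi`) → `M`
(inverse-Wishart with scale `I_R + sum over active nodes of u_k u_k'`) →
`mu` (normal) → `(lambda_r, pi_r)` for `r = 1..R` (three-point enumeration
with log-sum-exp normalization, then Dirichlet with the single component-r
indicator).  Inside the node loop, `Delta` retains its value from the
previous sweep — its own update needs the completed `xi` vector.

The node update marginalizes the slab: the spike probability is
`w = (1-Delta) N(g_k | 0, tau2 H_k) / [(1-Delta) N(g_k | 0, tau2 H_k) +
Delta N(g_k | 0, tau2 H_k + U* M U*')]` where `g_k` collects the `V - 1`
off-diagonal coefficients incident to node k, `H_k` their scales, and `U*`
the other nodes' factors times `Lambda`.  On inclusion, `u_k` is drawn from
the conjugate slab posterior with precision `M^-1 + U*' H_k^-1 U* / tau2`.
Both quantities share a Woodbury/determinant-lemma factorization of the
`R x R` posterior precision, so the per-node cost is `O(V R^2 + R^3)` rather
than `O(V^3)`.

One deliberate structural choice, inherited from the algorithm's published
form: the node update conditions on the off-diagonal coefficients only.  The
diagonal coefficient's prior mean `u_k' Lambda u_k` is quadratic in `u_k`
and would destroy Gaussian conjugacy.  Consequently, when diagonal main
effects are included, the sweep is a conditionally-approximate (pseudo-Gibbs)
kernel with respect to that single factor; with `include_diagonal=False`
every update is an exact full conditional, and the joint-distribution
(getting-it-right) test in the suite is run in that configuration.  The
diagonal entries of the prior-mean vector `W` do retain `u_k' Lambda u_k`,
so diagonal coefficients shrink toward the latent-factor structure in the
`gamma`, `s` and `lambda` updates.

### Numerical choices

- GIG draws use the identity `X ~ GIG(1/2, chi, psi) <=> 1/X ~
  InverseGaussian(mean = sqrt(psi/chi), shape = psi)` with numpy's Wald
  sampler (vectorized over all q scales).  `chi = (gamma - W)^2 / tau2` is
  floored at 1e-300; below `1e-200 * psi` (where the Wald mean would
  overflow) the exact `chi -> 0` limit `Gamma(1/2, rate = psi/2)` is drawn
  instead.  The parameterization `p = 1/2, chi, psi = theta` is the one
  forced by conjugacy of the `Exp(theta/2)` prior.
- All mixture weights (spike probability, three-point lambda posterior) are
  computed in log space with max-shift normalization.
- Cholesky factorizations escalate a relative diagonal jitter
  `0 -> 1e-10 -> 1e-8 -> 1e-6` before raising.
- The tau2 conditional raises a degenerate-posterior error if its scale is
  exactly zero (perfect fit with `gamma = W`), which cannot occur with
  continuous data.

## Multi-chain runner and convergence

`run_chains` runs independent chains whose generators are spawned from
`SeedSequence(seed)`, making runs bit-reproducible and chains independent;
chain dispersion comes from the `u ~ N(0, I)` initialization draw (all other
coordinates start at moment-based values: `mu = mean(y)`, `tau2 = var(y)`,
`xi = 1`, `s = 1`, prior means elsewhere).  Every `check_interval`
generations past `min_samples`, rank-normalized split-R̂ (arviz's
implementation of the Vehtari et al. diagnostic) is computed for every
`gamma` and `xi` coordinate on the second half of each chain.  Sampling
stops when the maximum drops to 1.01 (strict) or at `max_samples`, in which
case a warning is emitted and the 1.1 fallback bound is reported.  A
coordinate constant across all chains (common for `xi` entries pinned at 0
or 1) is degenerate and reported as R̂ = 1.0.  Half of each chain is
discarded as burn-in; summaries pool retained draws across chains.

Defaults: 3 chains, minimum 10,000 and maximum 800,000 generations, checks
every 10,000.  Hyperparameter defaults: `eta = 1.01`, `a_Delta = b_Delta =
1`, `zeta = iota = 1`, `nu = R + 2`; `R` is user-chosen (5 is a reasonable
starting point; larger values sharpen recovery but increase the risk of
floating-point trouble in the latent-factor algebra).

## Synthetic-data study

The generator reproduces the validation study's conditions and is the basis
of all end-to-end tests:

- **Phylogeny.** A rooted binary tree grown from a cherry by splitting a
  uniformly chosen leaf edge until `V` leaves exist; branch lengths i.i.d.
  Uniform(0, 1) (the convention of the standard random-tree routine the
  study used, which fixes only the splitting process).  Defaults `V = 30`.
- **Networks.** Each sample observes `k` taxa drawn uniformly without
  replacement (`k` in 8/15/22 in the study); `a_ij` is the inverse patristic
  distance when both taxa are present, zero otherwise.  Diagonals are zero
  in the theoretical setting and presence indicators (0/1) in the realistic
  ones.
- **Node influence.** One Bernoulli(pi) coin per node (`pi` in 0.3/0.8); an
  edge is influential iff both endpoints are.  A per-edge coin at pi = 0.3
  would make essentially every node influential (1 − 0.7^29 ≈ 1),
  contradicting the sparse-truth design, so the per-node reading is used.
- **Phenotypes.**  *theoretical*: `y = <A, B>_F + eps` with
  `b_ij ~ N(mu, 1)` on influential pairs (`mu` in 0.8/1.6), zero diagonal;
  *additive*: sum of main effects `b_j ~ N(mu_b, 1)` — i.i.d. or, in
  phylogenetic mode, jointly `N(mu_b 1, Sigma)` with `Sigma` the
  Brownian-motion tree covariance (shared root-to-MRCA path length) — over
  influential taxa present in the sample; *interaction*: additive plus
  `a_jl b_jl` with `b_jl ~ N(0.4, 1)` drawn once per influential pair and
  held fixed across samples (they are truth, not noise); *redundant*: the
  interaction phenotype capped at `L` (3/7/22/30 by `(pi, mu)` setting,
  chosen so some but not all responses saturate).  Noise is N(0, 1).  The
  cap is applied after adding noise by default (`cap_before_noise`
  switches).
- **Augmentation.** Originals are cycled round-robin; each pseudo-sample
  adds a `N(0, s_P^2/4)` response offset (`s_P^2` = sample variance of the
  original responses) and flips presence independently (keep 0.9 / add
  0.1), rebuilding the network from the flipped presence with the same
  construction rule; an optional positivity fix redraws negative responses
  from `(1/15) chi-square(3)`.

What the generator does *not* emulate: compositional abundance structure,
network-estimation error (networks derive deterministically from the true
tree), sequencing noise, or environmental covariates.  Passing tests
demonstrate correct inference when the network construction is known and
exact; real co-occurrence networks add estimation error the model currently
ignores.

## Evaluation conventions

`pp_node` is the exact mean of stored `xi` draws.  Credible intervals are
equal-tailed type-7 empirical quantiles of pooled draws at the 90% and 95%
levels.  The point estimate of `B` is the posterior mean of `gamma` mapped
back through `b_kl = gamma_kl/2`.  Node influence calls threshold `pp` (0.5
by default); edge and main-effect calls use CI-excludes-zero.  Recovery
metrics: coefficient MSE against the true vectorized coefficients, response
MSE against posterior-mean predictions, FPR/FNR at the probability cutoff,
and an ROC sweep of the cutoff over 0.1..1.0.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run a scaled-down version of the
study: `V = 10`, `k = 5`, `n = 500`, `mu = 1.6`, `pi = 0.3`, `R = 5`, three
chains, minimum 10,000 and maximum 60,000 generations with checks every
10,000.  At this scale the fit converges strictly (max split-R̂ ≈ 1.01 at
20,000 generations) in a few CPU-minutes and recovers every influential
node and edge; the full-size study conditions (`V = 30`, `n` up to 1000, up
to 800,000 generations) are reachable through the same interfaces.  The
getting-it-right check uses `V = 4`, `R = 2`, `n = 6` with 125,000 sweeps
thinned by 25 against 5,000 independent prior draws, with `(mu, tau2)` held
fixed because their improper prior cannot be sampled; their conditionals
are validated separately against closed-form moments.

## Known limitations

- Large `R` can produce ill-conditioned latent-factor algebra; the jitter
  ladder guards the factorizations but does not remove the statistical
  pathology.  Prefer the smallest `R` that recovers structure.
- With diagonal main effects included the sweep is pseudo-Gibbs in one
  factor (above); empirically this does not impair recovery, but exactness
  claims apply to the edges-only configuration.
- Binary `xi` coordinates pinned at 0/1 across all chains yield degenerate
  R̂ = 1.0 by convention; convergence evidence for those coordinates comes
  from the continuous `gamma` coordinates.
- Functional-redundancy phenotypes saturate the response and weaken
  identifiability when many taxa are sampled per draw; this is a property
  of the design, not of the sampler.
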