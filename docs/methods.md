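# Methods

`sdmevol` implements the comparative-methods toolchain used to ask why
temperature-dependent sex determination (TSD) dominates in turtles while
genotypic sex determination (GSD) dominates in lizards: is the binary
sex-determining mechanism (SDM) associated with diversification, are the
transition rates between mechanisms asymmetric, what was the ancestral
state, and does lifespan evolve differently in TSD and GSD lineages?  All
analyses run on rooted, ultrametric, bifurcating trees with a binary tip
character (0 = GSD, 1 = TSD).

## Discrete character model (Mk2)

The character evolves as a two-state continuous-time Markov chain with
instantaneous rates `q_GT` (= `q01`, GSD→TSD) and `q_TG` (= `q10`), per
lineage per unit branch length.  The likelihood uses Felsenstein pruning
with the closed-form 2×2 transition matrix

    P(t) = [ (q10 + q01 e^{-st})/s   q01(1 - e^{-st})/s ]
           [ q10(1 - e^{-st})/s      (q01 + q10 e^{-st})/s ],   s = q01 + q10,

partials rescaled at every internal node.  Tips of unknown state can be
marginalized (partial (1,1)); the pipeline's empirical-style default is to
prune unknown-state taxa first, while the missing-data recovery analyses
keep the full tree and marginalize.

Root treatment is configurable: `flat`, `stationary`, `obs-weighted`
(weights proportional to each state's root partial — the common default of
the diversification-software family this mirrors), or `fixed:0/1`.  The
default is `obs-weighted`; reports record the choice because ML rate
estimates are mildly sensitive to it.

**Fitting.** L-BFGS-B on log rates, bounds [1e-9, 100], five starts (one at
the 1/total-tree-length scale, the rest log-uniform in [1e-7, 10] from a
fixed internal stream, so fits are deterministic).  The equal-rates model
(`q_GT = q_TG`) is the null of a 1-df likelihood-ratio test (chi-square).

**MCMC.** Univariate slice sampling (step-out, width 1.0 on the log-rate
axis) in a fixed scan order (`q_GT` then `q_TG`), independent exponential
priors with mean 0.1, 2000 steps with the first 25% discarded — the
settings the analyses this package reproduces were run with.  The reported
statistic is PP = fraction of retained samples with `q_TG > q_GT`,
significant outside [0.025, 0.975].

**Marginal ancestral states.** Standard two-pass algorithm: tipward
partials D from pruning, rootward partials G by a preorder sweep (the root
row is the prior; each child combines its parent's G with the sibling's
lifted partial), node marginal ∝ G·D renormalized.  Verified against
exhaustive joint-state enumeration on small trees (1e-10).

## State-dependent diversification (BiSSE)

The joint likelihood of tree and tip states with state-dependent speciation
(λ_i), extinction (μ_i) and transitions (q_ij) integrates the standard
coupled ODEs along each branch, from the tips toward the root:

    E_i' = μ_i − (λ_i + μ_i + q_ij) E_i + q_ij E_j + λ_i E_i²
    D_i' = −(λ_i + μ_i + q_ij) D_i + q_ij D_j + 2 λ_i E_i D_i

with skeletal-tree sampling fractions entering the boundary conditions
(E_i(0) = 1 − f_i; D_i(0) = f_i for the observed state).  A single f is
applied to both states by default (the analyses assume equal sampling of
TSD and GSD).  Integration is fixed-step classical RK4 in a numba kernel
with step ≤ 0.01 / (fastest total rate), capped at 2000 steps per branch;
E is clamped to [0,1] and D to ≥ 0 against round-off.  At this step size
the likelihood agrees with the closed-form pure-birth (Yule) value to
better than 1e-8 on 100-tip trees (tested).  D is rescaled per node with an
accumulated log-scaler.

Root treatment: survival conditioning (divide D_i by λ_i (1 − E_i)²) is on
by default, followed by obs-weighted combination; both are configurable and
logged.  Rates are bounded above at 200 expected events per root-to-tip
path — generous relative to anything identifiable, and it keeps the
optimizer out of numerically absurd territory.

Two constrained tests mirror the study design:

* **transition test** — λ and μ shared between states; free (q_GT, q_TG)
  vs equal-q, LRT with 1 df.  With state-independent diversification the
  likelihood factorizes (checked exactly at μ = 0), so these rate MLEs
  agree with the plain Mk2 MLEs — an internal-consistency check asserted
  at 5% relative tolerance in the acceptance suite.
* **diversification test** — shared-λ null vs state-dependent λ; the
  log-likelihood difference (ΔLL) is the statistic handed to the
  parametric bootstrap, since the chi-square reference is known to be
  anti-conservative for this comparison.

Marginal reconstruction under BiSSE exploits the linearity of the D system:
each branch is summarized by a 2×2 transfer matrix integrated alongside the
(data-independent) E trajectory, after which the same up/down marginalization
as in Mk2 applies with λ factors at nodes.  With equal λ, μ → 0 and f = 1 it
reproduces the Mk2 marginals (tested to 1e-4).

## Species-richness contrasts (MacroCAIC-style)

At every internal node whose daughters differ in (reconstructed) predictor
value, the response contrast is ln(N₁/N₀) of summed clade richness, oriented
so the daughter with the higher predictor value is the numerator; predictor
contrasts follow the standard independent-contrasts down-pass (Felsenstein
weighting, branch lengthening; zero-length branches floored at 1e-8).
Per-tip richness counts are supplied as a table (default 1 per tip), so a
pruned tree can carry full-clade richness.  Contrasts are filtered by a
minimal clade size (MNS ∈ {10, 20, 30, 40} by default) and fitted by a
through-origin regression (statsmodels OLS; F on (1, k−1) df; the reported
r² is the adjusted value, which can be negative).  The F statistic feeds the
bootstrap harness.

## Parametric bootstrap

The harness fits an Mk2 model to the observed states (free rates for
diversification statistics, equal rates for the transition-rate null —
matching each described use), simulates `n_reps` neutral characters on the
fixed tree with the root set to the reconstructed ancestral state (not
resampled), recomputes the statistic per replicate, and reports
p = #(null ≥ observed)/n — the uncorrected rule; the (k+1)/(n+1) rule is
available and recommended when p = 0 would otherwise be reported.
Replicate i uses seed `seed + i`, so results are independent of execution
order.  Replicates where the statistic is undefined (e.g. no informative
contrasts) are dropped and counted; more than 20% failures aborts.  The
harness is statistic-agnostic; factories for MacroCAIC-F, BiSSE-ΔLL,
Mk2-ΔLL and Mk2-PP are provided and share no special casing.

## Lifespan models (BM1 / BM2 / OU1 / OUM)

Lifespans (years) are natural-log transformed.  The tree is painted into
GSD/TSD regimes — each branch takes the regime of its child node, argmax of
the marginal reconstruction at internal nodes, the observed state at tips,
exact ties resolving toward the parent.  Four Gaussian models are fitted
through the exact tip covariance:

* **BM1**: Σ = σ² C, C the shared root-to-MRCA path lengths.
* **BM2**: Σ = σ²_GSD C_GSD + σ²_TSD C_TSD, the C_r being the per-regime
  partition of C along the painted branches.
* **OU1 / OUM**: shared α and σ²; covariance is the non-stationary
  (rooted-process) form Σ_ij = σ²/(2α) · e^{−2α(T−t_ij)}(1 − e^{−2α t_ij}),
  which reduces continuously to Brownian motion as α → 0 — the stationary
  form does not have this limit, and the α → 0 identity is part of the test
  contract.  OUM tip expectations weight each regime's optimum by the
  exponentially discounted time the lineage spent in it, with the residual
  root weight e^{−αT} assigned to the root regime (root value = root
  optimum); rows of the design matrix sum to one, so θ_GSD = θ_TSD
  collapses OUM to OU1 exactly.

Location parameters and the overall scale are profiled out by GLS
(Cholesky), leaving a one-dimensional search (log α, or the BM2 rate
ratio) done by a 31–61-point log-grid scan plus bounded refinement;
α ∈ [1e-8/T, 50/T].  Parameter counts for AIC: BM1 2, BM2 3, OU1 3, OUM 4;
LRTs BM1-vs-BM2 and OU1-vs-OUM each use 1 df.  Optima are reported
back-transformed to years.  Fits carry a data fingerprint so models
compared by AIC/LRT are guaranteed to have seen identical data.

## Synthetic data

The generators replace the empirical turtle/lizard datasets everywhere:

* **Trees** — forward Gillespie birth–death conditioned on the extant tip
  count: the simulation stops when the count first reaches n and the tips
  are extended by the waiting time to the next (unrealized) event, so
  internode waiting times are exactly Exp(kλ) and the conditioned Yule MLE
  (n−2)/total-length is unbiased.  Study conditions: λ = 0.1, μ = 0.
* **Characters** — exact event-time simulation (exponential waits between
  flips); the full change history is retained so reconstruction and
  painting can be validated against truth.
* **Traits** — branch-by-branch BM/OU transitions under a regime painting,
  using the exact OU transition mean and variance.

Two profiles bundle these into study-shaped fixtures.  *Turtle-like*:
TSD root, equal rates q = 0.008, OUM lifespans with optima 22.6 / 35.9
years (GSD / TSD) — the study-scale values — α = 0.08, σ² = 0.015
(stationary sd ≈ 0.3 log-years).  *Lizard-like*: TSD root, q_GT = 0.0018,
q_TG = 0.038 (the ~21-fold TSD→GSD excess found in lizards, rescaled to the
synthetic tree height so the expected GSD tip share is the observed ~86%;
the empirical per-My rates on much deeper trees would leave the character
far from its stationary mix here), optima 7.9 / 10.1 years.  Richness is
geometric (mean 5) and independent of state.  A stated fraction of states
can be masked to unknown, uniformly at random — the real missing data
cluster taxonomically, so the fixtures are optimistic about missingness;
masked fractions matching the empirical datasets (0.72 turtles, 0.90
lizards) are recorded in the profiles but not applied by default.

What the fixtures do **not** emulate: state-dependent diversification
(trees are neutral by construction — intentional, since the bootstrap
nulls assume it), non-random missingness, rate heterogeneity across clades
or time, measurement error in lifespans, and polytomies or calibration
uncertainty in the empirical trees.  Passing tests therefore demonstrate
correctness and calibration of the methods under their own assumptions,
not robustness to those violations.

## Problem sizes and numerical choices

The test suite runs every statistical check at sizes chosen to finish in a
few minutes while keeping Monte-Carlo error well below the asserted
tolerances: rate recovery at 50 replicates of 1000-tip trees per rate
combination (mean within 2 Monte-Carlo SEs); missing-data recovery at 75%
and 95% masking, same criterion; bootstrap calibration at 40 datasets ×
200 replicates (MacroCAIC-F, 64 tips) and 20 × 60 (BiSSE-ΔLL, 45 tips),
KS uniformity at p > 0.01; Mk2/BiSSE rate agreement on 20 datasets of 300
tips at 5% relative; OUM optimum-ordering recovery on 50 turtle-like
fixtures of 87 tips (the empirical turtle sample size) at ≥ 90%.  Exact
oracles (enumeration, Yule closed form, pattern-sum conservation) use
tolerances 1e-10 / 1e-8.  `scripts/acceptance.py` re-runs the recovery
design from scratch at 50 replicates.

Known numerical limitations: the BiSSE RK4 step is fixed (no embedded
error estimate), so pathological rate combinations near the bound rely on
the step cap; the Mk2 optimizer can sit at the 1e-9 rate floor when a state
is absent (by design — the data contain no transitions into it); and the
OU grid refinement resolves log α to ~1e-8, far below the statistical
uncertainty of any fit shown here.
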