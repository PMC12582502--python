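# Methods

## Model and inference

The observed table W (n samples × m taxa) is modelled hierarchically: per
sample i, mode indicators δ_ij ~ Bernoulli(π_j); Dirichlet concentrations
θ_ij equal α_{j,1} when δ_ij = 1 and α_{j,0} otherwise; the true composition
X_i ~ Dirichlet(θ_i); counts W_i ~ Multinomial(N_i, X_i) with N_i the
observed depth. The construction is equivalent to drawing independent
per-taxon gamma absolute abundances (two-component mixture of shapes) and
normalising; the gamma scale cancels from the composition and is pinned to 1
in the simulator — no inference code consumes it.

The posterior over (X, δ) mixes 2^m configurations per sample and is
intractable, so it is approximated by the mean field
g(X|β) q(δ|γ) = ∏_i Dirichlet(β_i) ∏_ij Bernoulli(γ_ij), optimised by
coordinate ascent inside a variational EM loop:

- **E-step.** β_ij = W_ij + γ_ij α_{j,1} + (1−γ_ij) α_{j,0} (exact CAVI
  optimum for the Dirichlet factor). Responsibilities are updated cyclically
  across taxa, vectorised over samples:
  γ_ij = logistic(h_ij(1) − h_ij(0) + logit π_j), where
  h_ij(d) = lgamma(α_{j,d} + Σ_{k≠j} ᾱ_ik) + (α_{j,d}−1)(ψ(β_ij) − ψ(Σ_k β_ik))
  − lgamma(α_{j,d}) and ᾱ_ik = γ_ik α_{k,1} + (1−γ_ik) α_{k,0}. The lgamma
  term is a Jensen lower bound (log-gamma is convex) of the intractable
  expectation over the other taxa's indicators; it is deterministic, unlike
  a Monte-Carlo estimate, which keeps the optimisation stable. Up to 20
  sweeps per outer iteration, stopping when max |Δγ| < 1e−4.
- **M-step.** π_j = mean_i γ_ij, clipped to [0, 1−1e−8] to keep π_j < 1.
  α maximises Σ_i lgamma(Σ_j ᾱ_ij) + Σ_ij [(ᾱ_ij−1)(ψ(β_ij)−ψ(Σ_j β_ij))
  − γ_ij lgamma(α_{j,1}) − (1−γ_ij) lgamma(α_{j,0})] by L-BFGS-B in log-α
  with analytic gradients, bounds [1e−6, 1e4], warm-started at the previous
  value and never returned worse than the warm start.

**Monitored objective and the ascent guarantee.** Convergence is tracked by
the surrogate evidence lower bound: the exact ELBO with the expectation of
lgamma of the summed concentrations replaced by the same (unconditional)
Jensen bound used in the M-step. Every β, π and α update provably does not
decrease this quantity. The responsibility proposal, however, derives from
the tighter bound *conditioned* on the taxon being updated, and a move that
improves the conditional bound can in principle lower the monitored
objective. Each coordinate move is therefore accepted only if its exactly
computable effect on the monitored objective is non-negative; rejected moves
keep the current value. This makes the recorded trace non-decreasing by
construction while leaving the proposal — and hence the fitted posterior —
essentially untouched (rejections are rare in practice). The outer loop
stops when the relative objective change falls below 1e−6 (default) or at
200 iterations.

**Initialisation** (the reference description leaves it open): γ_ij = 1
where W_ij > 0 else 0; π_j = prevalence of taxon j; α_{j,0} = 0.01 (near-zero
spike); α_{j,1} = A · (mean nonzero proportion of taxon j), with A a
Dirichlet method-of-moments total concentration clipped to [1, 1000]. A
seeded random initialisation is available as a guard against local optima.

**Identifiability.** The likelihood is invariant under swapping the two
modes of a taxon together with γ → 1−γ and π → 1−π; after each M-step the
canonical ordering α_{j,0} ≤ α_{j,1} is restored by exactly that relabelling.
With α_{j,0} = α_{j,1} the model collapses to a Dirichlet-multinomial and the
posterior mean is (W_ij + α_j)/(N_i + Σ_k α_k) exactly, for any γ — a useful
conjugate sanity check. All-zero taxa are retained with a warning; their
posterior is prior-driven. One-taxon tables are rejected as degenerate.
All gamma-function terms are evaluated in log space; responsibilities via
the logistic of log-odds differences.

Known limitations: the mean-field factorisation ignores posterior
correlation between a taxon's mode indicator and its composition, which
makes γ overconfident when the data cannot separate the modes — most
visibly at m = 2, where the "other taxa" carry almost no information. The
composition posterior mean is far more robust than γ itself. No convergence
proof is claimed beyond monotone ascent of the surrogate objective.

## Imputation and posterior sampling

The posterior mean β_ij/Σ_k β_ik is the single-imputation estimate; it is
strictly positive. Multiple imputations are L independent Dirichlet(β_i)
draws — under the mean-field factorisation X is independent of δ, so this
is the full variational posterior of the composition; the mode indicators
are not resampled first. The default L = 100 balances Monte-Carlo error
against cost (20 suffices for expensive downstream engines). Posterior
predictive replicates redraw counts via Multinomial(N_i, X_i) and are
summarised by per-taxon zero proportions and count standard deviations.

Naive baselines: plain proportions; +1 pseudocount; zeros → 0.5; zeros →
N_i / max{N_k : W_kj = 0} (depth-ratio rule), each renormalised.
Preprocessing applies, in this fixed order: drop samples with fewer than
1000 reads, drop taxa below 20% prevalence (prevalence = fraction of
retained samples with a nonzero count), then winsorize each taxon column at
its 0.97 empirical quantile (linear interpolation, cap rounded to keep
counts integral). Winsorization is per taxon, matching the filtering
conventions of bias-corrected log-linear analysis.

## Synthetic data

The model-faithful generator runs the hierarchy forward and records
composition, mode assignments and hyperparameters. Its benchmark defaults
(`default_bimodal_hyperparams`) draw per taxon π ~ U(0.1, 0.9), α_0 ~
logU(0.01, 0.1), α_1 ~ logU(0.5, 20): a mixture of rare, transient and core
taxa spanning realistic abundance scales. Depths are log-uniform on
[5 × 10³, 5 × 10⁴], typical of 16S genus-level libraries.

Misspecified generators draw absolute abundances from gamma
(shape ~ U(0.3, 2)) or log-normal (σ ~ U(1, 2)) marginals with mean
abundances log-normal(0, 1.5) across taxa, correlated through a Gaussian
copula (exchangeable or AR(1)); compositions are the normalised abundances
and counts are multinomial. Poisson and negative-binomial (size 0.5)
variants draw counts directly with cell means proportional to depth, and
the recorded truth is the normalised mean-abundance vector. Two-group
designs split samples into equal halves and multiply the mean abundance of
a random ⌈proportion × m⌉ taxa by a fold-change in group 1.

What the generators do *not* emulate: taxonomic tree structure, batch
effects, sample covariates beyond the two-group label, and the heavy-tailed
template structure of real datasets. Passing tests therefore certify the
algorithmic claims (posterior accuracy, ascent, recovery, calibration,
error control under these parametric laws), not performance on any
particular real cohort.

## Evaluation metrics

Fifteen scores compare an estimated composition matrix to the truth, all
oriented "smaller is better" and aggregated by unweighted means: elementwise
MSE, mean per-sample and per-taxon Euclidean distances; mean absolute
differences of Shannon (natural log) and Simpson diversity, mean paired
Bray-Curtis, KL, Jensen-Shannon (natural log, ≤ ln 2) and Hellinger
distances; mean absolute differences of per-taxon Gini coefficients and
coefficients of variation, mean Euclidean distance of (mean, sd) pairs, mean
per-taxon two-sample Kolmogorov-Smirnov and 1-Wasserstein distances, and the
Frobenius distance between taxon-taxon Pearson correlation matrices
(Spearman optional). Conventions chosen where definitions fork: KL is
KL(truth ‖ estimate) with the estimate floored at 1e−12 (penalises
underestimating truly present taxa); standard deviations are population
(ddof 0); constant taxa contribute zero correlation; with a single sample
the correlation score is defined as 0. Each report carries the definition
strings for auditability.

## Differential abundance

The engine is deliberately a simplified member of the bias-corrected
log-linear family (it is not a reimplementation of any published tool): per
taxon, log relative abundance is regressed on the binary group; because
scaling absolute to relative abundance shifts every taxon's coefficient by
the same unknown constant, that constant is estimated as the mode of the m
coefficients (Gaussian-kernel density, Silverman bandwidth, 512-point grid)
and subtracted; t-tests on the corrected coefficients are BH-adjusted.
Zero-variance taxa receive the mean residual variance across taxa so their
inference stays defined.

For L imputations, "stacked" combination treats draws as repeated
measurements: per taxon a linear mixed model with fixed group effect and a
random intercept per sample. The design is balanced — every sample
contributes exactly L replicates and group is constant within sample — so
the REML fixed-effect estimate and standard error coincide with OLS on the
per-sample means of log abundance; the implementation uses that closed form
with df = n − 2. This df is deliberately conservative: counting the stacked
nL rows would overstate the information, since replicates of a sample share
its random intercept. Rubin combination instead runs the per-draw test and
pools with between- plus within-imputation variance and Barnard-Rubin
small-sample degrees of freedom. The shuffled-label harness measures, per
target level in 0.01–0.25, the fraction of label permutations yielding any
discovery — which under the global null equals the empirical FDR.

## Problem sizes

The validation experiments use: exact-enumeration comparison at n = 20,
m = 3 (the enumeration oracle refuses m > 15); ascent checks on ten random
datasets at n = 50, m = 20; hyperparameter recovery at n = 300, m = 30 over
five seeds; imputation benchmarking at n = 80, m = 100 over ten replicates;
predictive calibration at n = 100, m = 50 with 200 replicates; differential
abundance operating characteristics at n = 50, m = 50 with 20 imputations
over 100 replicates, and null calibration from 100 label shuffles. These
sizes reflect typical genus-level studies while keeping every experiment
reproducible in minutes on a single CPU.
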