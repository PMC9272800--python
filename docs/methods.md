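# Methods

## The model

`hicmrf` classifies the entries of an intra-chromosomal contact matrix into
a noise component, a true-signal component and (optionally) a false-signal
component.  Each retained matrix entry — a pair of genomic bins
s = {i, j} — carries a contact count y_s and four bias covariates: the
genomic distance D_s between the bin midpoints (bp), and the two-bin
averages of GC fraction (GC_s), transposable-element count (TE_s) and DNA
accessibility (ACC_s).

The observation model is a K-component mixture

    f(y_s) = alpha_1 ZIP(tau, lambda_s^(1)) + sum_{k=2}^K alpha_k Pois(lambda_s^(k)),

where the noise component is zero-inflated Poisson (probability tau of an
extra zero, so the ZIP mean is (1 - tau) lambda and its variance
lambda (1 - tau)(1 + tau lambda)), and every component mean absorbs the
systematic biases through a log-linear regression

    log lambda_s^(k) = b0^(k) + b1^(k) log D_s + b2^(k) log GC_s
                       + b3^(k) log TE_s + b4^(k) log ACC_s.

Latent component labels z_s live on the two-dimensional lattice of matrix
entries, with neighbours N_s = {(i±1, j), (i, j±1)}, and carry a K-state
Potts prior

    p(z | gamma) = C(gamma)^-1 exp(gamma * #{concordant neighbour pairs}),

which encourages spatially coherent blocks of signal (loops, domain
corners) rather than salt-and-pepper calls.  Each unordered neighbour pair
is counted once; counting it twice would only rescale gamma, and fixing
the convention makes gamma values comparable across runs.  gamma = 0 is an
independent uniform label field; gamma near 1 produces strong spatial
clustering.  The partition function C(gamma) sums over K^n label
configurations and is intractable for any realistic lattice; a brute-force
enumeration (≤ 16 sites) is provided purely as a test oracle.

The mixture weights alpha_k are not sampled separately: the Potts field is
the sole prior on the labels, and alpha is reported as the empirical label
frequency of the chain.  This keeps a single coherent generative story for
the labels while leaving alpha available for reporting and for non-spatial
simulation.

## Inference

A Metropolis-within-Gibbs sampler iterates four blocks:

1. **Labels.** A chromatic (checkerboard) Gibbs sweep: all even-parity
   sites are updated given the odd ones, then vice versa.  Within a parity
   class sites are conditionally independent, so the sweep is a valid
   systematic scan and vectorizes; categorical draws use the Gumbel-max
   trick.  The full conditional multiplies exp(gamma * n_k(s)) by the
   component emission (ZIP for k = 1, Poisson otherwise).
2. **Regression coefficients.** Per component, per coefficient random-walk
   Metropolis under normal priors, using only sites currently assigned to
   that component.  Proposal scales (default 0.05) are tuned by a
   Robbins-Monro rule toward 44% acceptance during burn-in only and frozen
   afterwards, preserving detailed balance in the retained chain.
   Proposals that push |log lambda| past a cap (default 50) are rejected;
   the cap prevents overflow while leaving extreme but finite fitted
   intercepts reachable once the covariate logs are subtracted.
3. **tau.** Data augmentation: each noise-labelled zero receives an
   extra-zero indicator Bernoulli(tau / (tau + (1 - tau) e^-lambda)),
   followed by a conjugate Beta update.
4. **gamma (ABC).** The Potts coupling's likelihood ratio involves
   C(gamma), so gamma is updated likelihood-free.  The current label field
   is the "observed data"; its sufficient statistic is the concordant
   neighbour-pair count.  A candidate is drawn from the prior, a
   pseudo-field is simulated at the candidate (fixed number of Gibbs
   sweeps, default 15, from a uniform random start), and the candidate is
   accepted when |S(pseudo) - S(observed)| falls below a tolerance set as
   the 1% empirical quantile of pilot-simulation distances (default 10
   pilot draws, refreshed every update).  Because the concordance count is
   sufficient for gamma, this ABC step is exact in the epsilon -> 0 limit.
   A tolerance quantile of 1 disables the data constraint entirely
   (epsilon = infinity), in which case accepted draws reproduce the prior —
   a property the tests exploit.  The gamma prior is Beta(10, 5) scaled to
   [0, gamma_max] (default gamma_max = 1, making the support of the
   printed Beta prior explicit).

Initialization is deterministic: labels by count quantiles with the
lowest-count fraction pi0 (default 0.6) assigned to noise, coefficients at
their prior means, tau and gamma at their prior means.  Chains are
bit-reproducible under a seed.

**Priors.**  Two modes.  *Fixed*: user-supplied normal priors per
coefficient (`informative_prior` builds the simulation-study prior, normal
and centred on the generating values).  *Empirical Bayes*: a deterministic
moment-based construction — observations are split into K strata by count
quantiles; within each stratum an OLS fit of log(y + 1) on the four log
covariates gives the prior means, with prior sds the coefficient standard
errors inflated tenfold; the tau prior reflects the overall zero fraction
with weight 0.01 per observation.  This is a declared stand-in for a
hierarchical fit: it is deliberately crude but reproducible, and its
calibration (prior means within two prior sds of the truth for >= 80% of
coefficients on simulated data) is itself under test.

**Identifiability.**  Mixture components are exchangeable a priori; after
sampling, components are ordered by their average fitted mean
lambda-bar_k = mean_s exp(x_s' b-hat_k): the smallest mean is noise, the
intermediate the true signal and the largest the false signal.  Ties
within 1e-9 raise an error rather than silently picking an order.

## Model selection

K is chosen by a deviance information criterion for latent-variable
models on the complete-data likelihood,

    DIC = -4 E_{theta,z|y}[log f(y, z | theta)] + 2 log f(y, z-hat | theta-hat),

with the expectation averaged over retained draws (labels included) and
the plug-in at posterior-mean parameters and per-site modal labels;
smaller is better.  The complete-data likelihood is the product of the
component emissions and the multinomial label-allocation probability with
empirical weights, log f(y, z | theta) = sum_s log f(y_s | z_s, theta) +
sum_k n_k log(n_k / n).  The allocation term is essential: conditioning on
labels alone rewards *any* split of the data (an extra component can
always partition the zero-inflated noise and raise the conditional
likelihood), whereas the allocation term charges the entropy cost of the
split, and only genuinely distinct components pay for themselves.  The
latent-variable DIC family has several members; this "complete-data,
plug-in at posterior mean" form is fixed here because it is cheap,
reproducible, and validated by the ordering property (the generating K
wins on simulated data in both directions) — magnitudes are not anchored
to any external reference.

## Calling and characterization

Per-pair posterior component probabilities are the label frequencies of
the retained chain, mapped to roles.  A pair is a significant interaction
when its most probable role is "signal" and that probability clears a
threshold (default 0.5); ties break toward the lower-mean role, which is
the conservative direction.  The threshold rule is the simplest one
consistent with reporting a probability per pair; it is exposed as a flag.
Characterization tallies significant calls by genomic-distance class, by
TAD co-membership (inside a TAD iff both bins lie within one common TAD
interval), and by anchor category with precedence promoter > gene > other
(promoters are excluded from the gene category by construction).

## Synthetic data

The generator reproduces exactly the structure the model assumes: labels
from either an i.i.d. multinomial(alphas) or a Gibbs-sampled Potts field
(200 burn-in sweeps by default), covariates from declared distributions,
counts from the ZIP/Poisson mixture with log-linear means.  Labels are
drawn on the full rectangular lattice and the first n_pairs row-major
sites are kept, which keeps the procedure deterministic for any
n_pairs <= rows * cols.

The default design ("noise-heavy") is the two-component simulation study:
n = 2500 pairs on a 50 x 50 lattice, alphas = (0.7, 0.3), tau = 0.3,
i.i.d. labels.  The covariate distributions, never part of the published
design, are fixed once at realistic ranges for 2 kb bins: D uniform on the
bin-distance grid {2 kb, ..., 200 kb}; GC uniform on (0.3, 0.7); TE from
Poisson(2) + 1; ACC log-normal(0, 0.5).  The generating coefficients give
noise means near 1 and signal means near 30 — count scales typical of
short-range 2 kb Hi-C — so the components are well separated.  Presets
"equal" (0.5/0.5), "signal-heavy" (0.3/0.7) and "three-component"
(0.6/0.3/0.1, false-signal mean near 300) cover the other study designs.

**What the generator does not emulate:** read-level artefacts (ligation
noise, mappability), matrix-balancing residuals, trans contacts, and the
strong empirical coupling between distance and count dispersion in real
Hi-C.  Passing recovery tests therefore demonstrates correctness of the
inference machinery under the model's own assumptions, not robustness to
real-data misspecification.

## The simulation-study prior width

The fixed informative prior used in the recovery study is N(truth, sd)
with sd = 0.015 per coefficient.  This is deliberately tight, and the
reason is an identifiability calculation, not convenience.  The GC
covariate lives on (0.3, 0.7), so log GC spans only ~0.85 with standard
deviation ~0.12; with ~750 signal-labelled sites at mean ~30 the Fisher
information for b2 gives a likelihood standard error of ~0.06, and the
noise component (ZIP, mean ~1) is several times worse.  A recovery
criterion of +-0.02 on *every* coefficient is therefore out of reach of
the likelihood alone at n = 2500 under any diffuse prior — the study is a
joint property of the data and an informative prior, and the prior width
is chosen so the prior contributes the share the criterion demands while
the likelihood still dominates the well-identified coefficients (distance
slopes, signal intercept).  The empirical-Bayes mode, with data-driven and
much wider priors, is the realistic-use path and is tested separately
under looser, qualitative criteria (calibration, calling accuracy, model
selection).

## Numerical choices and degenerate inputs

- All log-densities are computed in log space (`logaddexp`, `logsumexp`);
  tau = 0 and tau = 1 are handled exactly.
- Covariates must be strictly positive before the log transform.  The IO
  layer floors the two-bin averages at per-covariate pseudocounts — TE at
  0.5 (additive smoothing of a count), GC and ACC at 0.01 (far below any
  real value, so the floor only rescues genuinely empty bins) — and
  replaces the diagonal distance (i = j) by 0.5 * bin_size.  A single
  0.5 floor for all covariates would clobber real GC fractions, hence the
  per-covariate values.
- Dense enumeration: a region of m bins always yields m(m+1)/2 pairs
  including the diagonal, with absent pairs filled as zero counts.
- Degenerate inputs fail loudly: all-identical counts (empirical Bayes
  strata undefined), zero-variance covariates, tied component means,
  conflicting symmetric duplicates in a contact matrix, overlapping
  bedGraph intervals.
- The brute-force Potts partition oracle refuses more than 16 sites or
  ~1e6 configurations.

## Problem sizes used in the test suite

The acceptance-style checks run at the study's own scale (n = 2500) with
shortened chains where the property at stake is qualitative: the recovery
check uses 5,000 iterations / 2,500 burn-in (the full 20,000 / 10,000 run
is what `scripts/acceptance.py` performs); model-selection and calling
checks use a few hundred iterations per fit across 10 seeds, which pilot
runs showed is ample for those orderings to stabilize.  Exactness checks
against enumeration use 4-9-site lattices, where total-variation distance
can actually be estimated to the tolerance being asserted; on larger
configuration spaces the estimator's own noise floor exceeds the bound,
so the 3 x 3 sampler check compares the distribution of the Potts
sufficient statistic instead of the full joint.

## Known limitations

- The ABC pseudo-fields use a fixed, small number of Gibbs sweeps from a
  random start; near the Potts critical coupling this under-equilibrates
  and biases the summary slightly toward disorder.  The gamma posterior is
  calibrated to ~0.1 accuracy on 20 x 20 lattices, which is adequate for
  its role as a smoothing hyper-parameter.
- DIC magnitudes depend on the chosen latent-variable variant; only
  orderings are meaningful.
- The upper-triangle lattice gives diagonal-adjacent sites fewer
  neighbours; no mirror-image neighbours are imputed.
- Binary matrix formats (cool/hic) are out of scope; matrices arrive as
  sparse triplet text, and matrix balancing is deliberately absent — bias
  correction happens inside the mean model.
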