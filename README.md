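# hicmrf

Bayesian significant-interaction calling for Hi-C and micro-C contact
maps.

Chromosome-conformation-capture experiments produce a matrix of contact
counts between pairs of fixed-size genomic bins.  Deciding which entries
reflect genuine chromatin interactions — loops, promoter-enhancer
contacts, domain structure — rather than random ligation noise is
confounded by systematic biases (distance decay, GC content,
transposable-element density, chromatin accessibility) and by the extreme
zero-inflation of high-resolution maps.  `hicmrf` addresses this with a
hidden-Markov-random-field mixture model fit by MCMC, for genomicists who
want probabilistic interaction calls with explicit bias correction rather
than ratio-threshold heuristics.

## The model

Each upper-triangle matrix entry s = {i, j} carries a count y_s and four
covariates (distance D, GC, TE content, accessibility ACC).  Counts follow
a K-component mixture

    f(y_s) = α₁ ZIP(τ, λ_s⁽¹⁾) + Σ_{k=2}^K α_k Pois(λ_s⁽ᵏ⁾),

with a zero-inflated-Poisson noise component (extra-zero probability τ)
and Poisson signal components, and log-linear bias correction per
component:

    log λ_s⁽ᵏ⁾ = β₀⁽ᵏ⁾ + β₁⁽ᵏ⁾ log D_s + β₂⁽ᵏ⁾ log GC_s + β₃⁽ᵏ⁾ log TE_s + β₄⁽ᵏ⁾ log ACC_s.

Latent labels z_s live on the 2-D lattice of matrix entries and carry a
K-state Potts prior p(z|γ) ∝ exp(γ · #concordant neighbour pairs), which
favours spatially coherent signal blocks.  Because the Potts partition
function is intractable, γ is updated by Approximate Bayesian Computation
on the model's sufficient statistic; all other blocks use Gibbs or
Metropolis updates.  Components are identified post hoc by their average
fitted mean (smallest = noise, intermediate = signal, largest = false
signal), and the number of components is chosen by a latent-variable DIC.
See `docs/methods.md` for the full account.

## Worked example

Simulate the two-component study design (2,500 bin pairs, 70% noise /
30% signal, τ = 0.3) and fit it with fixed informative priors:

```python
import numpy as np
from hicmrf import (MCMCConfig, informative_prior, label_components,
                    preset_config, run_mcmc, simulate_dataset)
from hicmrf.selection import call_interactions, compute_dic

cfg = preset_config("noise-heavy", seed=7)
ds = simulate_dataset(cfg)
chain = run_mcmc(ds.observations, ds.lattice, K=2,
                 prior=informative_prior(cfg.betas),
                 cfg=MCMCConfig(iterations=2000, burn_in=1000, seed=8))
print(np.round(chain.beta_means(), 3))
roles = label_components(chain, ds.observations)
calls = call_interactions(chain, ds.observations, roles, threshold=0.5)
print(sum(c.significant for c in calls), "significant calls")
```

Output (posterior means over the retained draws, truth in comments):

```
[[ 2.704 -0.195  0.3   -0.199 -0.298]     # noise,  truth ( 2.7, -0.2, 0.3, -0.2, -0.3)
 [ 6.999 -0.299  0.403  0.097  0.202]]    # signal, truth ( 7.0, -0.3, 0.4,  0.1,  0.2)
773 significant calls
```

Every regression coefficient is recovered to within ±0.01 here; the 773
significant pairs are the sites whose posterior probability of the signal
component exceeds 0.5 (the design plants 30% signal among 2,500 pairs, and
calling recovers them with perfect label accuracy on this seed).  The
average fitted means of the two components (1.15 vs 32.9) fix the
noise/signal role assignment.

## Command line

```bash
hicmrf simulate --preset noise-heavy --seed 1 --out sim/
hicmrf fit --covariates sim/sim.covariates.tsv --lattice-shape 50,50 \
           --K 2,3 --iterations 20000 --burn-in 10000 --out fit/
hicmrf call --fit-dir fit/ --covariates sim/sim.covariates.tsv \
            --threshold 0.5 --out calls/
```

`fit` writes per-K chains, posterior summaries and a DIC table; `call`
emits BEDPE with per-pair posterior probabilities plus distance/TAD/
promoter characterization tables.  Real data enters as sparse triplet
text (from any matrix-building tool) plus a genome FASTA, TE annotation
(BED/GFF) and accessibility bedGraph, assembled per bin by
`hicmrf.io`.

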