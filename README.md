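# hierflow

Joint Bayesian gating of multi-sample flow cytometry data with a
hierarchical Gaussian mixture model.

## The problem

Flow cytometry measures a handful of markers on 10⁴–10⁶ individual cells
per sample. Grouping cells into populations ("gating") is classically done
by hand, sample by sample. Automated methods that pool samples ignore
inter-sample variation; methods that gate each sample separately share no
information. `hierflow` models all samples jointly: each cell population is
a *latent cluster* shared across samples, and each sample's realization of
it may shift in location and shape. The fitted model yields a consistent
gating of every sample, posterior probabilities that a population is
present in each sample, and direct estimates of between-sample variation.

## The model

Within sample *j*, cells follow a *K*-component Gaussian mixture plus a
broad shared outlier component:

    f(y_ij) = Σ_k π_jk N(y_ij; μ_jk, Σ_jk) + π_j0 N(y_ij; μ_0, Σ_0)

with a latent hierarchy linking components across samples,

    μ_jk | θ_k, Σ_θk ~ N(θ_k, Σ_θk),      Σ_jk | Ψ_k, ν_k ~ IW(Ψ_k, ν_k),

conjugate hyper-priors θ_k ~ N(t_k, S_k), Σ_θk ~ IW(Q_k, n_θk),
Ψ_k ~ W(H_k, n_Ψk), an exponential prior on the integers ν_k ≥ d+2,
π_j ~ Dirichlet(a), and binary activation flags Z_jk ∈ {0,1} with prior
∝ exp(−c_s Σ_k Z_jk), allowing populations to be absent from individual
samples.

Inference is blocked Gibbs sampling with conjugate conditionals, a
Metropolis step for ν_k, and reversible-jump birth/death moves for the
activation flags, run through a five-phase burn-in schedule. After
sampling, latent clusters are merged into *super clusters* (cell
populations) using the Bhattacharyya distance between moment-matched
Gaussians with two thresholds d₁ < d₂; borderline pairs are merged only if
no low-overlap 1-D projection (coordinate axes and Fisher's discriminant
coordinate) is declared multimodal by Hartigan's dip test (bootstrap
p < 0.28). A quality-control battery screens runs for convergence,
population confusion, residual multimodality and posterior-predictive fit.

## Worked example

```python
import numpy as np
from hierflow import PriorSpec, McmcConfig, run_mcmc, merge_latent_clusters, add_dither
from hierflow.synth import small_design, generate_dataset
from hierflow.evaluate import theta_coverage, center_errors, activation_rates

cfg = small_design(scale=0.15, seed=11)      # 12 samples x 2,250 cells, 3-D
samples, truth = generate_dataset(cfg)
priors = PriorSpec.from_data(samples, K=4)
trace = run_mcmc(samples, priors, McmcConfig(n_burnin=2000, n_production=2000, seed=5), K=4)

print(theta_coverage(trace, truth))    # (1.0, 12, 12)
print(center_errors(trace, truth))     # (0.0032, 0.0311)
rates = activation_rates(trace, truth)
print(rates["min_present"], rates["max_absent"])   # 1.0 0.0
```

On this run every one of the 12 latent-mean coordinates lies inside its
central 95% posterior interval; the posterior-mean component centers miss
the per-sample truth by 0.003 on average, an order of magnitude better
than the 0.031 error of using the shared latent mean for every sample
(what a model without between-sample variation could at best achieve); and
the sampler identifies exactly which samples contain which planted
populations (activation probability 1.0 where present, 0.0 where absent),
including a population holding 1% of all cells.

A command-line interface wraps the same pipeline:

```bash
hierflow simulate --design small --scale 0.1 --seed 1 --out data/
hierflow fit --input data/ --output run1/ -k 4 --seed 7
hierflow merge --run run1/ --input data/ --d1 0.1 --d2 1.0
hierflow qc --run run1/ --input data/
hierflow report --run run1/
```

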