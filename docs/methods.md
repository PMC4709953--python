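# Methods

## Model

Each of J flow cytometry samples is a Gaussian mixture over K components
plus one outlier component shared across samples. Component k of sample j
has mean μ_jk and covariance Σ_jk drawn from a latent cluster:
μ_jk ~ N(θ_k, Σ_θk) and Σ_jk ~ IW(Ψ_k, ν_k). The latent mean θ_k and the
latent covariance Ψ_k/(ν_k−d−1) describe the population itself; Σ_θk and
ν_k control how much its location and shape vary between samples (larger
ν_k means component covariances cluster more tightly around the latent
covariance). Hyper-priors are conjugate: θ_k ~ N(t_k, S_k),
Σ_θk ~ IW(Q_k, n_θk), Ψ_k ~ W(H_k, n_Ψk); ν_k carries an unnormalized
exponential mass exp(−λ_k ν) restricted to integers ν ≥ d+2 so the latent
covariance always exists (no upper truncation). Mixing proportions π_j
(including the outlier weight π_j0 at index 0) are Dirichlet(a), restricted
to the outlier plus the active set. Activation flags Z_jk indicate which
populations exist in which samples; their prior ∝ exp(−c_s ΣZ)·I(ΣZ>0) is
used unnormalized, as specified, which only shifts the joint posterior by a
constant per activation count and is exactly what the reversible-jump
acceptance ratio consumes.

Outlier parameters are fixed, not sampled: μ_0 is the pooled mean and Σ_0 a
diagonal matrix with standard deviation 3x the pooled marginal SD, a broad
noise catcher identical across samples.

The joint log posterior is assembled from exactly these factors
(`hierflow.model.log_joint_posterior`), assuming the conditional
independencies of the hierarchy; constants independent of the parameters
are dropped. Every Gibbs conditional in the sampler is consistent with this
function; the test suite checks each one against joint differences and
against brute-force discretized posteriors in d=1.

## Sampling

One sweep updates, per sample: assignments x_ij (categorical, log-sum-exp
safe), weights (Dirichlet), component parameters (normal / inverse-Wishart
conditionals; components with no assigned cells are redrawn from their
hierarchical prior); then per cluster: θ_k, Σ_θk (conjugate), Ψ_k (Wishart
conditional with degrees of freedom n_Ψk + J_k ν_k, sums over active
samples only), and ν_k by an integer Metropolis step (proposal ±U{1..2} by
default, rejected below d+2).

Activation uses a reversible-jump pair. A birth draws (μ, Σ) from the
hierarchical prior and the new weight v from the Dirichlet stick-breaking
conditional Beta(a_k, Σ_rest a), rescaling existing weights by (1−v); with
this proposal all prior, proposal and Jacobian factors cancel and the
acceptance ratio is exp(−c_s)(1−v)^{n_j}. The matching death move (allowed
only for components with no assigned cells, and never leaving a sample with
no active component) accepts with exp(+c_s)(1−π_jk)^{−n_j}. Correctness is
verified against exhaustive enumeration on a 5-event instance in which the
latent priors are made nearly degenerate so the transdimensional state
space is finite up to negligible error.

Label-switching is a Metropolis swap of two components' full per-sample
blocks (parameters, weight, activation, assignments); only the
latent-prior and Dirichlet factors change, so the swap cheaply relinks a
sample's component to a different latent cluster.

### Burn-in schedule

Five phases with lengths proportional to 4:4:1:3:4 of the burn-in budget
(config-overridable). Phase 1 tightens the location prior (n_θk x10, Q_k
/10) to force corresponding components together; phase 2 restores the
priors; at the end of phase 2, components whose pooled assignment fraction
is below 10⁻⁴ are switched off; phase 3 keeps activations frozen; phases
4–5 and production enable activation moves. Label switching is proposed
during phases 1–4 only. These defaults are this package's own calibration
of the schedule; the phase mechanics (tighten, restore, prune, freeze,
release) are the contract.

Each production iteration stores all latent and component parameters,
weights and activations, accumulates per-event assignment
responsibilities (their production average is the soft clustering w_ijk),
and draws one posterior-predictive event per sample (configurable), so a
finished trace carries n_production predictive events per sample.

### Initialization and priors from data

Initialization runs EM (scikit-learn `GaussianMixture`, 5 restarts) on a
pooled subsample (default 20,000 events); latent means start at the EM
means and per-sample components at the latent values. A user-supplied
(mean, covariance) can override individual components for informative
starts. `PriorSpec.from_data` builds weakly informative priors on
percentile-scaled data: t_k = pooled mean, S_k = 1² per marker,
E[Σ_θk] = (0.05)² per marker, n_θk = d+2+0.3·J (prior strength expressed
per sample so one setting behaves similarly across dataset sizes), H/n_Ψk
sized from a tenth of the pooled variance, λ_k = 0.1, a = 0.5 per
component, c_s = 10. c_s trades off sensitivity to small populations
against spurious activations; with Dirichlet-multinomial bookkeeping the
posterior odds of an empty component being active are roughly
exp(a_k log n_j − c_s), so the default keeps them around a per-mille for
thousands of cells per sample.

A diagonal-covariance mode switches all covariance algebra to diagonal
matrices (inverse-gamma/gamma conditionals), reducing the assignment cost
from O(n K d²) to O(n K d) per sample.

## Merging and the dip test

Super clusters are built iteratively: moment-match each current super
cluster against the pooled (dithered) events using the soft clustering;
merge the closest pair by Bhattacharyya distance if below d₁; if within
[d₁, d₂), test the pair's events (hard-assigned by maximal responsibility,
subsampled to 2,000) for unimodality on every coordinate axis whose
marginal Bhattacharyya distance exceeds d₁ (the "low overlap" criterion,
reusing the merge scale) and on Fisher's discriminant coordinate
(Σ₁+Σ₂)⁻¹(μ₁−μ₂); any projection with dip bootstrap p < 0.28 blocks the
merger. Defaults d₁ = 0.1, d₂ = 1.0 are configuration values, deliberately
exposed because the appropriate scale depends on the data distribution.
Ties in the distance ordering break toward the lowest cluster index pair.
Super-cluster distances are re-moment-matched after every merge rather
than cached.

The dip statistic is computed exactly from its definition: the smallest
half-width D such that a unimodal CDF (convex, then concave, jump allowed
only at the mode, values in [0,1]) fits inside the ±D band around the
ECDF. Feasibility at a given D is decided in linear time per sweep via
greatest-convex-minorant conditions plus minimal/maximal branch-end values
from tangent-slope line envelopes, and D is found by bisection to 10⁻¹¹.
The test suite pins this against an independent linear-programming oracle
of the same definition (100 random samples, agreement to 10⁻⁸) and against
closed forms (equally spaced points: 1/(2n); balanced two-atom sample:
1/4). P-values come from 1,000 uniform bootstrap replicates of the same
size; the replicate table is cached per sample size within a process.
Before any dip test the data are dithered with Gaussian noise of sd 0.003
(in percentile-scaled units), because digitized measurements produce
striped patterns that the dip test mistakes for multimodality.

## Quality control

Scalar checks, each also retained as a plot: (1) Geweke-style z-scores per
latent-mean coordinate (spectral variance at frequency zero; |z| > 3
flags); (2) separation — each sample component must be closer (in both
Bhattacharyya and Euclidean distance) to its own latent component than to
any latent component outside its super cluster; (3) dip tests per super
cluster and axis at the merge threshold p < 0.28; (4) total-variation
distances between observed and posterior-predictive 1-D and 2-D histograms
(advisory, no auto-fail); (5) robust-z flags for outlying component
centers (advisory). `overall_pass` is the conjunction of the enforced
checks, so adding a failing check can never turn a failing report into a
passing one. There is no automated accept/rerun loop; failed runs are
meant to be rerun manually, possibly with different settings.

## Evaluation metrics

The F-measure against a reference gating follows the population-weighted
convention: for each reference population the best-matching predicted
cluster by F(r,c) = 2PR/(P+R) is found, and the overall score is the
population-size-weighted average; events the reference leaves unlabeled
are excluded by default (configurable), since reference gatings may or may
not label noise. Population-size similarity between samples uses the l1
distance between per-sample population-proportion vectors, split into
within-donor and between-donor pairs.

## Synthetic data

The generator draws from exactly the model the sampler assumes (latent
clusters fixed, per-sample parameters from the hierarchy, events from the
mixtures), which is what makes parameter-recovery claims meaningful: a
passing recovery test shows the inference machinery is correct under the
model, not that the model fits any particular instrument's output. Real
data depart from the generator through non-Gaussian populations, spillover
artifacts, digitization and acquisition drift; of these only digitization
is emulated (via the dither step's rationale), so conclusions about real
data rest on the merging and QC stages rather than on these simulations.

Committed designs: the small design (3 dimensions, 4 latent clusters, 80
samples x 15,000 cells = 1.2 million events; one cluster in only 8 samples
holding 1% of all cells, another in 24 samples at 10%) and the large
design (8 dimensions, 11 latent clusters, 192 samples x 150,000 cells;
4 clusters missing in half the samples). Both accept a `scale` factor that
shrinks J and n proportionally while preserving presence counts (at least
one sample) and total cell shares — within-sample weights of pinned
clusters are share·J/J_k, so the rare cluster keeps 1% of all cells at any
scale. Defaults chosen once for realism on percentile-scaled data: latent
means separated by at least 0.35 in the unit box, within-cluster sd
0.04–0.08, between-sample location sd 0.02, ν = 35 (or drawn from
U{25..45}), Dirichlet weight concentration 200. Cluster placement and
shapes are drawn from the seed, so every dataset is reproducible byte for
byte.

## Problem sizes used in the checked examples

The recovery, pooling and activation checks run the small design at scale
0.15 (12 samples x 2,250 cells, 3 dimensions, 4 clusters, rare share
preserved) with 2,000 burn-in and 2,000 production iterations — the same
configuration `scripts/acceptance.py` reruns, chosen as a desk-scale
analog that preserves the design's structure. The full-scale designs
(1.2M and 28.8M events) remain available through `scale=1`.

## Numerical choices

One Cholesky factorization per covariance per update; non-SPD inputs raise
a dedicated error rather than LinAlgError. Categorical sampling uses the
Gumbel-max trick on log densities (no raw exponentials). Singular
inverse-Wishart scale matrices are retried with trace-scaled jitter (3
attempts, logged). The joint log posterior is evaluated every 500
iterations; a non-finite value aborts with a diagnostic dump of the
current state. All randomness in a run flows from one integer seed
(`numpy.random.default_rng`); dataset generation holds its own seed.

## Known limitations

Heavy-tailed or skewed populations are represented by merged Gaussian
components, not t or skew components. The sampler is single-machine;
there is no multi-node or GPU path. Merging quality depends on the soft
clustering actually visited by the chain; a chain stuck in a poor labeling
passes its uncertainty to the merge step (the QC battery, not the merge
itself, is the guard). FCS reading covers the common single-dataset
float/double/integer list-mode layout only. With more than ~20 markers a
full-covariance Gaussian mixture becomes statistically fragile; the
diagonal mode mitigates cost but not the underlying dimensionality
problem.
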