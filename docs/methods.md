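# Methods

This note documents the models, numerical choices and known limitations of
`cochlevo`. Notation: a rooted ultrametric phylogeny with branch lengths in
million years (My); one continuous trait value per tip; all trait logs are
base 10.

## Morphometrics

**Membrane length.** The basilar membrane is represented by an ordered 3D
landmark path from base to apex; its length is the sum of Euclidean
distances between consecutive landmarks. This chord-length estimate is a
strict lower bound on the arc length of the underlying smooth curve and
converges from below under refinement; at 86 roughly equidistant landmarks
the shortfall on realistic cochlear spirals is below 0.5%, and at 43
landmarks it is on the order of a few percent (both checked against a
dense-quadrature oracle in the test suite).

**Turn counting.** The path is projected along a caller-supplied modiolar
("apical view") axis. The primary estimate is the cumulative winding angle
about the spiral centre divided by 360°, reported to the nearest quarter
turn. The centre is estimated from the path itself: arcs under one
revolution use a Kasa circle fit; longer spirals are refined iteratively by
regressing the measured radius on `(1, θ, cos θ, sin θ)` — a centre offset
appears as the cos/sin ripple — which converges for archimedean-like paths
including ones that begin at the centre. Points within 1% of the maximum
radius of the centre are excluded from the winding sum (their bearing is
numerically unstable and the true arc they subtend is negligible for
cochlear geometry). A secondary estimator counts crossings of the full line
through the basal (round-window) landmark and the centre — the manual
convention — and the two must agree within a quarter turn or a geometry
error is raised; an endpoint lying exactly on the line counts as half a
crossing. The estimators are validated against each other on noise-free
spirals of 0.5–4.25 turns, the published mammalian range.

**Relative membrane length** is `length / mass^(1/3)` (mm·g^(-1/3)). The
exact cube root is the default; 0.33 is accepted for compatibility with
rounded published usage (differences are sub-1% over mammalian masses).

## Allometry

OLS of log membrane length on log cube-root mass over a caller-supplied
reference mask (e.g. non-echolocating placentals); the fitting itself is
delegated to statsmodels, and the stored fit (coefficients, RSE, df,
(X'X)⁻¹) suffices to reproduce predictions without the data. Prediction —
not confidence — intervals: `ŷ ± t(1−α/2, df)·RSE·√(1 + x₀'(X'X)⁻¹x₀)`,
default level 0.95. Species are classified above/within/below their own
interval; points numerically on a bound (within 1e-9 relative) count as
within, so noise-free data classify as "within" rather than flipping on
float error. Degenerate fits (RSE ≈ 0) return width-zero intervals with a
warning.

## Brownian-motion machinery

Under BM with rate σ² the tip covariance is σ²C with `C[i,j]` the shared
root-to-MRCA path length. Pagel's λ multiplies the off-diagonal entries
only; as a tree transformation this is: scale every branch by λ, then
extend each tip branch by `(1−λ)·depth`, so tip variances are untouched.

Two independent likelihood routes are maintained and cross-checked to 1e-8:
the O(n) contrast (pruning) factorisation, using the tree-determinant
identity `det C = v_root·∏V_k`, and the dense multivariate-normal
evaluation via Cholesky. ML estimates use the n-denominator rate
`σ̂² = Σu²_k/n`; the REML-unbiased contrast estimator `Σu²_k/(n−1)` is
exposed separately and verified unbiased by simulation.

**Ancestral states.** Point estimates are the GLS conditional expectations
under a flat root prior. They are computed two ways: linear-time Gaussian
message passing on the tree (the re-rooted-contrast construction, tagged
"PIC") and dense GLS ("ML"); the pair is a built-in oracle and agrees to
numerical precision at every node. Standard errors are
conditional-on-tips standard deviations, including the root-mean
uncertainty term, scaled by the ML rate; for a constant trait they approach
zero. Polytomies are accepted (contrasts resolve them arbitrarily with
zero-length branches, with a warning; the message-passing and GLS routes
handle them natively).

**Pagel's λ** is profiled over [0,1] by bounded scalar searches from
multiple brackets ((0,.5), (.5,1), (0,1), plus both endpoints; tolerance
1e-6), guarding against rare multimodal profiles. LR statistics against
λ=0 and λ=1 are referred to χ²(1) even at the λ=1 boundary, matching the
convention of the standard comparative tooling; this is conservative there
(the boundary null is a 50:50 mixture of χ²(0) and χ²(1)), which the
recovery simulations confirm (rejection of a true λ=1 well below nominal).
Fewer than 10 tips triggers a weak-identification warning.

## Phylogenetic regression

**PGLS** whitens by the Cholesky factor of C(λ) and solves OLS in the
whitened space; λ may be fixed or profiled by ML. On an ultrametric tree
C(0) is a scalar matrix, so λ=0 reproduces OLS coefficients exactly.

**BPMM.** The animal-model form `y = Xβ + u + e` with `u ~ N(0, σ²ₚC)`,
`e ~ N(0, σ²ₑI)`; C is normalised by tree depth so the variance components
are on the response scale. Priors: improper flat on β, inverse-gamma
(shape 0.001, scale 0.001) on both variances — the customary weak setting,
exposed as parameters, standing in for unavailable original settings. The
Gibbs sampler rotates u into the eigenbasis of C, where its full
conditional is diagonal, giving O(n²) sweeps; defaults are 13,000
iterations, 3,000 burn-in, thinning 10 (1,000 draws). Convergence is
monitored by a split-chain R̂ per parameter (warning above 1.1; results are
still returned). pMCMC is `2·min(P(>0), P(<0))`, clamped below at
2/n_draws — a tail is never estimated as exactly zero from finite draws.
DIC uses the conditional-deviance convention
`2·mean(D) − D(posterior means)`, and ΔDIC ≥ 2 flags a significant
improvement (sign convention: `delta = DIC_a − DIC_b`, positive when model
b is better).

## Rate-shift detection

The trait follows BM with branch-specific rates: branch variance is
`rate × length`. Rates are organised by clade-wise shifts: a shift **at**
node v assigns a new rate to the branches descending from v (inherited
until overridden by a deeper shift); v's own stem branch keeps the
ancestral rate, because the shift is the event at v. A consequence is that
tips are not eligible shift locations — a terminal-branch rate change can
only be expressed together with its sibling. The likelihood is the
restricted (contrast) BM likelihood on the rate-rescaled tree, which is
independent of the unknown root state and costs O(n) per evaluation.

Priors: shift count Poisson(mean 1) truncated at the number of eligible
nodes, with locations uniform over subsets; log rates (base and shifts)
Normal(μ₀, 2²) with μ₀ the log of the pooled contrast rate estimate — a
weak empirical-Bayes centring that keeps the sampler scale-free. Moves and
their default weights: rate update 0.45 (log-scale random walk, sd 0.5),
shift birth 0.2 (rate drawn from the prior, which cancels in the
acceptance ratio), shift death 0.2, shift relocation 0.15 (uniform among
free nodes, fully symmetric). Acceptance ratios for birth/death reduce to
`likelihood ratio × λ_Poisson/(k+1) × w_death/w_birth` and its inverse;
the test suite verifies forward/reverse antisymmetry of the log ratios to
1e-10 and that disabling trans-dimensional moves recovers the single-rate
ML estimate. Desk-scale default chains are 200,000 generations sampled
every 200 with 25% burn-in (the production scale of 4,000,000 / 4,000 is
the CLI's `--paper-scale`). Reported quantities: per-node posterior shift
probability (significant above 0.95) and model-averaged per-branch rates,
with shift direction judged against the tree-wide median branch rate.

A known operating characteristic, established by simulation with known
truth: for a ×10-rate 16-tip clade on a 64-tip tree, the posterior
probability at the exact stem node typically reaches 0.95 but honestly
falls short in roughly a third of replicates, because alternative
configurations that carve the clade into two or more rate classes can fit
chance heterogeneity among the ~15 within-clade contrasts; profile
likelihoods confirm the posterior is faithful to the data in those cases.
False positives on single-rate data are rare (no node approaches the 0.95
threshold in null simulations).

## Synthetic data

The generator produces the statistical structure the pipeline assumes, with
every parameter recorded for recovery tests, and all outputs
bit-reproducible given (config, seed).

* **Trees.** Pure-birth (Yule) simulation conditioned on n tips, rescaled
  to a fixed chronogram depth (default 64 My); mean root heights match the
  Yule closed form Σ 1/(λk). A fully balanced equal-branch tree is provided
  as a maximally regular testbed (used for the rate-shift positive control,
  where every clade has a stem of known length).
* **Traits.** Body mass: BM on log10 grams, root ~20 g, rate sized so tip
  masses spread with sd ≈ 1.5 log10 units over the tree — a cross-mammal
  compilation spanning grams to tonnes, as in comparative allometries that
  include both small bats and large cetartiodactyls. Membrane length: the
  allometric line (slope 0.498, intercept 0.717 on log10 mass^(1/3)) plus
  a +0.12 log10 offset for echolocators (~+32%), a BM deviation (λ-dilution
  and clade rate multipliers supported, with the same at-node semantics as
  the rate-shift model), and iid noise (sd 0.02). The echolocator group is
  the root-child clade closest to half the species, so group and phylogeny
  are confounded exactly as in real data. Turns follow the cross-mammal
  relationship on log relative membrane length (slope 0.123, intercept
  0.342, noise 0.08), quarter-rounded. Call frequencies follow the built-in
  phylogenetic coefficient set plus log-normal noise, echolocators only.
* **Landmark spirals.** Tapered helices sampled at approximately equal arc
  increments, with the true arc length computed by 1e5-segment quadrature
  and returned as an oracle.
* **Audiogram calibrations.** Synthetic generative curves (declared as such
  in the source): high-frequency limits decline with log relative membrane
  length, low-frequency limits with log(membrane)×turns, scaled so a
  bat-ancestor-like cochlea hears to ~100 kHz at 60 dB and down to ~1 kHz.
  They are not fitted to any published audiogram set, so tests against them
  demonstrate calibration *mechanics* (exact noise-free recovery,
  CI coverage under noise), not real mammalian hearing curves.

What passing tests on these data do **not** show: robustness to measurement
error in landmarks, non-BM trait evolution (OU, early bursts), imbalanced
real topologies, or the paper-specific species values (the published
per-species matrix is not machine-readable, which is also why Fig-1-level
coefficients are checked structurally rather than numerically).

## Hearing and call-frequency prediction

Call-frequency models are per-parameter (min/peak/max) regressions of log10
frequency on log10 **absolute** membrane length (mm) and log10 turns; the
absolute reading is used because only it reproduces the published ancestral
predictions (~40/~50/~65 kHz) from the published ancestral morphology —
the relative-length reading gives ~92 kHz for the minimum. Two published
coefficient sets ship as JSON data files (`davies2013_phylo`, used by
default, and the non-phylogenetic `davies2013_ols`). Audiogram calibration
fits four OLS regressions (30/60 dB high limits on log relative membrane
length; 30/60 dB low limits on the log(membrane)×turns product — the
factor-logging convention is configurable since the published form is
loose; unlogged turns is the default). Predicted minimum exceeding the
predicted maximum triggers a warning (extrapolation outside calibration),
not an error.

## Pipeline and reproducibility

The CLI wraps the library stage by stage; `cochlevo run` executes a YAML
config in dependency order and writes a manifest with SHA-256 hashes of all
inputs, every stage's parameters and the produced files, so silent input
changes are detectable across reruns. Config validation (structure, paths,
mandatory seed for stochastic stages) happens before any stage runs;
validation is explicit Python rather than a schema engine, with the same
contract. All randomness flows through `numpy.random.default_rng(seed)`;
identical config and seed reproduce stochastic outputs bit-identically.

Problem sizes used by the automated checks — 200-tip trees for λ recovery
(50 replicates), 64-tip trees and 200,000-generation chains for rate-shift
operating characteristics, 200-species datasets for end-to-end recovery —
were chosen as the smallest at which the statistical behaviour under test
is stable.
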