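# Methods

## Model

Each node i of a symmetric, non-negative weighted graph C carries a binary unit
S_i ∈ {0, 1}. Single-site (heat-bath / Glauber) dynamics resample one uniformly
random site per step to 1 with probability g(W Σ_j C_ij S_j − θ̃), where
g(x) = 1/(1 + e^(−εx)), W scales the coupling, θ̃ is the activation threshold
and ε is an inverse temperature. For symmetric C the stationary distribution is
the Boltzmann–Gibbs law P(S) ∝ exp(−ε H(S)) with

    H(S) = c_θ Σ_i S_i − ½ W Σ_{i,j} C_ij S_i S_j   (double sum over ordered pairs).

The model statement that motivates this package contains a θ-vs-θ/2
inconsistency between its update rule and its energy function. We resolve it
explicitly rather than silently:

- The analytics default to the **half-theta** energy, c_θ = θ/2
  (`energy_convention="half_theta"`); a `full_theta` variant (c_θ = θ) is
  provided for sensitivity checks.
- The simulator's default mode is **energy_consistent**, θ̃ = θ/2, the
  heat-bath rule whose stationary law is exactly the half-theta Boltzmann
  distribution — so simulation and enumeration agree and can cross-validate.
  A `paper_literal` mode, θ̃ = θ, keeps the unhalved threshold of the update
  rule as written. The two coincide at θ = 0.

The attractor-landscape entropy is the Shannon entropy of P in nats, computed
through the identity E = ε⟨H⟩ + ln Z, which the implementation also verifies
numerically (it holds to 1e−9 at every sweep point).

## Parameters

| parameter | default | meaning |
|---|---|---|
| θ | 12 | activation threshold (dimensionless); the reference operating point |
| W | 1, swept on a grid | global coupling scale on C |
| ε | 1 | inverse temperature; no canonical value exists for this model, so it defaults to 1 and is always explicit in configs and logs |
| energy_convention | half_theta | see above |
| enumeration cap | N ≤ 28 | larger systems require explicit node subsampling |
| chunk size | 2^16 states | streamed enumeration granularity |

Entropy sweeps default to W ∈ [0, 8] on 33 points (41 points to 10 in the
acceptance checks); with θ = 12 and binary graphs of mean degree ≈ 4 this
brackets the full low–high–low entropy curve, since the all-active state
becomes the ground state near W ≈ θN/(2·edges) ≈ 3.

## Exact enumeration

All 2^N bitmasks are streamed in chunks. Per state the activity count
s = Σ_i S_i and quadratic form q = SᵀCS depend only on the graph, so one
enumeration pass serves an entire W grid (energies are H = c_θ s − ½ W q).
Accumulation uses a running-maximum log-sum-exp: partial sums of
w = exp(−εH − M) are rescaled whenever a new chunk raises the maximum M, so
εH in the hundreds cannot overflow. Marginals P(S_i = 1) and pairwise joints
P(S_i = 1, S_j = 1) are accumulated in the same pass as weighted bit sums.
Entropies that round to small negative values (beyond −1e−9) raise rather than
clamp; values in (−1e−9, 0) are clamped to 0 (frozen states).

## Edge of bifurcation

Given a sweep (W_k, E_k), W* is the grid point with the largest forward
difference ΔE/ΔW among points at or below the entropy argmax, ties toward
smaller W. Flat sweeps and sweeps whose maximum sits at the first grid point
are rejected. This is a grid-resolution-limited estimate of where the entropy
begins its rapid rise; an optional offset lets callers probe slightly before
or after it.

## Pairwise statistics

Because P is exact, mutual information and Pearson correlation between spins
are computed exactly from each pair's 2×2 joint distribution. Fréchet bounds
are enforced on the joint before forming the four cells, so float round-off at
saturated marginals (P ≈ 0 or 1) cannot create negative cell masses; cells or
products that underflow to zero contribute zero. The MI matrix stores marginal
entropies on its diagonal (a convenient normalizer, excluded from pooled
distributions); correlations involving a zero-variance node are defined as 0
rather than NaN so that pooled distributions at extreme couplings stay finite.

## Graph ensembles

Regular, small-world and random graphs come from the Watts–Strogatz
construction (ring lattice of the even degree nearest the target mean degree,
rewired with P = 0, 0.25, 1 respectively); scale-free graphs from
Barabási–Albert preferential attachment with m chosen so m(N−m) is nearest the
target edge count. Since none of these hits an arbitrary edge count exactly
(e.g. 38 edges at N = 20), every instance is post-edited by uniformly random
single-edge additions/deletions to the exact target, with deletions that would
disconnect the graph rejected and resampled; the edit count is recorded in
ensemble manifests. Size sweeps hold the mean degree at 3.8 (edges =
round(1.9·N)), so sparsity does not drive size comparisons. Per-instance seeds
derive deterministically from (ensemble seed, instance index) via
`numpy.random.SeedSequence`.

## Power-law fitting

The Clauset–Shalizi–Newman procedure: for each candidate threshold xmin (every
distinct data value with at least `min_tail` = 10 points above it), the
continuous MLE γ̂ = 1 + n/Σ ln(x_i/xmin) (discrete variant: xmin − ½ shift) and
the KS distance between empirical and fitted tail CDFs; the KS-minimizing xmin
wins, ties toward smaller xmin. Goodness of fit is a semiparametric bootstrap
(body resampled empirically below xmin, tail drawn from the fitted law, full
re-scan per replicate; default 1000 replicates, 100 at desk scale). One known
property of the free-xmin scan deserves note: on data that are not power laws
(e.g. exponential), the scan can retreat into a far tail of a few dozen points
where a power law is locally adequate, yielding a non-significant p; forcing a
substantial tail (larger `min_tail`) restores power against such alternatives.
Zeros (e.g. leaf-node betweenness) must be excluded before fitting; the CLI
does this and logs the count.

## Synthetic connectomes and FC

The generator emulates, at desk scale, the organisation visible in human
cortical connectivity matrices: modules denser inside than between
(p_intra = 0.9 vs p_inter = 0.15), a mirrored two-hemisphere layout in which
node i and node i + N/2 are homotopic counterparts with identical
intra-hemisphere weights, homotopic links present with probability 0.9 and all
cross-hemisphere weights attenuated ×0.5, hub nodes with +0.4 attachment
probability, and log-normal(0, 0.5) weights. The default configuration —
N = 16, 4 modules, 2 hubs, mirrored — is chosen to be exactly enumerable in
tests while retaining all qualitative features. It does **not** reproduce the
quantitative weight distribution, spatial embedding, or distance-dependent
connection probabilities of real tractography data, so passing tests demonstrate
pipeline correctness and qualitative behaviour, not empirical fidelity.

Synthetic "empirical" FC perturbs the exact model FC of a ground-truth
connectome on the Fisher-z scale (keeping values inside (−1, 1) without
truncation artifacts), then symmetrizes and sets the diagonal to 1. The null
model for recovery experiments is a degree-preserving rewiring of the true
connectome (connectivity-preserving double-edge swaps, 10 per edge, original
weight multiset reassigned at random).

## Problem sizes and test design

Exact enumeration is O(2^N), so the package's study conditions are desk-scale
by design: topology comparisons use 20-instance ensembles of 16-node graphs at
30 edges (mean degree 3.8, the same as the 20-node/38-edge reference
configuration, which is also supported), size sweeps use N ∈ {10, 14, 18},
Glauber cross-checks use 60 000 sweeps on 10 and 6 nodes, and fitter
calibration uses 20 datasets of 2000 samples with 100 bootstrap replicates.
Glauber/exact comparisons run at θ = 2 rather than 12 so that marginals are
far from 0/1 and the comparison is informative. All stochastic tests fix their
seeds.

## Known limitations

- The independent-spin entropy floor: at W = 0 the entropy is exactly
  N·h(1/(1 + e^(εθ/2))) under the half-theta convention (≈ 0.277 nats at
  N = 16, θ = 12, ε = 1). The low-coupling end of an entropy curve therefore
  cannot fall below this floor, which at desk-scale N is a non-negligible
  fraction (≈ 6–20%) of the curve maximum; "entropy ≈ 0 at both extremes" is
  strictly true only asymptotically in θ or under the full-theta convention.
- Enumeration caps at N = 28; hemisphere-scale (N = 33) empirical matrices
  must be node-subsampled, which perturbs both entropy and FC estimates.
- W* is grid-quantized; FC at the edge of bifurcation inherits that
  resolution.
- The discrete power-law variant uses the standard xmin − ½ continuous
  approximation for both MLE and CDF, adequate for tails with xmin ≳ 6 but
  approximate below.
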