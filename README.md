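# isingnet

Exact Ising-spin attractor-landscape analysis of brain-like networks.

## The problem

Resting-state fMRI reveals coherent networks of brain areas whose spontaneous
activity is correlated, and these patterns are strongly shaped by the anatomical
(white-matter) wiring between areas. A minimal, analytically tractable way to
study this structure–dynamics relationship is to place a stochastic binary unit
("spin") S_i ∈ {0, 1} on every node of a connectivity graph C and let the units
evolve under single-site Glauber dynamics. For symmetric couplings the
stationary distribution over global states S is the Boltzmann–Gibbs law

    P(S) = exp(−ε H(S)) / Z,
    H(S) = ½ θ Σ_i S_i − ½ W Σ_{i,j} C_ij S_i S_j,

with threshold θ, global coupling W, inverse temperature ε, and partition
function Z = Σ_S exp(−ε H(S)). Because P is known in closed form, everything
about the equilibrium — the Shannon entropy of the state distribution
E = ε⟨H⟩ + ln Z (the "attractor-landscape entropy", a measure of how rich the
network's repertoire of likely activity patterns is), exact per-node marginals,
and exact pairwise mutual information and correlation — can be computed by
enumerating the 2^N states. No sampling, no mean-field approximation.

`isingnet` implements this analysis for networks up to N = 28 nodes:

- **Entropy-vs-coupling sweeps.** As W grows the system passes from a single
  quiescent state (all spins 0, low entropy) through a multistable region
  (many competing activity patterns, high entropy) to a single saturated state
  (all spins 1, low entropy). The coupling where entropy starts its rapid rise
  — the *edge of bifurcation* — is the regime relevant for resting-state
  dynamics, and the package locates it from the sweep.
- **Topology comparisons.** Ensembles of regular, small-world (Watts–Strogatz,
  rewiring probability P = 0.25), random (P = 1) and scale-free
  (Barabási–Albert) graphs at exactly matched node and edge counts, to test how
  architecture — in particular the hubs of scale-free graphs — shapes the
  maximal attainable entropy.
- **Model functional connectivity.** The exact spin-correlation matrix at the
  edge of bifurcation, compared against an empirical (or synthetic) FC matrix
  by Pearson correlation over the strict upper triangle.
- **Glauber simulation** as an independent cross-check of the exact analytics.
- **Power-law diagnostics.** Clauset-type maximum-likelihood tail fitting with
  KS threshold selection and semiparametric bootstrap goodness-of-fit, for
  betweenness-centrality and pooled mutual-information distributions.
- **Synthetic data.** A generator for modular, hemispherically mirrored,
  hub-containing weighted connectomes and noisy FC matrices with known ground
  truth, so the entire pipeline is testable without any external data.

Empirical structural/functional matrices (e.g. a 66-area diffusion-tractography
parcellation split into two 33-node hemispheres) can be supplied as plain CSV /
TSV / edge-list files; they are optional inputs, not bundled data.

## Worked example

```python
import numpy as np
from isingnet import (IsingParams, SynthConnectomeSpec, fc_pattern_correlation,
                      find_edge_of_bifurcation, entropy_sweep, model_fc,
                      synth_connectome, synth_empirical_fc)

params = IsingParams()            # W=1, theta=12, epsilon=1, half-theta energy
sc = synth_connectome(SynthConnectomeSpec(seed=0))   # 16-node mirrored connectome
sweep = entropy_sweep(sc, params, np.linspace(0, 8, 33))
w_star = find_edge_of_bifurcation(sweep)
print(f"entropy max  : {sweep['entropy'].max():.3f} nats at W = "
      f"{sweep.loc[sweep['entropy'].idxmax(), 'W']:g}")
print(f"edge of bifurcation W* = {w_star:g}")

fc_model, _ = model_fc(sc, params)
fc_noisy = synth_empirical_fc(sc, params, noise_sd=0.2, seed=1, model=fc_model)
r = fc_pattern_correlation(fc_model, fc_noisy)
print(f"model-vs-noisy FC pattern correlation = {r:.3f}")
```

prints

```
entropy max  : 2.949 nats at W = 2
edge of bifurcation W* = 1.75
model-vs-noisy FC pattern correlation = 0.504
```

Reading: sweeping the global coupling on this 16-node modular connectome, the
state-distribution entropy peaks at 2.95 nats around W = 2; the steepest rise
of the curve — the edge of bifurcation, where resting-state-like correlation
structure emerges — sits at W* = 1.75. The exact correlation matrix computed
there, compared with a noisy surrogate of itself (Gaussian noise of sd 0.2 on
the Fisher-z scale), retains a pattern correlation of 0.50 over node pairs.

The same stages are available from the shell:

```bash
isingnet synth --nodes 16 --seed 0 --out-dir out/synth
isingnet sweep --connectome out/synth/sc.csv --out out/sweep.tsv
isingnet compare-fc --sc out/synth/sc.csv --fc out/synth/fc.csv --out out/report.json
isingnet ensemble-sweep --topology scale-free -n 16 -e 30 --instances 20 --out out/sf.tsv
```

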