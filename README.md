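# mepkit

Pathway energetics for conformational transitions, at desk scale: the
mean-forces string method for minimum free-energy paths, umbrella sampling
with MBAR reweighting along a path progress coordinate, alchemical
free-energy estimators with a double-decoupling binding cycle, and
allosteric-coupling maps from reactive-trajectory resampling plus Kraskov
k-nearest-neighbor mutual information.

Large membrane transporters such as AcrB convert a proton-gradient into drug
efflux through cyclic conformational changes of their protomers.  Studying
such transitions computationally combines several statistical machines: a
discretized pathway of M images `x_1 … x_M` in collective-variable space is
relaxed toward the minimum free-energy path by iterating

    x_i  ←  x_i + Δτ · k_r(⟨x⟩_i − x_i),     then smooth, then reparameterize,

where `k_r(⟨x⟩_i − x_i)` is the mean force from a harmonically restrained
window at image i; window data are reweighted with MBAR to the unbiased
ensemble and binned along the progress coordinate inside a "reactive tube"
(orthogonal squared distance below a cutoff) to give a free-energy profile
F(s); absolute binding free energies follow from two alchemical decoupling
legs, ΔG_bind = ΔG_site − ΔG_solv, estimated by EXP (Zwanzig) or BAR; and
inter-domain coupling is read off the mutual information
MI = ∫∫ p(r₁,r₂) ln [p(r₁,r₂)/(p(r₁)p(r₂))] dr₁dr₂ between group
center-of-mass coordinates over resampled reactive trajectories, estimated
without binning from k-NN distances.

`mepkit` implements all of this against synthetic dynamics — restrained
Metropolis-adjusted Langevin sampling on analytic potentials (Müller–Brown,
double well, …), λ-coupled toy models with closed-form ΔF, and Gaussian
coordinate ensembles with planted correlations — so every stage is
validated against an exact or independent reference.  It is aimed at method
developers and students who want a transparent, fully testable
implementation of this workflow rather than a cluster-scale MD pipeline.

## Worked example

Stratified decoupling of a toy ligand (a spring whose constant is
λ-interpolated from 1 to 4, kT = 1) over 25 stages, estimated both ways:

```python
import numpy as np
import mepkit as mk
from mepkit.alchemy import exp_fep, bar_estimate, staged_decoupling

site = staged_decoupling("harmonic_k_change", n_states=26, n_per_state=1000,
                         seed=1, k0=1.0, k1=4.0)
est = exp_fep(site)
print(f"EXP: dF = {est.dF:.4f} +/- {est.se:.4f} kT   (analytic {site.analytic_dF:.4f})")
b = bar_estimate(site)
print(f"BAR: dF = {b.dF:.4f} +/- {b.se:.4f} kT")

rng = np.random.default_rng(0)
x = rng.standard_normal(4000)
y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(4000)
print(f"MI(rho=0.9) = {mk.kraskov_mi(x, y, k=3):.4f} nats   "
      f"(exact {-0.5 * np.log(1 - 0.81):.4f})")
```

prints

```
EXP: dF = 0.6885 +/- 0.0066 kT   (analytic 0.6931)
BAR: dF = 0.6918 +/- 0.0047 kT
MI(rho=0.9) = 0.8396 nats   (exact 0.8304)
```

The EXP and BAR totals agree with the partition-function ratio
kT·ln(4)/2 = 0.6931 within their standard errors (BAR, using both
directions, is the tighter estimate), and the k-NN mutual information
recovers the bivariate-Gaussian value −½ln(1−ρ²) to within its ~0.01 nat
estimator noise at n = 4000.

The full toy pipeline — steered initial path on the Müller–Brown surface,
string optimization, umbrella/MBAR profile, alchemical legs, MI matrix —
runs from the command line:

```sh
mepkit run --seed 1 --out runs/demo          # all stages, resumable
mepkit pmf --seed 1 --out runs/demo          # just through the profile
```

Each stage writes CSV artifacts plus a JSON sidecar carrying the
configuration hash; rerunning with the same config and seed reproduces
every CSV byte-for-byte, and a changed config refuses to resume onto stale
artifacts.

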