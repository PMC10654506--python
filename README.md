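# retinotile

Single-cell retinotopy analysis for topographic projections: how precisely
do the axon terminals of retinal ganglion cells (RGCs) — and the superior
colliculus (SC) neurons they innervate — tile their target so that
neighboring cells in the retina stay neighbors in the brain?

The package is written for systems neuroscientists with paired
anatomical/functional point data (cell or axon-patch centroids in μm,
receptive-field centers in visual degrees, from two-photon calcium
imaging): it quantifies local map precision, and inverts a generative model
of the projection to turn an observed precision into circuit parameters.

## What it computes

**Tiling-pattern match.** For two point patterns paired by cell id, the
Delaunay triangulation is computed in each space and edges are compared as
id pairs:

&nbsp;&nbsp;&nbsp;&nbsp;match = 100 · |E_a ∩ E_b| / mean(|E_a|, |E_b|) &nbsp; [%]

with a permutation bootstrap (10,000 relabelings, threshold at the 95th
percentile) for the chance level, and a least-squares affine registration
whose per-point residuals Δᵢ (summarized median ± MAD) measure each cell's
deviation from its topographically ideal position.

**Generative model and inversion.** RGC RF centers are a jittered
hexagonal lattice (spacing L = 7.2°, jitter SD 0.1 L); their axons are the
same lattice rescaled to L = 100 μm plus Gaussian projection jitter
N[0, σ²]; SC somata are an independent 56 μm lattice; each SC neuron
integrates its k nearest axons (k ~ zero-truncated Poisson, mean λ) with
weights from the dendritic-field/axonal-field disk overlap (radius 200 μm /
diameter 135 μm). Sweeping σ (0–50 μm) and λ (1–10) and inverting the
median match-vs-parameter curves at observed match levels yields σ̂ and λ̂
with simulation-band 95% CIs.

**Receptive fields.** Reverse correlation of deconvolved activity against
binary checkerboard noise (3.7° × 2.9° fields at 4 Hz; 0.5 s window,
16.7 ms bins), elliptical 2D Gaussian fit at the peak latency, screen/border
inclusion rules, RF/patch overlap fractions and size statistics.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

```python
from retinotile import (SimConfig, simulate_model, tiling_match,
                        bootstrap_chance, affine_fit, deviation_summary)

cfg = SimConfig(sigma=27.0, lambda_mean=5.5, seed=0)   # 9x9 lattices
gt = simulate_model(cfg)
interior = cfg.interior_ids()   # boundary nodes excluded from the match

axon_match = tiling_match(gt.rgc_rf, gt.axon, restrict_ids=interior)
soma_match = tiling_match(gt.sc_soma, gt.sc_rf, restrict_ids=interior)
null = bootstrap_chance(gt.rgc_rf, gt.axon, repetitions=10_000, seed=1)
med, mad = deviation_summary(affine_fit(gt.rgc_rf, gt.axon))

print(f"axon-vs-RF tiling match:   {axon_match.fraction:.1f}%")
print(f"soma-vs-RF tiling match:   {soma_match.fraction:.1f}%")
print(f"chance level (p=0.05):     {null.threshold:.1f}%")
print(f"affine deviation Delta:    {med:.0f} +/- {mad:.0f} um")
```

prints

```
axon-vs-RF tiling match:   79.8%
soma-vs-RF tiling match:   66.7%
chance level (p=0.05):     9.9%
affine deviation Delta:    33 +/- 13 um
```

One stochastic realization at σ = 27 μm, λ = 5.5: the axon pattern matches
its RF pattern far above the ~10% chance level of an 81-node pattern, the
soma pattern matches less well (convergence of only ~5.5 inputs averages
the jitter incompletely), and each axon sits ~30 μm from its affine-ideal
position — about a third of the 100 μm spacing between neighbors, i.e.
retinotopy is preserved at single-cell grain. Medians over many
realizations (85% and 77% at these parameters) are what the inversion uses.

The same analyses run from the shell on CSV/TIFF inputs:

```sh
retinotile run --demo --out demo_out/          # simulate → rf → tiling → infer
retinotile tiling --a axons.csv --b rfs.csv --bootstrap 10000 --seed 0
retinotile infer sigma --observed 84 --seed 0
```

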