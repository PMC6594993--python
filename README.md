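# neurosmc

Automated reconstruction of single-neuron morphologies from 3D
fluorescence microscopy image stacks by sequential Monte Carlo (particle
filter) branch tracing — together with a synthetic-stack simulator whose
ground truth is the input SWC file, and the standard distance/overlap
metrics for scoring reconstructions.

It is aimed at neuroscientists and bioimage analysts who need digital
reconstructions (SWC trees) of dendritic/axonal arbors from noisy
single-neuron stacks, and at method developers who need controlled
synthetic data and reproducible evaluation.

## Method

The pipeline has six stages:

1. **Soma extraction.** Grayscale erosion (radius *r_s*, separable)
   removes the thin arbor; Gaussian smoothing (σ = *r_s*) and
   maximum-entropy (Kapur) thresholding segment the remaining blob. The
   soma is modeled as one spherical node at the blob centroid with radius
   equal to the mean voxel-to-centroid distance.
2. **Seed extraction.** Multiscale Hessian vesselness: at each scale σ
   the eigenvalues |λ₁| ≤ |λ₂| ≤ |λ₃| of the Gaussian-scale Hessian score
   tubularity

   υ = (1 − e^(−Rₐ²/2α²)) · e^(−R_b²/2β²) · (1 − e^(−S²/2c²)),  υ = 0 if λ₂ > 0 or λ₃ > 0,

   with Rₐ = |λ₂|/|λ₃|, R_b = |λ₁|/√|λ₂λ₃|, S = √(λ₁²+λ₂²). Seeds are
   noise-tolerant local maxima of the scale-maximized map, thinned by
   non-maximum suppression in oriented cylinders (radius 3σ, length σ)
   and vetted by cylindrical-template correlation.
3. **Branch tracing.** Each seed spawns two particle filters (along ±v).
   The state x = [p, v, σ] evolves by a von Mises–Fisher direction prior
   (concentration κ), a truncated-Gaussian step length around *d*, and a
   Gaussian scale walk (std ζ). The likelihood is exp(K·c) where c is the
   zero-normalized cross-correlation of the image with a Gaussian-profile
   cylinder template at the particle pose. Weights are renormalized every
   iteration; systematic resampling fires when the effective sample size
   1/Σw² drops below 0.8 N; the posterior centroid is emitted as a trace
   node. Tracing stops when the mean correlation falls below c_min, at
   the iteration limit L, when the local node-density cap δₙ is exceeded,
   or at the volume border.
4. **Trace refinement.** Traces are resampled to one-voxel spacing and
   mean-shifted (flat kernel, radius = each node's initial radius, five
   synchronous iterations), collapsing redundant traces of one branch
   onto its centerline.
5. **Node grouping.** A greedy pass merges each highest-correlation
   ungrouped node with its ungrouped neighbors within r_g into a group
   node (unweighted means); all node links project onto the group graph.
6. **Tree construction.** Breadth-first traversal from the soma (or the
   highest-correlation group) turns the group graph into a rooted SWC
   tree, dropping cycle-closing edges, tiny disconnected components and
   single-node terminal branches.

The **simulator** renders an SWC tree as the per-voxel fraction occupied
by the union of tapered capsules spanning its edges, draws Poisson photon
counts at a requested SNR = (mean_fg − mean_bg)/std_fg, optionally
smooths at scale COR while preserving the measured SNR, and writes an
8-bit stack. The **metrics** module scores reconstructions against ground
truth with SD / SSD / %SSD and precision / recall / F at a spatial
threshold S (default 2 voxels), after densely resampling both trees.

## Worked example

```python
import numpy as np
from neurosmc import (SimulationParams, generate_toy_tree, simulate,
                      reconstruct_with_info, score)

tree = generate_toy_tree("Y", length=48, radius=2, origin=(8, 32, 8))
params = SimulationParams(snr=4, cor=0, seed=17)
volume = simulate(tree, (64, 64, 16), params).astype(float)

recon, info = reconstruct_with_info(volume, rng_seed=1)
report = score(recon, tree, s=2.0)
print("stage counts:", info)
print(f"F = {report.f:.3f}  precision = {report.precision:.3f}  "
      f"recall = {report.recall:.3f}")
print(f"SD = {report.sd:.3f} voxels  %SSD = {report.pct_ssd:.1f}%")
```

Output:

```
stage counts: {'soma_found': False, 'n_seeds': 6, 'n_traces': 12, 'n_nodes': 257, 'n_groups': 20, 'n_output_nodes': 19}
F = 0.994  precision = 1.000  recall = 0.988
SD = 0.381 voxels  %SSD = 0.7%
```

Six seeds were found on the bifurcating phantom, each traced in both
directions; the 257 resampled trace nodes collapsed into 20 group nodes
and a 19-node tree. At the standard matching threshold S = 2 voxels,
99.4% harmonic-mean node overlap (F) with the ground truth and a mean
reciprocal node distance (SD) of 0.38 voxels were obtained — at SNR 4,
i.e. clearly noisy data.

The same workflow is available from the shell:

```bash
neurosmc simulate --swc y.swc --snr 4 --shape 64,64,16 --seed 17 --out y.tif
neurosmc reconstruct --image y.tif --seed 1 --out recon.swc
neurosmc evaluate --recon recon.swc --truth y.truth.swc --s-values 1,2,3 --out scores.csv
neurosmc sweep --image y.tif --truth y.truth.swc --tau-grid 8,10 --out sweep.csv
```

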