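# ridgemetrics

Quantitative analysis of **actin microridges** — the laterally elongated,
actin-filled protrusions that tile the apical surface of squamous epithelial
(periderm) cells in labyrinthine patterns.  The package takes 4D
fluorescence stacks (XYZT) and produces segmentations and biophysical
numbers, for cell biologists and biophysicists studying apical actomyosin
patterning:

* **stack preprocessing** — Shannon-entropy selection of periderm z-slices
  and mean projection per time point,
* **cell segmentation & tracking** — Butterworth high-pass membrane
  demarcation, single-cell extraction (area/solidity cuts, convex-image
  masking), centroid linkage under a 2.5 µm cutoff,
* **ridge segmentation** — a classical labeling chain (rectified Laplacian
  of Gaussian → sigmoid → Otsu) that generates training labels, and a small
  U-net encoder–decoder (pure NumPy) trained on them, with physical
  pixel-size restoration after resizing (Δx = x_o·psz/256),
* **ridge geometry** — skeleton branch tracing, curvature series, and an
  effective persistence length from the rescaled-curvature distribution
  P(κ_s) = √(L_p/4π)·exp(−L_p κ_s²/4), hence flexural rigidity
  EI = L_p·k_B·T and the Euler buckling force f_c = π²k_B T·L_p/L²,
* **pattern metrics** — Fourier-moment pattern wavelength λ = 2π/wn and
  skeleton branch lengths,
* **flow analysis** — Lucas–Kanade optic flow, divergence 𝒟,
  growth/shrinkage event velocities (|𝒟| > 0.12 min⁻¹), strain-rate tensor
  S = ½(V+Vᵀ) and its area–deviatoric split S = S^area + S^dev,
* **cluster dynamics** — ridge tracking (LAP, 2.3 µm cutoff), 1D intensity
  profiles along the ridge axis, and Gaussian curvature of the
  intensity-height surface with ±K/±𝒟 coincidence counts,
* **synthetic data** — generators with known ground truth (worm-like
  chains, stripe/labyrinth patterns, advected flow scenes, entropy-separable
  z-stacks, cell sheets) that back every test in the suite.

See `docs/methods.md` for the models, parameter choices and numerical
details.

## Worked example: persistence length of simulated microridges

Generate 2D worm-like chains with a known persistence length, pool their
rescaled curvatures, and recover the stiffness parameters:

```python
import numpy as np
from ridgemetrics import geometry, synthetic

chains = synthetic.make_wormlike_chains(lp_true=6.1, step=0.1,
                                        n_points=1001, n_chains=100, seed=42)
kappa_s = np.concatenate([geometry.curvature_series(c).kappa_s
                          for c in chains.chains])
est = geometry.fit_lp(kappa_s, temperature=300.0)
print(f"persistence length : {est.lp:.2f} um  ({est.n_segments} segments)")
print(f"flexural rigidity  : {est.ei:.3e} N m^2")
print(f"f_c (L = 1 um)     : {geometry.critical_force(est.lp, 1.0):.2f} pN")
```

prints

```
persistence length : 6.09 um  (99900 segments)
flexural rigidity  : 2.523e-26 N m^2
f_c (L = 1 um)     : 0.25 pN
```

The estimator recovers the generator's 6.1 µm to well within 1% from 10⁵
turn-angle segments.  The flexural rigidity is EI = L_p·k_B·T, and the
critical force says a 1-µm protrusion of this stiffness buckles under
≈ 0.25 pN of axial load — for comparison, a bare actin filament
(L_p ≈ 17 µm) gives `geometry.critical_force(17.0, 1.0)` ≈ 0.69 pN.

## Command line

Every stage is also a CLI subcommand (thin wrappers over the library):

```bash
ridgemetrics synth --kind zstack --seed 3 --out stack.tif
ridgemetrics preprocess stack.tif --global-h 5.0 --out pp/
ridgemetrics segment-cells pp/projection.tif --min-area 200 --out cells/
ridgemetrics lp-estimate mask.tif --pixel-size 0.098 --out lp.json
ridgemetrics flow movie.tif --dt 0.5 --div-threshold 0.12 --out flow/
ridgemetrics run stack.tif --config config.yaml --out results/
```

`ridgemetrics run` executes the full pipeline (preprocess → segment → track
→ label → metrics) and writes a manifest with SHA-256 checksums of every
artifact alongside the serialized config.

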