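# tagstrain

Myocardial deformation and strain analysis from tagged (SPAMM) cine MRI.

Cardiac MR tagging imprints sinusoidal intensity stripes on the myocardium at
end-diastole; the stripes deform with the tissue, so two sequences with
linearly independent tag directions disambiguate in-plane material motion.
`tagstrain` turns such a pair of sequences into dense deformation-gradient
and Lagrangian strain fields:

1. **HARP phase extraction** — each sequence is band-pass filtered around its
   first spectral harmonic; the resulting harmonic phase φ(x, t) is a
   material invariant. Phase gradients are computed directly from the
   complex image (no unwrapping anywhere).
2. **Multiscale optic flow** — the optic-flow constraint φ_t + v·∇φ = 0,
   applied to both phases together with its first spatial derivatives under
   a local first-order flow model v(x) = v₀ + L(x − x₀), closes a 6×6 linear
   system per pixel for the velocity v and velocity-gradient tensor
   L = ∂v/∂x — no regularization prior. The Gaussian derivative scale is
   selected per pixel by minimizing the 2-norm condition number of the
   system, ties toward the smaller scale.
3. **Deformation integration** — the deformation gradient obeys the linear
   matrix ODE Ḟ = L F, F(t₀, t₀) = I. It is solved along tracked material
   trajectories by multiplicative integrals: ordered products of
   (I + L Δt) (default) or exp(L Δt) (volume-exact for divergence-free
   flows, since det exp A = exp tr A). A truncated matricant
   (iterated-integral) expansion is provided as an independent cross-check.
4. **Strain** — E = ½(FᵀF − I) (general metrics supported, including the
   carry-along metric that nullifies E identically — a built-in correctness
   oracle), projected onto radial/circumferential unit vectors of the polar
   frame at the ROI midpoint (E_rr, E_cc, E_cr) and onto the principal
   eigensystem (E_min, E_max), then regularized by masked Gaussian smoothing.
5. **Reporting** — ROI mean ± spatial standard deviation per frame and
   scalar, long-format CSV curves, strain maps.

Because clinical tagged MRI is not shipped with the package, a synthetic
phantom module renders SPAMM-tagged sequences from analytic motion models
(including an incompressible contracting-and-twisting annulus) with
closed-form F, L and E oracles, so the entire pipeline is testable
end-to-end against exact ground truth.

## Worked example

```python
from tagstrain import TagStrainModel

# default phantom: 128x128 at 1 mm, 21 frames over a 0.4 s systole,
# annulus radii 25/45 mm, incompressible contraction (lambda: 0 -> -150 mm^2)
# plus 0.15 rad twist, 7 mm tag spacing, noise-free
model = TagStrainModel.from_phantom(noise_sd=0.0, n_frames=21)
results = model.fit()
print(results.summary())
```

```
Tagged-MRI deformation and strain analysis
========================================================
frames: 21   grid: 128x128 @ 1 mm   dt: 0.02 s
ROI pixels: 4400   polar center: (63.5, 63.5) mm
carriers (rad/mm): (+0.889, +0.000), (+0.000, +0.889)
integration: linear_product   scales: 3.53-21.20 mm (8)   sigma: 1 px
--------------------------------------------------------
ROI strain at peak-|E_max| frame 20 (mean +/- spatial std):
  E_cc   -0.060 +/- 0.017   (n = 4400)
  E_rr   +0.063 +/- 0.015   (n = 4400)
  E_cr   -0.005 +/- 0.006   (n = 4400)
  E_min  -0.060 +/- 0.018   (n = 4400)
  E_max  +0.063 +/- 0.015   (n = 4400)
========================================================
```

The negative circumferential strain (shortening) and positive radial strain
(wall thickening) are the expected systolic pattern; for this phantom the
analytic mid-wall values are E_cc ≈ −0.06 and E_rr ≈ +0.07, and the
pipeline's ROI-median absolute tensor error against the closed-form oracle
is ≈ 0.002. `results.strain_curves()` returns the per-frame table,
`results.plot_curves()` / `results.plot_strain_maps()` draw the temporal
curves and color-coded maps.

## Command line

```sh
tagstrain phantom --model annulus --frames 21 --noise-sd 0.02 --out data/
tagstrain run --tags-a data/tags_a.tif --tags-b data/tags_b.tif \
              --mask data/mask.tif --out out/
```

`run` writes every intermediate stack (phase, velocity-gradient,
deformation, strain), `strain_curves.csv`, a text summary and a
reproducibility manifest; identical config + seed gives byte-identical
outputs. The staged verbs `harp`, `motion`, `deform`, `strain`, `report`
expose the individual pipeline steps on saved field stacks, and
`--config FILE` accepts a YAML configuration.

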