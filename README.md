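# bilayerlab

Analysis toolkit for studying how pH (headgroup protonation) reshapes
anionic lipid membranes — the kind of question raised by lysosomal lipids
such as bis(monoacylglycero)phosphate (BMP), whose vesicles fold and stack
under mild acidification while its isomer DOPG does not. The package bundles
the quantitative building blocks such a study needs, each testable end to
end on synthetic data with known ground truth:

* **Vesicle imaging** — detect a GUV's bounding circle in a phase-contrast
  micrograph and score its surface *heterogeneity*

  H = Σ<sub>θ=0°</sub><sup>179°</sup> (1/r) Σ<sub>i=1</sub><sup>N_r</sup>
  |I<sub>i</sub>(θ) − I<sub>−i</sub>(θ)|,

  the radius-normalised sum of intensity asymmetries of pixel pairs mirrored
  about the centre. Smooth vesicles give H ≈ 0; membrane protrusions and
  folds push H above the empirical smooth/folded boundary of 5.
* **Lamellar SAXS** — evaluate and fit
  I(q) = κ·(2πA/q²)·P<sub>t</sub>(q)·[u + (1−u)·S<sub>MCT</sub>(q)],
  a three-strip bilayer form factor times a modified Caillé structure
  factor for a stack of N bilayers at repeat distance d with disorder η,
  mixed with a fraction u of uncorrelated bilayers; reconstruct
  electron-density profiles and d-spacings (d = 2π/q<sub>peak</sub>).
* **Spectroscopy & electrokinetics** — Laurdan generalized polarization
  GP = (I₄₄₀ − I₄₉₀)/(I₄₄₀ + I₄₉₀) and ΔGP series; monoprotic
  Henderson–Hasselbalch protonation f(pH) = 1/(1+10^(pH−pKa)) with a
  least-squares pKa fitter; ζ potential from electrophoretic mobility via
  Helmholtz–Smoluchowski.
* **Trajectory analysis** — phosphate flip-state classification from the
  signed cosines of the O11–P / O12–P bonds to the bilayer normal
  (both > 0: flipped-out; both < 0: flipped-in), flip populations,
  z-displacement histograms, chain-pair distance profiles, geometric
  hydrogen bonds (0.35 nm / 35°), density profiles, A_L/V_L/D_HH, S_CD
  order parameters, and medoid (representative) conformations by pairwise
  RMSD.
* **Synthetic data** — seeded generators for each of the above, emitting
  ground truth next to every fixture.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
from bilayerlab import guv, spectra
from bilayerlab.synthetic import (
    GUVImageSpec, TitrationSimSpec, gen_guv_image, gen_titration)

# a smooth vesicle and one carrying a 60-degree protrusion sector
img = gen_guv_image(GUVImageSpec(noise_sigma=0.005, seed=0))
fit = guv.detect_vesicle(img)
print(f"smooth:    center=({fit.center[0]:.1f}, {fit.center[1]:.1f})  "
      f"r={fit.radius:.1f} px  H={guv.heterogeneity(img, fit).H:.2f}")

img2 = gen_guv_image(GUVImageSpec(noise_sigma=0.005, seed=0,
                                  protrusions=((15.0, 60.0, 0.4, 0.5),)))
fit2 = guv.detect_vesicle(img2)
print(f"protruded: H={guv.heterogeneity(img2, fit2).H:.2f}")

# apparent pKa from a noisy titration
pts = gen_titration(TitrationSimSpec(pKa_true=3.5, noise_sigma=0.02, seed=3))
print(spectra.fit_pka(pts, init=5.0).summary())
print(f"protonated at pH 4.5: {100 * spectra.protonation_fraction(4.5, 3.5):.1f}%")
```

prints

```
smooth:    center=(256.0, 256.0)  r=150.0 px  H=0.69
protruded: H=12.24
Protonation isotherm fit (monoprotic Henderson-Hasselbalch)
  pKa      = 3.5036 +/- 0.0178
  residual = 0.0116327 (sum of squares)
protonated at pH 4.5: 9.1%
```

The smooth vesicle sits far below the H = 5 folding boundary while the
protruded one lands near its analytic expectation (span × contrast ×
radial-fraction ≈ 60·0.5·0.4 = 12). The titration fit recovers the true
pKa 3.5 within its standard error, and at pH 4.5 that pKa leaves roughly
one lipid in ten protonated — small changes in charge state that
nevertheless accompany large morphological rearrangements.

A CLI mirrors the library (`bilayerlab synth ...`, `bilayerlab guv
heterogeneity`, `bilayerlab saxs fit`, `bilayerlab pka-fit`,
`bilayerlab flip`, ...); every `synth` subcommand writes a JSON sidecar with
the generating truth.

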