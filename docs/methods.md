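# Methods

This note documents the models implemented in `bilayerlab`, the choices made
where the underlying procedures are conventionally under-specified, and what
the synthetic fixtures do and do not emulate.

## Vesicle detection and the heterogeneity statistic

A giant unilamellar vesicle (GUV) in phase contrast appears as a bright,
approximately circular halo. Detection proceeds in three stages:

1. Gaussian blur (`blur_sigma`, default 2 px) and Canny edge extraction,
   followed by a circular Hough transform over a coarse radius sweep to
   propose up to `n_candidates` (default 10) candidate circles.
2. Derivative-free (Nelder–Mead) refinement of each candidate `(cx, cy, r)`
   maximising the mean image-gradient magnitude sampled (bilinearly) on the
   circle perimeter. The best-scoring circle wins; if no candidate exceeds
   the edge-strength floor, a `NoVesicleFoundError` is raised.
3. A bounded crest polish (Powell) of `(cx, cy, r)` that maximises the mean
   *intensity* on the perimeter of the blurred image. The gradient objective
   of stage 2 is flat across the width of a symmetric halo — its magnitude
   peaks on both flanks and vanishes on the crest — so it localises the
   circle only to within the halo width. The intensity crest is sharply
   peaked in all three parameters and pins the membrane midline to
   sub-pixel precision. For step-like (filled-disc) boundaries, where the
   crest is not defined, pass `refine_radius="gradient"` to stop after
   stage 2.

The heterogeneity of a detected vesicle of radius `r` centred at `c` is

    H = Σ_{θ=0°}^{179°} (1/r) Σ_{i=1}^{N_r} | I_i(θ) − I_{−i}(θ) |,

with `N_r = floor(r)` pixel pairs per direction sampled at `c ± i·(cos θ,
sin θ)` by bilinear interpolation (nearest-neighbour available). Dividing by
`r` makes each angular term an average intensity difference per unit radial
length, so vesicles of different sizes are comparable. H is exactly zero for
a point-symmetric image, invariant under additive intensity offsets, and
scales linearly with multiplicative rescaling — consequently H values are
only comparable between images on a common intensity scale, and all loaders
map 8-/16-bit data onto [0, 1]. The image is *not* re-normalised inside the
statistic (that would destroy the multiplicative-scaling property), and the
blur of stage 1 is used for detection only; H is computed on the raw image.

A protrusion sector of angular span `s` (degrees), contrast `c` and radial
fraction `f` contributes approximately `s · c · f` to H (each of the `s`
affected directions gains `(1/r)·(f·r)·c`), which places the synthetic
fixtures used in the tests firmly on either side of the H = 5 boundary that
separates smooth from folded vesicles: a symmetric vesicle with noise
σ = 0.005 measures H ≈ 0.7 (noise pairs contribute ≈ 180·σ·√2·√(2/π) before
interpolation smoothing), while a 60°/0.5/0.4 protrusion adds ≈ 12.

## Lamellar SAXS model

Scattered intensity of a dilute vesicle suspension whose bilayer is thin
compared to the vesicle radius:

    I(q) = κ · (2πA / q²) · P_t(q) · [u + (1 − u) · S_MCT(q)]

* `κ·2πA` — instrumental scale times basal-plane area. Only the product is
  identifiable; it is fitted and reported as one compound scale. Note the
  related degeneracy with the electron densities (the model depends on
  scale·ρ²): fitted densities are determined up to a common factor, while
  the strip geometry, `d`, `η`, `N` and `u` remain identifiable.
* `P_t(q) = F(q)²` with the analytic transform of a symmetric three-strip
  contrast profile (methyl trough `|z| < z_M`, methylene `z_M < |z| < z_C`,
  headgroup `z_C < |z| < z_H`, densities relative to water):

      F(q) = (2/q)[ρ_M sin(q z_M) + ρ_C(sin(q z_C) − sin(q z_M))
                   + ρ_H(sin(q z_H) − sin(q z_C))]

  verified against numerical quadrature of the step profile to 1e-8.
* `S_MCT(q)` — modified Caillé theory structure factor of a stack of `N`
  bilayers at repeat distance `d` with disorder parameter `η`:

      S(q) = N + 2 Σ_{k=1}^{N−1} (N−k) cos(kqd)
                 · exp(−(d/2π)² q² η γ_E) · (πk)^(−(d/2π)² q² η)

  (`γ_E` Euler–Mascheroni). At `η = 0` the Bragg orders reach `S = N²`;
  increasing `η` damps and broadens the peaks. `N = 1` gives `S ≡ 1`.
* `u` — fraction of positionally uncorrelated bilayers; `u = 1` is the pure
  unilamellar branch.

Canonical q unit is nm⁻¹; Å⁻¹ input is accepted with an explicit tag and
multiplied by 10.

Fitting (`LamellarSAXSModel.fit`) is bounded trust-region least squares on
residuals weighted by σ when provided, else √I (Poisson-like; only relative
weights matter). `N` is an integer searched exhaustively over `n_range`
(default 1–5, matching the 2–3-bilayer granularity such stacks show); the
nine continuous parameters start from the user's initial guess plus
`n_starts − 1` multi-starts jittered ±20% (seeded). Invalid geometries
(`z_M < z_C < z_H` violated) are rejected with a large residual rather than
a hard constraint. The `converged` flag requires both optimiser success and
a χ² meaningfully below the no-model variance floor, so a fit to pure noise
does not report silent success. Round-trip recovery on noiseless
self-generated curves: `d` within 2%, `η` within 20%, `N` exact.

Peak finding operates on the Lorentz-corrected `I·q²` with prominence
relative to its dynamic range and parabolic sub-grid refinement;
`d = 2π/q_peak` converts peak positions to repeat distances (q = 0.30 nm⁻¹
→ d ≈ 21 nm). Electron-density profiles are reconstructed as the mirrored
piecewise-constant contrast, optionally Gaussian-smoothed for display, with
`D_HH` the head-peak separation.

## Laurdan GP, protonation, zeta potential

GP = (I440 − I490)/(I440 + I490), with the band intensities taken by linear
interpolation at exactly 440 and 490 nm (a ±`window_nm` averaging mode is
available; the two agree to ~0.01 for smooth spectra). GP is bounded in
[−1, 1] and invariant under rescaling of the whole spectrum. ΔGP subtracts
the GP of the series point nearest a reference pH (default 8.0, required
within 0.2 pH units).

Protonation follows the monoprotic Henderson–Hasselbalch isotherm
`f(pH) = 1/(1 + 10^(pH − pKa))` — a single apparent pKa, no
surface-potential correction. `TitrationModel.fit` is a one-parameter
bounded least-squares fit with the covariance from the Jacobian; on
noiseless data it recovers pKa to machine precision, and at noise σ = 0.02
it is unbiased within 0.05 pH units over 50 replicates.

Zeta potential uses the Helmholtz–Smoluchowski relation
`ζ = μη/(ε₀ε_r)` (valid in the thin-double-layer limit appropriate for
~100 nm liposomes in aqueous buffer). Water-at-25 °C defaults
(η = 8.9e-4 Pa·s, ε_r = 78.4) are explicit, overridable fields, not hidden
constants.

## Headgroup flip states and trajectory observables

The signed orientation cosine of an O→P bond is its z-component divided by
its length: +1 parallel to the bilayer normal, −1 antiparallel. A
lipid-frame is flipped-out when both O11–P and O12–P cosines are positive,
flipped-in when both are negative; mixed-sign pairs (and exact zeros) are
labelled `unclassified` rather than forced into either class. Populations
are computed over a leaflet selection (default upper; derived per frame
from lipid mean z against the bilayer midplane when tags are absent) and
reported per frame and as trajectory means with binomial standard errors —
exact when frames are independent, an underestimate for autocorrelated
dynamics.

Other observables: 2-D occurrence histograms of the (P–O11, P–O12)
z-displacements; intramolecular chain-pair distance profiles per carbon
index (minimum-image); geometric hydrogen-bond counts with cutoffs
0.35 nm / 35° — the angle is hydrogen–donor–acceptor by default, switchable
to donor–hydrogen–acceptor; frame-averaged, peak-normalised number-density
profiles against the per-frame midplane; `A_L = ⟨LxLy⟩/(n_lipids/2)`,
`V_L = (⟨V⟩ − n_waters·v_w)/n_lipids` with `v_w = 0.03017 nm³` by default;
`D_HH` from the phosphate density-profile peak separation (resolution
limited by the histogram bin width); deuterium order parameters
`S_CD = ⟨(3cos²θ_z − 1)/2⟩` per carbon. All interatomic distances use the
minimum-image convention in an orthorhombic box; intramolecular bonds are
assumed pre-whole.

Representative conformations: within the most populated cluster (cluster
labels are an input; the package does not impose a clustering algorithm),
the medoid is the member minimising the mean pairwise RMSD after optimal
rigid-body superposition (Kabsch, via MDAnalysis), ties broken toward the
lowest index.

## Synthetic fixtures

Generators are deterministic per seed and emit ground truth alongside the
data. Default parameters are chosen once to represent the study conditions
the analyses target:

* GUV images: 512×512, radius 150 px, ring contrast 0.8 over background
  0.1, Gaussian halo width 2 px, additive noise σ = 0.005 on the [0, 1]
  scale; integer-pixel centres make the noise-free image exactly
  point-symmetric. Protrusion sectors add their contrast over their angular
  span and outer radial fraction on one side only. Not emulated:
  phase-contrast optics, polydispersity, multi-vesicle fields.
* SAXS curves: the lamellar model itself (default d = 21 nm, N = 3,
  η = 0.05, u = 0.5, strip geometry 0.35/1.4/1.9 nm with densities
  −90/−60/+180 e/nm³ relative to water) with optional relative Gaussian
  noise whose scale fills the σ column. No instrument smearing.
* Spectra: two Gaussian bands at 440/490 nm (default width 25 nm) on a
  370–600 nm grid. Real Laurdan bands are asymmetric; GP only reads two
  ordinates, so band shape is immaterial to the tests.
* Flip trajectories: per-lipid two-state first-order Markov chains
  (initialised from the stationary distribution) driving both O–P bonds
  along ±z with magnitude `z_offset` (default 0.15 nm) and independent
  Gaussian tilt noise (default 5°); 64 lipids × 200 frames in the upper
  leaflet. Kinetics are a fixture device — the analyses only assume
  two-state coexistence, not rates.
* Titrations: the isotherm plus Gaussian noise, clipped to [0, 1], on a pH
  grid 1.0–7.0.

Passing tests on these fixtures demonstrate the estimators' correctness and
calibration under the assumed statistical structure; they do not certify
performance on real micrographs, measured scattering curves or force-field
trajectories, whose artefacts (optics, smearing, undulations, wrapping) are
deliberately out of scope.

## Numerical choices and limitations

* Bilinear interpolation for all off-grid sampling (H statistic, perimeter
  scores); nearest-neighbour behind a flag.
* H sums over integer angles 0–179° exactly; the outer sum is not averaged
  over angles.
* Fit convergence honesty: `converged` combines optimiser status with a
  variance-floor criterion; χ² is reported unscaled.
* The problem sizes used in tests and in the acceptance script (20 image
  seeds, 300-point q grids, 64×200 lipid-frames, 50 titration replicates)
  were chosen as the smallest sizes at which the statistical assertions
  have comfortable margins.
* `D_HH` inherits the density-histogram bin width as its resolution.
* The SAXS fitter explores a multimodal landscape in `d` (the cosine series
  oscillates); multi-starts mitigate but do not guarantee escape from local
  minima for poor initial guesses.
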