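# Methods

This note documents the models, conventions and design choices behind
`noscolor`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Optical forward model

The slide is modelled as a coherent planar multilayer
`air | tissue | Si₃N₄ | Si(semi-infinite)` and solved with the
characteristic-matrix (Abelès/Macleod) form of the transfer-matrix
method. Conventions:

* **Complex index** `ñ = n − i·k` under `exp(+iωt)`, so `k ≥ 0`
  attenuates forward propagation. Single-interface and single-layer
  results are pinned against closed-form Fresnel and Airy formulas to
  1e-9 in the tests.
* **Substrate** silicon is treated as optically semi-infinite (no
  back-surface reflection): in the visible it is strongly absorbing, so
  the wafer back never contributes coherently.
* **Incidence** defaults to normal, unpolarised = mean of s and p
  intensity reflectances; oblique angles up to <90° are supported
  (Snell's law with principal-branch complex cosines).
* **Grid** 360–830 nm at 1 nm.
* **Tissue** is a non-dispersive lossless film described by a single RI —
  the same abstraction used when quoting "healthy ≈ 1.27, cancerous
  ≈ 1.37" — with thickness in the 0.3–1 µm range typical of dewaxed
  nominal-2-µm paraffin sections.
* The **glass control model** (used only by the synthetic pipeline) is a
  transmittance proxy `T = 1 − R` of the air/tissue/glass (n = 1.523)
  stack. It is a deliberately simple stand-in for brightfield
  transmission through an uncoated slide: with no nanocavity, interface
  reflections are weak and the colour barely responds to tissue RI.

## Colorimetry

Tristimulus values are discrete sums `X = k·Σ R(λ)S(λ)x̄(λ)Δλ` (likewise
Y, Z) with `k` fixed so the perfect reflector has `Y = 100`. Chromaticity
is `x = X/(X+Y+Z)`, `y = Y/(X+Y+Z)`. CIELAB uses the standard cube-root /
linear-segment transform against the illuminant's own white point, and
colour difference is CIE76 `ΔE*ab` (Euclidean in Lab). sRGB encoding uses
the IEC 61966-2-1 matrix and gamma with a von-Kries scaling to the sRGB
reference white; out-of-gamut channels are clipped and flagged.

**Bundled tables are synthetic stand-ins**, generated by
`scripts/make_reference_tables.py`:

* the 2° observer is the multi-lobe piecewise-Gaussian analytic fit of
  Wyman, Sloan & Shirley (2013), accurate to roughly 1% of peak, with the
  three functions rescaled to share one sum on the grid so the
  equal-energy stimulus maps exactly to (1/3, 1/3);
* "D65" is a Planckian radiator at 6504 K normalised at 560 nm — a smooth
  approximation of daylight without the atmospheric absorption structure
  of the tabulated CIE D65 SPD;
* Si n,k is a smooth interpolation of handbook-scale visible-range
  values; Si₃N₄ uses a stoichiometric-nitride Sellmeier relation with
  k = 0 (PECVD films can sit a few percent lower in index).

Consequences: absolute colour coordinates carry a few-percent model
uncertainty, and every derived sensitivity number (notably the JND
percentages) inherits it. All *relative* statements tested here —
ordering, monotonicity, metric identities — are robust to it.

## JND scan

`jnd_fraction_scan` perturbs tissue RI or thickness multiplicatively,
grows a bracket geometrically from 1e-4 until `ΔE*ab ≥` threshold
(default 2.3, the classical just-noticeable difference; configurable
because the criterion is conventional), then bisects to relative
tolerance 1e-3. Both directions are scanned; the headline value is their
minimum. Directions that cannot reach the threshold within ±50% report
`None`; if both fail the scan raises. With the defaults (green 111 nm
cavity, tissue n = 1.37, 500 nm) the RI scan lands at ≈1.7%: percent-level
physical changes of the section are chromatically visible. The thickness
scan at the same baseline gives ≈1.3% — slightly more sensitive than RI,
and somewhat below the few-percent figure one would quote loosely for
both parameters; given the synthetic dispersion/illuminant stand-ins this
~1 percentage-point scale uncertainty is expected.

## Point-cloud separation metrics

* **Extraction**: an 81×81 px region (6561 pixels, row-major) is
  converted sRGB→CIELAB with the D65/2° transform of
  `skimage.color.rgb2lab` (identical convention to MATLAB's `rgb2lab`);
  a\*, b\* are clamped to [−128, 127].
* **KDE**: exact evaluation of `p(x) = (1/N)Σ K_σ(x−x_i)` (normalised
  product-Gaussian kernel) at every node of a regular 3D grid — no
  binning, so small cases match a brute-force loop to 1e-10. Bandwidth
  defaults to Scott's rule per axis, `σ_d = sd_d·n^(−1/7)`; for group
  comparisons one pooled bandwidth and one shared grid (spanning all
  clouds plus 3σ padding, default 64³ nodes, 32³ in the desk-scale
  pipeline defaults) keep all densities comparable. With 3σ padding the
  grid captures ≥98% of the mass.
* **KDE-IoU** `Σ min/Σ max` is exactly 1 for identical grids and decays
  to 0 for disjoint supports; the cell volume cancels. Because both
  densities are kernel-smoothed, the analytic check in the tests compares
  against the closed-form overlap of two Gaussians with variance
  inflated by the kernel, `σ² → σ² + h²`.
* **Frobenius norm** is applied to the two density grids on the shared
  grid (the raw clouds have unequal extents and orderings, so an
  element-wise difference is only meaningful on a common discretisation).
* **Chamfer distance** jointly min-max normalises each axis over `a ∪ b`
  (zero-range axes are dropped and reported), averages nearest-neighbour
  distances in both directions (optional per-point weights, uniform by
  default; ties broken by first index), and rescales the normalised
  scalar by the RMS of the kept per-axis ranges. The RMS convention makes
  the two-single-point case reproduce the plain Euclidean distance; the
  normalised value is reported alongside.
* The **5×5 protocol** computes all 25 healthy×cancer pairwise IoUs; two
  protocols (e.g. NOS vs glass rendering) are compared with a two-sided
  independent-samples t-test (`scipy.stats.ttest_ind`) on their 25-value
  samples.

## Agreement and classifier statistics

Cohen's κ, consistency rate (= P₀), and the confusion-count metrics
follow the standard definitions; metrics with zero denominators are
reported as `nan` with an explicit `undefined` flag, never coerced to 0.
The ROC sweep groups tied scores at a single threshold and anchors
(0,0)/(1,1); its trapezoidal area equals the Mann–Whitney pairwise-win
probability with ties counted ½ (pinned to 1e-12 in the tests, and
cross-checked against scikit-learn implementations).

## Synthetic-data generator

What it emulates: class-conditional RI distributions (truncated normal,
defaults N(1.27, 0.02²) healthy / N(1.37, 0.02²) cancerous, truncated to
[1.0, 1.6]; the distribution family is a modelling choice — measured RI
maps show clustered unimodal distributions without a stated family),
thickness uniform on 0.3–1 µm, optional Gaussian spatial smoothing
(σ in px; the spatial covariance of real tissue is not characterised, so
this is a free parameter), additive Gaussian sensor noise (default
0.01 sRGB units), and rendering through the NOS or glass forward model.
Rendering uses a bilinear lookup table over (RI, thickness) — default
64×64, with the worst-case colour error over a pixel subsample audited
into the provenance record (`lut_max_delta_e`); `lut_size=None` renders
every pixel exactly.

What it does **not** emulate: histomorphology (glands, nuclei, goblet
cells), scanner optics/stitching, illumination non-uniformity, staining.
Passing tests therefore demonstrate that the *statistics* behave as
designed under the assumed physical contrast mechanism — not clinical
performance on real slides.

Tiles for the screening experiment are class-pure crops from per-subject
renderings; train and test sets use disjoint subject seeds, emulating a
patient-level split. The baseline classifier is a nearest-centroid model
on six colour features per tile (mean and SD of L\*, a\*, b\*), scored by
the difference of distances to the two class centroids (a logistic
variant is available); it is a desk-scale stand-in for a deep network,
described and evaluated as exactly that.

### Null calibrations

Two permutation-style nulls are exercised: (i) truth-blind simulated
raters give κ within ±0.03 of 0 at 10⁴ items; (ii) breaking the
score–label pairing of the evaluated tiles gives AUC within ±0.05 of 0.5
at 500 tiles. Note that permuting the *training* labels of the centroid
model is **not** a usable single-shuffle null here: with strongly
separated classes, residual class imbalance in a shuffle aligns the
centroid axis with the true class axis, making the resulting AUC bimodal
near 0 and 1 (mean 0.5 only across shuffles). The score–label permutation
is the standard calibration of the AUC statistic itself and is what the
acceptance test uses.

## Problem sizes and numerical choices

Desk-scale defaults (pipeline `RunConfig`): 160×160 px sections, five
27×27 px regions per class, 32³ KDE grid, 32×32 rendering LUT, 40+40
training and test tiles of 24 px — sizes chosen so a full comparison
experiment runs in ~2 s and the 20-seed ordering study in under a minute,
while leaving every statistical conclusion unchanged at larger settings.
Degenerate inputs are handled explicitly: zero-thickness layers are
identity to 1e-12; zero-range Chamfer axes are dropped and recorded;
all-zero density pairs, single-class label sets and `P_e = 1` confusion
matrices raise typed errors rather than returning conventional values.

## Known limitations

* Bundled observer/illuminant/material tables are analytic approximations
  (above); absolute colorimetry is a few percent off tabulated standards.
* Tissue is non-dispersive and lossless; no scattering, fluorescence or
  incoherent averaging.
* The glass control is a transmittance proxy, not a radiometric model of
  brightfield microscopy.
* KDE evaluation is exact but O(grid × points); very large clouds on 64³
  grids are seconds-per-cloud.
* Multi-label rater determinations are reduced to a single primary call
  per item before κ (dominant-epithelial-call rule, configurable by the
  caller supplying already-reduced calls); the package does not model the
  reduction beyond that.
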