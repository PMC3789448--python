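# Methods

`skinmaps` models reflectance imaging of human skin with a two-layer
Kubelka–Munk (K–M) medium, reconstructs reflectance cubes from a simulated
ten-band multispectral camera, and retrieves five per-pixel skin parameters
by genetic-algorithm (GA) inversion. This note records the model, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic tests do and do not establish about real data.

## Two-layer skin model

Skin is treated as an epidermis (melanin layer) over a dermis (haemoglobin
layer); the subcutis is ignored because little visible light returns from
it. Five parameters drive the model:

| parameter | meaning | units | physical range |
|---|---|---|---|
| `f_mel` | melanosome volume fraction of the epidermis | fraction (shown as %) | 1.3–45 % |
| `d_epi` | epidermis thickness | mm | 0.01–0.15 |
| `f_blood` | haemoglobin volume fraction of the dermis | fraction (shown as %) | 0.2–7 % |
| `c_oxy` | oxygenated fraction of total haemoglobin | fraction (shown as %) | 25–90 % |
| `d_dermis` | dermis thickness | mm | 0.6–3 |

Fractions are stored in [0, 1] and rendered as percent only at I/O
boundaries; thicknesses are converted mm→cm at the K–M boundary, because the
optical coefficients are in cm⁻¹.

Absorption. The epidermis mixes a melanin power law,
μ_mel(λ) = 6.6·10¹¹ λ⁻³·³³ cm⁻¹, with a chromophore-free baseline,
μ_base(λ) = 0.244 + 85.3 exp(−(λ−164)/66.2) cm⁻¹, weighted by `f_mel`. The
dermis mixes whole-blood oxy-/deoxyhaemoglobin absorption, weighted by
`f_blood` and `c_oxy`, with the same baseline. The bundled haemoglobin table
(`skinmaps/data/hemoglobin_synthetic.csv`, 400–1000 nm every 2 nm) is a
synthetic compilation: landmark molar-extinction values of the published
compilations (Soret bands near 415/430 nm, the oxy double peak at 542/578 nm
with its 560 nm valley, the 555 nm deoxy peak, red/NIR anchors) interpolated
monotonically in log space and converted to whole-blood absorption with
150 g/L haemoglobin, 64 500 g/mol and the ln 10 factor. It has the correct
spectral structure and magnitudes but is not a copy of any published file;
`scripts/build_hemoglobin_table.py` regenerates it.

Scattering. No scattering values are pinned down by the physics above, so
both layers default to one reduced-scattering power law
μ_s(λ) = a_mie (λ/500)^(−b_mie) + a_ray (λ/500)^(−4) with a_mie = 27.1,
b_mie = 0.91, a_ray = 18.9 cm⁻¹ (46 cm⁻¹ at 500 nm, Rayleigh fraction 0.41)
— typical visible/NIR values for skin. Both laws are injectable per layer.
The full-scattering convention (several hundred cm⁻¹) was examined and makes
the dermal parameters nearly unobservable through the strongly backscattering
epidermis, so the reduced-scattering magnitudes are kept.

Layer solution. With k = 2μ_a, s = 2μ_s, K = √(k(k+2s)) and
β = √(k/(k+2s)), a layer of thickness d has

    R = (1−β²)(e^{Kd}−e^{−Kd}) / D,   T = 4β / D,
    D = (1+β)² e^{Kd} − (1−β)² e^{−Kd},

and two layers combine through the closed-form inter-reflection series
R_tot = R₁ + T₁²R₂/(1−R₁R₂), T_tot = T₁T₂/(1−R₁R₂). K and β are the square
roots written above — the hyperbolic solution is dimensionally consistent
only with the roots in place. No refractive-index or internal-reflection
correction is applied at the interfaces.

Numerics: the layer formulae are evaluated with e^{Kd} factored out, so
optically thick layers reach their semi-infinite limit R → (1−β)/(1+β),
T → 0 without overflow at any Kd; a pure scatterer (μ_a = 0) uses the
closed-form limit R = sd/(1+sd), T = 1/(1+sd); zero thickness returns
(R, T) = (0, 1).

## Acquisition chain and calibration

The synthetic camera applies, per band k,
d_k = quantize(offset + gain · scale_k Σ_λ I Φ_k r o α Δλ + noise) at
12 bits, with ten Gaussian bandpass filters (centres equally spaced
420–960 nm, FWHM 80 nm — neighbouring filters overlap), smooth broadband
defaults for the illuminant I, optics o and sensor α (all injectable), a
vignetting-plus-gradient per-pixel gain field, read noise (2 DN) and shot
noise (4 e⁻/DN). Per-band exposure scales place a 99 %-reflectance target
near 88 % of full scale. Offset frames image a uniform 2 % target and
flat-field frames a 99 % target, each averaged over 8 exposures.

Calibration assumes the linear sensor model R = O + U·S: the gain is
S = (F−O)/DR with DR = 4096, and the correction U = (R−O)/S inverts the
model to within quantisation. Pixels with F ≤ O are masked, not
interpolated; the per-pixel inversion skips them.

## Reflectance-cube reconstruction

A linear heteroassociative memory (affine map from 10 calibrated band
responses to 37 reflectance samples, 420–780 nm at 10 nm) is trained on a
24-patch chart by an iterative batch delta rule. Three numerical choices
matter:

- Preconditioning: inputs are centred and PCA-whitened before training and
  the transform is folded back into the returned affine map. This is purely
  a conditioning device — band responses are strongly correlated and the
  plain delta rule would need ~10⁵ epochs; whitened, it converges in tens.
- Regularisation: a small ridge (10⁻⁶ of the whitened input power) replaces
  the pseudoinverse, which would amplify noise.
- Smoothness prior: the training loss adds `smooth`·‖D₂WX‖²/n (second
  differences along wavelength, default weight 10). Real reflectance
  spectra are smooth; the prior is what lets a 24-patch chart generalise to
  spectra outside its exact span instead of adding wiggly out-of-span
  residuals. With `smooth=0` the memory reduces to a ridge interpolator of
  its training data.

The bundled training chart is a synthetic stand-in for a physical colour
chart: 24 smooth in-gamut curves (six greys, rising/falling sigmoids,
Gaussian bumps, two skin-like curves with a haemoglobin dip). Reconstructed
cubes are clipped to [0, 1]. Reconstruction quality is scored with the
goodness-of-fit coefficient GFC = |⟨a,b⟩|/(‖a‖‖b‖); 0.99 is the usual
"good" threshold. On the noise-free synthetic loop the worst per-pixel GFC
is ≥ 0.99 (tested); with default noise the worst pixels sit just below it.

## Genetic-algorithm inversion

A chromosome is the real-valued five-parameter vector, always confined to
the physical bounds above. Each generation of the default scheme
(population 100, 25 generations, RMSE fitness) is assembled from: 5 elites,
25 survivors picked uniformly at random (diversity), 60 offspring from 30
crossover operations — each swaps one randomly chosen gene between two
rank-weighted random parents — 2 offspring mutations that redraw one gene
uniformly within its bound, and 10 fresh uniform-random individuals filling
the remainder. Alternative fitness metrics (GFC, RecP = 100(1−‖m−s‖/‖m‖),
MSAS = mean-centred spectral angle, SSV = √(RMSE²+(1−r²)²)) are provided;
RMSE is the default and the only one used by the shipped experiments. The
inversion grid is 420–780 nm at 10 nm — the range the reconstruction can
deliver.

Identifiability and an honest accuracy statement. The inverse problem is
unimodal but its objective has a narrow curved valley: epidermal attenuation
depends on `f_mel` and `d_epi` almost only through their product, and
`c_oxy`/`f_blood`/`d_dermis` span directions whose spectral signatures are
an order of magnitude weaker than pigmentation (relative-parameter Jacobian
condition ≈ 50 at typical skin). The scheme's moves are all axis-aligned —
a swap or a single-gene redraw changes one coordinate — and axis-aligned
proposals descend a curved valley only logarithmically. In practice the
best fit stalls at an RMSE of order 10⁻³–10⁻² against the target, with
single-pixel parameter errors of order 10 % (melanin and thicknesses) to
tens of percent (blood fraction, which also keeps a visible pull toward the
mean of its uniform initialisation range). The shipped accuracy experiment
(two characteristic parameter sets, ±0.1 noise with the 3σ convention, ten
repetitions averaged; `skinmaps.accuracy_experiment`) quantifies exactly
this and is what `scripts/acceptance.py` reports. Region statistics are
much better behaved than single pixels: averaging over a region cancels the
per-pixel scatter, and ratios between regions cancel most of the remaining
bias — the lesion phantom recovers a 0.27 melanin ratio to within a few
percent while single-pixel melanin errors are ten times larger.

The characteristic parameter sets are `LIGHT_SKIN` (10 %, 0.05 mm, 2 %,
70 %, 1.0 mm) and `DARK_SKIN` (30 %, 0.08 mm, 2 %, 70 %, 1.0 mm): typical
lightly/darkly pigmented skin with forearm-like layer thicknesses. The
noise convention reads "amplitude ±0.1" as σ = 0.1/3 (≈99.7 % of draws
within the amplitude), clipped to [0, 1]. The experiment reports, per
parameter, both the signed mean relative error over repetitions (noise is
zero-mean, so this is the figure that averaging repetitions is meant to
improve) and the mean absolute error, plus the RMSE of the best-fit
spectrum against the noise-free target.

Per-pixel runs derive each pixel's random stream from the master seed and
the pixel's absolute (row, column) via `numpy` seed sequences, so a
sub-window inversion reproduces the corresponding pixels of a full run and
strided runs are composable.

## Phantoms and what the tests show

Phantoms multiply each base parameter by a smooth (Gaussian-filtered,
mean-centred, ±3 %) spatial texture, optionally scale melanin inside an
elliptical lesion (hypopigmentation factor < 1, hyperpigmentation > 1), clip
to the physical bounds, and render the cube through the forward model. The
occlusion series scales `f_blood` ×1.75 and `c_oxy` ×0.77 for the occluded
acquisition and ×1.0625 / ×1.066 for the post-release acquisition, so the
ground-truth percentage differences are +75 % / −23 % and +6.25 % / +6.6 %.

The generator emulates the acquisition geometry, spectral mixing, gain and
offset structure, quantisation and simple noise of a real system. It does
not emulate specular reflection, polarisation, skin texture or
subject motion, and — most importantly — its phantom "truth" is produced by
the same forward model the inversion fits. Passing tests therefore
establish internal consistency of the chain (calibration inverts the sensor
model, reconstruction preserves spectra, inversion statistics behave as
characterised), not clinical accuracy on real skin, which would require
validation against spectrophotometer measurements and histology.

Property tests at pipeline level run the GA at a generous budget
(population 200, 100 generations, all counts doubled) so the property under
test — region ratios, sub-window composability — is not confounded with the
optimiser's stall; the accuracy experiment deliberately keeps the standard
settings, because those settings are part of what it characterises.

## Known limitations

- The GA's axis-aligned operators cannot reach the sub-percent single-pixel
  accuracy sometimes quoted for K–M inversions; see the identifiability
  discussion above. Gradient or hybrid refinement would fix this but is out
  of scope by design.
- Two layers only; no carotene, bilirubin, water or collagen chromophores;
  the stratum corneum is merged into the epidermis.
- The haemoglobin table and training chart are synthetic stand-ins with the
  right structure, not measured data.
- `d_dermis` is weakly observable whenever the dermis is optically thick at
  all grid wavelengths; its retrieved values then reflect the bounded search
  more than the tissue.
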