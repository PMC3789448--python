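# skinmaps

Quantitative skin analysis from multispectral images. `skinmaps` implements
the computational pipeline of a filter-wheel dermatology camera: offset and
flat-field calibration of raw 12-bit monoband frames, reconstruction of
reflectance cubes (x, y, λ) from ten band responses with a linear
heteroassociative memory, a two-layer Kubelka–Munk model of light transport
in skin, and a genetic-algorithm inversion that turns every pixel spectrum
into five skin parameters:

- melanosome volume fraction `f_mel` (pigmentation),
- epidermis thickness `d_epi` (mm),
- haemoglobin volume fraction `f_blood`,
- oxygenated haemoglobin fraction `c_oxy` (tissue oxygen saturation),
- dermis thickness `d_dermis` (mm).

It is written for researchers in tissue optics and computational
dermatology who want a complete, testable reference chain — a synthetic
acquisition model (illuminant, ten overlapping 80 nm bandpass filters,
optics, sensor, per-pixel gain/offset, quantisation) and skin phantoms with
ground-truth parameter maps make the whole pipeline runnable and verifiable
without hardware.

## Model

A skin pixel is an epidermis over a dermis. Layer absorption mixes
chromophores linearly:

    μ_a,epi(λ)  = f_mel μ_mel(λ) + (1 − f_mel) μ_base(λ)
    μ_a,derm(λ) = f_blood [c_oxy μ_oxy(λ) + (1 − c_oxy) μ_deoxy(λ)] + (1 − f_blood) μ_base(λ)

with μ_mel(λ) = 6.6·10¹¹ λ⁻³·³³ cm⁻¹ and
μ_base(λ) = 0.244 + 85.3 e^{−(λ−164)/66.2} cm⁻¹. Each layer's diffuse
reflectance/transmittance follows the two-flux (Kubelka–Munk) solution with
k = 2μ_a, s = 2μ_s, K = √(k(k+2s)), β = √(k/(k+2s)), and the two layers
combine through the inter-reflection series
R_tot = R₁ + T₁²R₂/(1−R₁R₂). Inversion minimises the RMSE between a
measured and a simulated spectrum over a bounded population of real-valued
parameter vectors (elitism, single-gene swap crossover, single-gene
mutation, random survivors). `docs/methods.md` documents every default and
the identifiability analysis of the inverse problem.

## Worked example

Forward model (`examples/forward_model.py`): reflectance of lightly
pigmented, well-oxygenated skin —

```
 wavelength [nm]  reflectance
             500       0.4286
             540       0.3922      <- oxyhaemoglobin band
             560       0.4254
             580       0.4104      <- oxyhaemoglobin band
             620       0.6210
             700       0.6861
```

The dips at 540/580 nm with the rebound at 560 nm are the oxyhaemoglobin
"W"; the steep rise into the red is why skin looks red-orange.

Full synthetic chain (`examples/full_pipeline.py`): phantom → ten-band
acquisition → calibration → chart-trained memory → reflectance cube —

```
raw stack: (16, 16, 10) (12-bit), saturation 0.00%
chart training RMSE 1.03e-02 in 178 epochs
per-pixel GFC: min 0.9900, mean 0.9990
```

A goodness-of-fit coefficient (GFC) above 0.99 at every pixel means the
reconstructed spectra match the ground truth to within the conventional
"good reconstruction" threshold.

Lesion quantification (`examples/lesion_analysis.py`): a vitiligo phantom
whose lesion melanin is 0.27× its surround, inverted per pixel —

```
parameter  ref_mean  measured_mean   R_diff  P_diff_pct
    f_mel  0.148280       0.038084 0.256839  -74.316056
    d_epi  0.061181       0.065578 1.071855    7.185538
  f_blood  0.021531       0.020896 0.970549   -2.945135
    c_oxy  0.646818       0.647206 1.000600    0.059950
 d_dermis  1.324894       1.295512 0.977824   -2.217650

ground-truth melanin ratio 0.269, retrieved 0.257
```

The lesion/healthy melanin ratio is recovered to a few percent while the
other parameters stay near 1 — the hypopigmentation signature.

Occlusion series (`examples/ischemia_series.py`): pressure-cuff phantoms
show `f_blood` +75 % and `c_oxy` −23 % under occlusion, returning to within
~6 % of baseline after release, with melanin and thicknesses unchanged.

A thin CLI mirrors the pipeline stages
(`skinmaps simulate|calibrate|learn|reconstruct|invert|compare`), each
reading/writing TIFF/ENVI/CSV files; run `skinmaps --help`.

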