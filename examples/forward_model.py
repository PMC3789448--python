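"""Forward model: from five skin parameters to a reflectance spectrum.

Builds a lightly pigmented, well-oxygenated skin and prints its two-layer
diffuse reflectance at a few wavelengths. The local minima near 540 and
580 nm are the oxyhaemoglobin absorption bands (the "W" shape); reflectance
rises steeply into the red where blood stops absorbing.
"""

from skinmaps import SkinParams, forward_spectrum

p = SkinParams(f_mel=0.05, d_epi=0.04, f_blood=0.04, c_oxy=0.85, d_dermis=1.2)
spectrum = forward_spectrum(p)

print("skin parameters:", p)
print(f"{'wavelength [nm]':>16} {'reflectance':>12}")
for lam, r in zip(spectrum.grid.wavelengths, spectrum.values):
    if lam in (440, 500, 540, 560, 580, 620, 700, 780):
        print(f"{lam:16.0f} {r:12.4f}")
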