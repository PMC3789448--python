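"""Regenerate the bundled synthetic whole-blood haemoglobin absorption table.

The table approximates the widely used compilations of oxy-/deoxyhaemoglobin
molar extinction: landmark values (Soret bands near 415/430 nm, the oxy
double peak at 542/578 nm with the 560 nm valley, the deoxy 555 nm peak, the
red/NIR anchors at 600, 660, 760, 800 and 940 nm) are interpolated with a
monotone cubic (PCHIP) in log space onto a 2 nm grid from 400 to 1000 nm.
Molar extinction (cm^-1/M) is converted to the absorption coefficient of
whole blood with 150 g/L haemoglobin, 64 500 g/mol and the ln(10) factor:

    mu_a [cm^-1] = ln(10) * eps * 150 / 64500

The result is a synthetic stand-in with the correct spectral structure and
magnitudes, not a copy of any published data file.

Run from the repository root:  python scripts/build_hemoglobin_table.py
"""

from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

# (wavelength nm, molar extinction cm^-1/M)
OXY_LANDMARKS = [
    (400, 266000), (410, 470000), (414, 520000), (420, 380000),
    (430, 120000), (440, 42000), (450, 28000), (460, 21000),
    (470, 19000), (480, 17500), (490, 18500), (500, 20900),
    (510, 25800), (520, 31800), (530, 39000), (542, 53236),
    (550, 45000), (560, 32620), (570, 44000), (578, 50104),
    (585, 29000), (590, 14400), (600, 3200), (610, 1506),
    (620, 942), (630, 610), (650, 368), (660, 320),
    (680, 276), (700, 290), (720, 364), (740, 446),
    (760, 586), (780, 710), (800, 816), (820, 916),
    (840, 1022), (860, 1092), (880, 1154), (900, 1198),
    (920, 1220), (940, 1214), (960, 1200), (980, 1160),
    (1000, 1086),
]

DEOXY_LANDMARKS = [
    (400, 223000), (410, 290000), (420, 400000), (430, 553236),
    (440, 255000), (450, 62816), (460, 32000), (470, 24000),
    (480, 21500), (490, 20800), (500, 21000), (510, 23500),
    (520, 27500), (530, 35000), (540, 46592), (550, 52276),
    (555, 53412), (560, 53292), (570, 45072), (578, 38000),
    (585, 31000), (590, 25000), (600, 14677), (610, 11000),
    (620, 8800), (630, 6510), (650, 3750), (660, 3227),
    (680, 2407), (700, 1794), (720, 1420), (730, 1280),
    (740, 1344), (750, 1500), (760, 1674), (780, 1076),
    (800, 762), (820, 693), (840, 692), (860, 700),
    (880, 726), (900, 761), (920, 750), (940, 693),
    (960, 650), (980, 630), (1000, 620),
]

MOLAR_TO_MUA = np.log(10.0) * 150.0 / 64500.0  # whole blood, cm^-1 per (cm^-1/M)


def build(step_nm: float = 2.0) -> np.ndarray:
    lam = np.arange(400.0, 1000.0 + step_nm / 2, step_nm)
    cols = [lam]
    for landmarks in (OXY_LANDMARKS, DEOXY_LANDMARKS):
        lw, eps = map(np.asarray, zip(*landmarks))
        interp = PchipInterpolator(lw, np.log(eps.astype(float)))
        cols.append(np.exp(interp(lam)) * MOLAR_TO_MUA)
    return np.column_stack(cols)


def main() -> None:
    out = Path(__file__).resolve().parents[1] / "src" / "skinmaps" / "data" / "hemoglobin_synthetic.csv"
    table = build()
    header = "wavelength_nm,mu_a_oxy_cm1,mu_a_deoxy_cm1"
    np.savetxt(out, table, delimiter=",", header=header, comments="", fmt="%.6g")
    print(f"wrote {out} ({table.shape[0]} rows)")


if __name__ == "__main__":
    main()
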