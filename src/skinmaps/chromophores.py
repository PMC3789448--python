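"""Chromophore absorption/scattering models and the skin parameter vector.

The two-layer skin model is driven by five parameters: melanosome volume
fraction ``f_mel`` and thickness ``d_epi`` of the epidermis, haemoglobin
volume fraction ``f_blood``, oxygenated-haemoglobin fraction ``c_oxy`` and
thickness ``d_dermis`` of the dermis. Fractions are stored in [0, 1] and
rendered as percent only at I/O boundaries; thicknesses are in mm and
converted to cm at the Kubelka-Munk boundary. All optical coefficients are
in cm^-1.

Epidermal absorption mixes a melanin power law with a chromophore-free
baseline; dermal absorption mixes whole-blood oxy/deoxyhaemoglobin
absorption (bundled table) with the same baseline. Reduced scattering
follows a configurable Mie + Rayleigh power law, since only literature
citations — not values — constrain it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "SkinParams",
    "ParameterBounds",
    "HaemoglobinTable",
    "PowerLawScattering",
    "ScatteringModel",
    "melanin_absorption",
    "baseline_absorption",
    "epidermis_absorption",
    "dermis_absorption",
    "oxygen_saturation",
    "layer_scattering",
]

#: Canonical ordering of the five skin parameters.
PARAM_NAMES = ("f_mel", "d_epi", "f_blood", "c_oxy", "d_dermis")


@dataclass(frozen=True)
class SkinParams:
    """Five-parameter description of the two-layer skin model.

    f_mel, f_blood, c_oxy are fractions in [0, 1]; d_epi, d_dermis in mm.
    """

    f_mel: float
    d_epi: float
    f_blood: float
    c_oxy: float
    d_dermis: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "SkinParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5,):
            raise ValueError("parameter vector must have 5 entries")
        return cls(*(float(v) for v in arr))

    def __iter__(self) -> Iterator[float]:
        return iter(self.to_array())


def _default_intervals() -> dict:
    # f_mel 1.3-45 %, d_epi 0.01-0.15 mm, f_blood 0.2-7 %, c_oxy 25-90 %,
    # d_dermis 0.6-3 mm; fractions stored in [0, 1].
    return {
        "f_mel": (0.013, 0.45),
        "d_epi": (0.01, 0.15),
        "f_blood": (0.002, 0.07),
        "c_oxy": (0.25, 0.90),
        "d_dermis": (0.6, 3.0),
    }


@dataclass(frozen=True)
class ParameterBounds:
    """Physical (min, max) interval per skin parameter."""

    intervals: dict = field(default_factory=_default_intervals)

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.intervals)
        if missing:
            raise ValueError(f"missing bounds for {sorted(missing)}")
        for name in PARAM_NAMES:
            lo, hi = self.intervals[name]
            if not lo < hi:
                raise ValueError(f"bound for {name} must satisfy min < max")

    def lower(self) -> np.ndarray:
        return np.array([self.intervals[n][0] for n in PARAM_NAMES])

    def upper(self) -> np.ndarray:
        return np.array([self.intervals[n][1] for n in PARAM_NAMES])

    def contains(self, p: SkinParams, atol: float = 1e-12) -> bool:
        arr = p.to_array()
        return bool(np.all(arr >= self.lower() - atol) and np.all(arr <= self.upper() + atol))

    def validate(self, p: SkinParams) -> None:
        if not self.contains(p):
            raise ValueError(f"parameters {p} outside physical bounds")

    def clip(self, arr: np.ndarray) -> np.ndarray:
        return np.clip(arr, self.lower(), self.upper())


def melanin_absorption(lam) -> np.ndarray:
    """Melanosome interior absorption coefficient, 6.6e11 * lam^-3.33 (cm^-1)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    return 6.6e11 * lam ** -3.33


def baseline_absorption(lam) -> np.ndarray:
    """Chromophore-free skin baseline absorption, 0.244 + 85.3 exp(-(lam-164)/66.2)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    return 0.244 + 85.3 * np.exp(-(lam - 164.0) / 66.2)


def epidermis_absorption(lam, f_mel: float) -> np.ndarray:
    """Epidermal absorption: melanosome fraction mixing melanin with baseline."""
    if not 0.0 <= f_mel <= 1.0:
        raise ValueError("f_mel must be in [0, 1]")
    return f_mel * melanin_absorption(lam) + (1.0 - f_mel) * baseline_absorption(lam)


def oxygen_saturation(c_hbo2: float, c_hb: float) -> float:
    """Oxygenated-haemoglobin fraction from oxy/deoxy concentrations."""
    if c_hbo2 < 0 or c_hb < 0:
        raise ValueError("concentrations must be non-negative")
    total = c_hbo2 + c_hb
    if total == 0:
        raise ValueError("oxygen saturation undefined for zero total haemoglobin")
    return c_hbo2 / total


class HaemoglobinTable:
    """Whole-blood oxy/deoxyhaemoglobin absorption (cm^-1) vs wavelength (nm).

    The packaged default is a synthetic compilation: literature landmark
    molar-extinction values interpolated to 2 nm and converted to whole-blood
    absorption (150 g/L, 64 500 g/mol, ln 10). See
    ``scripts/build_hemoglobin_table.py`` for its construction.
    """

    def __init__(self, wavelengths, mu_a_oxy, mu_a_deoxy):
        lam = np.asarray(wavelengths, dtype=float)
        oxy = np.asarray(mu_a_oxy, dtype=float)
        deoxy = np.asarray(mu_a_deoxy, dtype=float)
        if lam.ndim != 1 or lam.size < 2 or np.any(np.diff(lam) <= 0):
            raise ValueError("table wavelengths must be strictly increasing")
        if oxy.shape != lam.shape or deoxy.shape != lam.shape:
            raise ValueError("table columns must be aligned")
        if np.any(oxy <= 0) or np.any(deoxy <= 0):
            raise ValueError("absorption values must be positive")
        self.wavelengths = lam
        self.mu_a_oxy = oxy
        self.mu_a_deoxy = deoxy

    _default: "HaemoglobinTable | None" = None

    @classmethod
    def default(cls) -> "HaemoglobinTable":
        if cls._default is None:
            path = resources.files("skinmaps.data") / "hemoglobin_synthetic.csv"
            with resources.as_file(path) as p:
                data = np.loadtxt(p, delimiter=",", skiprows=1)
            cls._default = cls(data[:, 0], data[:, 1], data[:, 2])
        return cls._default

    def _check_range(self, lam: np.ndarray) -> None:
        if np.any(lam < self.wavelengths[0]) or np.any(lam > self.wavelengths[-1]):
            raise ValueError(
                f"wavelength outside table coverage "
                f"[{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm"
            )

    def mu_oxy(self, lam) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        self._check_range(lam)
        return np.interp(lam, self.wavelengths, self.mu_a_oxy)

    def mu_deoxy(self, lam) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        self._check_range(lam)
        return np.interp(lam, self.wavelengths, self.mu_a_deoxy)


def dermis_absorption(lam, f_blood: float, c_oxy: float, table: HaemoglobinTable | None = None) -> np.ndarray:
    """Dermal absorption: blood fraction weighting oxy/deoxy blood plus baseline."""
    if not 0.0 <= f_blood <= 1.0 or not 0.0 <= c_oxy <= 1.0:
        raise ValueError("f_blood and c_oxy must be in [0, 1]")
    table = table or HaemoglobinTable.default()
    return (
        f_blood * c_oxy * table.mu_oxy(lam)
        + f_blood * (1.0 - c_oxy) * table.mu_deoxy(lam)
        + (1.0 - f_blood) * baseline_absorption(lam)
    )


@dataclass(frozen=True)
class PowerLawScattering:
    """Reduced-scattering law a_mie*(lam/500)^-b_mie + a_ray*(lam/500)^-4 (cm^-1).

    Defaults give 46 cm^-1 at 500 nm with a 0.41 Rayleigh fraction and Mie
    slope 0.91 — typical for skin in the visible/NIR.
    """

    a_mie: float = 27.1
    b_mie: float = 0.91
    a_ray: float = 18.9

    def __post_init__(self) -> None:
        if self.a_mie < 0 or self.a_ray < 0 or (self.a_mie == 0 and self.a_ray == 0):
            raise ValueError("scattering amplitudes must be non-negative, not both zero")
        if self.b_mie < 0:
            raise ValueError("Mie exponent must be non-negative")

    def __call__(self, lam) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        if np.any(lam <= 0):
            raise ValueError("wavelength must be positive")
        x = lam / 500.0
        return self.a_mie * x ** -self.b_mie + self.a_ray * x ** -4.0


@dataclass(frozen=True)
class ScatteringModel:
    """Per-layer reduced-scattering laws (epidermis and dermis share defaults)."""

    epidermis: PowerLawScattering = field(default_factory=PowerLawScattering)
    dermis: PowerLawScattering = field(default_factory=PowerLawScattering)


def layer_scattering(lam, layer: str, model: ScatteringModel | None = None) -> np.ndarray:
    """Evaluate the configured power law for ``layer`` ('epidermis'|'dermis')."""
    model = model or ScatteringModel()
    try:
        law = getattr(model, layer)
    except AttributeError:
        raise ValueError(f"unknown layer {layer!r}") from None
    return law(lam)
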