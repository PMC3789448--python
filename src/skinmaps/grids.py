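"""Wavelength grids and sampled spectra.

All spectral quantities in the package live on a :class:`SpectralGrid`, an
ordered, uniformly spaced set of wavelengths in nanometres. The default grid
is the reconstructable range of the imaging chain: 420-780 nm at a 10 nm
step (37 samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpectralGrid", "Spectrum"]


@dataclass(frozen=True)
class SpectralGrid:
    """Strictly increasing, uniformly spaced wavelength axis (nm)."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        if lam.ndim != 1 or lam.size < 2:
            raise ValueError("grid needs at least two wavelengths")
        diffs = np.diff(lam)
        if np.any(diffs <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(diffs, diffs[0], rtol=0, atol=1e-9):
            raise ValueError("wavelength step must be uniform")
        object.__setattr__(self, "wavelengths", lam)

    @classmethod
    def default(cls, start: float = 420.0, stop: float = 780.0, step: float = 10.0) -> "SpectralGrid":
        return cls(np.arange(start, stop + step / 2, step))

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.allclose(self.wavelengths, other.wavelengths, rtol=0, atol=1e-9)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.wavelengths.size, float(self.wavelengths[0]), self.step))

    def require_match(self, other: "SpectralGrid") -> None:
        if self != other:
            raise ValueError("spectral grids do not match")


@dataclass
class Spectrum:
    """Values (reflectance or coefficients) sampled on a grid."""

    grid: SpectralGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.grid),):
            raise ValueError("values must match grid length")
        self.values = vals
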