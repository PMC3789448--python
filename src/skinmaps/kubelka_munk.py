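"""Two-flux (Kubelka-Munk) reflectance of a two-layer skin medium.

A single homogeneous layer with absorption mu_a, scattering mu_s and
thickness d has flux variables k = 2 mu_a, s = 2 mu_s,
K = sqrt(k (k + 2 s)) and beta = sqrt(k / (k + 2 s)); its diffuse
reflectance and transmittance follow the classical hyperbolic solution.
Two layers (epidermis over dermis) are combined with the standard
inter-reflection series summed in closed form. The subcutis is ignored.

Evaluation is vectorised over wavelength and, for the inverse problem, over
whole populations of parameter vectors at once (:class:`ForwardContext`).
Exponentials are factored so that optically thick layers (K d large) reach
their semi-infinite limits without overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chromophores import (
    HaemoglobinTable,
    ParameterBounds,
    ScatteringModel,
    SkinParams,
    baseline_absorption,
    melanin_absorption,
)
from .grids import SpectralGrid, Spectrum

__all__ = [
    "FluxVariables",
    "LayerRT",
    "StackRT",
    "flux_variables",
    "layer_rt",
    "stack_two",
    "forward_spectrum",
    "ForwardContext",
]

MM_PER_CM = 10.0


@dataclass(frozen=True)
class FluxVariables:
    k: np.ndarray
    s: np.ndarray
    K: np.ndarray
    beta: np.ndarray


@dataclass(frozen=True)
class LayerRT:
    R: np.ndarray
    T: np.ndarray


@dataclass(frozen=True)
class StackRT:
    R_total: np.ndarray
    T_total: np.ndarray


def flux_variables(mu_a, mu_s) -> FluxVariables:
    """Flux variables k, s, K, beta from absorption and scattering (cm^-1)."""
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s = np.asarray(mu_s, dtype=float)
    if np.any(mu_a < 0) or np.any(mu_s < 0):
        raise ValueError("coefficients must be non-negative")
    if np.any((mu_a == 0) & (mu_s == 0)):
        raise ValueError("mu_a and mu_s cannot both be zero")
    k = 2.0 * mu_a
    s = 2.0 * mu_s
    K = np.sqrt(k * (k + 2.0 * s))
    beta = np.sqrt(k / (k + 2.0 * s))
    return FluxVariables(k=k, s=s, K=K, beta=beta)


def _layer_rt_arrays(k, s, K, beta, d_cm):
    """Stable single-layer R, T; handles K d -> 0, K d large and k = 0."""
    x = K * d_cm
    # factor e^x out of the denominator: all terms bounded for x >= 0
    e2 = np.exp(-2.0 * np.clip(x, 0.0, 350.0))
    e2 = np.where(x > 350.0, 0.0, e2)
    denom = (1.0 + beta**2) * (1.0 - e2) + 2.0 * beta * (1.0 + e2)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (1.0 - beta**2) * (1.0 - e2) / denom
        T = 4.0 * beta * np.exp(-np.clip(x, 0.0, 700.0)) / denom
    # pure scattering (k = 0): R = s d / (1 + s d), T = 1 / (1 + s d)
    sd = s * d_cm
    pure = k == 0
    R = np.where(pure, sd / (1.0 + sd), R)
    T = np.where(pure, 1.0 / (1.0 + sd), T)
    # zero thickness: no medium
    zero_d = np.asarray(d_cm) == 0
    R = np.where(zero_d, 0.0, R)
    T = np.where(zero_d, 1.0, T)
    return R, T


def layer_rt(mu_a, mu_s, d) -> LayerRT:
    """Diffuse reflectance/transmittance of one layer of thickness d (cm)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("thickness must be non-negative")
    fv = flux_variables(mu_a, mu_s)
    R, T = _layer_rt_arrays(fv.k, fv.s, fv.K, fv.beta, d)
    return LayerRT(R=R, T=T)


def stack_two(layer1: LayerRT, layer2: LayerRT) -> StackRT:
    """Combine two layers via the closed-form inter-reflection series."""
    R1, T1 = np.asarray(layer1.R, dtype=float), np.asarray(layer1.T, dtype=float)
    R2, T2 = np.asarray(layer2.R, dtype=float), np.asarray(layer2.T, dtype=float)
    prod = R1 * R2
    if np.any(prod >= 1.0):
        raise ValueError("R1 * R2 must be < 1")
    R_total = R1 + T1**2 * R2 / (1.0 - prod)
    T_total = T1 * T2 / (1.0 - prod)
    return StackRT(R_total=R_total, T_total=T_total)


class ForwardContext:
    """Cached spectral basis for fast repeated forward evaluation on one grid.

    Caches melanin, baseline, oxy/deoxy blood absorption and per-layer
    scattering on the grid, so that evaluating a population of parameter
    vectors is a handful of broadcast operations.
    """

    def __init__(
        self,
        grid: SpectralGrid | None = None,
        table: HaemoglobinTable | None = None,
        scattering: ScatteringModel | None = None,
        bounds: ParameterBounds | None = None,
    ):
        self.grid = grid or SpectralGrid.default()
        self.table = table or HaemoglobinTable.default()
        self.scattering = scattering or ScatteringModel()
        self.bounds = bounds or ParameterBounds()
        lam = self.grid.wavelengths
        self._mu_mel = melanin_absorption(lam)
        self._mu_base = baseline_absorption(lam)
        self._mu_oxy = self.table.mu_oxy(lam)
        self._mu_deoxy = self.table.mu_deoxy(lam)
        self._mus_epi = self.scattering.epidermis(lam)
        self._mus_derm = self.scattering.dermis(lam)

    def reflectance_batch(self, params: np.ndarray) -> np.ndarray:
        """Total reflectance spectra for an (n, 5) parameter array -> (n, n_lam)."""
        P = np.atleast_2d(np.asarray(params, dtype=float))
        f_mel = P[:, 0:1]
        d_epi = P[:, 1:2] / MM_PER_CM
        f_blood = P[:, 2:3]
        c_oxy = P[:, 3:4]
        d_derm = P[:, 4:5] / MM_PER_CM

        mua_epi = f_mel * self._mu_mel + (1.0 - f_mel) * self._mu_base
        mua_derm = (
            f_blood * c_oxy * self._mu_oxy
            + f_blood * (1.0 - c_oxy) * self._mu_deoxy
            + (1.0 - f_blood) * self._mu_base
        )
        k1, s1 = 2.0 * mua_epi, 2.0 * self._mus_epi * np.ones_like(mua_epi)
        k2, s2 = 2.0 * mua_derm, 2.0 * self._mus_derm * np.ones_like(mua_derm)
        K1 = np.sqrt(k1 * (k1 + 2.0 * s1))
        b1 = np.sqrt(k1 / (k1 + 2.0 * s1))
        K2 = np.sqrt(k2 * (k2 + 2.0 * s2))
        b2 = np.sqrt(k2 / (k2 + 2.0 * s2))
        R1, T1 = _layer_rt_arrays(k1, s1, K1, b1, d_epi)
        R2, T2 = _layer_rt_arrays(k2, s2, K2, b2, d_derm)
        return stack_two(LayerRT(R1, T1), LayerRT(R2, T2)).R_total


def forward_spectrum(
    p: SkinParams,
    grid: SpectralGrid | None = None,
    table: HaemoglobinTable | None = None,
    scattering: ScatteringModel | None = None,
    bounds: ParameterBounds | None = None,
    check_bounds: bool = True,
) -> Spectrum:
    """Total skin reflectance spectrum for one parameter vector.

    Thicknesses in ``p`` are mm; they are converted to cm here, at the
    model boundary.
    """
    ctx = ForwardContext(grid=grid, table=table, scattering=scattering, bounds=bounds)
    if check_bounds:
        ctx.bounds.validate(p)
    values = ctx.reflectance_batch(p.to_array()[None, :])[0]
    return Spectrum(grid=ctx.grid, values=values)
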