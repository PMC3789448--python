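"""Synthetic acquisition chain and skin phantoms.

Emulates the full imaging chain — broadband illuminant, ten overlapping
bandpass interference filters (centres 420-960 nm, FWHM 80 nm), optics,
a 12-bit sensor with per-pixel gain (vignetting) and offset — together with
skin phantoms whose ground-truth parameter maps drive the two-layer forward
model. Every stage of the real pipeline (calibration, reconstruction,
inversion, region comparison) can therefore be exercised without hardware.

The camera signal for band k at a pixel with reflectance r(lambda) is

    d_k = quantize( offset + gain * scale_k * sum_lambda I Phi_k r o alpha dlambda + noise )

and matching offset / flat-field calibration stacks are produced from
uniform 2 % and 99 % reflectance targets, as in a real calibration session.
Illuminant, optics and sensor curves default to smooth broadband shapes and
are all injectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import CalibrationFrames, average_frames, correct_image
from .chromophores import PARAM_NAMES, ParameterBounds, SkinParams
from .grids import SpectralGrid
from .kubelka_munk import ForwardContext
from .reconstruction import ReflectanceCube, TrainingSet

__all__ = [
    "FilterBank",
    "make_filterbank",
    "AcquisitionModel",
    "AcquisitionResult",
    "simulate_acquisition",
    "make_training_chart",
    "make_training_set",
    "Phantom",
    "make_skin_phantom",
    "make_ischemia_series",
    "add_noise",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class FilterBank:
    """Gaussian-profile bandpass filters with unit peak transmittance."""

    centres: np.ndarray
    fwhm: float

    def __post_init__(self) -> None:
        c = np.asarray(self.centres, dtype=float)
        if c.size < 1:
            raise ValueError("need at least one filter")
        if np.any(np.diff(c) <= 0):
            raise ValueError("centres must be sorted increasing")
        if self.fwhm <= 0:
            raise ValueError("FWHM must be positive")
        object.__setattr__(self, "centres", c)

    @property
    def n_filters(self) -> int:
        return int(self.centres.size)

    def transmittance(self, lam) -> np.ndarray:
        """(n_filters, n_lam) transmittance curves; value 0.5 at centre +- FWHM/2."""
        lam = np.asarray(lam, dtype=float)
        return np.exp(-4.0 * np.log(2.0) * ((lam[None, :] - self.centres[:, None]) / self.fwhm) ** 2)


def make_filterbank(centres=None, fwhm: float = 80.0) -> FilterBank:
    """Default: ten filters equally spaced from 420 to 960 nm, FWHM 80 nm."""
    if centres is None:
        centres = np.linspace(420.0, 960.0, 10)
    return FilterBank(centres=np.asarray(centres, dtype=float), fwhm=fwhm)


def _default_illuminant(lam: np.ndarray) -> np.ndarray:
    # smooth xenon-arc-like broadband: rises in the blue, gently declining NIR
    return 0.55 + 0.45 * np.exp(-(((lam - 520.0) / 320.0) ** 2))


def _default_optics(lam: np.ndarray) -> np.ndarray:
    return 0.92 - 0.10 * ((lam - 400.0) / 600.0) ** 2


def _default_sensor(lam: np.ndarray) -> np.ndarray:
    # CMOS quantum-efficiency-like curve peaking near 600 nm
    return 0.15 + 0.85 * np.exp(-(((lam - 600.0) / 280.0) ** 2))


@dataclass
class AcquisitionModel:
    """Spectral and electronic description of the camera chain."""

    wavelengths: np.ndarray = field(default_factory=lambda: np.arange(400.0, 1000.0 + 1, 2.0))
    illuminant: np.ndarray | None = None
    optics: np.ndarray | None = None
    sensor: np.ndarray | None = None
    bit_depth: int = 12
    read_noise_dn: float = 2.0
    electrons_per_dn: float = 4.0
    offset_level_dn: float = 96.0
    vignetting_strength: float = 0.25
    gain_gradient: float = 0.05
    full_scale_fraction: float = 0.88

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        self.wavelengths = lam
        if self.illuminant is None:
            self.illuminant = _default_illuminant(lam)
        if self.optics is None:
            self.optics = _default_optics(lam)
        if self.sensor is None:
            self.sensor = _default_sensor(lam)
        for name in ("illuminant", "optics", "sensor"):
            curve = np.asarray(getattr(self, name), dtype=float)
            if curve.shape != lam.shape or np.any(curve < 0):
                raise ValueError(f"{name} must be non-negative on the model wavelength axis")
            setattr(self, name, curve)
        if not 8 <= self.bit_depth <= 16:
            raise ValueError("bit depth must be in 8..16")

    @property
    def max_dn(self) -> int:
        return (1 << self.bit_depth) - 1

    def gain_field(self, shape: tuple[int, int]) -> np.ndarray:
        """Low-order per-pixel gain: radial vignetting times a mild gradient."""
        h, w = shape
        y, x = np.mgrid[0:h, 0:w]
        ry = (y - (h - 1) / 2) / max(h / 2, 1)
        rx = (x - (w - 1) / 2) / max(w / 2, 1)
        r2 = rx**2 + ry**2
        g = (1.0 - self.vignetting_strength * r2 / 2.0) ** 2
        g *= 1.0 + self.gain_gradient * (rx + ry) / 2.0
        return g / g.mean()

    def offset_field(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        x = np.linspace(-1, 1, w)[None, :]
        return self.offset_level_dn * (1.0 + 0.05 * x) * np.ones((h, 1))

    def band_weights(self, bank: FilterBank) -> np.ndarray:
        """(n_filters, n_lam) integrand weights I*Phi_k*o*alpha*dlambda."""
        dlam = float(self.wavelengths[1] - self.wavelengths[0])
        return bank.transmittance(self.wavelengths) * self.illuminant * self.optics * self.sensor * dlam

    def band_scales(self, bank: FilterBank) -> np.ndarray:
        """Per-band exposure scaling placing the 99 % flat target near full scale."""
        B = self.band_weights(bank).sum(axis=1)
        headroom = self.full_scale_fraction * self.max_dn - self.offset_level_dn * 1.1
        return headroom / (0.99 * B)


@dataclass
class AcquisitionResult:
    """Raw 10-band stack plus matching calibration frames and bookkeeping."""

    raw: np.ndarray  # (h, w, bands) uint16
    frames: CalibrationFrames
    band_centres: np.ndarray
    saturation_fraction: float
    model: AcquisitionModel
    bank: FilterBank

    def corrected(self) -> np.ndarray:
        """Offset/flat-field corrected stack (h, w, bands), NaN where invalid."""
        h, w, nb = self.raw.shape
        out = np.empty((h, w, nb))
        for b in range(nb):
            out[..., b] = correct_image(self.raw[..., b], self.frames.offset[b], self.frames.gain(b))
        return out


def _band_responses(reflectance: np.ndarray, grid: SpectralGrid, model: AcquisitionModel, bank: FilterBank) -> np.ndarray:
    """Noise-free useful signal (h, w, bands) before gain/offset/quantisation."""
    flat = reflectance.reshape(-1, len(grid))
    # interpolate spectra onto the model axis with edge extension
    r_model = np.empty((flat.shape[0], model.wavelengths.size))
    for i, spec in enumerate(flat):
        r_model[i] = np.interp(model.wavelengths, grid.wavelengths, spec)
    W = model.band_weights(bank)  # (bands, n_lam)
    scales = model.band_scales(bank)  # (bands,)
    resp = r_model @ W.T * scales
    return resp.reshape(reflectance.shape[:-1] + (bank.n_filters,))


def _expose(useful: np.ndarray, gain: np.ndarray, offset: np.ndarray, model: AcquisitionModel, rng: np.random.Generator) -> np.ndarray:
    """One quantised raw frame from the useful signal (h, w, bands)."""
    signal = offset[..., None] + useful * gain[..., None]
    noise = rng.normal(0.0, model.read_noise_dn, signal.shape)
    if model.electrons_per_dn > 0:
        noise = noise + rng.normal(0.0, 1.0, signal.shape) * np.sqrt(
            np.maximum(signal, 0.0) / model.electrons_per_dn
        )
    return np.clip(np.round(signal + noise), 0, model.max_dn).astype(np.uint16)


def simulate_acquisition(
    reflectance,
    grid: SpectralGrid | None = None,
    model: AcquisitionModel | None = None,
    bank: FilterBank | None = None,
    seed: int | np.random.Generator | None = 0,
    n_calibration_frames: int = 8,
) -> AcquisitionResult:
    """Simulate a 10-band acquisition of a reflectance cube plus calibration frames.

    ``reflectance`` is an (h, w, n_lam) array on ``grid`` (or a
    :class:`ReflectanceCube`). Offset frames image a uniform 2 % target and
    flat-field frames a 99 % target; both are averaged over
    ``n_calibration_frames`` noisy exposures.
    """
    if isinstance(reflectance, ReflectanceCube):
        grid = reflectance.grid
        reflectance = reflectance.data
    if grid is None:
        raise ValueError("a spectral grid is required with a bare array")
    reflectance = np.asarray(reflectance, dtype=float)
    if reflectance.ndim != 3 or reflectance.shape[2] != len(grid):
        raise ValueError("reflectance must be (h, w, n_lam) on the given grid")
    model = model or AcquisitionModel()
    bank = bank or make_filterbank()
    rng = _rng(seed)

    h, w = reflectance.shape[:2]
    gain = model.gain_field((h, w))
    offset = model.offset_field((h, w))

    useful = _band_responses(reflectance, grid, model, bank)
    raw = _expose(useful, gain, offset, model, rng)
    saturation = float(np.mean(raw == model.max_dn))

    def target_stack(level: float) -> np.ndarray:
        uniform = np.full((h, w, len(grid)), level)
        u = _band_responses(uniform, grid, model, bank)
        frames = [_expose(u, gain, offset, model, rng) for _ in range(n_calibration_frames)]
        return np.stack(
            [average_frames([f[..., b] for f in frames]) for b in range(bank.n_filters)]
        )

    frames = CalibrationFrames(offset=target_stack(0.02), flatfield=target_stack(0.99), dr=float(1 << model.bit_depth))
    return AcquisitionResult(
        raw=raw,
        frames=frames,
        band_centres=bank.centres.copy(),
        saturation_fraction=saturation,
        model=model,
        bank=bank,
    )


def make_training_chart(grid: SpectralGrid | None = None, n_patches: int = 24) -> np.ndarray:
    """24 smooth synthetic reflectance curves standing in for a colour chart.

    Synthetic stand-in: published chart spectra are not bundled, so the set
    mixes neutral greys, rising/falling sigmoids, Gaussian bumps and two
    skin-like curves — smooth, in-gamut shapes spanning the visible range.
    """
    grid = grid or SpectralGrid.default()
    lam = grid.wavelengths

    def sigmoid(c, width, lo, hi):
        return lo + (hi - lo) / (1.0 + np.exp(-(lam - c) / width))

    def bump(c, width, lo, amp):
        return lo + amp * np.exp(-(((lam - c) / width) ** 2))

    patches = [np.full_like(lam, g) for g in (0.04, 0.12, 0.25, 0.40, 0.60, 0.88)]
    patches += [sigmoid(c, wdt, 0.06, hi) for c, wdt, hi in
                ((580, 18, 0.85), (600, 25, 0.75), (620, 15, 0.65), (560, 30, 0.70), (640, 20, 0.80))]
    patches += [sigmoid(c, -wdt, 0.08, hi) for c, wdt, hi in
                ((540, 25, 0.70), (580, 30, 0.55), (500, 20, 0.60))]
    patches += [bump(c, wdt, lo, amp) for c, wdt, lo, amp in
                ((540, 60, 0.08, 0.5), (500, 50, 0.10, 0.45), (460, 45, 0.06, 0.55),
                 (600, 70, 0.12, 0.40), (650, 60, 0.08, 0.5), (480, 80, 0.15, 0.35))]
    # skin-like: rising sigmoid with a haemoglobin-band dip near 560 nm
    patches += [
        sigmoid(570, 30, 0.10, 0.60) - 0.06 * np.exp(-(((lam - 560) / 25) ** 2)),
        sigmoid(590, 35, 0.05, 0.45) - 0.04 * np.exp(-(((lam - 555) / 22) ** 2)),
    ]
    patches += [
        0.3 + 0.25 * np.sin((lam - 420) / 360 * np.pi),
        0.5 - 0.3 * ((lam - 600) / 180) ** 2,
    ]
    patches = np.clip(np.stack(patches[:n_patches]), 0.02, 0.98)
    if patches.shape[0] < n_patches:
        raise ValueError("not enough patch prototypes")
    return patches


def make_training_set(
    grid: SpectralGrid | None = None,
    model: AcquisitionModel | None = None,
    bank: FilterBank | None = None,
    seed: int | np.random.Generator | None = 0,
    patch_px: int = 6,
) -> TrainingSet:
    """Simulate a chart acquisition and return calibrated patch responses.

    The 24 patches are tiled into a 4 x 6 mosaic, acquired through the full
    chain, offset/flat-field corrected, and averaged per patch.
    """
    grid = grid or SpectralGrid.default()
    chart = make_training_chart(grid)
    n = chart.shape[0]
    rows, cols = 4, 6
    mosaic = np.empty((rows * patch_px, cols * patch_px, len(grid)))
    for i in range(n):
        r, c = divmod(i, cols)
        mosaic[r * patch_px:(r + 1) * patch_px, c * patch_px:(c + 1) * patch_px] = chart[i]
    acq = simulate_acquisition(mosaic, grid, model=model, bank=bank, seed=seed)
    corrected = acq.corrected()
    responses = np.empty((n, acq.bank.n_filters))
    for i in range(n):
        r, c = divmod(i, cols)
        cell = corrected[r * patch_px:(r + 1) * patch_px, c * patch_px:(c + 1) * patch_px]
        responses[i] = np.nanmean(cell.reshape(-1, cell.shape[-1]), axis=0)
    return TrainingSet(responses=responses, spectra=chart, grid=grid)


@dataclass
class Phantom:
    """Ground-truth parameter maps, optional lesion mask and rendered cube."""

    maps: dict
    lesion_mask: np.ndarray | None
    cube: ReflectanceCube
    base: SkinParams
    lesion: str = "none"
    factor: float = 1.0
    seed: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps[PARAM_NAMES[0]].shape

    def param_stack(self) -> np.ndarray:
        """(h*w, 5) parameter array in canonical order."""
        h, w = self.shape
        return np.stack([self.maps[n].ravel() for n in PARAM_NAMES], axis=1)

    def render(self, grid: SpectralGrid, ctx: ForwardContext | None = None) -> np.ndarray:
        """Re-render the ground-truth cube on another wavelength grid."""
        ctx = ctx or ForwardContext(grid=grid)
        h, w = self.shape
        return ctx.reflectance_batch(self.param_stack()).reshape(h, w, len(grid))


def _smooth_field(shape, rng: np.random.Generator, sigma_px: float = 4.0) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, shape)
    smooth = ndimage.gaussian_filter(noise, sigma_px, mode="reflect")
    smooth -= smooth.mean()
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _ellipse_mask(shape) -> np.ndarray:
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    return ((y - h / 2) / (h * 0.28)) ** 2 + ((x - w / 2) / (w * 0.28)) ** 2 <= 1.0


def make_skin_phantom(
    base: SkinParams,
    lesion: str = "none",
    factor: float = 1.0,
    shape: tuple[int, int] = (32, 32),
    seed: int = 0,
    texture_amplitude: float = 0.03,
    bounds: ParameterBounds | None = None,
    grid: SpectralGrid | None = None,
    ctx: ForwardContext | None = None,
) -> Phantom:
    """Skin phantom: smooth spatial fields around ``base`` with an optional lesion.

    ``lesion`` is 'none', 'vitiligo' (factor < 1) or 'melasma' (factor > 1);
    inside the elliptical lesion mask the melanin fraction is multiplied by
    ``factor``. Values are clipped to the physical bounds with a warning.
    Exactly reproducible from (base, lesion, factor, shape, seed).
    """
    if lesion not in ("none", "vitiligo", "melasma"):
        raise ValueError("lesion must be 'none', 'vitiligo' or 'melasma'")
    if lesion == "vitiligo" and factor >= 1.0:
        raise ValueError("vitiligo is hypopigmentation: factor < 1")
    if lesion == "melasma" and factor <= 1.0:
        raise ValueError("melasma is hyperpigmentation: factor > 1")
    bounds = bounds or ParameterBounds()
    bounds.validate(base)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xF0,)))

    maps = {}
    for name, value in zip(PARAM_NAMES, base.to_array()):
        field2d = value * (1.0 + texture_amplitude * _smooth_field(shape, rng))
        maps[name] = field2d
    mask = None
    if lesion != "none":
        mask = _ellipse_mask(shape)
        maps["f_mel"] = np.where(mask, maps["f_mel"] * factor, maps["f_mel"])

    lo, hi = bounds.lower(), bounds.upper()
    for j, name in enumerate(PARAM_NAMES):
        clipped = np.clip(maps[name], lo[j], hi[j])
        if not np.array_equal(clipped, maps[name]):
            warnings.warn(f"phantom {name} clipped to physical bounds", stacklevel=2)
        maps[name] = clipped

    ctx = ctx or ForwardContext(grid=grid, bounds=bounds)
    h, w = shape
    P = np.stack([maps[n].ravel() for n in PARAM_NAMES], axis=1)
    data = ctx.reflectance_batch(P).reshape(h, w, len(ctx.grid))
    cube = ReflectanceCube(data=data, grid=ctx.grid, meta={"seed": seed, "lesion": lesion, "factor": factor})
    return Phantom(maps=maps, lesion_mask=mask, cube=cube, base=base, lesion=lesion, factor=factor, seed=seed)


def make_ischemia_series(
    baseline: SkinParams,
    occl_blood_scale: float = 1.75,
    occl_oxy_scale: float = 0.77,
    reperf_blood_scale: float = 1.0625,
    reperf_oxy_scale: float = 1.066,
    shape: tuple[int, int] = (32, 32),
    seed: int = 0,
    **kwargs,
) -> tuple[Phantom, Phantom, Phantom]:
    """Three-phantom cuff-occlusion series: baseline, occlusion, reperfusion.

    Occlusion scales the blood fraction up and the oxygenation down;
    reperfusion sits slightly above baseline (hyperaemia nearly over). All
    three share the same spatial texture (same seed), so ground-truth region
    means differ exactly by the scale factors.
    """
    def scaled(bs: float, os: float) -> SkinParams:
        return SkinParams(
            f_mel=baseline.f_mel,
            d_epi=baseline.d_epi,
            f_blood=baseline.f_blood * bs,
            c_oxy=baseline.c_oxy * os,
            d_dermis=baseline.d_dermis,
        )

    acq1 = make_skin_phantom(baseline, shape=shape, seed=seed, **kwargs)
    acq2 = make_skin_phantom(scaled(occl_blood_scale, occl_oxy_scale), shape=shape, seed=seed, **kwargs)
    acq3 = make_skin_phantom(scaled(reperf_blood_scale, reperf_oxy_scale), shape=shape, seed=seed, **kwargs)
    return acq1, acq2, acq3


def add_noise(values, amplitude: float, seed=None, clip: tuple[float, float] | None = (0.0, 1.0)) -> np.ndarray:
    """Add zero-mean Gaussian noise with sigma = amplitude / 3, then clip.

    The 3-sigma convention places ~99.7 % of draws within +-amplitude.
    Reproducible per seed; ``amplitude = 0`` is the identity.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    values = np.asarray(values, dtype=float)
    if amplitude == 0:
        return values.copy()
    rng = _rng(seed)
    noisy = values + rng.normal(0.0, amplitude / 3.0, values.shape)
    if clip is not None:
        noisy = np.clip(noisy, clip[0], clip[1])
    return noisy
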