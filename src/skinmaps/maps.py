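"""Per-pixel inversion of reflectance cubes and region-comparison statistics.

Each pixel spectrum is inverted independently with the genetic algorithm;
pixels are subsampled with a stride to bound computation time, and every
pixel gets its own deterministic random stream derived from the master seed
and its absolute (row, column) position, so a sub-window inversion equals
the corresponding sub-window of a full inversion.

Region statistics follow the lesion and occlusion analyses: the relative
difference R_diff is the ratio of the measured-region mean to the
reference-region mean, and the percentage difference P_diff is
100 * (acq - baseline) / baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromophores import PARAM_NAMES
from .ga import GAConfig, invert_spectrum
from .kubelka_munk import ForwardContext
from .reconstruction import ReflectanceCube

__all__ = [
    "ParameterMaps",
    "RegionComparison",
    "invert_cube",
    "region_mean",
    "relative_difference",
    "percentage_difference",
    "compare_regions",
]


@dataclass
class ParameterMaps:
    """Five co-registered parameter maps plus fitness map and inversion mask.

    Values are stored in model units (fractions in [0, 1], thicknesses in
    mm); ``as_percent`` views fractions in percent for presentation.
    """

    data: dict
    fitness: np.ndarray
    mask: np.ndarray
    stride: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.data)
        if missing:
            raise ValueError(f"missing maps for {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def as_percent(self, name: str) -> np.ndarray:
        arr = self.data[name]
        return arr * 100.0 if name in ("f_mel", "f_blood", "c_oxy") else arr

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in PARAM_NAMES:
            vals = self.data[name][self.mask]
            rows.append(
                {
                    "parameter": name,
                    "mean": float(np.mean(vals)),
                    "std": float(np.std(vals)),
                    "n_pixels": int(vals.size),
                }
            )
        return pd.DataFrame(rows)


def pixel_rng(master_seed: int, row: int, col: int) -> np.random.Generator:
    """Deterministic per-pixel stream keyed by absolute pixel coordinates."""
    return np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=(row, col)))


def invert_cube(
    cube: ReflectanceCube,
    cfg: GAConfig | None = None,
    stride: int = 1,
    seed: int = 0,
    ctx: ForwardContext | None = None,
    origin: tuple[int, int] = (0, 0),
) -> ParameterMaps:
    """Invert every stride-th pixel of a reflectance cube into parameter maps.

    ``origin`` is the cube's absolute offset in a larger image; per-pixel
    seeds use absolute coordinates, making sub-window runs composable.
    Pixels containing NaNs are skipped and left masked.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    cfg = cfg or GAConfig()
    ctx = ctx or ForwardContext(grid=cube.grid)
    cube.grid.require_match(ctx.grid)

    h, w = cube.data.shape[:2]
    maps = {name: np.full((h, w), np.nan) for name in PARAM_NAMES}
    fitness = np.full((h, w), np.nan)
    mask = np.zeros((h, w), dtype=bool)
    for y in range(0, h, stride):
        for x in range(0, w, stride):
            spec = cube.data[y, x]
            if not np.all(np.isfinite(spec)):
                continue
            rng = pixel_rng(seed, origin[0] + y, origin[1] + x)
            best, cost = invert_spectrum(spec, cfg, ctx=ctx, seed=rng)
            arr = best.to_array()
            for j, name in enumerate(PARAM_NAMES):
                maps[name][y, x] = arr[j]
            fitness[y, x] = cost
            mask[y, x] = True
    return ParameterMaps(data=maps, fitness=fitness, mask=mask, stride=stride, seed=seed)


def region_mean(map2d: np.ndarray, region: np.ndarray, inverted: np.ndarray | None = None) -> float:
    """Arithmetic mean of a map over a region mask, restricted to inverted pixels."""
    map2d = np.asarray(map2d, dtype=float)
    region = np.asarray(region, dtype=bool)
    if region.shape != map2d.shape:
        raise ValueError("mask and map shapes differ")
    sel = region & np.isfinite(map2d)
    if inverted is not None:
        sel &= np.asarray(inverted, dtype=bool)
    if not np.any(sel):
        raise ValueError("empty region selection")
    return float(map2d[sel].mean())


def relative_difference(ref_mean: float, measured_mean: float) -> float:
    """R_diff = measured / reference (ratio of region means, unitless)."""
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    return measured_mean / ref_mean


def percentage_difference(baseline_mean: float, acq_mean: float) -> float:
    """P_diff = 100 * (acquisition - baseline) / baseline, in percent."""
    if baseline_mean == 0:
        raise ValueError("baseline mean must be non-zero")
    return 100.0 * (acq_mean - baseline_mean) / baseline_mean


@dataclass
class RegionComparison:
    """Per-parameter region means with their relative and percentage differences."""

    ref_means: dict
    measured_means: dict
    r_diff: dict
    p_diff: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(PARAM_NAMES),
                "ref_mean": [self.ref_means[n] for n in PARAM_NAMES],
                "measured_mean": [self.measured_means[n] for n in PARAM_NAMES],
                "R_diff": [self.r_diff[n] for n in PARAM_NAMES],
                "P_diff_pct": [self.p_diff[n] for n in PARAM_NAMES],
            }
        )


def compare_regions(maps: ParameterMaps, ref_mask: np.ndarray, measured_mask: np.ndarray) -> RegionComparison:
    """Region means over two masks and their R_diff / P_diff per parameter.

    Works on ground-truth map dicts as well as inverted :class:`ParameterMaps`.
    """
    if isinstance(maps, ParameterMaps):
        data, inverted = maps.data, maps.mask
    else:
        data, inverted = maps, None
    ref_means, meas_means, r_diff, p_diff = {}, {}, {}, {}
    for name in PARAM_NAMES:
        ref_means[name] = region_mean(data[name], ref_mask, inverted)
        meas_means[name] = region_mean(data[name], measured_mask, inverted)
        r_diff[name] = relative_difference(ref_means[name], meas_means[name])
        p_diff[name] = percentage_difference(ref_means[name], meas_means[name])
    return RegionComparison(ref_means=ref_means, measured_means=meas_means, r_diff=r_diff, p_diff=p_diff)
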