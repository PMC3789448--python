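"""Reflectance-cube reconstruction with a linear heteroassociative memory.

A heteroassociative memory is a linear map trained to associate calibrated
camera responses (10 bands) with known reflectance spectra (default 37
bands, 420-780 nm). Training uses the 24 patches of a colour chart and an
iterative delta rule with ridge regularisation — the regularisation, rather
than a plain pseudoinverse, is what keeps the map robust to measurement
noise. Applying the learned map per pixel turns a calibrated multispectral
image into a reflectance cube (x, y, lambda) clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import SpectralGrid, Spectrum

__all__ = ["TrainingSet", "CoefficientMatrix", "ReflectanceCube", "learn_map", "reconstruct_cube", "gfc"]


@dataclass
class TrainingSet:
    """Per-patch camera responses paired with known reflectance spectra."""

    responses: np.ndarray  # (n_patches, n_bands)
    spectra: np.ndarray  # (n_patches, n_wavelengths)
    grid: SpectralGrid

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.responses.ndim != 2 or self.spectra.ndim != 2:
            raise ValueError("responses and spectra must be 2-D")
        if self.responses.shape[0] != self.spectra.shape[0]:
            raise ValueError("responses and spectra must be aligned one-to-one")
        if self.spectra.shape[1] != len(self.grid):
            raise ValueError("spectra must live on the training grid")
        if np.any(self.spectra < -1e-9) or np.any(self.spectra > 1 + 1e-9):
            raise ValueError("training spectra must lie in [0, 1]")

    @property
    def n_patches(self) -> int:
        return self.responses.shape[0]


@dataclass
class CoefficientMatrix:
    """Learned affine map from band-response space to wavelength space.

    ``weights`` has shape (n_wavelengths, n_bands + 1) and acts affinely on
    raw calibrated responses; the final column is the bias.
    """

    weights: np.ndarray
    grid: SpectralGrid
    training_rmse: float = float("nan")
    epochs: int = 0
    ridge: float = 0.0

    @property
    def n_bands(self) -> int:
        return self.weights.shape[1] - 1

    def apply(self, responses: np.ndarray, clip: bool = True) -> np.ndarray:
        """Apply the map to (..., n_bands) responses -> (..., n_wavelengths)."""
        resp = np.asarray(responses, dtype=float)
        if resp.shape[-1] != self.n_bands:
            raise ValueError(
                f"got {resp.shape[-1]} bands, map expects {self.n_bands}"
            )
        out = resp @ self.weights[:, :-1].T + self.weights[:, -1]
        return np.clip(out, 0.0, 1.0) if clip else out


@dataclass
class ReflectanceCube:
    """(x, y, lambda) skin reflectance in [0, 1] on a spectral grid."""

    data: np.ndarray
    grid: SpectralGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != len(self.grid):
            raise ValueError("cube must be (x, y, lambda) with lambda = grid length")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def pixel(self, y: int, x: int) -> Spectrum:
        return Spectrum(grid=self.grid, values=self.data[y, x])


def learn_map(
    train: TrainingSet,
    ridge: float = 1e-6,
    smooth: float = 10.0,
    tol: float = 1e-12,
    max_epochs: int = 200_000,
) -> CoefficientMatrix:
    """Train the linear associative memory with an iterative batch delta rule.

    Inputs are centred and PCA-whitened first (a pure preconditioning step:
    the whitening transform is folded back into the returned affine map).
    The delta rule minimises

        ||Y - W X||^2 / n + smooth ||D2 W X||^2 / n + ridge ||W||^2,

    where D2 takes second differences along the wavelength axis: real
    reflectance spectra are smooth, and the curvature prior is what lets a
    24-patch chart generalise to spectra outside its exact span (set
    ``smooth=0`` for a pure ridge memory that interpolates its training
    data). ``ridge`` is relative to the whitened input power. Raises if the
    weight update has not fallen below ``tol`` within ``max_epochs``.
    Deterministic (zero initialisation).
    """
    if train.n_patches < 2:
        raise ValueError("need at least two training patches")
    if np.all(train.responses == 0):
        raise ValueError("degenerate all-zero responses")

    R = train.responses
    n, b = R.shape
    offset = R.mean(axis=0)
    Rc = R - offset
    cov = Rc.T @ Rc / n
    evals, evecs = np.linalg.eigh(cov)
    floor = max(float(evals[-1]), 1.0) * 1e-14
    T = (evecs / np.sqrt(np.maximum(evals, floor))).T  # whitening: x' = T (x - offset)
    X = np.hstack([Rc @ T.T, np.ones((n, 1))]).T  # (b+1, n), cov ~ identity
    Y = train.spectra.T  # (L, n)

    n_out = Y.shape[0]
    D2 = np.zeros((max(n_out - 2, 0), n_out))
    for i in range(n_out - 2):
        D2[i, i : i + 3] = (1.0, -2.0, 1.0)
    P = smooth * (D2.T @ D2)  # curvature prior on predicted spectra

    C = X @ X.T / n
    lam = ridge * float(np.trace(C)) / C.shape[0]
    eigs = np.linalg.eigvalsh(C)
    p_max = float(np.linalg.eigvalsh(P)[-1]) if smooth else 0.0
    L = (1.0 + p_max) * float(eigs[-1]) + lam
    # step/momentum from the active spectrum only: directions with (near-)zero
    # input power carry no gradient and stay at their zero initialisation
    active = eigs[eigs > 1e-10 * max(float(eigs[-1]), 1e-30)]
    mu = float(active[0]) + lam if active.size else L
    eta = 4.0 / (np.sqrt(L) + np.sqrt(mu)) ** 2
    beta = ((np.sqrt(L) - np.sqrt(mu)) / (np.sqrt(L) + np.sqrt(mu))) ** 2

    W = np.zeros((n_out, X.shape[0]))
    prev = W.copy()
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        grad = (W @ X - Y) @ X.T / n + lam * W
        if smooth:
            grad += P @ W @ C
        new = W - eta * grad + beta * (W - prev)
        step = new - W
        prev, W = W, new
        if float(np.max(np.abs(step))) < tol:
            break
    else:
        raise RuntimeError("delta-rule training did not converge within max_epochs")

    rmse = float(np.sqrt(np.mean((W @ X - Y) ** 2)))
    # fold the whitening back into one affine map on raw responses
    M = W[:, :-1] @ T
    bias = W[:, -1] - M @ offset
    weights = np.hstack([M, bias[:, None]])
    return CoefficientMatrix(
        weights=weights, grid=train.grid, training_rmse=rmse, epochs=epoch, ridge=lam
    )


def reconstruct_cube(msi: np.ndarray, W: CoefficientMatrix, clip: bool = True) -> ReflectanceCube:
    """Per-pixel affine application of the learned map to an (h, w, bands) image."""
    msi = np.asarray(msi, dtype=float)
    if msi.ndim != 3:
        raise ValueError("multispectral image must be (h, w, bands)")
    data = W.apply(msi, clip=clip)
    return ReflectanceCube(data=data, grid=W.grid, meta={"bands_in": W.n_bands})


def gfc(a, b) -> float:
    """Goodness-of-fit coefficient between two spectra on one grid, in [0, 1].

    Values above 0.99 are conventionally read as a good reconstruction.
    """
    av = a.values if isinstance(a, Spectrum) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, Spectrum) else np.asarray(b, dtype=float)
    if isinstance(a, Spectrum) and isinstance(b, Spectrum):
        a.grid.require_match(b.grid)
    if av.shape != bv.shape:
        raise ValueError("spectra must share one grid")
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na == 0 or nb == 0:
        raise ValueError("GFC undefined for a zero-norm spectrum")
    return float(abs(np.dot(av, bv)) / (na * nb))
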