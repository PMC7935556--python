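"""Savitzky-Golay spectral filtering and its joint spatial-spectral 2D
extension (TSG).

A 1D Savitzky-Golay filter of half-window ``m`` and polynomial order ``n``
smooths by local least-squares polynomial fitting; the fit at the window
center reduces to a fixed symmetric convolution kernel — the center row of
the projection matrix ``B = X (X^T X)^-1 X^T`` built from the Vandermonde
design on offsets -m..m.

The TSG kernel places those 1D coefficients along the four symmetry
directions of a square (2m+1)^2 window — horizontal, vertical and the two
diagonals — at radial distance index ``floor(sqrt(i^2 + j^2))``, divided by
4 so each direction carries a quarter of the weight; the center keeps the
full center coefficient.  Offsets whose distance index exceeds ``m`` (outer
diagonal corners) get weight 0.  The raw construction can have DC gain
slightly below 1 (226/231 at m=3, n=4), so kernels are renormalized to unit
sum by default; the unnormalized variant is retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from hsiprep.cube_io import HyperCube, ValidationError

__all__ = [
    "SGKernel1D",
    "TSGKernel2D",
    "sg_projection_matrix",
    "sg_kernel",
    "sg_filter_spectra",
    "tsg_kernel",
    "tsg_filter",
]


def _check_mn(m: int, n: int) -> None:
    if m < 1:
        raise ValidationError(f"half-window m must be >= 1, got {m}")
    if not (0 <= n < 2 * m + 1):
        raise ValidationError(f"polynomial order n must satisfy 0 <= n < 2m+1, got m={m}, n={n}")


@dataclass(frozen=True)
class SGKernel1D:
    """Symmetric 1D smoothing kernel of window 2m+1, polynomial order n."""

    m: int
    n: int
    coefficients: np.ndarray     # length 2m+1, indexed by offset -m..m

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (2 * self.m + 1,):
            raise ValidationError("coefficient length must be 2m+1")
        if not np.allclose(c, c[::-1], atol=1e-12):
            raise ValidationError("SG coefficients must be symmetric")
        if abs(c.sum() - 1.0) > 1e-12:
            raise ValidationError("SG coefficients must sum to 1")

    def by_distance(self, d: int) -> float:
        """Coefficient at absolute offset ``d`` from the center; 0 beyond m."""
        return float(self.coefficients[self.m + d]) if d <= self.m else 0.0


@dataclass(frozen=True)
class TSGKernel2D:
    """The 2D four-direction SG kernel on a (2m+1)^2 grid."""

    m: int
    n: int
    grid: np.ndarray             # (2m+1, 2m+1), indexed by offsets (i, j)
    renormalized: bool


def sg_projection_matrix(m: int, n: int) -> np.ndarray:
    """The least-squares smoothing projection ``B = X (X^T X)^-1 X^T``.

    ``X`` is the Vandermonde design on offsets -m..m with columns x^0..x^n.
    ``B`` is symmetric and idempotent; row ``k`` gives the fitted value at
    window position ``k`` as a linear function of the raw window.
    """
    _check_mn(m, n)
    # scaling x to [-1, 1] leaves the column space (hence B) unchanged but
    # keeps the design well-conditioned at large m, n
    x = np.arange(-m, m + 1, dtype=float) / m
    X = np.vander(x, N=n + 1, increasing=True)
    Q, R = np.linalg.qr(X)
    assert np.min(np.abs(np.diag(R))) > 0, "design matrix rank-deficient"
    B = Q @ Q.T
    return B


def sg_kernel(m: int, n: int) -> SGKernel1D:
    """The SG smoothing kernel: center row of the projection matrix."""
    B = sg_projection_matrix(m, n)
    center = B[m].copy()
    # enforce exact symmetry and unit sum against floating-point residue
    center = 0.5 * (center + center[::-1])
    center /= center.sum()
    return SGKernel1D(m, n, center)


def sg_filter_spectra(cube: HyperCube, m: int, n: int,
                      padding: str = "mirror") -> HyperCube:
    """Smooth every pixel's spectrum with the (m, n) SG kernel.

    ``padding="mirror"`` reflects the spectrum about its end bands;
    ``padding="polynomial-edge"`` fits the edge windows with the same local
    polynomial model instead of convolving padded values.
    """
    _check_mn(m, n)
    if cube.n_bands < 2 * m + 1:
        raise ValidationError(
            f"need at least 2m+1 = {2 * m + 1} bands, cube has {cube.n_bands}"
        )
    if padding == "mirror":
        kern = sg_kernel(m, n)
        out = ndimage.convolve1d(cube.data.astype(float), kern.coefficients,
                                 axis=2, mode="mirror")
    elif padding == "polynomial-edge":
        out = signal.savgol_filter(cube.data.astype(float), 2 * m + 1, n,
                                   axis=2, mode="interp")
    else:
        raise ValidationError(f"unknown padding {padding!r}")
    return cube.with_data(out, extra_metadata={"filter": f"sg(m={m}, n={n}, {padding})"})


def tsg_kernel(m: int, n: int, renormalize: bool = True) -> TSGKernel2D:
    """Build the four-direction 2D SG kernel.

    grid(0,0) = b[0]; grid(i,j) = b[floor(sqrt(i^2+j^2))]/4 when (i,j) lies
    on an axis or diagonal; 0 elsewhere and wherever the distance index
    exceeds m.  ``renormalize`` divides by the grid sum so constant images
    pass through unchanged.
    """
    kern1d = sg_kernel(m, n)
    size = 2 * m + 1
    grid = np.zeros((size, size))
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            if i == 0 and j == 0:
                grid[m, m] = kern1d.by_distance(0)
            elif i == 0 or j == 0 or i == j or i == -j:
                d = math.floor(math.sqrt(i * i + j * j))
                grid[m + i, m + j] = kern1d.by_distance(d) / 4.0
    if renormalize:
        total = grid.sum()
        if abs(total) < 1e-12:
            raise ValidationError(f"TSG kernel sum ~ 0 at m={m}, n={n}; cannot renormalize")
        grid = grid / total
    return TSGKernel2D(m, n, grid, renormalize)


def _pad_mode(padding: str) -> str:
    if padding == "mirror":
        return "reflect"          # numpy 'reflect' = mirror about the edge sample
    if padding == "zero":
        return "constant"
    raise ValidationError(f"unknown padding {padding!r}")


def tsg_filter(cube: HyperCube, m: int, n: int, padding: str = "mirror",
               method: str = "fft", renormalize: bool = True) -> HyperCube:
    """Convolve every band image with the TSG kernel.

    ``method="fft"`` uses FFT-based convolution (the intended fast path);
    ``method="direct"`` is the spatial-domain reference — the two agree to
    1e-8 relative error.  Spatial extents are preserved via edge padding.
    """
    if method not in ("fft", "direct"):
        raise ValidationError(f"unknown method {method!r}")
    kern = tsg_kernel(m, n, renormalize=renormalize)
    nx, ny, _ = cube.shape
    if nx < 2 * m + 1 or ny < 2 * m + 1:
        raise ValidationError(
            f"band images ({nx}x{ny}) smaller than the {2*m+1}x{2*m+1} kernel"
        )
    padded = np.pad(cube.data.astype(float),
                    ((m, m), (m, m), (0, 0)), mode=_pad_mode(padding))
    out = np.empty_like(cube.data, dtype=float)
    for b in range(cube.n_bands):
        if method == "fft":
            out[:, :, b] = signal.fftconvolve(padded[:, :, b], kern.grid, mode="valid")
        else:
            out[:, :, b] = signal.convolve(padded[:, :, b], kern.grid,
                                           mode="valid", method="direct")
    return cube.with_data(
        out,
        extra_metadata={"filter": f"tsg(m={m}, n={n}, {padding}, {method}, "
                                  f"renormalize={renormalize})"},
    )
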