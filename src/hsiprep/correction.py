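"""Radiometric correction against standard reflectance plates.

For a line-scan cube the measured DN decomposes as ``f = g + xi`` where ``g``
is the true (illumination-weighted) signal and ``xi`` additive dark-current
noise, constant along the scan axis ``x`` at fixed detector row ``y`` and
band.  Two calibration plates of known reflectance R1, R2 imaged in the same
scene give per-(y, band) column-mean profiles f1, f2; because illumination
cancels between plates at equal (y, band), g1/g2 = R1/R2, and the noise
solves to

    xi(y, b) = (R1 * f2(y, b) - R2 * f1(y, b)) / (R1 - R2)

Subtracting ``xi`` and dividing by the noise-subtracted profile of a plate of
known reflectance converts DN to reflectance exactly whenever plate means
equal their model values — an algebraic identity, not an asymptotic one.

The classical black-and-white baseline
``ref = R * (f - f_dark) / (f_white - f_dark)`` is provided for comparison;
it degrades when the dark frame was acquired under drifted dark current.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from hsiprep.cube_io import HyperCube, ValidationError

__all__ = [
    "PlateRegion",
    "PlateProfile",
    "NoiseField",
    "CalibrationError",
    "plate_profile",
    "estimate_noise",
    "subtract_noise",
    "reflectance_invert",
    "black_white_correct",
    "correction_mse",
]

R_TOLERANCE = 1e-6  # minimum |R1 - R2| for a usable plate pair


class CalibrationError(ValueError):
    """Raised for degenerate or non-positive calibration inputs."""


@dataclass(frozen=True)
class PlateRegion:
    """A reference plate: known reflectance and spatial footprint.

    ``reflectance`` is a scalar fraction in (0, 1] or a per-band curve;
    calibrated plates are spectrally near-flat but a curve is accepted.
    Intervals are half-open pixel index ranges on the cube grid.
    """

    reflectance: float | np.ndarray
    x_interval: tuple[int, int]
    y_interval: tuple[int, int]

    def __post_init__(self) -> None:
        refl = np.asarray(self.reflectance, dtype=float)
        if np.any(refl <= 0) or np.any(refl > 1):
            raise ValidationError(f"plate reflectance must lie in (0, 1], got {self.reflectance}")
        for name, (lo, hi) in (("x", self.x_interval), ("y", self.y_interval)):
            if not (0 <= lo < hi):
                raise ValidationError(f"empty or negative {name}_interval {(lo, hi)}")

    def check_within(self, cube: HyperCube) -> None:
        nx, ny, _ = cube.shape
        if self.x_interval[1] > nx or self.y_interval[1] > ny:
            raise ValidationError(
                f"plate footprint x{self.x_interval} y{self.y_interval} exceeds "
                f"cube extents ({nx}, {ny})"
            )


@dataclass
class PlateProfile:
    """Per-(y, band) mean DN of a plate, averaged over its scan columns."""

    values: np.ndarray               # (ny, n_bands)
    region: PlateRegion

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("plate profile must be 2D (y, band)")


@dataclass
class NoiseField:
    """Per-(y, band) additive noise estimate xi."""

    values: np.ndarray               # (ny, n_bands)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or not np.all(np.isfinite(self.values)):
            raise ValidationError("noise field must be 2D and finite")


def plate_profile(cube: HyperCube, region: PlateRegion) -> PlateProfile:
    """Mean DN over the plate's scan columns, for every detector row.

    The mean is taken over ``x`` in ``region.x_interval`` (the ':' of the
    plate measurement).  Rows outside ``region.y_interval`` — plates that do
    not span the full field-of-view line — are filled by nearest-neighbor
    extrapolation along ``y``, with a warning, since the noise estimate is
    needed at every row.
    """
    region.check_within(cube)
    x0, x1 = region.x_interval
    y0, y1 = region.y_interval
    ny = cube.shape[1]
    measured = cube.data[x0:x1, y0:y1, :].mean(axis=0)   # (y1-y0, nb)
    if y0 == 0 and y1 == ny:
        values = measured
    else:
        warnings.warn(
            f"plate spans rows [{y0}, {y1}) of {ny}; extrapolating the profile "
            "to the remaining rows by nearest neighbor",
            stacklevel=2,
        )
        idx = np.clip(np.arange(ny), y0, y1 - 1) - y0
        values = measured[idx, :]
    return PlateProfile(values, region)


def _reflectance_column(region_or_value: PlateRegion | float | np.ndarray,
                        n_bands: int) -> np.ndarray:
    refl = region_or_value.reflectance if isinstance(region_or_value, PlateRegion) else region_or_value
    arr = np.asarray(refl, dtype=float)
    if arr.ndim == 0:
        return np.full((1, n_bands), float(arr))
    if arr.shape != (n_bands,):
        raise ValidationError(f"per-band reflectance has length {arr.size}, expected {n_bands}")
    return arr[None, :]


def estimate_noise(p1: PlateProfile, p2: PlateProfile,
                   R1: float | np.ndarray | None = None,
                   R2: float | np.ndarray | None = None) -> NoiseField:
    """Solve the two-plate system for the additive noise field.

    ``xi = (R1 * f2 - R2 * f1) / (R1 - R2)`` elementwise over (y, band).
    Reflectances default to the profiles' own regions.  Exact whenever the
    plate column means equal their model values.
    """
    if p1.values.shape != p2.values.shape:
        raise ValidationError(
            f"plate profiles disagree in shape: {p1.values.shape} vs {p2.values.shape}"
        )
    nb = p1.values.shape[1]
    r1 = _reflectance_column(p1.region if R1 is None else R1, nb)
    r2 = _reflectance_column(p2.region if R2 is None else R2, nb)
    if np.any(np.abs(r1 - r2) < R_TOLERANCE):
        raise CalibrationError(
            f"plate reflectances too close (|R1 - R2| < {R_TOLERANCE}); "
            "the two-plate system is degenerate"
        )
    xi = (r1 * p2.values - r2 * p1.values) / (r1 - r2)
    return NoiseField(xi)


def subtract_noise(cube: HyperCube, noise: NoiseField) -> HyperCube:
    """Remove the additive noise estimate: g(x,y,b) = f(x,y,b) - xi(y,b)."""
    if noise.values.shape != cube.shape[1:]:
        raise ValidationError(
            f"noise field shape {noise.values.shape} does not match cube "
            f"(y, band) extents {cube.shape[1:]}"
        )
    return cube.with_data(cube.data - noise.values[None, :, :],
                          extra_metadata={"noise_subtracted": True})


def reflectance_invert(true_dn: HyperCube, calib_profile: PlateProfile,
                       R_calib: float | np.ndarray | None = None,
                       floor: float | None = None) -> HyperCube:
    """Convert noise-subtracted DN to reflectance against a known plate.

    ``reflectance = R_calib * g / g_calib`` with ``g_calib`` the calibration
    plate's noise-subtracted profile.  Calibration DN at or below ``floor``
    (default 1e-9 of the profile's full scale) raises, listing how many
    (y, band) cells offend, rather than silently producing infinities.
    """
    nb = true_dn.n_bands
    r = _reflectance_column(calib_profile.region if R_calib is None else R_calib, nb)
    g_calib = calib_profile.values
    if g_calib.shape != true_dn.shape[1:]:
        raise ValidationError("calibration profile extents do not match the cube")
    if floor is None:
        floor = 1e-9 * float(np.max(np.abs(g_calib), initial=0.0))
    bad = g_calib <= floor
    if np.any(bad):
        ys, bands = np.nonzero(bad)
        raise CalibrationError(
            f"calibration DN <= {floor:g} at {bad.sum()} (y, band) cells "
            f"(first: y={ys[0]}, band={bands[0]}); check plate footprint and "
            "noise subtraction"
        )
    refl = r[None, :, :] * true_dn.data / g_calib[None, :, :]
    return true_dn.with_data(refl, value_kind="reflectance",
                             extra_metadata={"correction": "double-plate"})


def black_white_correct(cube: HyperCube, white_profile: np.ndarray,
                        dark_frame: np.ndarray, R: float | np.ndarray = 0.98) -> HyperCube:
    """Classical normalization ``ref = R * (f - f_dark) / (f_white - f_dark)``.

    ``white_profile`` and ``dark_frame`` are (y, band) fields; the white
    reference is the DN of a plate of reflectance ``R`` and the dark frame a
    lens-capped acquisition.  A dark frame acquired at a different time than
    the scene carries a different dark-current realization, which is exactly
    the error mode the double-plate method eliminates.
    """
    white = np.asarray(white_profile, dtype=float)
    dark = np.asarray(dark_frame, dtype=float)
    if white.shape != cube.shape[1:] or dark.shape != cube.shape[1:]:
        raise ValidationError("white/dark references must match cube (y, band) extents")
    denom = white - dark
    if np.any(denom == 0):
        raise CalibrationError("white minus dark reference is zero somewhere")
    r = _reflectance_column(R, cube.n_bands)
    refl = r[None, :, :] * (cube.data - dark[None, :, :]) / denom[None, :, :]
    return cube.with_data(refl, value_kind="reflectance",
                          extra_metadata={"correction": "black-white"})


def correction_mse(corrected_spectrum: np.ndarray, calibration_spectrum: np.ndarray,
                   wavelengths: np.ndarray | None = None,
                   band_window: tuple[float, float] | None = None,
                   ) -> tuple[np.ndarray, float]:
    """Per-band squared error and its mean between two reflectance spectra.

    ``band_window`` is a wavelength interval in nm (inclusive); bands outside
    it are excluded from both outputs.  Used to score a corrected spectrum
    against the calibration spectrum of a plate of known reflectance.
    """
    a = np.asarray(corrected_spectrum, dtype=float)
    b = np.asarray(calibration_spectrum, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("spectra must be 1D and equal length")
    sq = (a - b) ** 2
    if band_window is not None:
        if wavelengths is None:
            raise ValidationError("band_window requires the wavelength axis")
        wl = np.asarray(wavelengths, dtype=float)
        if wl.shape != a.shape:
            raise ValidationError("wavelength axis length mismatch")
        lo, hi = band_window
        keep = (wl >= lo) & (wl <= hi)
        if not np.any(keep):
            raise ValidationError(f"no bands inside window {band_window}")
        sq = sq[keep]
    return sq, float(sq.mean())
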