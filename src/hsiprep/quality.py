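"""Image-quality metrics for hyperspectral bands.

Per-band metrics: histogram Shannon entropy (bits), single-image SNR
(20*log10(mean/std), dB), clarity (mean gradient magnitude, an "average
gradient" sharpness score), and — against a reference — PSNR (dB) and
structural similarity.  ``quality_report`` tabulates all of them band by
band with a final band-average row.

Conventions: the single-image SNR and clarity definitions vary across the
literature; the ones here are the simplest standard forms and are meant for
before/after-filtering comparisons (directional behavior), not for matching
any externally published absolute table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from hsiprep.cube_io import HyperCube, ValidationError

__all__ = [
    "UndefinedMetricError",
    "QualityReport",
    "image_entropy",
    "image_snr",
    "image_clarity",
    "psnr",
    "ssim",
    "quality_report",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given image (e.g. zero std)."""


def image_entropy(image: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the histogram over ``bins`` equal-width bins
    spanning the image's own value range.  Constant images have entropy 0;
    empty bins contribute 0."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValidationError("empty image")
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(image, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / image.size
    return float(-(p * np.log2(p)).sum())


def image_snr(image: np.ndarray) -> float:
    """Single-image SNR in dB: ``20 * log10(mean / std)`` of pixel values."""
    image = np.asarray(image, dtype=float)
    mu = image.mean()
    sigma = image.std()
    if sigma == 0 or mu == 0:
        raise UndefinedMetricError(
            f"SNR undefined for mean={mu}, std={sigma} (constant or zero-mean image)"
        )
    return float(20.0 * math.log10(abs(mu) / sigma))


def image_clarity(image: np.ndarray) -> float:
    """Mean gradient magnitude sqrt(gx^2 + gy^2) over interior pixels
    (central differences)."""
    image = np.asarray(image, dtype=float)
    if min(image.shape) < 2:
        raise ValidationError("clarity needs both extents >= 2")
    gx, gy = np.gradient(image)
    mag = np.hypot(gx, gy)
    interior = mag[1:-1, 1:-1] if min(image.shape) >= 3 else mag
    return float(interior.mean())


def psnr(reference: np.ndarray, test: np.ndarray, peak: float | None = None) -> float:
    """Peak SNR in dB: ``10 * log10(peak^2 / MSE)``; identical images give
    ``inf``.  ``peak`` defaults to the reference maximum."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValidationError(f"shape mismatch {reference.shape} vs {test.shape}")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return math.inf
    if peak is None:
        peak = float(np.abs(reference).max())
    return float(10.0 * math.log10(peak * peak / mse))


def ssim(reference: np.ndarray, test: np.ndarray, window: int = 11,
         sigma: float = 1.5, peak: float | None = None) -> float:
    """Mean local structural similarity (Gaussian window, standard
    luminance-contrast-structure form with C1=(0.01*peak)^2,
    C2=(0.03*peak)^2)."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValidationError(f"shape mismatch {reference.shape} vs {test.shape}")
    if min(reference.shape) < window:
        raise ValidationError(f"image smaller than the {window}x{window} SSIM window")
    if peak is None:
        hi = max(reference.max(), test.max())
        lo = min(reference.min(), test.min())
        peak = float(hi - lo) or 1.0
    return float(structural_similarity(
        reference, test, win_size=window, gaussian_weights=True, sigma=sigma,
        use_sample_covariance=False, data_range=peak, K1=0.01, K2=0.03,
    ))


@dataclass
class QualityReport:
    """Per-band metric table plus a band-average row (band = 'average')."""

    table: pd.DataFrame

    @property
    def averages(self) -> pd.Series:
        return self.table[self.table["band"] == "average"].iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def quality_report(original: HyperCube, filtered: HyperCube | None = None,
                   bins: int = 256) -> QualityReport:
    """Tabulate per-band quality metrics.

    entropy/snr/clarity describe ``filtered`` when given (else ``original``);
    psnr/ssim compare ``filtered`` against ``original`` and are only present
    when both cubes are supplied.
    """
    if filtered is not None and filtered.shape != original.shape:
        raise ValidationError(
            f"cube extents differ: {original.shape} vs {filtered.shape}"
        )
    subject = filtered if filtered is not None else original
    rows = []
    for b in range(subject.n_bands):
        image = subject.band(b)
        row: dict[str, object] = {
            "band": b,
            "entropy": image_entropy(image, bins=bins),
            "snr_db": image_snr(image),
            "clarity": image_clarity(image),
        }
        if filtered is not None:
            ref = original.band(b)
            row["psnr_db"] = psnr(ref, image)
            row["ssim"] = ssim(ref, image)
        rows.append(row)
    table = pd.DataFrame(rows)
    avg = {"band": "average"}
    for col in table.columns:
        if col != "band":
            avg[col] = float(table[col].mean())
    table = pd.concat([table, pd.DataFrame([avg])], ignore_index=True)
    return QualityReport(table)
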