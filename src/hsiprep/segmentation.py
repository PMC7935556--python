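"""Spectral-angle + PCA segmentation with mask intersection.

Two independent foreground estimates are intersected:

* Spectral-angle branch — each band image, flattened to a vector, is scored
  by its angle to a reference direction; the angle is a scale-invariant
  spatial-heterogeneity score, large for bands where the targets contrast
  strongly with the stage.  The top-k band images are averaged (suppressing
  uncorrelated per-band noise) and thresholded: segmentation result 1.
* PCA branch — pixels are observations, bands variables; a principal
  component score image with clear target contours is thresholded:
  segmentation result 2.

Result 3 = result 1 AND result 2 masks the cube, removing stage background
while keeping every target pixel that both views agree on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu
from sklearn.decomposition import PCA

from hsiprep.cube_io import BinaryMask, HyperCube, ValidationError
from hsiprep.quality import image_entropy

__all__ = [
    "BandScore",
    "PCAResult",
    "SegmentParams",
    "band_spectral_angle",
    "select_top_bands",
    "select_band_by_entropy",
    "mean_band_image",
    "threshold_segment",
    "pca_decompose",
    "intersect_masks",
    "apply_mask",
    "segment_pipeline",
]


@dataclass(frozen=True)
class BandScore:
    band_index: int
    wavelength: float
    score: float     # angle in radians (or entropy in bits for that variant)


@dataclass
class PCAResult:
    """Principal components of a cube with pixels as observations."""

    component_images: list[np.ndarray]   # 2D (x, y) score images
    explained_ratio: np.ndarray          # per-component variance share
    mean_spectrum: np.ndarray            # per-band mean used for centering
    components: np.ndarray               # (n_components, n_bands) loadings

    def reconstruct(self) -> np.ndarray:
        """Centered data rebuilt from the kept components, shape (x, y, band)."""
        nx, ny = self.component_images[0].shape
        scores = np.stack([im.ravel() for im in self.component_images], axis=1)
        return (scores @ self.components).reshape(nx, ny, -1)


def _reference_vector(cube: HyperCube, reference: str) -> np.ndarray:
    n_pixels = cube.shape[0] * cube.shape[1]
    if reference == "ones":
        return np.ones(n_pixels)
    if reference == "mean_spectrum_direction":
        # the band-averaged image: the common spatial pattern across bands
        return cube.data.mean(axis=2).ravel()
    if reference == "basis_axis":
        vec = np.zeros(n_pixels)
        vec[0] = 1.0
        return vec
    raise ValidationError(f"unknown reference {reference!r}")


def band_spectral_angle(cube: HyperCube, reference: str = "ones") -> list[BandScore]:
    """Angle of each flattened band image to a reference direction.

    ``theta = arccos(<t, r> / (|t| |r|))``; for non-negative data and
    reference the angle lies in [0, pi/2].  An all-zero band has no
    direction; its angle is defined as pi/2 with a warning.
    """
    ref = _reference_vector(cube, reference)
    ref_norm = np.linalg.norm(ref)
    if ref_norm == 0:
        raise ValidationError("reference vector is zero")
    scores = []
    for b in range(cube.n_bands):
        t = cube.band(b).ravel().astype(float)
        t_norm = np.linalg.norm(t)
        if t_norm == 0:
            warnings.warn(f"band {b} is all zero; spectral angle set to pi/2", stacklevel=2)
            angle = np.pi / 2
        else:
            cosine = np.clip(np.dot(t, ref) / (t_norm * ref_norm), -1.0, 1.0)
            angle = float(np.arccos(cosine))
        scores.append(BandScore(b, float(cube.wavelengths[b]), angle))
    return scores


def select_top_bands(scores: Sequence[BandScore], k: int = 20) -> list[int]:
    """Indices of the k largest scores, returned sorted by band index.

    Ties are broken toward the lower band index.
    """
    if k <= 0:
        raise ValidationError(f"k must be positive, got {k}")
    if k > len(scores):
        raise ValidationError(f"k={k} exceeds band count {len(scores)}")
    order = sorted(scores, key=lambda s: (-s.score, s.band_index))
    return sorted(s.band_index for s in order[:k])


def select_band_by_entropy(cube: HyperCube, bins: int = 256) -> int:
    """Index of the band whose image has maximal histogram entropy
    (ties: lowest index)."""
    entropies = [image_entropy(cube.band(b), bins=bins) for b in range(cube.n_bands)]
    return int(np.argmax(entropies))


def mean_band_image(cube: HyperCube, bands: Sequence[int]) -> np.ndarray:
    """Pixelwise arithmetic mean over the listed band images."""
    if len(bands) == 0:
        raise ValidationError("band list is empty")
    return cube.data[:, :, list(bands)].mean(axis=2)


def threshold_segment(image: np.ndarray, method: str = "otsu",
                      threshold: float | None = None,
                      foreground: str = "below") -> BinaryMask:
    """Binarize an image at a threshold.

    ``foreground="below"`` marks pixels <= threshold (dark targets on a
    bright stage), ``"above"`` marks pixels > threshold.  ``method="otsu"``
    picks the threshold by minimizing intra-class variance; ``"manual"``
    uses the given value.
    """
    image = np.asarray(image, dtype=float)
    if foreground not in ("below", "above"):
        raise ValidationError(f"foreground must be 'below' or 'above', got {foreground!r}")
    if method == "manual":
        if threshold is None:
            raise ValidationError("manual thresholding requires a threshold value")
        t = float(threshold)
    elif method == "otsu":
        if image.min() == image.max():
            raise ValidationError(
                "Otsu threshold undefined for a constant image; use method='manual'"
            )
        t = float(threshold_otsu(image))
    else:
        raise ValidationError(f"unknown threshold method {method!r}")
    grid = image <= t if foreground == "below" else image > t
    return BinaryMask(grid)


def pca_decompose(cube: HyperCube, n_components: int) -> PCAResult:
    """PCA of a cube with pixels as observations and bands as variables.

    Data are centered by the mean spectrum; each component image is the
    projection reshaped to (x, y).  Eigenvector sign is arbitrary, so each
    component is flipped if needed to give its score image non-negative
    skewness (a reproducibility convention: the minority structure ends up
    on the positive side).
    """
    if not (1 <= n_components <= cube.n_bands):
        raise ValidationError(
            f"n_components must be in [1, {cube.n_bands}], got {n_components}"
        )
    nx, ny, nb = cube.shape
    flat = cube.data.reshape(nx * ny, nb).astype(float)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(flat)
    components = model.components_.copy()
    for j in range(n_components):
        if stats.skew(scores[:, j]) < 0:
            scores[:, j] = -scores[:, j]
            components[j] = -components[j]
    images = [scores[:, j].reshape(nx, ny) for j in range(n_components)]
    return PCAResult(images, model.explained_variance_ratio_.copy(),
                     model.mean_.copy(), components)


def intersect_masks(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Logical AND of two masks on the same grid."""
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return BinaryMask(a.grid & b.grid)


def apply_mask(cube: HyperCube, mask: BinaryMask, fill: float = 0.0) -> HyperCube:
    """Set background pixels to ``fill`` in every band; foreground unchanged."""
    mask.check_matches(cube)
    data = cube.data.astype(float).copy()
    data[~mask.grid, :] = fill
    return cube.with_data(
        data, extra_metadata={"mask": f"applied ({mask.count} foreground px, fill={fill})"}
    )


@dataclass
class SegmentParams:
    """Parameters of the two-branch segmentation pipeline.

    ``pc_index`` is 1-based; ``"auto"`` picks, among the leading components,
    the score image whose thresholded mask agrees best (Dice) with the
    spectral-angle mask — operationalizing the by-eye choice of "the
    component image with distinct target contours".  ``pc_polarity="auto"``
    likewise tries both sides of the threshold.
    """

    k_bands: int = 20
    reference: str = "ones"
    n_components: int = 6
    pc_index: int | str = "auto"
    threshold_method: str = "otsu"
    manual_threshold: float | None = None
    angle_polarity: str = "below"
    pc_polarity: str = "auto"


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    total = a.sum() + b.sum()
    return 2.0 * inter / total if total else 1.0


def segment_pipeline(cube: HyperCube,
                     params: SegmentParams | None = None) -> tuple[BinaryMask, dict]:
    """Run both segmentation branches and intersect them.

    Returns the result-3 mask and a diagnostics record (selected bands,
    thresholds, explained variance ratios, chosen component and polarity).
    """
    params = params or SegmentParams()
    scores = band_spectral_angle(cube, params.reference)
    top = select_top_bands(scores, min(params.k_bands, cube.n_bands))
    combined = mean_band_image(cube, top)
    result1 = threshold_segment(combined, params.threshold_method,
                                params.manual_threshold, params.angle_polarity)

    n_comp = min(params.n_components, cube.n_bands)
    pca = pca_decompose(cube, n_comp)

    polarities = (("below", "above") if params.pc_polarity == "auto"
                  else (params.pc_polarity,))
    if params.pc_index == "auto":
        candidates = range(n_comp)
    else:
        idx = int(params.pc_index) - 1
        if not (0 <= idx < n_comp):
            raise ValidationError(f"pc_index {params.pc_index} outside 1..{n_comp}")
        candidates = (idx,)

    best: tuple[float, int, str, BinaryMask] | None = None
    for comp in candidates:
        image = pca.component_images[comp]
        for polarity in polarities:
            try:
                mask = threshold_segment(image, params.threshold_method,
                                         params.manual_threshold, polarity)
            except ValidationError:
                continue
            score = _dice(mask.grid, result1.grid)
            if best is None or score > best[0]:
                best = (score, comp, polarity, mask)
    if best is None:
        raise ValidationError("no usable principal-component mask found")
    _, chosen_comp, chosen_polarity, result2 = best

    result3 = intersect_masks(result1, result2)
    diagnostics = {
        "selected_bands": top,
        "selected_wavelengths": [float(cube.wavelengths[b]) for b in top],
        "band_scores": [s.score for s in scores],
        "result1_count": result1.count,
        "result2_count": result2.count,
        "result3_count": result3.count,
        "explained_ratio": pca.explained_ratio.tolist(),
        "pc_index": chosen_comp + 1,
        "pc_polarity": chosen_polarity,
    }
    return result3, diagnostics
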