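"""Synthetic line-scan hyperspectral scene generator.

The sensor model mirrors a pushbroom/line-scan acquisition: the detector
records one field-of-view line (``y``) times spectrum (``band``) per scan
step (``x``), so for fixed ``(y, band)`` every scan position is read by the
same detector element.  The rendered digital number is

    DN(x, y, b) = L(y, b) * rho(x, y, b) + xi(y, b) + eps(x, y, b)

with ``L`` an illumination/gain field (mildly darker toward the line ends,
emulating uneven lamp illumination), ``xi`` a smooth additive dark-current
field that is *exactly constant along the scan axis* — the structural
assumption the double-plate correction exploits — and ``eps`` i.i.d. sensor
noise.

The stage background is a bright white surface; seeds are darker elliptical
blobs of two spectral classes (healthy / infected) with a radial shading
gradient emulating their 3D shape; calibrated reflectance plates (by default
2%, 50% and 98%) occupy x-intervals spanning the whole field-of-view line.
All randomness flows from ``SceneSpec.rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from hsiprep.cube_io import BinaryMask, HyperCube

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "PlacementError",
    "make_signature",
    "render_scene",
    "render_references",
]

CLASS_NAMES = ("healthy", "infected")


class PlacementError(RuntimeError):
    """Raised when seed blobs cannot be placed without overlap."""


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def make_signature(cls: str, wavelengths: np.ndarray, contrast: float = 0.12) -> np.ndarray:
    """A smooth reflectance spectrum for one scene class.

    ``background`` is the bright stage (flat, ~0.9).  ``healthy`` seeds show a
    vegetation-like red edge near 720 nm; ``infected`` seeds are brighter in
    the visible (bleached, pinkish tissue) and weaker past the red edge.
    ``contrast`` scales the healthy/infected difference; at the default the
    peak absolute separation is >= 0.1 reflectance.
    """
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or (w.size > 1 and not np.all(np.diff(w) > 0)):
        raise ValueError("wavelengths must be 1D strictly increasing")
    if cls == "background":
        return np.full_like(w, 0.9)
    edge = _sigmoid((w - 720.0) / 28.0)
    healthy = 0.30 + 0.32 * edge + 0.03 * np.exp(-((w - 550.0) ** 2) / (2 * 45.0**2))
    if cls == "healthy":
        spectrum = healthy
    elif cls == "infected":
        bump = np.exp(-((w - 600.0) ** 2) / (2 * 70.0**2))
        spectrum = healthy + contrast * (bump - 0.5 * edge)
    else:
        raise ValueError(f"unknown class {cls!r}")
    if not np.all((spectrum > 0) & (spectrum < 1)):
        raise ValueError("signature left (0, 1); adjust contrast")
    return spectrum


@dataclass
class SceneSpec:
    """Parameters of a synthetic scene.

    Defaults define the package's reference study conditions: structured
    noise amplitude 5% of full scale, sensor noise sigma 0.5% of full scale,
    2%/50%/98% plates, two seed classes in equal proportion.
    """

    nx: int = 220
    ny: int = 120
    n_bands: int = 60
    wl_min: float = 400.0
    wl_max: float = 1000.0
    full_scale: float = 1000.0
    # seed blobs
    n_blobs: int = 16
    blob_semiaxis_range: tuple[float, float] = (6.0, 10.0)
    blob_min_spacing: float = 20.0
    infected_fraction: float = 0.5
    blob_shading: float = 0.4        # edge darkening: s = 1 - shading * r^2
    signature_contrast: float = 0.12
    # plates: (reflectance, x-interval); each spans the full y line
    plates: tuple[tuple[float, tuple[int, int]], ...] = (
        (0.02, (0, 20)),
        (0.50, (24, 44)),
        (0.98, (200, 220)),
    )
    sample_x_interval: tuple[int, int] = (48, 196)
    # illumination: relative falloff toward the line ends
    illumination_falloff: float = 0.15
    # noise
    structured_noise_amplitude: float = 0.05   # fraction of full scale
    sensor_noise_sigma: float = 0.005          # fraction of full scale
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for refl, (x0, x1) in self.plates:
            if not (0.0 < refl <= 1.0):
                raise ValueError(f"plate reflectance {refl} not in (0, 1]")
            if not (0 <= x0 < x1 <= self.nx):
                raise ValueError(f"plate x-interval {(x0, x1)} out of bounds")
        s0, s1 = self.sample_x_interval
        for _, (x0, x1) in self.plates:
            if x0 < s1 and s0 < x1:
                raise ValueError("sample region overlaps a plate footprint")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_min, self.wl_max, self.n_bands)

    def plate_reflectances(self) -> tuple[float, ...]:
        return tuple(r for r, _ in self.plates)

    def plate_x_interval(self, reflectance: float, atol: float = 1e-9) -> tuple[int, int]:
        for refl, interval in self.plates:
            if abs(refl - reflectance) <= atol:
                return interval
        raise KeyError(f"no plate with reflectance {reflectance}")

    def illumination(self) -> np.ndarray:
        """Gain field L(y, band) in DN per unit reflectance."""
        y = np.arange(self.ny)
        center = (self.ny - 1) / 2.0
        falloff = 1.0 - self.illumination_falloff * ((y - center) / max(center, 1.0)) ** 2
        return self.full_scale * np.repeat(falloff[:, None], self.n_bands, axis=1)


@dataclass
class SceneTruth:
    """Ground truth of a rendered scene, for parameter-recovery tests."""

    reflectance_cube: HyperCube
    noise_field: np.ndarray          # xi(y, band)
    foreground_mask: BinaryMask      # seed pixels only (plates excluded)
    labels: list[str]                # per-blob class
    blob_map: np.ndarray             # (nx, ny) int, -1 = no blob
    dark_frame: np.ndarray           # xi + sensor-noise realization, (ny, nb)

    @property
    def label_map(self) -> np.ndarray:
        """Per-pixel class index: -1 background, else index into CLASS_NAMES."""
        out = np.full(self.blob_map.shape, -1, dtype=int)
        for blob_id, cls in enumerate(self.labels):
            out[self.blob_map == blob_id] = CLASS_NAMES.index(cls)
        return out


def _structured_noise(spec: SceneSpec, seed_stream: Sequence[int]) -> np.ndarray:
    """Smooth low-frequency additive field xi(y, band), positive, peak-scaled.

    Sum of a few random low-frequency cosine waves over the normalized
    (y, band) plane — a stand-in for temperature-driven dark-current drift
    that varies slowly across detector rows and spectral channels.
    """
    rng = np.random.default_rng(seed_stream)
    v, u = np.meshgrid(
        np.linspace(0, 1, spec.ny), np.linspace(0, 1, spec.n_bands), indexing="ij"
    )
    fld = np.zeros((spec.ny, spec.n_bands))
    for _ in range(4):
        fy, fb = rng.uniform(0.5, 2.0, size=2)
        phase = rng.uniform(0, 2 * math.pi)
        fld += rng.uniform(0.3, 1.0) * np.cos(2 * math.pi * (fy * v + fb * u) + phase)
    peak = np.max(np.abs(fld))
    if peak > 0:
        fld /= peak
    amplitude = spec.structured_noise_amplitude * spec.full_scale
    return amplitude * (0.6 + 0.4 * fld)   # strictly positive dark current


def _place_blobs(spec: SceneSpec, rng: np.random.Generator,
                 max_retries: int = 5000) -> list[tuple[float, float, float, float, float]]:
    """Sequential hard-core placement of elliptical blobs (cx, cy, a, b, theta)."""
    a_lo, a_hi = spec.blob_semiaxis_range
    x0, x1 = spec.sample_x_interval
    margin = a_hi + 1
    blobs: list[tuple[float, float, float, float, float]] = []
    for _ in range(spec.n_blobs):
        for attempt in range(max_retries):
            cx = rng.uniform(x0 + margin, x1 - margin)
            cy = rng.uniform(margin, spec.ny - margin)
            if all(math.hypot(cx - bx, cy - by) >= spec.blob_min_spacing
                   for bx, by, *_ in blobs):
                a, b = rng.uniform(a_lo, a_hi, size=2)
                theta = rng.uniform(0, math.pi)
                blobs.append((cx, cy, a, b, theta))
                break
        else:
            raise PlacementError(
                f"could not place blob {len(blobs) + 1}/{spec.n_blobs} after "
                f"{max_retries} retries; reduce n_blobs or blob_min_spacing"
            )
    return blobs


def render_scene(spec: SceneSpec) -> tuple[HyperCube, SceneTruth]:
    """Render a DN cube and its ground truth from a scene spec.

    Deterministic: identical ``spec.rng_seed`` gives bit-identical output.
    """
    wl = spec.wavelengths
    nb = spec.n_bands

    xi = _structured_noise(spec, [spec.rng_seed, 0])
    rng_blobs = np.random.default_rng([spec.rng_seed, 1])
    rng_eps = np.random.default_rng([spec.rng_seed, 2])
    rng_dark = np.random.default_rng([spec.rng_seed, 3])

    rho = np.empty((spec.nx, spec.ny, nb))
    rho[:] = make_signature("background", wl)[None, None, :]
    for refl, (x0, x1) in spec.plates:
        rho[x0:x1, :, :] = refl

    blobs = _place_blobs(spec, rng_blobs)
    n_infected = int(round(spec.infected_fraction * len(blobs)))
    classes = ["infected"] * n_infected + ["healthy"] * (len(blobs) - n_infected)
    rng_blobs.shuffle(classes)
    signatures = {c: make_signature(c, wl, spec.signature_contrast) for c in CLASS_NAMES}

    blob_map = np.full((spec.nx, spec.ny), -1, dtype=int)
    for blob_id, ((cx, cy, a, b, theta), cls) in enumerate(zip(blobs, classes)):
        half = int(math.ceil(max(a, b))) + 1
        xs = np.arange(max(0, int(cx) - half), min(spec.nx, int(cx) + half + 1))
        ys = np.arange(max(0, int(cy) - half), min(spec.ny, int(cy) + half + 1))
        dx = xs[:, None] - cx
        dy = ys[None, :] - cy
        ct, st = math.cos(theta), math.sin(theta)
        r2 = ((dx * ct + dy * st) / a) ** 2 + ((-dx * st + dy * ct) / b) ** 2
        inside = r2 <= 1.0
        shade = 1.0 - spec.blob_shading * r2
        sub = rho[xs[0]:xs[-1] + 1, ys[0]:ys[-1] + 1, :]
        sub[inside, :] = shade[inside, None] * signatures[cls][None, :]
        blob_map[xs[0]:xs[-1] + 1, ys[0]:ys[-1] + 1][inside] = blob_id

    L = spec.illumination()
    eps_sigma = spec.sensor_noise_sigma * spec.full_scale
    dn = L[None, :, :] * rho + xi[None, :, :]
    if eps_sigma > 0:
        dn = dn + rng_eps.normal(0.0, eps_sigma, size=dn.shape)

    cube = HyperCube(
        dn, wl, "dn",
        {
            "source": "hsiprep.phantom",
            "rng_seed": spec.rng_seed,
            "full_scale": spec.full_scale,
            "plates": [(r, list(iv)) for r, iv in spec.plates],
        },
    )
    dark = xi.copy()
    if eps_sigma > 0:
        dark = dark + rng_dark.normal(0.0, eps_sigma, size=dark.shape)
    truth = SceneTruth(
        reflectance_cube=HyperCube(rho, wl.copy(), "reflectance", {"source": "phantom truth"}),
        noise_field=xi,
        foreground_mask=BinaryMask(blob_map >= 0),
        labels=classes,
        blob_map=blob_map,
        dark_frame=dark,
    )
    return cube, truth


def render_references(spec: SceneSpec,
                      dark_noise_seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Reference measurements for black-and-white correction.

    Returns ``(dark_frame, white_profile)``: the dark frame is a realization
    of ``xi + eps`` (lens capped, signal term zero); the white profile is the
    per-(y, band) mean DN over the 98% plate's scan columns in the rendered
    scene.  Passing ``dark_noise_seed`` draws the dark frame from a
    *different* structured-noise realization, emulating a dark reference
    acquired at another time under drifted dark current (the failure mode of
    black-and-white correction that double-plate correction avoids).
    """
    try:
        x0, x1 = spec.plate_x_interval(0.98)
    except KeyError as exc:
        raise ValueError("scene spec has no 98% reference plate") from exc
    cube, truth = render_scene(spec)
    white_profile = cube.data[x0:x1, :, :].mean(axis=0)
    if dark_noise_seed is None:
        dark = truth.dark_frame
    else:
        xi_stale = _structured_noise(spec, [dark_noise_seed, 0])
        rng = np.random.default_rng([dark_noise_seed, 3])
        eps_sigma = spec.sensor_noise_sigma * spec.full_scale
        dark = xi_stale + (rng.normal(0.0, eps_sigma, size=xi_stale.shape)
                           if eps_sigma > 0 else 0.0)
    return dark, white_profile
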