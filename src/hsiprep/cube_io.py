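"""Hyperspectral cube data model and I/O.

A :class:`HyperCube` stores values on a canonical ``(x, y, band)`` grid where
``x`` is the scan (stage-motion) axis and ``y`` the detector field-of-view
line.  For a line-scan instrument every sample at fixed ``(y, band)`` is read
out by the same detector element, so additive dark-current noise is constant
along ``x`` — the premise the double-plate correction relies on.

Supported on-disk formats:

* ENVI raster — a ``.hdr`` text header next to a raw binary file, interleaves
  ``bsq``/``bil``/``bip``, dtypes uint16/float32/float64.  Reading
  canonicalizes axis order regardless of interleave; unknown header keys are
  preserved verbatim in ``metadata`` so a round trip is lossless.
* A single-file array container (NumPy ``.npz``) holding the data grid, the
  wavelength axis, the value kind and JSON-encoded metadata.

Masks travel either inside the array container or as 8-bit PNG (0/255),
stored with image rows = ``y`` so they display upright.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

__all__ = [
    "HyperCube",
    "BinaryMask",
    "FormatError",
    "ValidationError",
    "read_cube",
    "write_cube",
    "crop",
    "read_mask",
    "write_mask",
]


class FormatError(ValueError):
    """Raised when an on-disk file cannot be parsed as the declared format."""


class ValidationError(ValueError):
    """Raised when cube/mask contents violate a structural invariant."""


# ENVI "data type" codes for the dtypes this package reads and writes.
_ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


@dataclass
class HyperCube:
    """A hyperspectral data cube on the canonical ``(x, y, band)`` grid.

    Parameters
    ----------
    data
        3D array indexed ``(x, y, band)``; DN counts or reflectance fractions.
    wavelengths
        Per-band wavelength in nm, strictly increasing.
    value_kind
        ``"dn"`` for raw sensor counts, ``"reflectance"`` after inversion.
        Reflectance values are *not* clipped to [0, 1]; correction can
        legitimately overshoot slightly and clipping is left to the caller.
    metadata
        Free-form key/value pairs (source interleave, provenance, ...).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    value_kind: str = "dn"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(f"cube data must be 3D non-empty, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValidationError(
                f"wavelength count {self.wavelengths.size} != band count {self.data.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if self.value_kind not in ("dn", "reflectance"):
            raise ValidationError(f"value_kind must be 'dn' or 'reflectance', got {self.value_kind!r}")
        if self.value_kind == "reflectance" and not np.all(np.isfinite(self.data)):
            raise ValidationError("reflectance cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band(self, index: int) -> np.ndarray:
        """The 2D ``(x, y)`` image of one band."""
        return self.data[:, :, index]

    def with_data(self, data: np.ndarray, value_kind: str | None = None,
                  extra_metadata: Mapping[str, Any] | None = None) -> "HyperCube":
        """A copy sharing wavelengths/metadata but holding new values."""
        meta = dict(self.metadata)
        if extra_metadata:
            meta.update(extra_metadata)
        return HyperCube(data, self.wavelengths.copy(),
                         value_kind or self.value_kind, meta)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HyperCube):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and np.array_equal(self.data, other.data)
            and np.array_equal(self.wavelengths, other.wavelengths)
            and self.value_kind == other.value_kind
        )


@dataclass
class BinaryMask:
    """A 2D boolean foreground mask aligned to a cube's spatial ``(x, y)`` grid."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2 or min(self.grid.shape) < 1:
            raise ValidationError(f"mask must be 2D non-empty, got shape {self.grid.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        """Number of foreground pixels."""
        return int(self.grid.sum())

    def check_matches(self, cube: HyperCube) -> None:
        if self.grid.shape != cube.data.shape[:2]:
            raise ValidationError(
                f"mask shape {self.grid.shape} does not match cube spatial "
                f"extents {cube.data.shape[:2]}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return np.array_equal(self.grid, other.grid)


# ---------------------------------------------------------------------------
# ENVI header handling
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> dict[str, str]:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header (missing 'ENVI' magic line)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    pos = 0
    while pos < len(body):
        eq = body.find("=", pos)
        if eq < 0:
            break
        key = body[pos:eq].strip().lower()
        rest = body[eq + 1:].lstrip()
        offset = len(body) - len(rest)
        if rest.startswith("{"):
            close = rest.find("}")
            if close < 0:
                raise FormatError(f"unterminated '{{' list for header key {key!r}")
            value = rest[1:close].strip()
            pos = offset + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl < 0 else nl
            value = rest[:nl].strip()
            pos = offset + nl
        if key:
            fields[key] = value
    return fields


def _format_envi_header(fields: dict[str, str]) -> str:
    lines = ["ENVI"]
    for key, value in fields.items():
        if key == "wavelength" or "," in value or "\n" in value:
            lines.append(f"{key} = {{ {value} }}")
        else:
            lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"


def _header_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr") if path.suffix != ".hdr" else path


# On disk an ENVI raster is ordered (lines, samples, bands) permuted by the
# interleave; canonically lines = x (scan steps), samples = y (detector line).
_DISK_AXES = {"bsq": (2, 0, 1), "bil": (0, 2, 1), "bip": (0, 1, 2)}


def _read_envi(path: Path, wavelengths: np.ndarray | None) -> HyperCube:
    hdr_path = _header_path(path)
    if not hdr_path.exists():
        raise FormatError(f"missing ENVI header {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        nx = int(fields.pop("lines"))
        ny = int(fields.pop("samples"))
        nb = int(fields.pop("bands"))
        interleave = fields.pop("interleave").lower()
        dtype_code = int(fields.pop("data type"))
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required key: {exc}") from exc
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.pop("byte order", "0")):
        dtype = dtype.newbyteorder(">")
    offset = int(fields.pop("header offset", "0"))

    if "wavelength" in fields:
        wl = np.array([float(w) for w in fields.pop("wavelength").split(",")])
    elif wavelengths is not None:
        wl = np.asarray(wavelengths, dtype=float)
    else:
        raise FormatError("no wavelength list in header and none supplied")
    if wl.size != nb:
        raise ValidationError(f"header declares {nb} bands but {wl.size} wavelengths")

    raw = np.fromfile(path, dtype=dtype, count=nx * ny * nb, offset=offset)
    if raw.size != nx * ny * nb:
        raise FormatError(f"file {path} holds {raw.size} values, expected {nx * ny * nb}")
    axes = _DISK_AXES[interleave]
    disk_shape = tuple((nx, ny, nb)[a] for a in axes)
    data = np.ascontiguousarray(raw.reshape(disk_shape).transpose(np.argsort(axes)))
    data = data.astype(data.dtype.newbyteorder("="), copy=False)

    value_kind = fields.pop("value kind", "dn")
    meta: dict[str, Any] = {"source_interleave": interleave, "source_dtype": str(np.dtype(_ENVI_DTYPES[dtype_code]))}
    meta.update(fields)  # unknown keys preserved verbatim
    return HyperCube(data, wl, value_kind, meta)


def _write_envi(cube: HyperCube, path: Path, interleave: str) -> None:
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unsupported interleave {interleave!r}")
    dtype = cube.data.dtype
    if dtype not in _ENVI_CODES:
        dtype = np.dtype(np.float64)
    nx, ny, nb = cube.data.shape
    fields: dict[str, str] = {
        "description": "hsiprep hyperspectral cube",
        "lines": str(nx),
        "samples": str(ny),
        "bands": str(nb),
        "header offset": "0",
        "file type": "ENVI Standard",
        "data type": str(_ENVI_CODES[dtype]),
        "interleave": interleave,
        "byte order": "0",
        "value kind": cube.value_kind,
        "wavelength": ", ".join(repr(float(w)) for w in cube.wavelengths),
    }
    for key, value in cube.metadata.items():
        if key in ("source_interleave", "source_dtype") or key in fields:
            continue
        fields.setdefault(str(key), str(value))
    axes = _DISK_AXES[interleave]
    cube.data.astype(dtype, copy=False).transpose(axes).tofile(path)
    _header_path(path).write_text(_format_envi_header(fields))


# ---------------------------------------------------------------------------
# Array container (.npz)
# ---------------------------------------------------------------------------

def _read_container(path: Path) -> HyperCube:
    with np.load(path, allow_pickle=False) as archive:
        if "data" not in archive or "wavelengths" not in archive:
            raise FormatError(f"{path} is not an hsiprep cube container")
        data = archive["data"]
        wl = archive["wavelengths"]
        value_kind = str(archive["value_kind"]) if "value_kind" in archive else "dn"
        meta = json.loads(str(archive["metadata_json"])) if "metadata_json" in archive else {}
    return HyperCube(data, wl, value_kind, meta)


def _write_container(cube: HyperCube, path: Path) -> None:
    np.savez(
        path,
        data=cube.data,
        wavelengths=cube.wavelengths,
        value_kind=np.str_(cube.value_kind),
        metadata_json=np.str_(json.dumps(cube.metadata, default=str)),
    )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "array-container" if path.suffix == ".npz" else "envi"


def read_cube(path: str | Path, format: str | None = None,
              wavelengths: np.ndarray | None = None) -> HyperCube:
    """Read a cube from disk into canonical ``(x, y, band)`` order.

    ``format`` is ``"envi"`` or ``"array-container"``; inferred from the
    extension (``.npz`` → container) when omitted.  For ENVI files without a
    wavelength list in the header, pass ``wavelengths`` explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "envi":
        return _read_envi(path, wavelengths)
    if fmt == "array-container":
        return _read_container(path)
    raise FormatError(f"unknown format {fmt!r}")


def write_cube(cube: HyperCube, path: str | Path, format: str | None = None,
               interleave: str = "bsq") -> None:
    """Write a cube; ``read_cube(write_cube(c))`` is value-exact."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "envi":
        _write_envi(cube, path, interleave)
    elif fmt == "array-container":
        _write_container(cube, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def crop(cube: HyperCube, x_range: tuple[int, int] | None = None,
         y_range: tuple[int, int] | None = None,
         band_range: tuple[int, int] | None = None) -> HyperCube:
    """Crop by half-open index ranges; ``None`` keeps the full axis."""
    nx, ny, nb = cube.data.shape
    ranges = []
    for rng, extent, name in ((x_range, nx, "x"), (y_range, ny, "y"), (band_range, nb, "band")):
        lo, hi = (0, extent) if rng is None else rng
        if not (0 <= lo < hi <= extent):
            raise ValidationError(f"{name}_range {rng} invalid for extent {extent}")
        ranges.append((lo, hi))
    (x0, x1), (y0, y1), (b0, b1) = ranges
    return HyperCube(
        cube.data[x0:x1, y0:y1, b0:b1].copy(),
        cube.wavelengths[b0:b1].copy(),
        cube.value_kind,
        dict(cube.metadata, crop=f"x[{x0}:{x1}) y[{y0}:{y1}) band[{b0}:{b1})"),
    )


def read_mask(path: str | Path) -> BinaryMask:
    """Read a mask from PNG (0/255, rows = y) or ``.npz`` container."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as archive:
            return BinaryMask(archive["grid"])
    import imageio.v3 as iio

    image = np.asarray(iio.imread(path))
    if image.ndim == 3:
        image = image[..., 0]
    return BinaryMask(image.T > 127)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, grid=mask.grid)
        return
    import imageio.v3 as iio

    iio.imwrite(path, (mask.grid.T.astype(np.uint8) * 255))
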