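"""Grid-layer container and raster I/O.

Layers travel as :class:`GridLayer`: a 2-D array, a declared no-data
sentinel, a nominal affine transform (the synthetic grids are abstract
equal-area cells, so the transform is bookkeeping, not geodesy), a name
and a units string.

Two on-disk formats are supported:

* ``.asc`` — ESRI ASCII grid, a plain-text format, with a ``.asc.json``
  sidecar carrying name/units/dtype so round-trips are lossless.
* ``.tif`` — single-band TIFF via :mod:`tifffile`, with the metadata
  stored as JSON in the image description tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError

__all__ = ["GridLayer", "read_grid", "write_grid"]

#: default affine: (x origin, cell width, y origin, cell height)
NOMINAL_TRANSFORM = (0.0, 20000.0, 0.0, -20000.0)


@dataclass
class GridLayer:
    """A single aligned raster layer.

    ``values`` is a 2-D float or integer array; cells equal to ``nodata``
    carry no information and must be propagated (never treated as 0) by
    every operation.
    """

    values: np.ndarray
    name: str = ""
    nodata: float = -9999.0
    units: str = ""
    transform: tuple = field(default=NOMINAL_TRANSFORM)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise FormatError(f"layer {self.name!r}: expected 2-D values, got ndim={self.values.ndim}")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def mask_valid(self) -> np.ndarray:
        """Boolean mask of cells that are not no-data (NaN counts as no-data)."""
        v = self.values
        valid = v != self.nodata
        if np.issubdtype(v.dtype, np.floating):
            valid &= ~np.isnan(v)
        return valid


def _meta_dict(layer: GridLayer) -> dict:
    return {
        "name": layer.name,
        "units": layer.units,
        "nodata": float(layer.nodata) if np.issubdtype(type(layer.nodata), np.floating) else layer.nodata,
        "dtype": str(layer.values.dtype),
        "transform": list(layer.transform),
    }


def write_grid(layer: GridLayer, path: str | Path) -> Path:
    """Write a layer to ``path`` (.asc or .tif, chosen by suffix)."""
    path = Path(path)
    if path.suffix == ".asc":
        _write_asc(layer, path)
    elif path.suffix in (".tif", ".tiff"):
        _write_tif(layer, path)
    else:
        raise FormatError(f"unsupported raster suffix {path.suffix!r} (use .asc or .tif)")
    return path


def read_grid(path: str | Path, expected_kind: str | None = None,
              valid_codes: set | None = None) -> GridLayer:
    """Read a layer written by :func:`write_grid`.

    ``expected_kind`` may be ``"continuous"`` or ``"factor"``; factor grids
    are validated against ``valid_codes`` when given.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"raster file not found: {path}")
    if path.suffix == ".asc":
        layer = _read_asc(path)
    elif path.suffix in (".tif", ".tiff"):
        layer = _read_tif(path)
    else:
        raise FormatError(f"unsupported raster suffix {path.suffix!r}")
    if expected_kind == "factor":
        if not np.issubdtype(layer.values.dtype, np.integer):
            raise FormatError(f"{path}: expected factor (integer) grid, got {layer.values.dtype}")
        if valid_codes is not None:
            codes = set(np.unique(layer.values[layer.mask_valid()]).tolist())
            bad = codes - set(valid_codes)
            if bad:
                raise FormatError(f"{path}: factor codes {sorted(bad)} outside declared set")
    return layer


# -- ESRI ASCII ---------------------------------------------------------------

def _write_asc(layer: GridLayer, path: Path) -> None:
    nrows, ncols = layer.values.shape
    x0, dx, y0, dy = layer.transform
    isint = np.issubdtype(layer.values.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {y0 + dy * nrows!r}\n")
        fh.write(f"cellsize {abs(dx)!r}\n")
        fh.write(f"NODATA_value {layer.nodata!r}\n")
        fmt = "%d" if isint else "%.17g"
        np.savetxt(fh, layer.values, fmt=fmt)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(_meta_dict(layer), indent=1))


def _read_asc(path: Path) -> GridLayer:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "nodata_value"):
        if key not in header:
            raise FormatError(f"{path}: missing ASCII-grid header field {key!r}")
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError(
            f"{path}: data shape {values.shape} contradicts header "
            f"({int(header['nrows'])}, {int(header['ncols'])})")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    dtype = np.dtype(meta.get("dtype", "float64"))
    values = values.astype(dtype)
    cs = header["cellsize"]
    transform = tuple(meta.get("transform",
                               (header.get("xllcorner", 0.0), cs,
                                header.get("yllcorner", 0.0) + cs * values.shape[0], -cs)))
    nodata = dtype.type(header["nodata_value"])
    return GridLayer(values=values, name=meta.get("name", path.stem),
                     nodata=nodata, units=meta.get("units", ""), transform=transform)


# -- TIFF ---------------------------------------------------------------------

def _write_tif(layer: GridLayer, path: Path) -> None:
    tifffile.imwrite(path, layer.values, description=json.dumps(_meta_dict(layer)))


def _read_tif(path: Path) -> GridLayer:
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) != 1:
            raise FormatError(f"{path}: expected a single-band raster, found {len(tf.pages)} pages")
        page = tf.pages[0]
        values = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    if values.ndim != 2:
        raise FormatError(f"{path}: expected a single-band 2-D raster, got shape {values.shape}")
    dtype = np.dtype(meta.get("dtype", str(values.dtype)))
    nodata = dtype.type(meta.get("nodata", -9999.0))
    return GridLayer(values=values.astype(dtype), name=meta.get("name", path.stem),
                     nodata=nodata, units=meta.get("units", ""),
                     transform=tuple(meta.get("transform", NOMINAL_TRANSFORM)))
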