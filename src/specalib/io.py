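"""Readers and writers for the on-disk formats the toolkit touches.

Cubes are stored as multi-page TIFF (one page per band, lossless) with a
JSON sidecar carrying exposure and band metadata; a ``*_<ms>ms.tif``
filename convention is the fallback for the exposure.  A minimal ENVI
(header + raw BSQ) reader/writer is provided for interoperability with
hyperspectral tooling.  Tabular data (reference spectra, dark statistics,
estimates, experiment results) are plain CSV with units in the headers.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calibration import ExposureSeries
from .core import IlluminantSpectrum, SpectralCube, l1_normalize
from .errors import FormatError, SpecalibError

__all__ = [
    "read_cube",
    "write_cube",
    "read_envi",
    "write_envi",
    "read_spectra_table",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "read_dark_statistics",
    "write_dark_statistics",
    "read_exposure_series",
    "write_exposure_series",
]

_EXPOSURE_RE = re.compile(r"_(\d+(?:\.\d+)?)ms$")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _exposure_from_name(path: Path) -> float | None:
    m = _EXPOSURE_RE.search(path.stem)
    return float(m.group(1)) if m else None


def write_cube(cube: SpectralCube, path, force: bool = False) -> None:
    """Lossless TIFF storage (bands as pages) plus a JSON sidecar.

    Integer-valued cubes are stored as uint16, analog cubes as float32.
    Refuses to overwrite an existing file unless ``force`` is set.
    """
    path = Path(path)
    if path.exists() and not force:
        raise SpecalibError(f"refusing to overwrite {path} (pass force=True)")
    data = cube.data
    if np.allclose(data, np.rint(data)) and data.max(initial=0) < 2**16:
        stored = data.astype(np.uint16)
    else:
        stored = data.astype(np.float32)
    tifffile.imwrite(path, np.moveaxis(stored, 2, 0), photometric="minisblack")
    sidecar = {
        "exposure_ms": cube.exposure_ms,
        "band_ids": list(cube.labels()),
        "writer": "specalib",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_cube(path) -> SpectralCube:
    """Read a multi-band TIFF (or ENVI header) back into a cube."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".hdr":
        return read_envi(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        raise FormatError(f"{path} is single-band; cubes need at least 2 bands")
    if data.ndim != 3:
        raise FormatError(f"{path}: unexpected TIFF dimensionality {data.ndim}")
    data = np.moveaxis(data, 0, 2).astype(float)
    exposure = None
    band_ids = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        exposure = meta.get("exposure_ms")
        if meta.get("band_ids"):
            band_ids = tuple(meta["band_ids"])
    if exposure is None:
        exposure = _exposure_from_name(path)
    return SpectralCube(data, exposure_ms=exposure, band_ids=band_ids)


_ENVI_DTYPES = {2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}


def write_envi(cube: SpectralCube, header_path, force: bool = False) -> None:
    """Minimal ENVI writer: text ``.hdr`` plus band-sequential ``.raw``."""
    header_path = Path(header_path)
    raw_path = header_path.with_suffix(".raw")
    if (header_path.exists() or raw_path.exists()) and not force:
        raise SpecalibError(f"refusing to overwrite {header_path} (pass force=True)")
    rows, cols, bands = cube.shape
    data = cube.data
    integral = np.allclose(data, np.rint(data)) and data.max(initial=0) < 2**16
    dtype_code = 12 if integral else 4
    stored = np.moveaxis(data, 2, 0).astype(_ENVI_DTYPES[dtype_code])
    header = "\n".join(
        [
            "ENVI",
            "description = {specalib cube}",
            f"samples = {cols}",
            f"lines = {rows}",
            f"bands = {bands}",
            "header offset = 0",
            "file type = ENVI Standard",
            f"data type = {dtype_code}",
            "interleave = bsq",
            "byte order = 0",
            f"exposure_ms = {cube.exposure_ms if cube.exposure_ms is not None else 'unknown'}",
            "band names = {" + ", ".join(cube.labels()) + "}",
            "",
        ]
    )
    header_path.write_text(header)
    stored.tofile(raw_path)


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    # collapse {...} blocks onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" in line:
            key, value = line.split("=", 1)
            fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(header_path) -> SpectralCube:
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    fields = _parse_envi_header(header_path.read_text())
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
    except KeyError as exc:
        raise FormatError(f"ENVI header missing field: {exc}") from exc
    if bands < 2:
        raise FormatError("cubes need at least 2 bands")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    if int(fields.get("byte order", "0")) != 0:
        raise FormatError("only little-endian ENVI files are supported")
    raw_path = header_path.with_suffix(".raw")
    if not raw_path.exists():
        candidates = [header_path.with_suffix(s) for s in (".img", ".dat", "")]
        raw_path = next((c for c in candidates if c.exists() and c != header_path), raw_path)
    flat = np.fromfile(raw_path, dtype=_ENVI_DTYPES[dtype_code])
    if flat.size != rows * cols * bands:
        raise FormatError(f"{raw_path}: size does not match header dimensions")
    if interleave == "bsq":
        data = flat.reshape(bands, rows, cols)
        data = np.moveaxis(data, 0, 2)
    elif interleave == "bil":
        data = flat.reshape(rows, bands, cols)
        data = np.moveaxis(data, 1, 2)
    elif interleave == "bip":
        data = flat.reshape(rows, cols, bands)
    else:
        raise FormatError(f"unsupported interleave {interleave!r}")
    exposure = None
    if "exposure_ms" in fields and fields["exposure_ms"] != "unknown":
        exposure = float(fields["exposure_ms"])
    if exposure is None:
        exposure = _exposure_from_name(header_path)
    band_ids = None
    if "band names" in fields:
        band_ids = tuple(
            b.strip() for b in fields["band names"].strip("{} ").split(",") if b.strip()
        )
        if len(band_ids) != bands:
            band_ids = None
    return SpectralCube(data.astype(float), exposure_ms=exposure, band_ids=band_ids)


def read_spectra_table(path) -> dict[str, IlluminantSpectrum]:
    """Delimited text with columns (id, band, value) -> spectra grouped by id.

    Values must be non-negative and every group must have the same length;
    spectra are returned L1-normalized, ordered by the band column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"id", "band", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"spectra table needs columns {sorted(required)}")
    if (df["value"] < 0).any():
        raise FormatError("spectra table contains negative values")
    lengths = df.groupby("id").size()
    if lengths.nunique() > 1:
        raise FormatError("ragged spectra table: groups have differing lengths")
    out = {}
    for name, group in df.groupby("id"):
        values = group.sort_values("band")["value"].to_numpy(dtype=float)
        out[str(name)] = IlluminantSpectrum(l1_normalize(values), normalized=True)
    return out


def write_spectrum_csv(spectrum: IlluminantSpectrum, path, band_ids=None) -> None:
    path = Path(path)
    ids = band_ids or [f"b{k:02d}" for k in range(len(spectrum))]
    pd.DataFrame({"band_id": list(ids), "value": spectrum.values}).to_csv(path, index=False)


def read_spectrum_csv(path) -> IlluminantSpectrum:
    df = pd.read_csv(path)
    if "value" not in df.columns:
        raise FormatError("spectrum CSV needs a 'value' column")
    return IlluminantSpectrum(l1_normalize(df["value"].to_numpy(dtype=float)), normalized=True)


def write_dark_statistics(series: ExposureSeries, path) -> None:
    pd.DataFrame(
        {
            "exposure_ms": series.exposures,
            "dark_mean": series.dark_lightness_mean,
            "dark_std": series.dark_lightness_std,
        }
    ).to_csv(path, index=False)


def read_dark_statistics(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"exposure_ms", "dark_mean", "dark_std"}
    if not required.issubset(df.columns):
        raise FormatError(f"dark statistics CSV needs columns {sorted(required)}")
    return df


def write_exposure_series(series: ExposureSeries, directory, force: bool = False) -> None:
    """A directory of TIFF cubes named by exposure plus ``dark_stats.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t, cube in series.entries:
        name = f"calib_{t:07.2f}ms.tif" if t != int(t) else f"calib_{int(t):04d}ms.tif"
        write_cube(cube, directory / name, force=force)
    write_dark_statistics(series, directory / "dark_stats.csv")


def read_exposure_series(directory) -> ExposureSeries:
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(directory)
    stats = read_dark_statistics(directory / "dark_stats.csv")
    cubes = []
    for tif in sorted(directory.glob("*.tif")):
        cube = read_cube(tif)
        if cube.exposure_ms is None:
            raise FormatError(f"{tif}: exposure unknown (no sidecar, no *_<ms>ms name)")
        cubes.append((cube.exposure_ms, cube))
    if not cubes:
        raise FormatError(f"no cubes found in {directory}")
    cubes.sort(key=lambda tc: tc[0])
    stats = stats.sort_values("exposure_ms")
    if len(stats) != len(cubes) or not np.allclose(
        stats["exposure_ms"].to_numpy(), [t for t, _ in cubes]
    ):
        raise FormatError("dark statistics do not cover the cube exposures")
    return ExposureSeries(
        entries=tuple(cubes),
        dark_lightness_mean=stats["dark_mean"].to_numpy(dtype=float),
        dark_lightness_std=stats["dark_std"].to_numpy(dtype=float),
    )
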