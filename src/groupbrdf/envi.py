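"""ENVI-style raster I/O for reflectance cubes and observation-geometry stacks.

The on-disk dialect is the classic ENVI pair: a plain-text ``.hdr`` beside a
flat binary file in band-sequential (BSQ), band-interleaved-by-line (BIL) or
band-interleaved-by-pixel (BIP) order.  Reflectance is stored unscaled in
[0, ~1]; pixels carrying the ``data ignore value`` in any band are masked.

Observation stacks follow the AVIRIS ``obs_ort`` convention by default: a
ten-layer file whose layers include to-sensor and to-sun azimuth/zenith,
terrain slope and aspect (all in degrees).  A ``band_map`` lets callers remap
layer indices for other products.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DataError, FormatError, IntegrityError

DEFAULT_IGNORE = -9999.0

# ENVI data type codes understood by this reader.
_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

#: Layer order of an AVIRIS obs_ort file.  Only the mapped fields are used.
OBS_ORT_BAND_MAP = {
    "sensor_azimuth": 1,
    "sensor_zenith": 2,
    "solar_azimuth": 3,
    "solar_zenith": 4,
    "slope": 6,
    "aspect": 7,
}
OBS_ORT_N_LAYERS = 10


@dataclass
class MapInfo:
    """Minimal affine georeferencing: upper-left map coordinate and pixel size.

    Rotation is carried but must match between lines that are compared; the
    overlap finder only supports a shared grid orientation.
    """

    ulx: float = 0.0
    uly: float = 0.0
    x_size: float = 1.0
    y_size: float = 1.0
    rotation: float = 0.0

    def pixel_center(self, row, col):
        """Map coordinate of the center of pixel (row, col)."""
        x = self.ulx + (np.asarray(col) + 0.5) * self.x_size
        y = self.uly - (np.asarray(row) + 0.5) * self.y_size
        return x, y


@dataclass
class SceneHeader:
    n_rows: int
    n_cols: int
    n_bands: int
    wavelengths: np.ndarray | None = None  # nm, strictly increasing
    interleave: str = "bsq"
    data_ignore_value: float = DEFAULT_IGNORE
    map_info: MapInfo = field(default_factory=MapInfo)
    band_names: list[str] | None = None

    def __post_init__(self):
        if min(self.n_rows, self.n_cols, self.n_bands) < 1:
            raise FormatError("raster dimensions must all be >= 1")
        if self.interleave not in ("bsq", "bil", "bip"):
            raise FormatError(f"unknown interleave {self.interleave!r}")
        if self.wavelengths is not None:
            w = np.asarray(self.wavelengths, dtype=float)
            if w.size != self.n_bands:
                raise FormatError(
                    f"wavelength count {w.size} != bands {self.n_bands}"
                )
            if w.size > 1 and not np.all(np.diff(w) > 0):
                raise FormatError("wavelengths must be strictly increasing")
            self.wavelengths = w

    @property
    def shape(self):
        return (self.n_bands, self.n_rows, self.n_cols)


@dataclass
class ReflectanceCube:
    """Band x row x col reflectance with an explicit validity mask."""

    header: SceneHeader
    values: np.ndarray  # (bands, rows, cols), float
    valid_mask: np.ndarray  # (rows, cols), bool

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.header.shape:
            raise IntegrityError(
                f"values shape {self.values.shape} != header {self.header.shape}"
            )
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (self.header.n_rows, self.header.n_cols):
            raise IntegrityError("valid_mask shape mismatch")

    def copy(self):
        return ReflectanceCube(
            replace(self.header), self.values.copy(), self.valid_mask.copy()
        )


@dataclass
class ObservationStack:
    """Per-pixel observation geometry, degrees throughout.

    Zenith angles are measured from vertical, azimuths clockwise from north
    in [0, 360); slope in [0, 90].
    """

    sensor_zenith: np.ndarray
    sensor_azimuth: np.ndarray
    solar_zenith: np.ndarray
    solar_azimuth: np.ndarray
    slope: np.ndarray
    aspect: np.ndarray
    valid_mask: np.ndarray
    map_info: MapInfo = field(default_factory=MapInfo)

    _ANGLES = (
        "sensor_zenith", "sensor_azimuth", "solar_zenith",
        "solar_azimuth", "slope", "aspect",
    )

    def __post_init__(self):
        shape = np.asarray(self.sensor_zenith).shape
        for name in self._ANGLES:
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != shape:
                raise IntegrityError(f"layer {name} shape mismatch")
            setattr(self, name, arr)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != shape:
            raise IntegrityError("valid_mask shape mismatch")
        # Azimuth-like layers are wrapped, zenith-like layers validated.
        for name in ("sensor_azimuth", "solar_azimuth", "aspect"):
            arr = getattr(self, name)
            arr[self.valid_mask] = np.mod(arr[self.valid_mask], 360.0)
        self._check_range("sensor_zenith", 0.0, 90.0, open_upper=True)
        self._check_range("solar_zenith", 0.0, 90.0, open_upper=True)
        self._check_range("slope", 0.0, 90.0, open_upper=False)

    def _check_range(self, name, lo, hi, open_upper):
        arr = getattr(self, name)[self.valid_mask]
        bad = (arr < lo) | (arr > hi) | (open_upper & (arr == hi)) | ~np.isfinite(arr)
        if np.any(bad):
            raise DataError(
                f"{name} outside [{lo}, {hi}{')' if open_upper else ']'} "
                f"on {int(bad.sum())} valid pixels"
            )

    @property
    def shape(self):
        return self.sensor_zenith.shape


# ---------------------------------------------------------------------------
# header parsing / serialization


def _header_path(path):
    if path.endswith(".hdr"):
        return path
    if os.path.exists(path + ".hdr"):
        return path + ".hdr"
    root, _ = os.path.splitext(path)
    if os.path.exists(root + ".hdr"):
        return root + ".hdr"
    raise FormatError(f"no .hdr file found beside {path}")


def _binary_path(path):
    return path[:-4] if path.endswith(".hdr") else path

def _parse_header_text(text):
    """Parse ENVI 'key = value' pairs, with {...} lists spanning lines."""
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("missing ENVI magic line in header")
    fields = {}
    body = text.split("\n", 1)[1] if "\n" in text else ""
    pattern = re.compile(r"^\s*([^={}\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
    return fields


def _get_int(fields, key):
    if key not in fields:
        raise FormatError(f"header missing required key {key!r}")
    try:
        return int(fields[key])
    except ValueError as exc:
        raise FormatError(f"header key {key!r} is not an integer: {fields[key]!r}") from exc


def _get_list(fields, key):
    raw = fields[key]
    if not (raw.startswith("{") and raw.endswith("}")):
        raise FormatError(f"header key {key!r} is not a brace list")
    return [item.strip() for item in raw[1:-1].replace("\n", " ").split(",") if item.strip()]


def read_header(path):
    hdr_path = _header_path(path)
    with open(hdr_path) as fh:
        fields = _parse_header_text(fh.read())
    n_rows = _get_int(fields, "lines")
    n_cols = _get_int(fields, "samples")
    n_bands = _get_int(fields, "bands")
    dtype_code = _get_int(fields, "data type")
    if dtype_code not in _DTYPES:
        raise FormatError(f"unsupported data type code {dtype_code}")
    interleave = fields.get("interleave", "bsq").lower()
    wavelengths = None
    if "wavelength" in fields:
        try:
            wavelengths = np.array([float(v) for v in _get_list(fields, "wavelength")])
        except ValueError as exc:
            raise FormatError("non-numeric entry in wavelength list") from exc
    ignore = float(fields.get("data ignore value", DEFAULT_IGNORE))
    map_info = MapInfo()
    if "map info" in fields:
        items = _get_list(fields, "map info")
        if len(items) >= 7:
            map_info = MapInfo(
                ulx=float(items[3]), uly=float(items[4]),
                x_size=float(items[5]), y_size=float(items[6]),
                rotation=float(items[7].split("=")[-1]) if len(items) > 7 and "rotation" in items[7] else 0.0,
            )
    band_names = _get_list(fields, "band names") if "band names" in fields else None
    header = SceneHeader(
        n_rows=n_rows, n_cols=n_cols, n_bands=n_bands,
        wavelengths=wavelengths, interleave=interleave,
        data_ignore_value=ignore, map_info=map_info, band_names=band_names,
    )
    byte_order = int(fields.get("byte order", 0))
    dtype = np.dtype(_DTYPES[dtype_code]).newbyteorder("<" if byte_order == 0 else ">")
    offset = int(fields.get("header offset", 0))
    return header, dtype, offset


def _format_header(header: SceneHeader, dtype) -> str:
    mi = header.map_info
    lines = [
        "ENVI",
        "description = {groupbrdf export}",
        f"samples = {header.n_cols}",
        f"lines = {header.n_rows}",
        f"bands = {header.n_bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[np.dtype(dtype)]}",
        f"interleave = {header.interleave}",
        "byte order = 0",
        f"data ignore value = {header.data_ignore_value:g}",
        f"map info = {{Arbitrary, 1, 1, {mi.ulx:.6f}, {mi.uly:.6f}, "
        f"{mi.x_size:.6f}, {mi.y_size:.6f}, rotation={mi.rotation:.6f}}}",
    ]
    if header.wavelengths is not None:
        wl = ", ".join(f"{w:.3f}" for w in header.wavelengths)
        lines.append("wavelength units = Nanometers")
        lines.append(f"wavelength = {{{wl}}}")
    if header.band_names is not None:
        lines.append("band names = {" + ", ".join(header.band_names) + "}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# cube I/O


def _to_disk_order(values, interleave):
    if interleave == "bsq":
        return values  # (bands, rows, cols)
    if interleave == "bil":
        return np.transpose(values, (1, 0, 2))  # (rows, bands, cols)
    return np.transpose(values, (1, 2, 0))  # bip: (rows, cols, bands)


def _from_disk_order(raw, header):
    b, r, c = header.shape
    if header.interleave == "bsq":
        return raw.reshape(b, r, c)
    if header.interleave == "bil":
        return np.transpose(raw.reshape(r, b, c), (1, 0, 2))
    return np.transpose(raw.reshape(r, c, b), (2, 0, 1))


def read_raw(path):
    """Read any ENVI file into (header, values[band, row, col])."""
    header, dtype, offset = read_header(path)
    bin_path = _binary_path(_header_path(path))
    expected = int(np.prod(header.shape))
    raw = np.fromfile(bin_path, dtype=dtype, offset=offset)
    if raw.size != expected:
        raise IntegrityError(
            f"{bin_path}: binary holds {raw.size} values, header implies {expected}"
        )
    return header, _from_disk_order(raw, header).astype(np.float64)


def read_cube(path, scale_divisor: float = 1.0) -> ReflectanceCube:
    """Read a reflectance cube; ``scale_divisor`` rescales integer products."""
    header, values = read_raw(path)
    sentinel = values == header.data_ignore_value
    valid = np.isfinite(values).all(axis=0) & ~sentinel.any(axis=0)
    if scale_divisor != 1.0:
        values = values / scale_divisor
        values[:, ~valid] = header.data_ignore_value
    return ReflectanceCube(header, values, valid)


def write_raw(header: SceneHeader, values, path, dtype=np.float32):
    values = np.asarray(values)
    if values.shape != header.shape:
        raise IntegrityError("values shape does not match header")
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    disk = np.ascontiguousarray(_to_disk_order(values.astype(dtype), header.interleave))
    disk.tofile(path)
    with open(path + ".hdr", "w") as fh:
        fh.write(_format_header(header, dtype))


def write_cube(cube: ReflectanceCube, path, dtype=np.float32):
    """Write cube; masked pixels are flushed to the data-ignore sentinel."""
    values = cube.values.copy()
    values[:, ~cube.valid_mask] = cube.header.data_ignore_value
    write_raw(cube.header, values, path, dtype=dtype)


# ---------------------------------------------------------------------------
# observation I/O


def read_observation(path, band_map: dict | None = None) -> ObservationStack:
    """Read an observation stack (AVIRIS obs_ort layer order by default)."""
    band_map = dict(OBS_ORT_BAND_MAP if band_map is None else band_map)
    header, values = read_raw(path)
    missing = set(OBS_ORT_BAND_MAP) - set(band_map)
    if missing:
        raise ConfigurationError(f"band_map missing layers: {sorted(missing)}")
    for name, idx in band_map.items():
        if not 0 <= idx < header.n_bands:
            raise ConfigurationError(
                f"band_map[{name!r}] = {idx} out of range for {header.n_bands}-layer file"
            )
    layers = {name: values[idx] for name, idx in band_map.items()}
    sentinel = header.data_ignore_value
    valid = np.ones(values.shape[1:], dtype=bool)
    for arr in layers.values():
        valid &= np.isfinite(arr) & (arr != sentinel)
    return ObservationStack(valid_mask=valid, map_info=header.map_info, **layers)


def write_observation(obs: ObservationStack, path, data_ignore_value=DEFAULT_IGNORE,
                      dtype=np.float64):
    """Write an obs_ort-style ten-layer stack (unused layers zero-filled)."""
    rows, cols = obs.shape
    values = np.zeros((OBS_ORT_N_LAYERS, rows, cols))
    for name, idx in OBS_ORT_BAND_MAP.items():
        values[idx] = getattr(obs, name)
    values[:, ~obs.valid_mask] = data_ignore_value
    names = ["path_length", "to_sensor_azimuth", "to_sensor_zenith",
             "to_sun_azimuth", "to_sun_zenith", "phase", "slope", "aspect",
             "cosine_i", "utc_time"]
    header = SceneHeader(
        n_rows=rows, n_cols=cols, n_bands=OBS_ORT_N_LAYERS,
        interleave="bil", data_ignore_value=data_ignore_value,
        map_info=obs.map_info, band_names=names,
    )
    write_raw(header, values, path, dtype=dtype)
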