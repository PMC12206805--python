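"""Hyperspectral cube data model, ENVI I/O, and white/dark reflectance calibration.

A hyperspectral cube is an H x W x B reflectance volume with a wavelength axis
(band-last storage, matching line-scan acquisition and ENVI conventions).
Reflectance is made dimensionless by the white/dark correction

    R = (I_raw - I_dark) / (I_white - I_dark)

where the white reference is a scan of a >= 99%-reflectance standard and the
dark reference is acquired with the lens capped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthAxis",
    "HyperspectralCube",
    "CalibrationPair",
    "calibrate_reflectance",
    "read_envi",
    "write_envi",
    "band_index",
    "crop_spectral",
]

log = logging.getLogger(__name__)

#: Denominators with |white - dark| below this are treated as degenerate.
DENOM_EPS = 1e-6
#: Hard error when more than this fraction of denominators is degenerate.
MAX_DEGENERATE_FRACTION = 0.01


@dataclass(frozen=True)
class WavelengthAxis:
    """Ordered list of band-center wavelengths in nanometres."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("wavelength axis must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("wavelengths must be finite and positive")
        if np.any(np.diff(v) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    def __getitem__(self, i):
        return self.values[i]

    @classmethod
    def uniform(cls, lo_nm: float, hi_nm: float, n: int) -> "WavelengthAxis":
        return cls(np.linspace(lo_nm, hi_nm, n))


#: The working axis used throughout: 761 uniform points on 400-1000 nm.
def working_axis() -> WavelengthAxis:
    return WavelengthAxis.uniform(400.0, 1000.0, 761)


#: Full-sensor stand-in axis (305-1090 nm, 995 points) for crop tests.
def full_sensor_axis() -> WavelengthAxis:
    return WavelengthAxis.uniform(305.0, 1090.0, 995)


@dataclass
class HyperspectralCube:
    """H x W x B reflectance volume with its wavelength axis."""

    data: np.ndarray
    axis: WavelengthAxis
    interleave_hint: str = "bsq"

    def __post_init__(self):
        a = np.asarray(self.data)
        if a.ndim != 3:
            raise ValueError(f"cube data must be 3-D (H, W, B), got shape {a.shape}")
        if a.shape[2] != len(self.axis):
            raise ValueError(
                f"band count {a.shape[2]} does not match axis length {len(self.axis)}"
            )
        if self.interleave_hint.lower() not in ("bsq", "bil"):
            raise ValueError(f"unsupported interleave hint {self.interleave_hint!r}")
        self.data = a.astype(np.float32, copy=False)
        self.interleave_hint = self.interleave_hint.lower()

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class CalibrationPair:
    """White/dark reference scans.

    Either full cubes (H, W, B) or per-band row profiles (W, B) broadcast
    across lines, as in line-scan practice; (B,) profiles are also accepted.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self):
        self.white = np.asarray(self.white, dtype=np.float64)
        self.dark = np.asarray(self.dark, dtype=np.float64)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark references must share a shape")
        above = np.mean(self.white > self.dark)
        if above < 0.99:
            raise ValueError(
                f"calibration ill-posed: white > dark on only {above:.1%} of elements"
            )

    @property
    def n_bands(self) -> int:
        return self.white.shape[-1]


def calibrate_reflectance(
    raw: HyperspectralCube, cal: CalibrationPair, eps: float = DENOM_EPS
) -> HyperspectralCube:
    """White/dark correction R = (raw - dark) / (white - dark), element-wise.

    Bands/pixels where ``|white - dark| < eps`` are zeroed and counted; more
    than 1% degenerate denominators is a hard error.  The result carries the
    raw cube's wavelength axis.
    """
    if cal.n_bands != raw.n_bands:
        raise ValueError(
            f"band mismatch: raw has {raw.n_bands}, references have {cal.n_bands}"
        )
    try:
        white = np.broadcast_to(cal.white, raw.shape)
        dark = np.broadcast_to(cal.dark, raw.shape)
    except ValueError as e:
        raise ValueError(
            f"reference shape {cal.white.shape} not broadcastable to cube {raw.shape}"
        ) from e

    denom = white - dark
    degenerate = np.abs(denom) < eps
    frac = float(degenerate.mean())
    if frac > MAX_DEGENERATE_FRACTION:
        raise ValueError(
            f"calibration ill-posed: {frac:.2%} of denominators are degenerate "
            f"(limit {MAX_DEGENERATE_FRACTION:.0%})"
        )
    out = np.zeros(raw.shape, dtype=np.float64)
    ok = ~degenerate
    out[ok] = (raw.data.astype(np.float64)[ok] - dark[ok]) / denom[ok]
    if frac > 0:
        log.warning("calibration zeroed %d degenerate elements (%.3g%%)",
                    int(degenerate.sum()), 100 * frac)
    out = np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)
    return HyperspectralCube(out.astype(np.float32), raw.axis, raw.interleave_hint)


# ---------------------------------------------------------------------------
# ENVI format I/O (header text + raw little-endian float32 payload)
# ---------------------------------------------------------------------------

_SUPPORTED_INTERLEAVES = ("bsq", "bil")


def _data_path_for(header_path: Path) -> Path:
    if header_path.suffix.lower() == ".hdr":
        return header_path.with_suffix(".raw")
    return header_path.parent / (header_path.name + ".raw")


def write_envi(cube: HyperspectralCube, header_path) -> tuple[Path, Path]:
    """Emit an ENVI ``.hdr`` text file plus a raw float32 binary payload.

    Returns ``(header_path, data_path)``.  Wavelengths are serialized with
    four decimals; data are little-endian float32 (ENVI data type 4).
    """
    header_path = Path(header_path)
    data_path = _data_path_for(header_path)
    H, W, B = cube.shape
    interleave = cube.interleave_hint
    if interleave == "bsq":
        payload = np.ascontiguousarray(cube.data.transpose(2, 0, 1))  # (B, H, W)
    else:  # bil: line-major, bands within line
        payload = np.ascontiguousarray(cube.data.transpose(0, 2, 1))  # (H, B, W)
    wl = ", ".join(f"{v:.4f}" for v in cube.axis.values)
    hdr = (
        "ENVI\n"
        "description = {hyperleaf reflectance cube}\n"
        f"samples = {W}\n"
        f"lines = {H}\n"
        f"bands = {B}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(hdr)
    payload.astype("<f4").tofile(data_path)
    return header_path, data_path


def _parse_envi_header(text: str) -> dict:
    # key = value pairs; brace-delimited values may span lines; keys case-insensitive
    text = text.replace("\r\n", "\n")
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([^=\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(text):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
    return fields


def read_envi(header_path) -> HyperspectralCube:
    """Read an ENVI header + binary payload into a cube (H, W, B)."""
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())
    try:
        W = int(fields["samples"])
        H = int(fields["lines"])
        B = int(fields["bands"])
    except KeyError as e:
        raise ValueError(f"ENVI header missing required field: {e}") from e
    dtype_code = int(fields.get("data type", "4"))
    if dtype_code != 4:
        raise ValueError(f"unsupported ENVI data type {dtype_code} (only 4 = float32)")
    byte_order = int(fields.get("byte order", "0"))
    if byte_order != 0:
        raise ValueError("only little-endian (byte order 0) payloads are supported")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in _SUPPORTED_INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r} (bsq or bil)")
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing wavelength field")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wl = np.array([float(t) for t in wl_text.replace("\n", " ").split(",") if t.strip()])
    if wl.size != B:
        raise ValueError(
            f"header band count {B} does not match wavelength list length {wl.size}"
        )
    data_path = _data_path_for(header_path)
    flat = np.fromfile(data_path, dtype="<f4")
    if flat.size != H * W * B:
        raise ValueError(
            f"payload has {flat.size} values, expected {H * W * B} for {H}x{W}x{B}"
        )
    if interleave == "bsq":
        arr = flat.reshape(B, H, W).transpose(1, 2, 0)
    else:
        arr = flat.reshape(H, B, W).transpose(0, 2, 1)
    return HyperspectralCube(np.ascontiguousarray(arr), WavelengthAxis(wl), interleave)


# ---------------------------------------------------------------------------
# Wavelength arithmetic
# ---------------------------------------------------------------------------

def band_index(axis: WavelengthAxis, target_nm: float) -> int:
    """Index of the band whose center wavelength is nearest ``target_nm``.

    Ties resolve to the lower index.  Targets more than 10 nm outside the
    axis range are rejected.
    """
    v = axis.values
    if target_nm < v[0] - 10.0 or target_nm > v[-1] + 10.0:
        raise ValueError(
            f"target {target_nm} nm outside axis range [{v[0]}, {v[-1]}] (+/- 10 nm)"
        )
    return int(np.argmin(np.abs(v - target_nm)))


def crop_spectral(obj, lo_nm: float, hi_nm: float):
    """Retain bands with lo <= wavelength <= hi (inclusive).

    Accepts a HyperspectralCube (crops axis 2) or any object with ``X`` and
    ``axis`` attributes (a spectra table; crops columns).  Returns the same
    kind.
    """
    if lo_nm >= hi_nm:
        raise ValueError(f"need lo < hi, got [{lo_nm}, {hi_nm}]")
    if isinstance(obj, HyperspectralCube):
        axis = obj.axis
    else:
        axis = obj.axis
    keep = (axis.values >= lo_nm) & (axis.values <= hi_nm)
    if not keep.any():
        raise ValueError(f"no bands remain in [{lo_nm}, {hi_nm}] nm")
    new_axis = WavelengthAxis(axis.values[keep])
    if isinstance(obj, HyperspectralCube):
        return HyperspectralCube(obj.data[:, :, keep], new_axis, obj.interleave_hint)
    # spectra-table-like: rebuild via dataclasses.replace-compatible constructor
    import dataclasses

    return dataclasses.replace(obj, X=obj.X[:, keep], axis=new_axis)
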