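"""Colorimetric forward model: reflectance spectra -> XYZ -> sRGB and back.

Conventions fixed here for the whole package:

* illuminant: the shipped smooth daylight table with the D65 white
  chromaticity (see ``scripts/make_color_tables.py`` for provenance);
* observer: CIE 1931 2-degree curves (analytic-fit table, same script);
* integration: rectangular rule on the uniform 1 nm grid;
* Y scaling: the perfect reflector has Y = 100 under the illuminant;
* out-of-gamut sRGB values are clipped to [0, 1], optionally flagged.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

from .errors import DermspecError, GridMismatchError
from .grid import DEFAULT_GRID, SpectralGrid

__all__ = [
    "Illuminant",
    "ColorMatchingFunctions",
    "load_illuminant_d65",
    "load_cmf_1931_2deg",
    "validate_spectrum",
    "spectrum_to_xyz",
    "xyz_to_srgb",
    "srgb_to_xyz",
    "RGB_TO_XYZ",
    "XYZ_TO_RGB",
]

# Linear sRGB -> XYZ (Y=1 white), derived from the sRGB primary
# chromaticities and the white point of the shipped illuminant table;
# matches the IEC 61966-2-1 matrix to 4 decimals.  Regenerated by
# scripts/make_color_tables.py.
RGB_TO_XYZ = np.array(
    [
        [0.412407880517, 0.357589573767, 0.180432597688],
        [0.212647813391, 0.715179147534, 0.072173039075],
        [0.019331619399, 0.119196524589, 0.950278347821],
    ]
)
XYZ_TO_RGB = np.linalg.inv(RGB_TO_XYZ)

# Reflectance may exceed 1 slightly (specular highlights) but not wildly.
REFLECTANCE_CEILING = 1.5


@dataclass(frozen=True)
class Illuminant:
    """Relative spectral power distribution on a grid."""

    values: np.ndarray
    grid: SpectralGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        self.grid.require_length(values.size, "illuminant")
        if np.any(values < 0) or not np.any(values > 0):
            raise DermspecError("illuminant must be non-negative and not all zero")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class ColorMatchingFunctions:
    """Observer sensitivity curves xbar, ybar, zbar on a grid."""

    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray
    grid: SpectralGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        for name in ("xbar", "ybar", "zbar"):
            arr = np.asarray(getattr(self, name), dtype=float)
            self.grid.require_length(arr.size, name)
            if np.any(arr < 0):
                raise DermspecError(f"{name} must be non-negative")
            object.__setattr__(self, name, arr)

    def as_matrix(self) -> np.ndarray:
        """(n, 3) stacked curves."""
        return np.column_stack([self.xbar, self.ybar, self.zbar])


def _read_table(name: str, columns: int) -> np.ndarray:
    ref = importlib.resources.files("dermspec.data").joinpath(name)
    rows = np.loadtxt(str(ref), delimiter=",", skiprows=1)
    if rows.shape != (len(DEFAULT_GRID), columns + 1):
        raise DermspecError(f"{name}: expected {len(DEFAULT_GRID)} rows")
    if not np.allclose(rows[:, 0], DEFAULT_GRID.wavelengths):
        raise GridMismatchError(f"{name}: wavelength column off the default grid")
    return rows[:, 1:]


def load_illuminant_d65(grid: SpectralGrid = DEFAULT_GRID) -> Illuminant:
    """The package's daylight illuminant (D65 white chromaticity)."""
    grid.require_length(len(DEFAULT_GRID), "grid")
    return Illuminant(_read_table("illuminant_d65.csv", 1)[:, 0], grid)


def load_cmf_1931_2deg(grid: SpectralGrid = DEFAULT_GRID) -> ColorMatchingFunctions:
    """The package's CIE 1931 2-degree observer table."""
    grid.require_length(len(DEFAULT_GRID), "grid")
    table = _read_table("cie_xyz_1931_2deg.csv", 3)
    return ColorMatchingFunctions(table[:, 0], table[:, 1], table[:, 2], grid)


def validate_spectrum(values: np.ndarray, grid: SpectralGrid = DEFAULT_GRID) -> np.ndarray:
    """Check reflectance invariants; returns the array as float."""
    values = np.asarray(values, dtype=float)
    grid.require_length(values.shape[-1], "spectrum")
    if np.any(values < 0):
        raise DermspecError("reflectance must be non-negative")
    if np.any(values > REFLECTANCE_CEILING):
        raise DermspecError(f"reflectance exceeds ceiling {REFLECTANCE_CEILING}")
    return values


def spectrum_to_xyz(
    spectrum: np.ndarray,
    illuminant: Illuminant,
    cmf: ColorMatchingFunctions,
) -> np.ndarray:
    """Tristimulus XYZ of reflectance spectra (vectorised over leading axes).

    X = k * sum(R * S * xbar), likewise Y and Z, with k = 100 / sum(S * ybar)
    so the perfect reflector has Y = 100.
    """
    if illuminant.grid != cmf.grid:
        raise GridMismatchError("illuminant and observer on different grids")
    spectrum = np.asarray(spectrum, dtype=float)
    illuminant.grid.require_length(spectrum.shape[-1], "spectrum")
    weights = illuminant.values[:, None] * cmf.as_matrix()  # (n, 3)
    k = 100.0 / (illuminant.values @ cmf.ybar)
    return k * (spectrum @ weights)


def _srgb_encode(linear: np.ndarray) -> np.ndarray:
    a = 0.055
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        (1 + a) * np.power(np.clip(linear, 0.0031308, None), 1 / 2.4) - a,
    )


def _srgb_decode(encoded: np.ndarray) -> np.ndarray:
    a = 0.055
    return np.where(
        encoded <= 0.04045,
        encoded / 12.92,
        np.power((encoded + a) / (1 + a), 2.4),
    )


def xyz_to_srgb(xyz: np.ndarray, return_clipped: bool = False):
    """XYZ (Y=100 scale) to sRGB in [0, 1]; out-of-gamut values are clipped.

    With ``return_clipped=True`` also returns a boolean mask of inputs that
    required clipping.
    """
    xyz = np.asarray(xyz, dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise DermspecError("xyz must be finite")
    linear = (xyz / 100.0) @ XYZ_TO_RGB.T
    clipped = np.any((linear < 0) | (linear > 1), axis=-1)
    rgb = _srgb_encode(np.clip(linear, 0.0, 1.0))
    rgb = np.clip(rgb, 0.0, 1.0)
    if return_clipped:
        return rgb, clipped
    return rgb


def srgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    """sRGB in [0, 1] to XYZ on the Y=100 scale; exact inverse in gamut."""
    rgb = np.asarray(rgb, dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 1):
        raise DermspecError("sRGB channels must lie in [0, 1]")
    return 100.0 * (_srgb_decode(rgb) @ RGB_TO_XYZ.T)
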