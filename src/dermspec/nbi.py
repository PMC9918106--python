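"""Narrow-band image synthesis from a hyperspectral cube.

The characteristic absorption windows for skin lesions are 405-435 nm
(hemoglobin Soret band) and 525-555 nm; the default pseudo-color mapping
follows endoscopic NBI convention: the short window drives the blue and
red channels, the long window drives green.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DermspecError
from .grid import DEFAULT_GRID, SpectralGrid
from .reconstruction import HyperspectralCube

__all__ = [
    "BandWindow",
    "DEFAULT_WINDOWS",
    "NBIImage",
    "band_average",
    "synthesize_nbi",
]


@dataclass(frozen=True)
class BandWindow:
    """Inclusive wavelength window [lo_nm, hi_nm], both ends on the grid."""

    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if self.lo_nm > self.hi_nm:
            raise DermspecError("window lo_nm must not exceed hi_nm")

    def channel_slice(self, grid: SpectralGrid) -> slice:
        lo = grid.index_of(self.lo_nm)
        hi = grid.index_of(self.hi_nm)
        return slice(lo, hi + 1)

    def n_channels(self, grid: SpectralGrid = DEFAULT_GRID) -> int:
        s = self.channel_slice(grid)
        return s.stop - s.start


DEFAULT_WINDOWS = (BandWindow(405.0, 435.0), BandWindow(525.0, 555.0))


@dataclass
class NBIImage:
    data: np.ndarray  # H x W x 3 in [0, 1]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or data.shape[2] != 3:
            raise DermspecError("NBI image must be H x W x 3")
        if data.min() < 0 or data.max() > 1:
            raise DermspecError("NBI values must lie in [0, 1]")
        if not self.provenance.get("windows"):
            raise DermspecError("provenance must record at least one window")
        self.data = data

    def to_uint8(self) -> np.ndarray:
        return np.round(self.data * 255.0).astype(np.uint8)


def band_average(cube: HyperspectralCube, window: BandWindow) -> np.ndarray:
    """Per-pixel mean reflectance over the window's channels (inclusive)."""
    return cube.data[:, :, window.channel_slice(cube.grid)].mean(axis=2)


def _default_weights(n_windows: int) -> np.ndarray:
    if n_windows == 1:
        return np.ones((1, 3))
    if n_windows == 3:
        return np.eye(3)
    weights = np.zeros((2, 3))
    weights[0, 0] = weights[0, 2] = 1.0  # short window -> red + blue
    weights[1, 1] = 1.0  # long window -> green
    return weights


def synthesize_nbi(
    cube: HyperspectralCube,
    windows=DEFAULT_WINDOWS,
    channel_map: np.ndarray | None = None,
    normalization: str = "fixed",
) -> NBIImage:
    """Compose a 3-channel pseudo-color image from 1-3 band windows.

    ``channel_map`` is an (n_windows, 3) weight matrix: window ``i``
    contributes its band average times ``channel_map[i, c]`` to channel
    ``c``.  ``normalization`` is ``"fixed"`` (reflectance treated as
    already in [0, 1], clipped) or ``"minmax"`` (per-channel stretch).
    """
    windows = tuple(windows)
    if not 1 <= len(windows) <= 3:
        raise DermspecError("synthesize_nbi takes 1-3 windows")
    if normalization not in ("fixed", "minmax"):
        raise DermspecError(f"unknown normalization {normalization!r}")
    if channel_map is None:
        channel_map = _default_weights(len(windows))
    channel_map = np.asarray(channel_map, dtype=float)
    if channel_map.shape != (len(windows), 3):
        raise DermspecError("channel_map must be (n_windows, 3)")

    planes = np.stack([band_average(cube, w) for w in windows], axis=-1)
    out = planes @ channel_map  # H x W x 3
    if normalization == "minmax":
        lo = out.min(axis=(0, 1), keepdims=True)
        hi = out.max(axis=(0, 1), keepdims=True)
        span = np.where(hi - lo > 0, hi - lo, 1.0)
        out = (out - lo) / span
    out = np.clip(out, 0.0, 1.0)
    provenance = {
        "windows": [(w.lo_nm, w.hi_nm) for w in windows],
        "channel_map": channel_map.tolist(),
        "normalization": normalization,
    }
    return NBIImage(out, provenance)
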