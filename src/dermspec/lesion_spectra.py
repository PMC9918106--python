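"""Per-class lesion spectra: extraction, normalization, band separation
and greedy selection of discriminative wavelength windows."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DermspecError
from .grid import DEFAULT_GRID, SpectralGrid
from .nbi import BandWindow
from .reconstruction import HyperspectralCube

__all__ = [
    "ClassSpectrumSet",
    "roi_mean_spectrum",
    "normalize_spectrum",
    "band_separation",
    "select_windows",
    "mean_spectra_frame",
    "separation_profile_frame",
]


@dataclass
class ClassSpectrumSet:
    """A labelled collection of reflectance spectra (n, n_bands)."""

    class_label: str
    spectra: np.ndarray
    grid: SpectralGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.grid.require_length(spectra.shape[1], "spectra")
        if spectra.shape[0] < 1:
            raise DermspecError("class set needs at least one spectrum")
        self.spectra = spectra

    @property
    def mean_spectrum(self) -> np.ndarray:
        return self.spectra.mean(axis=0)


def roi_mean_spectrum(cube: HyperspectralCube, region) -> np.ndarray:
    """Mean spectrum over a region: an (xmin, ymin, xmax, ymax) half-open
    pixel box or a boolean H x W mask."""
    mask = np.asarray(region)
    if mask.dtype == bool:
        if mask.shape != (cube.height, cube.width):
            raise DermspecError("mask shape must match the cube")
        if not mask.any():
            raise DermspecError("empty region")
        return cube.data[mask].mean(axis=0)
    xmin, ymin, xmax, ymax = (int(v) for v in region)
    if not (0 <= xmin < xmax <= cube.width and 0 <= ymin < ymax <= cube.height):
        raise DermspecError("region box outside the image or degenerate")
    return cube.data[ymin:ymax, xmin:xmax].reshape(-1, cube.n_bands).mean(axis=0)


def normalize_spectrum(spectrum: np.ndarray, method: str = "max") -> np.ndarray:
    """``max``: divide by the peak (peak becomes exactly 1); ``area``:
    divide by the channel sum."""
    spectrum = np.asarray(spectrum, dtype=float)
    if method == "max":
        peak = spectrum.max()
        if peak <= 0:
            raise DermspecError("max-normalization needs a positive peak")
        return spectrum / peak
    if method == "area":
        total = spectrum.sum()
        if total <= 0:
            raise DermspecError("area-normalization needs a positive sum")
        return spectrum / total
    raise DermspecError(f"unknown normalization method {method!r}")


def band_separation(
    sets: list[ClassSpectrumSet], statistic: str = "range"
) -> np.ndarray:
    """Per-wavelength between-class separation score (>= 0, length 401).

    ``range`` (default): max over class pairs of |mean_i - mean_j| on
    max-normalized class means.  ``fisher``: between-class variance of
    normalized means divided by mean within-class variance.
    """
    if len(sets) < 2:
        raise DermspecError("band separation needs >= 2 classes")
    grid = sets[0].grid
    if any(s.grid != grid for s in sets):
        raise DermspecError("class sets on different grids")
    means = np.stack([normalize_spectrum(s.mean_spectrum) for s in sets])
    if statistic == "range":
        score = np.zeros(means.shape[1])
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                score = np.maximum(score, np.abs(means[i] - means[j]))
        return score
    if statistic == "fisher":
        between = means.var(axis=0)
        within = np.stack(
            [
                (s.spectra / np.maximum(s.mean_spectrum.max(), 1e-12)).var(axis=0)
                for s in sets
            ]
        ).mean(axis=0)
        return between / np.maximum(within, 1e-12)
    raise DermspecError(f"unknown separation statistic {statistic!r}")


def select_windows(
    profile: np.ndarray,
    width_nm: float = 31.0,
    n_windows: int = 2,
    grid: SpectralGrid = DEFAULT_GRID,
) -> list[BandWindow]:
    """Greedy non-overlapping fixed-width windows maximizing summed score.

    ``width_nm`` counts grid channels in nm (31 -> a 31-channel window,
    e.g. 405-435).  Ties break toward the shorter wavelength.
    """
    profile = np.asarray(profile, dtype=float)
    grid.require_length(profile.size, "profile")
    if np.any(profile < 0):
        raise DermspecError("profile scores must be non-negative")
    width = int(round(width_nm / grid.step_nm))
    if width < 1 or abs(width - width_nm / grid.step_nm) > 1e-9:
        raise DermspecError("width_nm must be a positive whole number of channels")
    if n_windows < 1:
        raise DermspecError("n_windows must be >= 1")
    if n_windows * width > profile.size:
        raise DermspecError("windows cannot fit without overlap")

    window_sums = np.convolve(profile, np.ones(width), mode="valid")
    available = np.ones(window_sums.size, dtype=bool)
    chosen: list[int] = []
    for _ in range(n_windows):
        if not available.any():
            raise DermspecError("windows cannot fit without overlap")
        masked = np.where(available, window_sums, -np.inf)
        start = int(np.argmax(masked))  # argmax takes the first max: short-wavelength tie-break
        chosen.append(start)
        lo = max(0, start - width + 1)
        available[lo : start + width] = False
    chosen.sort()
    lam = grid.wavelengths
    return [BandWindow(lam[s], lam[s + width - 1]) for s in chosen]


def mean_spectra_frame(sets: list[ClassSpectrumSet]) -> pd.DataFrame:
    """Long-format (wavelength_nm, class, reflectance) table for CSV export."""
    frames = [
        pd.DataFrame(
            {
                "wavelength_nm": s.grid.wavelengths,
                "class": s.class_label,
                "reflectance": s.mean_spectrum,
            }
        )
        for s in sets
    ]
    return pd.concat(frames, ignore_index=True)


def separation_profile_frame(
    profile: np.ndarray, grid: SpectralGrid = DEFAULT_GRID
) -> pd.DataFrame:
    return pd.DataFrame({"wavelength_nm": grid.wavelengths, "separation": profile})
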