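"""The shared spectral sampling grid.

Every spectrum, illuminant, observer curve and hyperspectral cube in this
package is sampled on one uniform wavelength grid.  The default covers
380-780 nm at 1 nm resolution: 401 channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError

__all__ = ["SpectralGrid", "DEFAULT_GRID"]


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform wavelength grid, endpoints inclusive."""

    start_nm: float = 380.0
    end_nm: float = 780.0
    step_nm: float = 1.0
    wavelengths: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        if self.end_nm <= self.start_nm:
            raise ValueError("end_nm must exceed start_nm")
        n = (self.end_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid endpoints are not an integer number of steps apart")
        lam = self.start_nm + self.step_nm * np.arange(int(round(n)) + 1)
        object.__setattr__(self, "wavelengths", lam)
        lam.setflags(write=False)

    def __len__(self) -> int:
        return self.wavelengths.size

    def index_of(self, nm: float) -> int:
        """Index of an on-grid wavelength; rejects off-grid values."""
        pos = (nm - self.start_nm) / self.step_nm
        idx = int(round(pos))
        if abs(pos - idx) > 1e-9 or not 0 <= idx < len(self):
            raise ValueError(f"{nm} nm is not on the grid")
        return idx

    def require_length(self, n: int, what: str = "array") -> None:
        if n != len(self):
            raise GridMismatchError(
                f"{what} has {n} samples but the grid has {len(self)}"
            )


DEFAULT_GRID = SpectralGrid()
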