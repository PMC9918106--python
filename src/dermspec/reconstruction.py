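"""Spectral reconstruction: from an RGB color back to a 401-band reflectance.

The model has two learned parts:

1. a PCA basis over calibration reflectance spectra (mean + orthonormal
   components), which decorrelates the spectral information and reduces
   dimensionality to ``k`` scores per spectrum;
2. an ordinary-least-squares regression from polynomially expanded XYZ
   coordinates to those PCA scores.

Reconstruction of an RGB pixel is then: sRGB -> XYZ -> expanded features
-> scores -> mean + scores . components, with negative reflectance clamped
to zero.  Whole images are reconstructed per unique 8-bit color.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DermspecError
from .grid import DEFAULT_GRID, SpectralGrid
from .spectral_model import (
    ColorMatchingFunctions,
    Illuminant,
    spectrum_to_xyz,
    srgb_to_xyz,
)

__all__ = [
    "SpectralBasis",
    "FeatureExpansion",
    "DEFAULT_EXPANSION",
    "ReconstructionModel",
    "HyperspectralCube",
    "fit_basis",
    "expand_features",
    "fit_reconstruction_model",
    "reconstruct_spectrum",
    "reconstruct_cube",
    "save_model",
    "load_model",
    "write_cube_envi",
    "read_cube_envi",
    "write_cube_npz",
    "read_cube_npz",
]


@dataclass(frozen=True)
class SpectralBasis:
    """Mean spectrum plus orthonormal principal component spectra."""

    mean_spectrum: np.ndarray
    components: np.ndarray  # (k, n_bands), rows orthonormal
    explained_variance_ratio: np.ndarray
    grid: SpectralGrid = DEFAULT_GRID

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def project(self, spectra: np.ndarray) -> np.ndarray:
        return (np.asarray(spectra, dtype=float) - self.mean_spectrum) @ self.components.T

    def synthesize(self, scores: np.ndarray) -> np.ndarray:
        return self.mean_spectrum + np.asarray(scores, dtype=float) @ self.components


@dataclass(frozen=True)
class FeatureExpansion:
    """Monomial exponents (a, b, c) applied to XYZ/100."""

    monomials: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        monos = tuple(tuple(int(e) for e in m) for m in self.monomials)
        if (0, 0, 0) not in monos:
            raise DermspecError("expansion must contain the constant monomial")
        if len(set(monos)) != len(monos):
            raise DermspecError("duplicate monomials in expansion")
        if any(len(m) != 3 or min(m) < 0 for m in monos):
            raise DermspecError("monomials must be non-negative integer triples")
        object.__setattr__(self, "monomials", monos)

    def __len__(self) -> int:
        return len(self.monomials)


def _degree_le_2_plus_cross() -> FeatureExpansion:
    monos = [
        (a, b, c)
        for a in range(3)
        for b in range(3)
        for c in range(3)
        if a + b + c <= 2
    ]
    monos.append((1, 1, 1))
    return FeatureExpansion(tuple(monos))


#: 10 monomials of total degree <= 2 plus the XYZ cross term: 11 features.
DEFAULT_EXPANSION = _degree_le_2_plus_cross()


@dataclass(frozen=True)
class ReconstructionModel:
    basis: SpectralBasis
    expansion: FeatureExpansion
    coefficients: np.ndarray  # (k, n_monomials)
    training_rmse: float

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.shape != (self.basis.k, len(self.expansion)):
            raise DermspecError("coefficient matrix shape mismatch")
        if not np.all(np.isfinite(coef)):
            raise DermspecError("coefficients must be finite")
        object.__setattr__(self, "coefficients", coef)


@dataclass
class HyperspectralCube:
    """H x W x 401 per-pixel reflectance, clamped non-negative."""

    data: np.ndarray
    grid: SpectralGrid = DEFAULT_GRID
    clamp_fraction: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise DermspecError("cube must be H x W x bands")
        self.grid.require_length(data.shape[2], "cube bands")
        if data.min() < 0:
            raise DermspecError("cube reflectance must be non-negative")
        self.data = data

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


def fit_basis(
    spectra: np.ndarray, k: int, grid: SpectralGrid = DEFAULT_GRID
) -> SpectralBasis:
    """Mean-centred PCA of a spectrum collection via SVD.

    ``k`` may not exceed min(n - 1, n_bands); a degenerate collection
    (zero total variance) yields zero explained-variance ratios.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2:
        raise DermspecError("spectra must be a 2-D collection")
    n, n_bands = spectra.shape
    grid.require_length(n_bands, "spectra")
    if k < 1:
        raise DermspecError("k must be >= 1")
    max_k = min(n - 1, n_bands)
    if n < k + 1 or k > max_k:
        raise DermspecError(f"k={k} exceeds available rank {max_k} (n={n})")

    mean = spectra.mean(axis=0)
    centred = spectra - mean
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    variances = svals**2 / (n - 1)
    total = variances.sum()
    # a collection of identical spectra has only rounding-level variance
    degenerate = total <= 1e-18 * max(1.0, float(np.sum(mean**2)))
    evr = variances / total if not degenerate else np.zeros_like(variances)
    # deterministic sign: largest-magnitude loading positive
    comps = vt[:k]
    signs = np.sign(comps[np.arange(k), np.abs(comps).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return SpectralBasis(mean, comps * signs[:, None], evr[:k], grid)


def expand_features(xyz: np.ndarray, expansion: FeatureExpansion = DEFAULT_EXPANSION) -> np.ndarray:
    """Monomial feature vector(s) of XYZ pre-scaled by 1/100."""
    xyz = np.asarray(xyz, dtype=float) / 100.0
    exps = np.asarray(expansion.monomials)  # (m, 3)
    # broadcast: (..., 1, 3) ** (m, 3) -> product over the channel axis
    return np.prod(xyz[..., None, :] ** exps, axis=-1)


def fit_reconstruction_model(
    calibration_spectra: np.ndarray,
    illuminant: Illuminant,
    cmf: ColorMatchingFunctions,
    k: int = 6,
    expansion: FeatureExpansion = DEFAULT_EXPANSION,
) -> ReconstructionModel:
    """Fit basis + regression from a calibration set of reflectance spectra."""
    spectra = np.asarray(calibration_spectra, dtype=float)
    if spectra.shape[0] < len(expansion):
        raise DermspecError(
            f"need >= {len(expansion)} calibration spectra, got {spectra.shape[0]}"
        )
    k_eff = min(k, spectra.shape[0] - 1, spectra.shape[1])
    if k_eff < k:
        warnings.warn(f"k reduced from {k} to feasible rank {k_eff}", stacklevel=2)
    if k_eff >= 1:
        basis = fit_basis(spectra, k_eff, illuminant.grid)
    else:  # mean-only model: a single calibration spectrum
        basis = SpectralBasis(
            spectra.mean(axis=0),
            np.zeros((0, spectra.shape[1])),
            np.zeros(0),
            illuminant.grid,
        )
    xyz = spectrum_to_xyz(spectra, illuminant, cmf)
    design = expand_features(xyz, expansion)  # (n, m)
    scores = basis.project(spectra)  # (n, k)
    coef, _, rank, _ = np.linalg.lstsq(design, scores, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            "rank-deficient design matrix; minimum-norm least squares used",
            stacklevel=2,
        )
    recon = np.clip(basis.synthesize(design @ coef), 0.0, None)
    rmse = float(np.sqrt(np.mean((recon - spectra) ** 2)))
    return ReconstructionModel(basis, expansion, coef.T, rmse)


def reconstruct_spectrum(
    rgb: np.ndarray, model: ReconstructionModel, return_clamp_count: bool = False
):
    """Reflectance spectra for sRGB color(s) in [0, 1]; negatives clamped."""
    xyz = srgb_to_xyz(rgb)
    features = expand_features(xyz, model.expansion)
    scores = features @ model.coefficients.T
    raw = model.basis.synthesize(scores)
    clamped = int(np.count_nonzero(raw < 0))
    spectrum = np.clip(raw, 0.0, None)
    if return_clamp_count:
        return spectrum, clamped
    return spectrum


def reconstruct_cube(image: np.ndarray, model: ReconstructionModel) -> HyperspectralCube:
    """Per-pixel reconstruction of an 8-bit RGB image, cached per unique color."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise DermspecError("expected an H x W x 3 RGB image")
    if image.dtype != np.uint8:
        raise DermspecError("expected an 8-bit image (dtype uint8)")
    h, w, _ = image.shape
    flat = image.reshape(-1, 3)
    colors, inverse = np.unique(flat, axis=0, return_inverse=True)
    spectra, clamped = reconstruct_spectrum(
        colors.astype(float) / 255.0, model, return_clamp_count=True
    )
    data = spectra[inverse].reshape(h, w, -1).astype(np.float32)
    frac = clamped / spectra.size if spectra.size else 0.0
    return HyperspectralCube(
        data, model.basis.grid, clamp_fraction=frac, meta={"unique_colors": len(colors)}
    )


# --- serialization -------------------------------------------------------

def save_model(model: ReconstructionModel, path: str | Path) -> None:
    grid = model.basis.grid
    payload = {
        "grid": {"start_nm": grid.start_nm, "end_nm": grid.end_nm, "step_nm": grid.step_nm},
        "mean_spectrum": model.basis.mean_spectrum.tolist(),
        "components": model.basis.components.tolist(),
        "explained_variance_ratio": model.basis.explained_variance_ratio.tolist(),
        "monomials": [list(m) for m in model.expansion.monomials],
        "coefficients": model.coefficients.tolist(),
        "training_rmse": model.training_rmse,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ReconstructionModel:
    payload = json.loads(Path(path).read_text())
    grid = SpectralGrid(**payload["grid"])
    basis = SpectralBasis(
        np.array(payload["mean_spectrum"]),
        np.array(payload["components"]),
        np.array(payload["explained_variance_ratio"]),
        grid,
    )
    expansion = FeatureExpansion(tuple(tuple(m) for m in payload["monomials"]))
    return ReconstructionModel(
        basis, expansion, np.array(payload["coefficients"]), payload["training_rmse"]
    )


# --- cube I/O ------------------------------------------------------------

def write_cube_envi(cube: HyperspectralCube, stem: str | Path) -> None:
    """ENVI-style pair: <stem>.hdr text header + <stem>.raw float32 BSQ."""
    stem = Path(stem)
    bsq = np.ascontiguousarray(np.moveaxis(cube.data.astype(np.float32), 2, 0))
    bsq.tofile(stem.with_suffix(".raw"))
    lam = ", ".join(f"{v:g}" for v in cube.grid.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cube.width}\n"
        f"lines = {cube.height}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {lam} }}\n"
    )
    stem.with_suffix(".hdr").write_text(header)


def read_cube_envi(stem: str | Path) -> HyperspectralCube:
    stem = Path(stem)
    fields = {}
    text = stem.with_suffix(".hdr").read_text()
    for line in text.splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
    h, w, b = int(fields["lines"]), int(fields["samples"]), int(fields["bands"])
    lam = [float(v) for v in fields["wavelength"].strip("{} ").split(",")]
    grid = SpectralGrid(lam[0], lam[-1], lam[1] - lam[0])
    bsq = np.fromfile(stem.with_suffix(".raw"), dtype=np.float32).reshape(b, h, w)
    return HyperspectralCube(np.moveaxis(bsq, 0, 2), grid)


def write_cube_npz(cube: HyperspectralCube, path: str | Path) -> None:
    """Compressed single-file variant."""
    np.savez_compressed(
        path,
        data=cube.data.astype(np.float32),
        grid=np.array([cube.grid.start_nm, cube.grid.end_nm, cube.grid.step_nm]),
    )


def read_cube_npz(path: str | Path) -> HyperspectralCube:
    with np.load(path) as archive:
        start, end, step = archive["grid"]
        return HyperspectralCube(archive["data"], SpectralGrid(start, end, step))
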