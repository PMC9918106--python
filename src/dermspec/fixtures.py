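"""Synthetic data generation for the whole pipeline.

Everything here is seeded and bit-reproducible: class reflectance spectra
with hemoglobin-like absorption dips, rendered lesion scenes with
ground-truth boxes and cubes, smooth calibration spectra for the
reconstruction model, and detection/ground-truth sets that materialise an
arbitrary extended confusion matrix exactly.

Seed discipline: public entry points take one integer seed and fan out to
independent streams via :func:`derived_rng` so tests never share streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .dataset_prep import AnnotatedImage, Box
from .detection_eval import Detection, ExtendedConfusionMatrix, GroundTruth
from .errors import DermspecError
from .grid import DEFAULT_GRID, SpectralGrid
from .lesion_spectra import ClassSpectrumSet
from .reconstruction import HyperspectralCube
from .spectral_model import (
    load_cmf_1931_2deg,
    load_illuminant_d65,
    spectrum_to_xyz,
    xyz_to_srgb,
)

__all__ = [
    "derived_rng",
    "SpectrumRecipe",
    "LesionSpec",
    "SceneRecipe",
    "make_class_spectra",
    "default_class_recipes",
    "render_scene",
    "make_calibration_set",
    "detections_from_matrix",
]


def derived_rng(seed: int, purpose: str) -> np.random.Generator:
    """Independent generator for (seed, purpose); stable across sessions."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(purpose.encode())])
    )


def _gaussian(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


@dataclass(frozen=True)
class SpectrumRecipe:
    """Baseline minus Gaussian absorption dips plus noise.

    ``slope`` tilts the baseline linearly over the grid (melanin-like).
    """

    baseline_level: float
    absorption_features: tuple[tuple[float, float, float], ...] = ()  # (center, width, depth)
    noise_sd: float = 0.0
    slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_level <= 1.4:
            raise DermspecError("baseline_level must lie in (0, 1.4]")
        feats = tuple((float(c), float(w), float(d)) for c, w, d in self.absorption_features)
        for center, width, depth in feats:
            if not 0 <= depth <= self.baseline_level:
                raise DermspecError("dip depth must lie in [0, baseline_level]")
            if width <= 0:
                raise DermspecError("dip width must be positive")
            if not DEFAULT_GRID.start_nm <= center <= DEFAULT_GRID.end_nm:
                raise DermspecError("dip center off the grid")
        if self.noise_sd < 0:
            raise DermspecError("noise_sd must be >= 0")
        object.__setattr__(self, "absorption_features", feats)

    def base_spectrum(self, grid: SpectralGrid = DEFAULT_GRID) -> np.ndarray:
        lam = grid.wavelengths
        s = self.baseline_level + self.slope * (lam - lam.mean()) / (lam[-1] - lam[0])
        for center, width, depth in self.absorption_features:
            s = s - depth * _gaussian(lam, center, width)
        return np.clip(s, 0.0, None)


def make_class_spectra(
    recipe: SpectrumRecipe,
    n: int,
    class_label: str = "synthetic",
    grid: SpectralGrid = DEFAULT_GRID,
) -> ClassSpectrumSet:
    """n noisy realisations of a recipe, clamped non-negative."""
    if n < 1:
        raise DermspecError("n must be >= 1")
    rng = derived_rng(recipe.seed, f"class-spectra:{class_label}")
    base = recipe.base_spectrum(grid)
    spectra = base + recipe.noise_sd * rng.standard_normal((n, len(grid)))
    return ClassSpectrumSet(class_label, np.clip(spectra, 0.0, None), grid)


def default_class_recipes(seed: int = 0) -> dict[str, SpectrumRecipe]:
    """Three lesion-class recipes: two vascular classes with
    hemoglobin-like dips near 420 and 545 nm (correlated, as for a single
    chromophore, at different concentrations), one keratosis-like class
    with a sloped baseline and weak dips."""
    return {
        "BCC": SpectrumRecipe(0.55, ((420.0, 15.0, 0.35), (545.0, 20.0, 0.20)), 0.01, 0.0, seed),
        "SCC": SpectrumRecipe(0.55, ((420.0, 15.0, 0.175), (545.0, 20.0, 0.10)), 0.01, 0.0, seed),
        "SK": SpectrumRecipe(0.55, ((420.0, 15.0, 0.05), (545.0, 20.0, 0.03)), 0.01, 0.06, seed),
    }


@dataclass(frozen=True)
class LesionSpec:
    class_label: str
    center: tuple[float, float]  # (cx, cy) pixels
    axes: tuple[float, float]  # (ax, ay) semi-axes, pixels
    recipe: SpectrumRecipe

    def bounding_box(self) -> Box:
        cx, cy = self.center
        ax, ay = self.axes
        return Box(self.class_label, cx - ax, cy - ay, cx + ax, cy + ay)


@dataclass(frozen=True)
class SceneRecipe:
    canvas: int
    lesions: tuple[LesionSpec, ...]
    background_recipe: SpectrumRecipe
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lesions:
            raise DermspecError("a scene needs at least one lesion")
        object.__setattr__(self, "lesions", tuple(self.lesions))
        for lesion in self.lesions:
            cx, cy = lesion.center
            ax, ay = lesion.axes
            if min(ax, ay) <= 0:
                raise DermspecError("lesion axes must be positive")
            if cx - ax < 0 or cy - ay < 0 or cx + ax > self.canvas or cy + ay > self.canvas:
                raise DermspecError("lesion ellipse outside the canvas")


def render_scene(
    recipe: SceneRecipe, grid: SpectralGrid = DEFAULT_GRID, image_id: str = "scene"
) -> tuple[np.ndarray, AnnotatedImage, HyperspectralCube]:
    """Render a scene to (8-bit RGB, annotations, ground-truth cube).

    Pixels take the spectrum of the topmost lesion ellipse covering their
    center, else the background; per-pixel Gaussian noise per recipe.
    """
    size = recipe.canvas
    yy, xx = np.mgrid[0:size, 0:size]
    px = xx + 0.5
    py = yy + 0.5
    region = np.full((size, size), -1, dtype=int)  # -1 = background
    for i, lesion in enumerate(recipe.lesions):
        cx, cy = lesion.center
        ax, ay = lesion.axes
        inside = ((px - cx) / ax) ** 2 + ((py - cy) / ay) ** 2 < 1.0
        region[inside] = i

    rng = derived_rng(recipe.seed, "render-scene")
    data = np.empty((size, size, len(grid)))
    recipes = [recipe.background_recipe] + [les.recipe for les in recipe.lesions]
    for idx, r in zip([-1] + list(range(len(recipe.lesions))), recipes):
        mask = region == idx
        n_pix = int(mask.sum())
        if n_pix == 0:
            continue
        base = r.base_spectrum(grid)
        data[mask] = base + r.noise_sd * rng.standard_normal((n_pix, len(grid)))
    data = np.clip(data, 0.0, None)

    cube = HyperspectralCube(data.astype(np.float32), grid)
    illum = load_illuminant_d65(grid)
    cmf = load_cmf_1931_2deg(grid)
    xyz = spectrum_to_xyz(data.reshape(-1, len(grid)), illum, cmf)
    rgb = xyz_to_srgb(xyz).reshape(size, size, 3)
    image = np.round(rgb * 255.0).astype(np.uint8)

    boxes = [les.bounding_box() for les in recipe.lesions]
    annotated = AnnotatedImage(image_id, size, size, boxes, image)
    return image, annotated, cube


def make_calibration_set(
    n: int = 24, seed: int = 1134, grid: SpectralGrid = DEFAULT_GRID
) -> np.ndarray:
    """(n, 401) smooth diverse skin-plausible reflectance spectra.

    Built as a sloped base curve plus random weights on eight smooth
    basis functions with decaying amplitudes, so the spectral covariance
    has at least six non-negligible components while six principal
    components still explain >= 99% of the variance.
    """
    if n < 12:
        raise DermspecError("calibration set needs n >= 12")
    rng = derived_rng(seed, "calibration-set")
    lam = grid.wavelengths
    u = (lam - 580.0) / 200.0
    # hemoglobin-like component: Soret and Q-band dips move together,
    # so the colorimetrically weak 420 nm dip is identifiable from color
    hemoglobin = -(1.75 * _gaussian(lam, 420.0, 15.0) + _gaussian(lam, 545.0, 20.0))
    basis = np.stack(
        [
            np.ones_like(lam),  # overall reflectance level
            hemoglobin,
            u,
            _gaussian(lam, 480.0, 40.0),
            _gaussian(lam, 620.0, 50.0),
            _gaussian(lam, 700.0, 45.0),
            _gaussian(lam, 390.0, 25.0),
            np.sin(lam / 37.0),
        ]
    )
    amplitudes = np.array([0.16, 0.12, 0.08, 0.025, 0.015, 0.01, 0.006, 0.004])
    base = 0.5 + 0.08 * u
    weights = rng.standard_normal((n, basis.shape[0])) * amplitudes
    spectra = base + weights @ basis
    return np.clip(spectra, 0.01, 1.45)


def detections_from_matrix(
    matrix: ExtendedConfusionMatrix, geometry_seed: int = 0
) -> tuple[list[Detection], list[GroundTruth]]:
    """Detections and ground truths whose greedy evaluation reproduces the
    matrix exactly.

    Each cell instance occupies its own slot on a non-overlapping box
    grid (all in one synthetic image): a matched pair shares one box with
    IoU 1, a background-column instance is a lone detection, a
    background-row instance a lone ground truth.  Confidence is 0.9.
    """
    k = matrix.n_classes
    counts = matrix.counts
    total = int(counts.sum())
    rng = derived_rng(geometry_seed, "detections-from-matrix")
    slots = rng.permutation(max(total, 1))
    pitch, side = 60.0, 40.0
    columns = int(np.ceil(np.sqrt(max(total, 1))))

    def slot_box(index: int) -> tuple[float, float, float, float]:
        row, col = divmod(int(slots[index]), columns)
        x = col * pitch
        y = row * pitch
        return (x, y, x + side, y + side)

    detections: list[Detection] = []
    ground_truths: list[GroundTruth] = []
    cursor = 0
    image_id = "synthetic"
    for p in range(k + 1):
        for t in range(k + 1):
            for _ in range(int(counts[p, t])):
                box = slot_box(cursor)
                cursor += 1
                if t < k:
                    ground_truths.append(GroundTruth(image_id, t, box))
                if p < k:
                    detections.append(Detection(image_id, p, 0.9, box))
    return detections, ground_truths
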