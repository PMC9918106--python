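"""Regenerate the colorimetric constant tables shipped in dermspec/data.

Fully deterministic and offline:

* ``cie_xyz_1931_2deg.csv`` -- CIE 1931 2-degree standard observer curves
  evaluated from the multi-lobe Gaussian fits of Wyman, Sloan & Shirley
  (JCGT 2013, "Simple analytic approximations to the CIE XYZ color matching
  functions") on the 380-780 nm / 1 nm grid.
* ``illuminant_d65.csv`` -- a smooth daylight illuminant: a 6504 K Planck
  radiator modulated by a quadratic chosen so that, under the observer
  table above, the perfect reflector has exactly the D65 white
  chromaticity (x, y) = (0.31272, 0.32903).  Normalised to 100 at 560 nm.

Run from the repository root:  python scripts/make_color_tables.py
"""

from __future__ import annotations

import pathlib

import numpy as np

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "dermspec" / "data"

WAVELENGTHS = np.arange(380.0, 781.0, 1.0)

# D65 white chromaticity (CIE 15:2004) and sRGB primaries (IEC 61966-2-1).
WHITE_XY = (0.31272, 0.32903)
PRIMARIES_XY = {"r": (0.6400, 0.3300), "g": (0.3000, 0.6000), "b": (0.1500, 0.0600)}


def _lobe(lam: np.ndarray, peak: float, sigma_lo: float, sigma_hi: float) -> np.ndarray:
    sigma = np.where(lam < peak, sigma_lo, sigma_hi)
    return np.exp(-0.5 * ((lam - peak) / sigma) ** 2)


def observer_1931_2deg(lam: np.ndarray) -> np.ndarray:
    """(n, 3) array of xbar, ybar, zbar from the Wyman et al. fit."""
    xbar = (
        1.056 * _lobe(lam, 599.8, 37.9, 31.0)
        + 0.362 * _lobe(lam, 442.0, 16.0, 26.7)
        - 0.065 * _lobe(lam, 501.1, 20.4, 26.2)
    )
    ybar = 0.821 * _lobe(lam, 568.8, 46.9, 40.5) + 0.286 * _lobe(lam, 530.9, 16.3, 31.1)
    zbar = 1.217 * _lobe(lam, 437.0, 11.8, 36.0) + 0.681 * _lobe(lam, 459.0, 26.0, 13.8)
    return np.clip(np.column_stack([xbar, ybar, zbar]), 0.0, None)


def planck(lam_nm: np.ndarray, temperature_k: float) -> np.ndarray:
    lam_m = lam_nm * 1e-9
    c2 = 1.4388e-2  # m K
    spd = lam_m**-5 / np.expm1(c2 / (lam_m * temperature_k))
    return spd / spd.max()


def daylight_6500(lam: np.ndarray, cmf: np.ndarray) -> np.ndarray:
    """Planck(6504 K) * (1 + b u + c u^2) hitting WHITE_XY exactly.

    The chromaticity constraints are linear in (b, c), so a 2x2 solve
    suffices.  u is a centred, scaled wavelength coordinate.
    """
    base = planck(lam, 6504.0)
    u = (lam - 560.0) / 220.0
    # tristimulus of base, base*u, base*u^2 (columns X, Y, Z)
    t0 = cmf.T @ base
    t1 = cmf.T @ (base * u)
    t2 = cmf.T @ (base * u * u)
    xw, yw = WHITE_XY

    def chroma_row(target: float, channel: int) -> tuple[np.ndarray, float]:
        # target * sum(T) - T[channel] = 0, affine in (b, c)
        a = np.array(
            [target * t1.sum() - t1[channel], target * t2.sum() - t2[channel]]
        )
        rhs = t0[channel] - target * t0.sum()
        return a, rhs

    a1, r1 = chroma_row(xw, 0)
    a2, r2 = chroma_row(yw, 1)
    b, c = np.linalg.solve(np.vstack([a1, a2]), np.array([r1, r2]))
    spd = base * (1.0 + b * u + c * u * u)
    if spd.min() <= 0:
        raise RuntimeError("daylight model went non-positive; adjust basis")
    return 100.0 * spd / spd[lam == 560.0]


def srgb_matrix(cmf: np.ndarray, illum: np.ndarray) -> np.ndarray:
    """Linear RGB -> XYZ matrix from primaries + the table white point (Y=1)."""
    cols = []
    for key in "rgb":
        x, y = PRIMARIES_XY[key]
        cols.append(np.array([x / y, 1.0, (1.0 - x - y) / y]))
    prim = np.column_stack(cols)
    k = 1.0 / (illum @ cmf[:, 1])
    white = k * (cmf.T @ illum)  # Y = 1
    scale = np.linalg.solve(prim, white)
    return prim * scale


def main() -> None:
    cmf = observer_1931_2deg(WAVELENGTHS)
    illum = daylight_6500(WAVELENGTHS, cmf)

    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "cie_xyz_1931_2deg.csv", "w") as fh:
        fh.write("wavelength_nm,xbar,ybar,zbar\n")
        for lam, (x, y, z) in zip(WAVELENGTHS, cmf):
            fh.write(f"{lam:.0f},{x:.8f},{y:.8f},{z:.8f}\n")
    with open(OUT / "illuminant_d65.csv", "w") as fh:
        fh.write("wavelength_nm,value\n")
        for lam, s in zip(WAVELENGTHS, illum):
            fh.write(f"{lam:.0f},{s:.8f}\n")

    m = srgb_matrix(cmf, illum)
    np.set_printoptions(precision=12, suppress=True)
    print("white XYZ (Y=100):", 100.0 * m.sum(axis=1))
    print("RGB->XYZ matrix:\n", m)


if __name__ == "__main__":
    main()
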