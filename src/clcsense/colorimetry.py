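"""CIE 1931 colorimetry of transmission spectra.

Maps a crossed-polarizer transmission spectrum to tristimulus values,
chromaticity coordinates and an sRGB display color, predicting the hue of
the corresponding polarizing-microscope texture.  Tristimulus values use
the standard normalization ``k = 100 / sum(S ybar dlam)`` so a
unit-transmittance spectrum has Y = 100 under any illuminant.

The CIE 1931 2-degree color-matching functions are shipped as a 5 nm
table and the D65 spectral power distribution as a 10 nm table; both are
linearly interpolated onto the spectrum's grid.  Display rendering uses
the sRGB primaries after Bradford chromatic adaptation from the
illuminant's own white to D65, so the reference white always maps to
(255, 255, 255) regardless of the chosen illuminant.

The microscope lamp of the source measurements is unknown, so the
illuminant is a free choice (default D65); predicted hues should be read
as hue classes, not exact display triples.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .optics import CellModel, Spectrum, simulate_spectrum

__all__ = [
    "CMFTable",
    "Illuminant",
    "ColorResult",
    "COLOR_GRID_NM",
    "spectrum_to_XYZ",
    "XYZ_to_xy",
    "XYZ_to_rgb8",
    "predict_texture_color",
]

#: default wavelength grid for colorimetric integration, nm
COLOR_GRID_NM = np.arange(380.0, 781.0, 5.0)

_BRADFORD = np.array(
    [
        [0.8951, 0.2664, -0.1614],
        [-0.7502, 1.7135, 0.0367],
        [0.0389, -0.0685, 1.0296],
    ]
)


def _srgb_matrix() -> tuple[np.ndarray, np.ndarray]:
    """XYZ->linear-sRGB matrix derived from the IEC 61966-2-1 primaries.

    Built at full precision from the primary/white chromaticities so the
    D65 white maps to exactly (1, 1, 1); published 4-decimal matrices
    miss by ~1e-4, enough to spuriously flag white as out of gamut.
    """
    xy = np.array([[0.64, 0.33], [0.30, 0.60], [0.15, 0.06]])
    white_xy = np.array([0.3127, 0.3290])
    prim = np.array([[x / y, 1.0, (1 - x - y) / y] for x, y in xy]).T
    white = np.array(
        [white_xy[0] / white_xy[1], 1.0, (1 - white_xy.sum()) / white_xy[1]]
    )
    scale = np.linalg.solve(prim, white)
    rgb_to_xyz = prim * scale
    return np.linalg.inv(rgb_to_xyz), white


_XYZ_TO_SRGB, _D65_WHITE = _srgb_matrix()


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("clcsense._data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class CMFTable:
    """Color-matching functions sampled on a wavelength grid."""

    wavelengths_nm: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    @classmethod
    def cie1931_2deg(cls) -> "CMFTable":
        t = _load_table("cie_1931_2deg_5nm.csv")
        return cls(
            t.wavelength_nm.to_numpy(float),
            t.xbar.to_numpy(float),
            t.ybar.to_numpy(float),
            t.zbar.to_numpy(float),
        )

    def resample(self, grid_nm: np.ndarray) -> "CMFTable":
        g = np.asarray(grid_nm, dtype=float)
        return CMFTable(
            g,
            np.interp(g, self.wavelengths_nm, self.xbar, left=0.0, right=0.0),
            np.interp(g, self.wavelengths_nm, self.ybar, left=0.0, right=0.0),
            np.interp(g, self.wavelengths_nm, self.zbar, left=0.0, right=0.0),
        )


@dataclass(frozen=True)
class Illuminant:
    """Relative spectral power distribution of a light source."""

    name: str
    wavelengths_nm: np.ndarray
    power: np.ndarray

    @classmethod
    def equal_energy(cls, grid_nm=COLOR_GRID_NM) -> "Illuminant":
        g = np.asarray(grid_nm, dtype=float)
        return cls("E", g, np.ones_like(g))

    @classmethod
    def d65(cls) -> "Illuminant":
        t = _load_table("illuminant_d65_10nm.csv")
        return cls("D65", t.wavelength_nm.to_numpy(float), t.power.to_numpy(float))

    @classmethod
    def incandescent_a(cls, grid_nm=COLOR_GRID_NM) -> "Illuminant":
        """CIE illuminant A: Planck radiator at 2856 K, normalized at 560 nm."""
        g = np.asarray(grid_nm, dtype=float)
        c2 = 1.4388e7  # nm K, per the ITS-90 definition of illuminant A
        planck = lambda lam: lam**-5 / (np.exp(c2 / (lam * 2856.0)) - 1.0)
        return cls("A", g, 100.0 * planck(g) / planck(560.0))

    @classmethod
    def named(cls, name: str) -> "Illuminant":
        key = name.upper()
        if key == "E":
            return cls.equal_energy()
        if key == "D65":
            return cls.d65()
        if key == "A":
            return cls.incandescent_a()
        raise ValueError(f"unknown illuminant {name!r}; use E, D65 or A")

    def resample(self, grid_nm: np.ndarray) -> "Illuminant":
        g = np.asarray(grid_nm, dtype=float)
        return Illuminant(
            self.name,
            g,
            np.interp(g, self.wavelengths_nm, self.power, left=0.0, right=0.0),
        )

    def white_XYZ(self, cmf: CMFTable | None = None) -> np.ndarray:
        """Tristimulus of the illuminant itself (T == 1), Y = 100."""
        grid = self.wavelengths_nm
        flat = Spectrum(grid, np.ones_like(grid), kind="absolute")
        return spectrum_to_XYZ(flat, self, cmf)


@dataclass(frozen=True)
class ColorResult:
    XYZ: tuple[float, float, float]
    xy: tuple[float, float] | None
    rgb8: tuple[int, int, int]
    gamut_clipped: bool


def spectrum_to_XYZ(
    s: Spectrum, ill: Illuminant, cmf: CMFTable | None = None
) -> np.ndarray:
    """Tristimulus values of a transmission spectrum under an illuminant.

    Illuminant and CMFs are linearly interpolated onto the spectrum's
    grid; the integration runs over the overlap of the three ranges.
    """
    if cmf is None:
        cmf = CMFTable.cie1931_2deg()
    grid = s.wavelengths_nm
    lo = max(grid[0], ill.wavelengths_nm[0], cmf.wavelengths_nm[0])
    hi = min(grid[-1], ill.wavelengths_nm[-1], cmf.wavelengths_nm[-1])
    if lo >= hi:
        raise ValueError(
            "spectrum, illuminant and CMF wavelength ranges do not overlap"
        )
    mask = (grid >= lo) & (grid <= hi)
    g = grid[mask]
    t = s.values[mask]
    S = np.interp(g, ill.wavelengths_nm, ill.power)
    c = cmf.resample(g)
    norm = np.sum(S * c.ybar)
    if norm <= 0:
        raise ValueError("illuminant has no power where the CMFs are non-zero")
    k = 100.0 / norm
    return k * np.array(
        [np.sum(S * t * c.xbar), np.sum(S * t * c.ybar), np.sum(S * t * c.zbar)]
    )


def XYZ_to_xy(XYZ) -> tuple[float, float]:
    X, Y, Z = (float(v) for v in XYZ)
    total = X + Y + Z
    if total <= 0:
        raise ValueError("chromaticity undefined for X + Y + Z <= 0")
    return (X / total, Y / total)


def _bradford_adapt(XYZ: np.ndarray, white_src: np.ndarray) -> np.ndarray:
    """Adapt XYZ (Y-scale arbitrary) from white_src to the nominal D65 white."""
    src = _BRADFORD @ (white_src / white_src[1])
    dst = _BRADFORD @ _D65_WHITE
    m = np.linalg.inv(_BRADFORD) @ np.diag(dst / src) @ _BRADFORD
    return m @ XYZ


def XYZ_to_rgb8(XYZ, white_point=None) -> tuple[tuple[int, int, int], bool]:
    """Render tristimulus values as an 8-bit sRGB triple.

    ``white_point`` is the XYZ of the scene white (any Y scale); the color
    is Bradford-adapted from it to D65 before the sRGB matrix so that the
    white itself maps to (255, 255, 255).  Out-of-gamut channels are
    clamped and flagged.
    """
    xyz = np.asarray(XYZ, dtype=float)
    if np.any(~np.isfinite(xyz)) or np.any(xyz < 0):
        raise ValueError("XYZ must be finite and non-negative")
    if white_point is None:
        white_point = 100.0 * _D65_WHITE
    white = np.asarray(white_point, dtype=float)
    # scale so the scene white has Y = 1 (maps to full display white)
    xyz = xyz / white[1]
    xyz = _bradford_adapt(xyz, white)
    linear = _XYZ_TO_SRGB @ xyz
    clipped = bool(np.any(linear < -1e-9) or np.any(linear > 1.0 + 1e-9))
    linear = np.clip(linear, 0.0, 1.0)
    srgb = np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.power(linear, 1.0 / 2.4) - 0.055,
    )
    rgb8 = tuple(int(v) for v in np.rint(255.0 * srgb))
    return rgb8, clipped


def predict_texture_color(
    cell: CellModel,
    ill: Illuminant | None = None,
    cmf: CMFTable | None = None,
    grid_nm=COLOR_GRID_NM,
) -> ColorResult:
    """Predicted texture color of a CLC cell between crossed polarizers."""
    if ill is None:
        ill = Illuminant.d65()
    if cmf is None:
        cmf = CMFTable.cie1931_2deg()
    spec = simulate_spectrum(cell, grid_nm)
    XYZ = spectrum_to_XYZ(spec, ill, cmf)
    white = ill.resample(np.asarray(grid_nm, dtype=float)).white_XYZ(cmf)
    rgb8, clipped = XYZ_to_rgb8(XYZ, white_point=white)
    if XYZ.sum() <= 0:
        xy = None
    else:
        xy = XYZ_to_xy(XYZ)
    return ColorResult(
        XYZ=tuple(float(v) for v in XYZ),
        xy=xy,
        rgb8=rgb8,
        gamut_clipped=clipped,
    )
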