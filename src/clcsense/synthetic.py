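"""Synthetic immunoassay data with the structure the analysis assumes.

Three generators emulate the sensor's measurement channels so every
pipeline stage is testable without instrument data:

* ``generate_readout_series`` — replicated haze / transmittance / RGB
  readouts that vary log-linearly with analyte concentration and then
  saturate, with homoscedastic Gaussian replicate noise;
* ``generate_texture`` — polarizing-microscope-like RGB textures: a
  signal region (disk or coffee-ring annulus, the deposit left by an
  evaporating protein droplet) alpha-blended over a uniform background,
  with the blend fraction a saturating function of log10 concentration;
* ``generate_noisy_spectrum`` — the forward optical model times
  multiplicative Gaussian noise, for tilt-fitting experiments.

Default magnitudes follow the study conditions being emulated: BSA
series span 1e-12..1e-2 g/mL with the red-channel statistic rising from
~29% to ~45% and saturating above 1e-5 g/mL, haze rising ~10 -> 40%,
parallel transmittance falling ~70 -> 30% and total transmittance
~60 -> 7%; CA125 series span 1e-10..1e-5 g/mL with haze ~10 -> 40% and
the red channel ~30 -> 47%.  The serum variant swaps the texture colors
(green signal on a yellow-orange background) and the analyzed channel to
green.  Every generator is deterministic given (model, seed); ground
truth is returned alongside each output for recovery tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .optics import CellModel, Spectrum, simulate_spectrum
from .quantitation import AssaySeries

__all__ = [
    "AssayModel",
    "TextureModel",
    "READOUT_DEFAULTS",
    "generate_readout_series",
    "generate_texture",
    "generate_noisy_spectrum",
    "substream",
]

Mode = Literal["BSA", "CA125", "CA125_serum"]

#: default concentration ladders, g/mL (one point per decade)
_GRIDS = {
    "BSA": np.logspace(-12, -2, 11),
    "CA125": np.logspace(-10, -5, 6),
    "CA125_serum": np.logspace(-10, -5, 6),
}

#: per-(mode, readout) response defaults: value at the lowest grid
#: concentration, change per decade, and the last linear concentration
#: (None = no saturation inside the grid).
READOUT_DEFAULTS: dict[tuple[str, str], dict] = {
    ("BSA", "R_rel"): dict(baseline=29.0, slope=16.0 / 7.0, saturation_onset=1e-5),
    ("BSA", "haze"): dict(baseline=10.0, slope=3.0, saturation_onset=None),
    ("BSA", "T_p"): dict(baseline=70.0, slope=-4.0, saturation_onset=None),
    ("BSA", "T"): dict(baseline=60.0, slope=-5.3, saturation_onset=None),
    ("CA125", "R_rel"): dict(baseline=30.0, slope=17.0 / 5.0, saturation_onset=None),
    ("CA125", "haze"): dict(baseline=10.0, slope=6.0, saturation_onset=None),
    ("CA125", "T_p"): dict(baseline=70.0, slope=-6.0, saturation_onset=None),
    ("CA125", "T"): dict(baseline=50.0, slope=-6.0, saturation_onset=None),
    ("CA125_serum", "G_rel"): dict(baseline=30.0, slope=17.0 / 5.0, saturation_onset=None),
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from one run seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class AssayModel:
    """Response model for one readout channel of one assay mode.

    ``response(c) = baseline + slope * log10(min(c, saturation_onset) / c_min)``
    clipped to ``bounds``; ``saturation_onset`` is the last concentration
    on the linear part (strictly higher concentrations sit on the
    plateau).  ``noise_sd`` is the SD of additive Gaussian replicate
    noise in the readout's own units (percentage points).
    """

    mode: Mode = "BSA"
    concentrations: np.ndarray = None  # type: ignore[assignment]
    baseline: float = 10.0
    slope_per_decade: float = 3.0
    saturation_onset: float | None = None
    bounds: tuple[float, float] = (0.0, 100.0)
    noise_sd: float = 1.0
    n_replicates: int = 3

    def __post_init__(self):
        grid = (
            _GRIDS[self.mode].copy()
            if self.concentrations is None
            else np.asarray(self.concentrations, dtype=float)
        )
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("concentration grid must be strictly increasing, n >= 2")
        if np.any(grid <= 0):
            raise ValueError("concentrations must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        object.__setattr__(self, "concentrations", grid)

    @classmethod
    def for_readout(cls, mode: Mode, readout: str, **overrides) -> "AssayModel":
        """Model preset for one (mode, readout) pair of the emulated study."""
        try:
            params = READOUT_DEFAULTS[(mode, readout)]
        except KeyError:
            raise ValueError(
                f"no defaults for mode={mode!r}, readout={readout!r}; "
                f"known: {sorted(READOUT_DEFAULTS)}"
            ) from None
        base = cls(
            mode=mode,
            baseline=params["baseline"],
            slope_per_decade=params["slope"],
            saturation_onset=params["saturation_onset"],
        )
        return replace(base, **overrides) if overrides else base

    def mean_response(self, conc) -> np.ndarray:
        """Noise-free readout mean at the given concentration(s)."""
        c = np.asarray(conc, dtype=float)
        c_min = self.concentrations[0]
        c_eff = c if self.saturation_onset is None else np.minimum(c, self.saturation_onset)
        y = self.baseline + self.slope_per_decade * np.log10(c_eff / c_min)
        return np.clip(y, *self.bounds)

    def first_plateau_index(self) -> int | None:
        """Index of the first grid concentration on the plateau, or None."""
        if self.saturation_onset is None:
            return None
        above = np.nonzero(self.concentrations > self.saturation_onset)[0]
        return int(above[0]) if above.size else None


def generate_readout_series(
    model: AssayModel, readout: str = "readout", seed=0
) -> tuple[AssaySeries, dict]:
    """Replicated noisy readout series plus its ground-truth record."""
    rng = _as_rng(seed)
    conc = np.repeat(model.concentrations, model.n_replicates)
    reps = np.tile(np.arange(1, model.n_replicates + 1), model.concentrations.size)
    mean = model.mean_response(conc)
    y = mean + rng.normal(0.0, model.noise_sd, size=mean.shape)
    y = np.clip(y, *model.bounds)
    series = AssaySeries(conc, y, reps, readout_name=readout)
    truth = {
        "mode": model.mode,
        "readout": readout,
        "baseline": model.baseline,
        "slope_per_decade": model.slope_per_decade,
        "saturation_onset": model.saturation_onset,
        "first_plateau_index": model.first_plateau_index(),
        "noise_sd": model.noise_sd,
        "n_replicates": model.n_replicates,
    }
    return series, truth


@dataclass(frozen=True)
class TextureModel:
    """Synthetic polarizing-microscope texture of one sensing spot.

    The signal geometry is a centred disk or a coffee-ring annulus (radii
    as fractions of the half-frame).  The signal color is alpha-blended
    over the background with fraction ``f(c) = f_max * logistic(
    steepness * (log10 c_eff - midpoint))`` where ``c_eff = min(c,
    saturation_onset)``, so the blend grows with log-concentration and
    then sits exactly on a plateau.
    """

    size: int = 512
    background_rgb: tuple[int, int, int] = (70, 165, 80)
    signal_rgb: tuple[int, int, int] = (200, 45, 40)
    geometry: Literal["disk", "coffee_ring"] = "coffee_ring"
    radius_frac: float = 0.8
    inner_radius_frac: float = 0.55
    logistic_midpoint_log10: float = -8.0
    logistic_steepness: float = 0.6
    mixing_max: float = 0.95
    saturation_onset: float | None = 1e-5
    noise_sd: float = 4.0
    mode: Mode = "BSA"

    def __post_init__(self):
        if not 0 < self.radius_frac <= 1:
            raise ValueError("radius_frac must lie in (0, 1]")
        if self.geometry == "coffee_ring" and not (
            0 < self.inner_radius_frac < self.radius_frac
        ):
            raise ValueError("coffee ring needs 0 < inner < outer radius fraction")
        for c in (*self.background_rgb, *self.signal_rgb):
            if not 0 <= c <= 255:
                raise ValueError("colors must be 8-bit (0..255)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def for_mode(cls, mode: Mode, **overrides) -> "TextureModel":
        if mode == "CA125_serum":
            # serum interferents red-shift the background to yellow-orange;
            # the antibody spot reverts to green on antigen binding
            base = cls(
                mode=mode,
                background_rgb=(230, 160, 35),
                signal_rgb=(60, 170, 70),
                logistic_midpoint_log10=-7.5,
                saturation_onset=None,
            )
        elif mode == "CA125":
            base = cls(mode=mode, logistic_midpoint_log10=-7.5, saturation_onset=None)
        elif mode == "BSA":
            base = cls(mode=mode)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return replace(base, **overrides) if overrides else base

    def signal_mask(self) -> np.ndarray:
        n = self.size
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(yy - (n - 1) / 2.0, xx - (n - 1) / 2.0) / ((n - 1) / 2.0)
        if self.geometry == "disk":
            return r <= self.radius_frac
        return (r >= self.inner_radius_frac) & (r <= self.radius_frac)

    def mixing_fraction(self, conc: float) -> float:
        c = float(conc)
        if c <= 0:
            raise ValueError("concentration must be positive")
        if self.saturation_onset is not None:
            c = min(c, self.saturation_onset)
        z = self.logistic_steepness * (np.log10(c) - self.logistic_midpoint_log10)
        return float(self.mixing_max / (1.0 + np.exp(-z)))


def generate_texture(
    model: TextureModel, concentration: float, seed=0
) -> tuple[np.ndarray, float]:
    """One synthetic texture image and its true signal mixing fraction."""
    rng = _as_rng(seed)
    f = model.mixing_fraction(concentration)
    bg = np.asarray(model.background_rgb, dtype=float)
    sig = np.asarray(model.signal_rgb, dtype=float)
    img = np.broadcast_to(bg, (model.size, model.size, 3)).copy()
    mask = model.signal_mask()
    img[mask] = (1.0 - f) * bg + f * sig
    if model.noise_sd > 0:
        img = img + rng.normal(0.0, model.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), f


def generate_noisy_spectrum(
    cell: CellModel, noise_sd: float = 0.01, seed=0, grid_nm=None
) -> Spectrum:
    """Forward-model spectrum with multiplicative Gaussian noise.

    ``T_noisy = T * (1 + eps)`` with ``eps ~ N(0, noise_sd^2)`` i.i.d.
    per wavelength, clipped at zero.  ``noise_sd = 0`` reproduces the
    noise-free model exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _as_rng(seed)
    clean = simulate_spectrum(cell, grid_nm)
    if noise_sd == 0:
        return clean
    eps = rng.normal(0.0, noise_sd, size=clean.values.shape)
    values = np.clip(clean.values * (1.0 + eps), 0.0, None)
    return Spectrum(clean.wavelengths_nm, values, kind="absolute")
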