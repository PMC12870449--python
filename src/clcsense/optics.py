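"""Forward optical model of a tilted, vertically aligned CLC cell.

A cholesteric liquid-crystal (CLC) film anchored homeotropically between
crossed polarizers is modelled as a single uniaxial retarder whose optic
axis is the effective helical axis, tilted by an angle ``theta`` from the
substrate normal.  Light propagating along the normal then sees the
effective extraordinary index

    n_eff(theta, lam) = n_o * n_e / sqrt(n_e^2 cos^2(theta) + n_o^2 sin^2(theta))

so the effective birefringence is ``n_eff - n_o``; it vanishes in the
homeotropic state (theta = 0, dark between crossed polarizers) and reaches
the full ``n_e - n_o`` at theta = 90 deg.  The phase retardation of a cell
of gap ``d`` is ``Gamma = 2 pi dn_eff d / lam`` and the crossed-polarizer
transmittance of an ideal retarder at azimuth ``phi`` is

    T = sin^2(2 phi) * sin^2(Gamma / 2).

Biomolecules adsorbed at the alignment layer disturb the anchoring and
increase the collective tilt by a few degrees, which shifts the
interference spectrum and hence the texture color seen under a polarizing
microscope.  ``fit_tilt`` inverts the model: it recovers the tilt angle
that best reproduces a measured (peak-normalized) transmission spectrum.

A full stacked Jones-matrix treatment of the cholesteric helix is a
documented extension point; the single-retarder model is the default
because it reproduces the observed spectral fitting behaviour and the
blue shift of the interference peaks with the fewest free parameters.
Scattering losses are deliberately not modelled here: haze and
transmittance readouts live in :mod:`clcsense.quantitation`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "UniaxialMaterial",
    "CellModel",
    "Spectrum",
    "TiltFitResult",
    "DEFAULT_MATERIAL",
    "default_material",
    "effective_birefringence",
    "retardance",
    "crossed_polarizer_transmittance",
    "simulate_spectrum",
    "normalize_spectrum",
    "principal_peak_nm",
    "fit_tilt",
    "FIT_GRID_NM",
]

#: wavelength grid used for spectral fitting (nm); matches a typical
#: visible-range transmission measurement window.
FIT_GRID_NM = np.arange(400.0, 701.0, 1.0)


@dataclass(frozen=True)
class UniaxialMaterial:
    """Dispersive positive uniaxial material with Cauchy-law indices.

    ``n(lam) = A + B/lam_um^2 + C/lam_um^4`` with lam in micrometres.
    """

    name: str
    n_o_cauchy: tuple[float, float, float]
    n_e_cauchy: tuple[float, float, float]
    #: wavelength validity range of the dispersion law, nm
    valid_range_nm: tuple[float, float] = (380.0, 780.0)

    def n_o(self, lambda_nm):
        return self._cauchy(self.n_o_cauchy, lambda_nm)

    def n_e(self, lambda_nm):
        return self._cauchy(self.n_e_cauchy, lambda_nm)

    def birefringence(self, lambda_nm):
        """Full birefringence n_e - n_o at the given wavelength(s)."""
        return self.n_e(lambda_nm) - self.n_o(lambda_nm)

    def _cauchy(self, coeffs, lambda_nm):
        self._check_lambda(lambda_nm)
        a, b, c = coeffs
        lam_um = np.asarray(lambda_nm, dtype=float) / 1000.0
        return a + b / lam_um**2 + c / lam_um**4

    def _check_lambda(self, lambda_nm):
        lam = np.asarray(lambda_nm, dtype=float)
        lo, hi = self.valid_range_nm
        if np.any(lam < lo) or np.any(lam > hi):
            raise ValueError(
                f"lambda_nm outside the material's dispersion range "
                f"[{lo}, {hi}] nm"
            )


def default_material() -> UniaxialMaterial:
    """An 8CB-like material: n_o ~ 1.52 and n_e ~ 1.67 at 589 nm.

    The Cauchy coefficients are configuration defaults representative of
    the cyanobiphenyl host, not fitted constants; supply your own
    :class:`UniaxialMaterial` for quantitative work on other mixtures.
    """
    return UniaxialMaterial(
        name="8CB-like",
        n_o_cauchy=(1.498, 0.0078, 0.0004),
        n_e_cauchy=(1.618, 0.0160, 0.0008),
    )


DEFAULT_MATERIAL = default_material()


@dataclass(frozen=True)
class CellModel:
    """Geometry and material of a single CLC cell.

    ``tilt_deg`` is the angle between the effective helical (optic) axis
    and the substrate normal; ``azimuth_deg`` the angle between the optic
    axis projection and the polarizer axis (45 deg gives maximal
    crossed-polarizer contrast).
    """

    gap_um: float
    tilt_deg: float
    azimuth_deg: float = 45.0
    material: UniaxialMaterial = field(default_factory=default_material)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.gap_um > 0:
            raise ValueError(f"gap_um must be positive, got {self.gap_um}")
        if not 0.0 <= self.tilt_deg <= 90.0:
            raise ValueError(f"tilt_deg must lie in [0, 90], got {self.tilt_deg}")
        if not 0.0 <= self.azimuth_deg <= 90.0:
            raise ValueError(
                f"azimuth_deg must lie in [0, 90], got {self.azimuth_deg}"
            )


@dataclass(frozen=True)
class Spectrum:
    """A sampled transmission spectrum on a strictly ascending grid."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "absolute"  # "absolute" in [0, 1], or "normalized" (max 1)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        tv = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.shape != tv.shape:
            raise ValueError("wavelengths_nm and values must be 1-D and equal length")
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly ascending (n >= 2)")
        if np.any(tv < 0) or not np.all(np.isfinite(tv)):
            raise ValueError("transmittance values must be finite and >= 0")
        if self.kind not in ("absolute", "normalized"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "normalized" and abs(tv.max() - 1.0) > 1e-9:
            raise ValueError("normalized spectrum must have max(values) == 1")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", tv)


@dataclass(frozen=True)
class TiltFitResult:
    tilt_deg: float
    residual: float
    converged: bool
    bounds: tuple[float, float]


def effective_birefringence(material: UniaxialMaterial, tilt_deg, lambda_nm):
    """Effective birefringence seen along the substrate normal.

    Vectorized over ``lambda_nm`` and ``tilt_deg`` (broadcast together).
    Monotonically increasing in tilt: 0 at 0 deg, n_e - n_o at 90 deg.
    """
    tilt = np.asarray(tilt_deg, dtype=float)
    if np.any(tilt < 0) or np.any(tilt > 90):
        raise ValueError(f"tilt_deg must lie in [0, 90], got {tilt_deg}")
    n_o = material.n_o(lambda_nm)
    n_e = material.n_e(lambda_nm)
    theta = np.deg2rad(tilt)
    n_eff = n_o * n_e / np.sqrt(
        n_e**2 * np.cos(theta) ** 2 + n_o**2 * np.sin(theta) ** 2
    )
    # enforce the exact endpoint identities, which round-off otherwise
    # misses at the 1e-16 level
    result = np.maximum(n_eff - n_o, 0.0)
    result = np.where(tilt == 0.0, 0.0, result)
    result = np.where(tilt == 90.0, n_e - n_o, result)
    if np.ndim(result) == 0:
        return float(result)
    return result


def retardance(delta_n, gap_um, lambda_nm):
    """Phase retardation Gamma = 2 pi dn d / lam, in radians."""
    dn = np.asarray(delta_n, dtype=float)
    if np.any(dn < 0):
        raise ValueError(f"delta_n must be >= 0, got {delta_n}")
    if not np.all(np.asarray(gap_um) > 0):
        raise ValueError(f"gap_um must be positive, got {gap_um}")
    if not np.all(np.asarray(lambda_nm) > 0):
        raise ValueError(f"lambda_nm must be positive, got {lambda_nm}")
    return 2.0 * np.pi * dn * (np.asarray(gap_um) * 1000.0) / np.asarray(lambda_nm)


def crossed_polarizer_transmittance(retardance_rad, azimuth_deg=45.0):
    """Ideal-retarder transmittance between crossed polarizers."""
    gamma = np.asarray(retardance_rad, dtype=float)
    if np.any(gamma < 0):
        raise ValueError(f"retardance_rad must be >= 0, got {retardance_rad}")
    phi = np.deg2rad(azimuth_deg)
    return np.sin(2.0 * phi) ** 2 * np.sin(gamma / 2.0) ** 2


def simulate_spectrum(cell: CellModel, grid_nm: Sequence[float] | None = None) -> Spectrum:
    """Crossed-polarizer transmission spectrum of a tilted CLC cell."""
    grid = FIT_GRID_NM if grid_nm is None else np.asarray(grid_nm, dtype=float)
    dn = effective_birefringence(cell.material, cell.tilt_deg, grid)
    gamma = retardance(dn, cell.gap_um, grid)
    values = crossed_polarizer_transmittance(gamma, cell.azimuth_deg)
    return Spectrum(grid, values, kind="absolute")


def normalize_spectrum(s: Spectrum) -> Spectrum:
    """Rescale a spectrum to unit maximum (peak normalization)."""
    peak = s.values.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    v = s.values / peak
    # guard against round-off pushing max() off exact unity
    v[np.argmax(v)] = 1.0
    return Spectrum(s.wavelengths_nm, v, kind="normalized")


def principal_peak_nm(s: Spectrum) -> float:
    """Wavelength of the principal (lowest-order) transmission maximum.

    For an ideal retarder every interference order peaks at exactly 1, so
    the raw grid argmax is decided by sampling noise at the 1e-4 level.
    The principal maximum is therefore defined as the longest-wavelength
    interior local maximum — the lowest interference order inside the
    window — refined by a local quadratic fit.  If the spectrum has no
    interior local maximum the grid argmax (possibly an endpoint) is
    returned.
    """
    wl, tv = s.wavelengths_nm, s.values
    interior = np.nonzero((tv[1:-1] > tv[:-2]) & (tv[1:-1] >= tv[2:]))[0] + 1
    if interior.size == 0:
        return float(wl[int(np.argmax(tv))])
    i = int(interior[-1])
    x0, x1, x2 = wl[i - 1 : i + 2]
    y0, y1, y2 = tv[i - 1 : i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # degenerate curvature: keep the grid point
        return float(x1)
    vertex = -b / (2.0 * a)
    return float(np.clip(vertex, x0, x2))


def _normalized_residual(observed_norm: np.ndarray, cell: CellModel, grid: np.ndarray) -> float:
    sim = simulate_spectrum(cell, grid)
    peak = sim.values.max()
    if peak <= 0:
        # homeotropic candidate against a non-zero observation
        return float(np.sum(observed_norm**2))
    return float(np.sum((sim.values / peak - observed_norm) ** 2))


def fit_tilt(
    observed: Spectrum,
    cell_template: CellModel,
    bounds: tuple[float, float] = (20.0, 70.0),
    grid_step_deg: float = 0.25,
) -> TiltFitResult:
    """Fit the effective tilt angle to an observed transmission spectrum.

    Minimizes the sum of squared differences between the peak-normalized
    simulated and observed spectra over tilt.  A deterministic coarse grid
    (``grid_step_deg`` steps over ``bounds``) is followed by a bounded
    local refinement inside the bracketing grid interval; ties on the grid
    break toward the smaller tilt.  ``converged`` is False when the
    minimum sits on a bound (e.g. the true tilt lies outside ``bounds``).
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    if not (0.0 <= lo < hi <= 90.0):
        raise ValueError(f"bounds must satisfy 0 <= lo < hi <= 90, got {bounds}")
    span = observed.wavelengths_nm[-1] - observed.wavelengths_nm[0]
    if span < 200.0:
        warnings.warn(
            f"observed spectrum covers only {span:.0f} nm; tilt fits on "
            "narrow windows may be ambiguous",
            stacklevel=2,
        )
    if observed.values.max() <= 0:
        raise ValueError("observed spectrum is identically zero")

    grid = observed.wavelengths_nm
    obs_norm = normalize_spectrum(observed).values

    def residual(tilt: float) -> float:
        cell = CellModel(
            gap_um=cell_template.gap_um,
            tilt_deg=float(tilt),
            azimuth_deg=cell_template.azimuth_deg,
            material=cell_template.material,
            metadata=cell_template.metadata,
        )
        return _normalized_residual(obs_norm, cell, grid)

    candidates = np.arange(lo, hi + 0.5 * grid_step_deg, grid_step_deg)
    candidates = candidates[candidates <= hi]
    if candidates[-1] < hi:
        candidates = np.append(candidates, hi)
    res = np.array([residual(t) for t in candidates])
    best = int(np.argmin(res))  # argmin takes the first minimum: smaller tilt

    b_lo = candidates[max(best - 1, 0)]
    b_hi = candidates[min(best + 1, len(candidates) - 1)]
    tilt_best, r_best = float(candidates[best]), float(res[best])
    if b_hi > b_lo:
        opt = minimize_scalar(
            residual, bounds=(b_lo, b_hi), method="bounded",
            options={"xatol": 1e-4},
        )
        if opt.fun <= r_best:
            tilt_best, r_best = float(opt.x), float(opt.fun)
    on_bound = (tilt_best - lo) < 2 * grid_step_deg * 1e-3 or (hi - tilt_best) < 2 * grid_step_deg * 1e-3
    # snap to the bound when the refinement's tolerance left us next to it
    if tilt_best - lo < 1e-3 and residual(lo) <= r_best + 1e-15:
        tilt_best, r_best, on_bound = lo, float(residual(lo)), True
    if hi - tilt_best < 1e-3 and residual(hi) <= r_best + 1e-15:
        tilt_best, r_best, on_bound = hi, float(residual(hi)), True
    return TiltFitResult(
        tilt_deg=tilt_best,
        residual=r_best,
        converged=not on_bound,
        bounds=(lo, hi),
    )
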