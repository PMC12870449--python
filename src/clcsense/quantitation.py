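"""Assay readout statistics and calibration for CLC biosensor data.

Four readout channels are supported, mirroring the multi-modal sensor:

* **RGB texture statistic** — the percent contribution of one color
  channel to the summed intensity over a region of interest of a
  polarizing-microscope image, ``100 * C / (R + G + B)``.  The red channel
  tracks analyte binding in buffer; in serum the background shifts toward
  yellow-orange and the green channel is analyzed instead.
* **Haze** — ``100 * I_d / I_t``, the percentage of transmitted light
  scattered by more than 2.5 degrees, from an integrating-sphere haze
  meter.
* **Transmittance differences** — ``delta_T = 100 * (T(0) - T(c)) / T(0)``
  turning the negative transmittance-vs-concentration correlation into a
  positive readout.

Calibration fits ordinary least squares to per-concentration means
(semi-log over the full linear range; linear concentration over the
low-concentration region for detection limits) and derives
``LOD = 3 s / |m|`` and ``LOQ = 10 s / |m|`` with ``s`` the standard
error of the regression intercept and ``m`` the slope.  Readouts that
saturate at high load are truncated first by ``detect_linear_range``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ChannelStat",
    "CalibrationResult",
    "AssaySeries",
    "default_roi",
    "channel_relative_intensity",
    "green_relative_intensity",
    "haze_percent",
    "delta_T",
    "fit_calibration",
    "detect_linear_range",
    "quantify_image_series",
    "calibrate_assay",
]

_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


@dataclass(frozen=True)
class ChannelStat:
    """Relative intensity of one RGB channel over a region of interest."""

    channel: str
    relative_intensity_pct: float
    sum_r: float
    sum_g: float
    sum_b: float


@dataclass(frozen=True)
class CalibrationResult:
    """OLS calibration line with detection limits.

    ``intercept_sd`` is the standard error of the intercept from the OLS
    closed form; LOD and LOQ are ``3 s / |m|`` and ``10 s / |m|`` in the
    units of the (possibly transformed) concentration axis.
    """

    slope: float
    intercept: float
    intercept_sd: float
    r_squared: float
    transform: str  # "log10_concentration" | "linear_concentration"
    conc_range: tuple[float, float]
    lod: float
    loq: float
    n_points: int


@dataclass
class AssaySeries:
    """Replicated readout measurements across a concentration ladder."""

    concentrations: np.ndarray  # one entry per measurement, g/mL
    readouts: np.ndarray
    replicates: np.ndarray
    readout_name: str = "readout"

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        y = np.asarray(self.readouts, dtype=float)
        r = np.asarray(self.replicates)
        if not (c.shape == y.shape == r.shape) or c.ndim != 1:
            raise ValueError("concentrations, readouts, replicates must be equal-length 1-D")
        if c.size == 0:
            raise ValueError("an assay series cannot be empty")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive (g/mL)")
        self.concentrations, self.readouts, self.replicates = c, y, r

    @classmethod
    def from_frame(cls, df: pd.DataFrame, readout_name: str = "readout") -> "AssaySeries":
        return cls(
            df["concentration_g_per_ml"].to_numpy(float),
            df["readout"].to_numpy(float),
            df["replicate"].to_numpy(),
            readout_name=readout_name,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration_g_per_ml": self.concentrations,
                "readout": self.readouts,
                "replicate": self.replicates,
            }
        )

    def grouped(self) -> pd.DataFrame:
        """Per-concentration mean, SD and replicate count, sorted by c."""
        g = (
            self.to_frame()
            .groupby("concentration_g_per_ml")["readout"]
            .agg(["mean", "std", "count"])
            .reset_index()
            .sort_values("concentration_g_per_ml")
        )
        g["std"] = g["std"].fillna(0.0)
        return g


def default_roi(shape: tuple[int, ...], border_frac: float = 0.05):
    """Full frame minus a fractional border, as (r0, r1, c0, c1) half-open."""
    h, w = shape[0], shape[1]
    dr, dc = int(round(border_frac * h)), int(round(border_frac * w))
    return (dr, h - dr, dc, w - dc)


def _roi_pixels(img: np.ndarray, roi) -> np.ndarray:
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (h, w, 3)")
    if roi is None:
        roi = default_roi(img.shape)
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != img.shape[:2]:
            raise ValueError("boolean ROI mask must match the image extent")
        px = img[roi]
    else:
        r0, r1, c0, c1 = roi
        h, w = img.shape[:2]
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"ROI {roi} outside the image extent {h}x{w}")
        px = img[r0:r1, c0:c1].reshape(-1, 3)
    if px.size == 0:
        raise ValueError("ROI selects no pixels")
    return px.astype(np.float64)


def channel_relative_intensity(img, roi=None, channel: str = "R") -> ChannelStat:
    """Percent contribution of one channel to the total ROI intensity."""
    if channel not in _CHANNEL_INDEX:
        raise ValueError(f"channel must be one of R, G, B, got {channel!r}")
    px = _roi_pixels(np.asarray(img), roi)
    sums = px.sum(axis=0)
    total = sums.sum()
    if total <= 0:
        raise ValueError("ROI is entirely black; relative intensity undefined")
    rel = 100.0 * sums[_CHANNEL_INDEX[channel]] / total
    return ChannelStat(channel, float(rel), *(float(s) for s in sums))


def green_relative_intensity(img, roi=None) -> ChannelStat:
    """Green-channel variant used for serum-matrix assays."""
    return channel_relative_intensity(img, roi, channel="G")


def haze_percent(i_diffuse: float, i_total: float) -> float:
    """Haze = 100 * I_d / I_t (diffuse over total transmitted light)."""
    if i_total <= 0:
        raise ValueError("total transmitted intensity must be positive")
    if i_diffuse < 0 or i_diffuse > i_total:
        raise ValueError(
            f"diffuse intensity {i_diffuse} must lie in [0, I_t={i_total}]"
        )
    return 100.0 * i_diffuse / i_total


def delta_T(t_zero: float, t_conc: float) -> float:
    """Relative transmittance drop 100 * (T(0) - T(c)) / T(0), percent."""
    if t_zero <= 0:
        raise ValueError("reference transmittance T(0) must be positive")
    if t_conc < 0:
        raise ValueError("transmittance T(c) must be >= 0")
    return 100.0 * (t_zero - t_conc) / t_zero


def fit_calibration(
    series: AssaySeries,
    transform: str = "log10_concentration",
    conc_range: tuple[float, float] | None = None,
) -> CalibrationResult:
    """OLS calibration of per-concentration means on a concentration axis.

    ``transform`` selects the x axis: ``log10_concentration`` for the
    semi-log calibration over the working range, ``linear_concentration``
    for the low-concentration fit from which LOD/LOQ are conventionally
    derived.  ``conc_range`` restricts the fit (inclusive); points outside
    are excluded, matching plateau truncation done by the caller.
    """
    if transform not in ("log10_concentration", "linear_concentration"):
        raise ValueError(f"unknown transform {transform!r}")
    g = series.grouped()
    if conc_range is not None:
        lo, hi = conc_range
        g = g[(g.concentration_g_per_ml >= lo) & (g.concentration_g_per_ml <= hi)]
    if len(g) < 3:
        raise ValueError("calibration needs at least 3 usable concentrations")
    c = g.concentration_g_per_ml.to_numpy(float)
    y = g["mean"].to_numpy(float)
    x = np.log10(c) if transform == "log10_concentration" else c
    if np.ptp(x) <= 0:
        raise ValueError("concentration axis has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    s = float(model.bse[0])
    if not np.isfinite(s):  # pragma: no cover - perfect fit on 2 dof edge
        s = 0.0
    r2 = float(model.rsquared)
    lod = 3.0 * s / abs(slope)
    loq = 10.0 * s / abs(slope)
    return CalibrationResult(
        slope=float(slope),
        intercept=float(intercept),
        intercept_sd=s,
        r_squared=r2,
        transform=transform,
        conc_range=(float(c.min()), float(c.max())),
        lod=float(lod),
        loq=float(loq),
        n_points=len(g),
    )


def detect_linear_range(series: AssaySeries, k: float = 1.0):
    """Maximal low-concentration prefix before the readout plateaus.

    The plateau onset is the first concentration whose mean increase over
    the previous one falls below ``k`` times the pooled replicate SD
    (exactly zero tolerance when the series is noise-free).  Returns
    ``(conc_lo, conc_hi), plateau_start_index`` where the index is into
    the sorted unique concentrations (``None`` when no plateau is found).
    A monotonicity violation beyond noise raises a warning, not an error.
    """
    g = series.grouped()
    if len(g) < 4:
        raise ValueError("plateau detection needs at least 4 concentrations")
    means = g["mean"].to_numpy(float)
    sds = g["std"].to_numpy(float)
    counts = g["count"].to_numpy(float)
    dof = np.maximum(counts - 1, 0)
    pooled_sd = float(np.sqrt(np.sum(dof * sds**2) / np.sum(dof))) if dof.sum() > 0 else 0.0
    direction = np.sign(means[-1] - means[0]) or 1.0
    diffs = direction * np.diff(means)

    threshold = k * pooled_sd
    onset = None
    for i, d in enumerate(diffs, start=1):
        if d <= threshold + 1e-12:
            onset = i
            break
    if np.any(diffs < -(3.0 * pooled_sd + 1e-12)):
        warnings.warn(
            "readout decreases against the series trend by more than 3x the "
            "pooled replicate SD; check the data",
            stacklevel=2,
        )
    conc = g.concentration_g_per_ml.to_numpy(float)
    if onset is None:
        return (float(conc[0]), float(conc[-1])), None
    if onset < 2:
        warnings.warn("no usable linear range before the plateau", stacklevel=2)
        return None, onset
    return (float(conc[0]), float(conc[onset - 1])), onset


def quantify_image_series(
    images: Sequence[np.ndarray],
    concentrations: Sequence[float],
    channel: str = "R",
    roi=None,
    replicates: Sequence | None = None,
) -> AssaySeries:
    """Map the channel statistic over a texture image stack.

    Images sharing a concentration are treated as replicates; explicit
    replicate ids may be supplied, otherwise they are numbered in order
    of appearance within each concentration.
    """
    if len(images) != len(concentrations):
        raise ValueError("images and concentrations must have equal length")
    if replicates is not None and len(replicates) != len(images):
        raise ValueError("replicates must match images in length")
    stats = [
        channel_relative_intensity(img, roi=roi, channel=channel) for img in images
    ]
    conc = np.asarray(concentrations, dtype=float)
    if replicates is None:
        seen: dict[float, int] = {}
        replicates = []
        for c in conc:
            seen[c] = seen.get(c, 0) + 1
            replicates.append(seen[c])
    return AssaySeries(
        conc,
        np.array([st.relative_intensity_pct for st in stats]),
        np.asarray(replicates),
        readout_name=f"{channel}_relative_intensity_pct",
    )


def calibrate_assay(
    series: AssaySeries,
    n_low: int = 4,
    plateau_k: float = 1.0,
):
    """Full calibration workflow for one readout channel.

    Excludes the saturated plateau, fits the semi-log calibration over
    the remaining range, and fits the ``n_low`` lowest concentrations on
    a linear axis for LOD/LOQ.  Returns a dict with the linear range, the
    two :class:`CalibrationResult` objects and any excluded plateau
    concentrations (reported, never silently dropped).
    """
    rng, onset = detect_linear_range(series, k=plateau_k)
    conc_sorted = np.sort(np.unique(series.concentrations))
    excluded = conc_sorted[onset:].tolist() if onset is not None else []
    if rng is None:
        raise ValueError("no linear range before the plateau; cannot calibrate")
    semilog = fit_calibration(series, "log10_concentration", conc_range=rng)
    in_range = conc_sorted[(conc_sorted >= rng[0]) & (conc_sorted <= rng[1])]
    low = in_range[: max(n_low, 3)]
    lowfit = fit_calibration(
        series, "linear_concentration", conc_range=(low[0], low[-1])
    )
    return {
        "linear_range": rng,
        "plateau_start_index": onset,
        "excluded_concentrations": excluded,
        "semilog_fit": semilog,
        "low_range_fit": lowfit,
        "lod": lowfit.lod,
        "loq": lowfit.loq,
    }
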