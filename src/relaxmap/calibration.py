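"""Relaxivity calibration, limit of detection, iron quantification and
NMRD profile utilities.

The calibration regresses (background-corrected) relaxation rates on iron
concentration by ordinary least squares; the slope is the relaxivity in
mM^-1 s^-1. The limit of detection uses the standard 3-sigma criterion,
LOD = 3 sigma_blank / slope, where sigma_blank is the standard deviation
of the zero-concentration (blank) rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GAMMA_MHZ_PER_T",
    "R_DIA_DEFAULT",
    "R1P_DEFAULT",
    "ConcentrationSeries",
    "CalibrationFit",
    "NMRDPoint",
    "fit_calibration",
    "calibrate_phantom_volume",
    "limit_of_detection",
    "iron_from_r1",
    "assemble_nmrd",
    "classify_field_regime",
    "classify_contrast_agent",
]

#: proton gyromagnetic ratio / 2 pi, MHz per tesla
GAMMA_MHZ_PER_T = 42.577

#: diamagnetic rate of the nitric-acid matrix of mineralized iron standards, s^-1
R_DIA_DEFAULT = 0.52
#: concentration-normalized relaxation rate of mineralized iron, mM^-1 s^-1
R1P_DEFAULT = 1.29


@dataclass
class ConcentrationSeries:
    """Relaxation rates of a dilution series versus iron concentration.

    ``rates`` are (corrected) rates in s^-1, ``fe_mM`` the matching iron
    concentrations in mM. ``rate_sds`` are optional per-level replicate
    standard deviations; the SD at the zero-concentration level feeds the
    limit-of-detection estimate.
    """

    fe_mM: np.ndarray
    rates: np.ndarray
    labels: Sequence[str] | None = None
    rate_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fe_mM = np.asarray(self.fe_mM, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.fe_mM.shape != self.rates.shape or self.fe_mM.ndim != 1:
            raise ValueError("fe_mM and rates must be 1-D and equal length")
        if np.any(self.fe_mM < 0):
            raise ValueError("concentrations must be >= 0")
        if self.rate_sds is not None:
            self.rate_sds = np.asarray(self.rate_sds, dtype=float)
            if self.rate_sds.shape != self.fe_mM.shape:
                raise ValueError("rate_sds must match fe_mM length")

    @property
    def has_blank(self) -> bool:
        return bool(np.any(self.fe_mM == 0))

    def blank_sd(self) -> float | None:
        """SD of blank-level rates: replicate SD if supplied, else the
        spread of repeated zero-concentration entries."""
        zero = self.fe_mM == 0
        if not np.any(zero):
            return None
        if self.rate_sds is not None:
            return float(np.mean(self.rate_sds[zero]))
        if zero.sum() >= 2:
            return float(np.std(self.rates[zero], ddof=1))
        return None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"fe_mM": self.fe_mM, "rate_s": self.rates})
        if self.labels is not None:
            df.insert(0, "label", list(self.labels))
        if self.rate_sds is not None:
            df["rate_sd_s"] = self.rate_sds
        return df


@dataclass(frozen=True)
class CalibrationFit:
    """OLS calibration line rate = slope * [Fe] + intercept.

    slope: relaxivity, mM^-1 s^-1; intercept and sigma_blank: s^-1;
    lod_mM = 3 sigma_blank / slope (NaN when undefined).
    """

    slope: float
    intercept: float
    r_squared: float
    sigma_blank: float | None = None
    lod_mM: float = float("nan")
    stderr_slope: float = float("nan")
    stderr_intercept: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "slope_mM-1s-1": self.slope,
            "intercept_s-1": self.intercept,
            "r_squared": self.r_squared,
            "sigma_blank_s-1": self.sigma_blank,
            "lod_mM": self.lod_mM,
            "stderr_slope": self.stderr_slope,
            "stderr_intercept": self.stderr_intercept,
        }


@dataclass(frozen=True)
class NMRDPoint:
    """One relaxivity-dispersion point: field (T), frequency (MHz),
    relaxivity (mM^-1 s^-1) on the r1 or r2 channel."""

    field: float
    frequency: float
    relaxivity: float
    channel: str = "r1"

    def __post_init__(self) -> None:
        if self.channel not in ("r1", "r2"):
            raise ValueError("channel must be 'r1' or 'r2'")
        if self.field > 0 and self.frequency > 0:
            expected = GAMMA_MHZ_PER_T * self.field
            if abs(self.frequency - expected) > 0.01 * expected:
                raise ValueError(
                    f"frequency {self.frequency} MHz inconsistent with field "
                    f"{self.field} T (expected {expected:.4g} MHz)"
                )


def fit_calibration(
    series: ConcentrationSeries, sigma_blank: float | None = None
) -> CalibrationFit:
    """OLS of rate on concentration; slope is the relaxivity.

    ``sigma_blank`` overrides the blank SD derived from the series. The
    LOD is computed when both a positive slope and a blank SD are
    available, and is NaN otherwise (a zero slope makes it undefined).
    """
    if np.unique(series.fe_mM).size < 3:
        raise ValueError("calibration requires >= 3 distinct concentrations")
    if np.ptp(series.fe_mM) == 0:
        raise ValueError("zero concentration variance")
    reg = stats.linregress(series.fe_mM, series.rates)
    slope, intercept = float(reg.slope), float(reg.intercept)
    if sigma_blank is None:
        sigma_blank = series.blank_sd()
    lod = float("nan")
    if sigma_blank is not None and slope > 0:
        lod = limit_of_detection(slope, sigma_blank)
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        r_squared=float(reg.rvalue**2),
        sigma_blank=sigma_blank,
        lod_mM=lod,
        stderr_slope=float(reg.stderr),
        stderr_intercept=float(reg.intercept_stderr),
    )


def limit_of_detection(slope: float, sigma_blank: float) -> float:
    """3-sigma limit of detection: LOD = 3 sigma_blank / slope, in mM."""
    if slope <= 0:
        raise ValueError("LOD requires a positive calibration slope")
    if sigma_blank < 0:
        raise ValueError("sigma_blank must be >= 0")
    return 3.0 * sigma_blank / slope


def iron_from_r1(
    r1_measured: float,
    r_dia: float = R_DIA_DEFAULT,
    r1p: float = R1P_DEFAULT,
) -> float:
    """Iron concentration (mM) from R1 = R_dia + [Fe] * r1p.

    Rates below the diamagnetic baseline give negative concentrations,
    which are returned unclamped with a warning (honest blank scatter).
    """
    if r1p == 0:
        raise ValueError("r1p must be nonzero")
    if not np.isfinite(r1_measured):
        raise ValueError("r1_measured must be finite")
    fe = (r1_measured - r_dia) / r1p
    if fe < 0:
        warnings.warn(
            f"measured R1 {r1_measured} below diamagnetic baseline {r_dia}; "
            f"negative concentration {fe:.4g} mM returned unclamped",
            stacklevel=2,
        )
    return float(fe)


def assemble_nmrd(
    points: Sequence[NMRDPoint | tuple | dict],
) -> pd.DataFrame:
    """Assemble an ordered NMRD profile from loose points.

    Each point supplies a field (T) or frequency (MHz) or both plus a
    relaxivity; the missing axis is filled via frequency = 42.577 * field.
    The output frame is sorted by field with duplicate (channel, field)
    entries averaged. Columns: field_T, freq_MHz, relaxivity, channel.
    """
    if len(points) == 0:
        raise ValueError("at least one point required")
    rows = []
    for p in points:
        if isinstance(p, NMRDPoint):
            field, freq, relax, channel = p.field, p.frequency, p.relaxivity, p.channel
        elif isinstance(p, dict):
            field = p.get("field_T", p.get("field"))
            freq = p.get("freq_MHz", p.get("frequency"))
            relax = p.get("relaxivity")
            channel = p.get("channel", "r1")
        else:
            field, freq, relax = (list(p) + [None])[:3] if len(p) == 2 else p[:3]
            if len(p) == 2:
                field, relax = p
                freq = None
            channel = p[3] if len(p) > 3 else "r1"
        if (field is None or not np.isfinite(field) or field <= 0) and (
            freq is None or not np.isfinite(freq) or freq <= 0
        ):
            raise ValueError("each point needs a positive field or frequency")
        if field is None or not np.isfinite(field) or field <= 0:
            field = freq / GAMMA_MHZ_PER_T
        if freq is None or not np.isfinite(freq) or freq <= 0:
            freq = GAMMA_MHZ_PER_T * field
        rows.append(
            {"field_T": float(field), "freq_MHz": float(freq),
             "relaxivity": float(relax), "channel": channel}
        )
    df = pd.DataFrame(rows)
    df = (
        df.groupby(["channel", "field_T"], as_index=False)
        .agg({"freq_MHz": "mean", "relaxivity": "mean"})
        .sort_values("field_T", kind="mergesort")
        .reset_index(drop=True)
    )
    return df[["field_T", "freq_MHz", "relaxivity", "channel"]]


def calibrate_phantom_volume(
    volume: np.ndarray,
    schedule,
    tube_masks: dict[str, np.ndarray],
    fe_mM: dict[str, float],
    background_mask: np.ndarray | None = None,
    sigma_blank: float | None = None,
) -> tuple[pd.DataFrame, CalibrationFit]:
    """Per-tube T2 fits on a 4-D phantom volume, then OLS calibration.

    Each tube's mean decay curve is fitted mono-exponentially and converted
    to a rate R2 = 1000/T2 (s^-1). The calibration line is the OLS of the
    *measured* tube rates on concentration, so its intercept is the shared
    background (agarose/water) rate and its slope the relaxivity; the
    returned table also lists background-corrected rates
    (measured minus the agarose-region rate), which shift the intercept
    but leave the slope unchanged.
    """
    from relaxmap.voxel_fitting import DecayCurve, fit_mono, subtract_background

    def region_rate(mask: np.ndarray) -> float:
        curve = DecayCurve(schedule, volume[mask].mean(axis=0))
        fit = fit_mono(curve)
        if not fit.converged or fit.params is None:
            raise RuntimeError("tube-level mono fit did not converge")
        return 1000.0 / fit.params.T

    r2_background = (
        region_rate(np.asarray(background_mask, bool))
        if background_mask is not None
        else None
    )
    rows = []
    for label, mask in tube_masks.items():
        r2 = region_rate(np.asarray(mask, bool))
        rows.append(
            {
                "label": label,
                "fe_mM": float(fe_mM[label]),
                "r2_measured_s": r2,
                "r2_corrected_s": (
                    subtract_background(r2, r2_background)
                    if r2_background is not None
                    else np.nan
                ),
            }
        )
    table = pd.DataFrame(rows).sort_values("fe_mM").reset_index(drop=True)
    series = ConcentrationSeries(
        fe_mM=table.fe_mM.to_numpy(),
        rates=table.r2_measured_s.to_numpy(),
        labels=list(table.label),
    )
    fit = fit_calibration(series, sigma_blank=sigma_blank)
    return table, fit


def classify_field_regime(field: float) -> str:
    """Field-strength regime: ULF (<0.1 T), IF (0.5-1.5 T), HF (>3 T),
    otherwise 'other' (gaps between the named bands)."""
    if field <= 0:
        raise ValueError("field must be > 0")
    if field < 0.1:
        return "ULF"
    if 0.5 <= field <= 1.5:
        return "IF"
    if field > 3.0:
        return "HF"
    return "other"


def classify_contrast_agent(r1: float, r2: float) -> tuple[str, float]:
    """Classify an agent from its r2/r1 ratio.

    ratio < 5 -> 'T1-dominant'; ratio > 10 -> 'T2-dominant'; otherwise
    'intermediate' (possible dual-mode behaviour). Returns (class, ratio).
    """
    if r1 <= 0:
        raise ValueError("r1 must be > 0")
    ratio = r2 / r1
    if ratio < 5:
        label = "T1-dominant"
    elif ratio > 10:
        label = "T2-dominant"
    else:
        label = "intermediate"
    return label, float(ratio)
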