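"""ROI time-course contrast metrics and organ-iron normalization.

Contrast enhancement is the relative signal change versus the
pre-injection baseline, 100 * (post - pre) / pre; negative values mean
hypointense (T2-type) enhancement. Both the signed value and its
magnitude are reported; signed is canonical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROITimeSeries",
    "OrganIron",
    "enhancement",
    "roi_timeseries",
    "organ_iron_normalize",
]


def enhancement(pre_mean: float, post_mean: float) -> float:
    """Percent signal change 100 * (post - pre) / pre."""
    if pre_mean == 0:
        raise ValueError("pre-injection mean must be nonzero")
    return 100.0 * (post_mean - pre_mean) / pre_mean


@dataclass
class ROITimeSeries:
    """Mean ROI signal over time with enhancement versus baseline.

    ``times`` holds the time labels (the first entry is the pre-injection
    baseline), ``mean_signal`` the per-time ROI means, and
    ``enhancement_percent`` the signed percent change versus baseline
    (0 at the baseline itself by construction).
    """

    roi_label: str
    times: Sequence
    mean_signal: np.ndarray
    enhancement_percent: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi": self.roi_label,
                "time": list(self.times),
                "mean_signal": self.mean_signal,
                "enhancement_percent": self.enhancement_percent,
                "enhancement_abs_percent": np.abs(self.enhancement_percent),
            }
        )


def roi_timeseries(
    volumes: Sequence[np.ndarray],
    roi: np.ndarray,
    times: Sequence,
    roi_label: str = "roi",
) -> ROITimeSeries:
    """Mean ROI signal per time point and enhancement versus the first
    (pre-injection) volume.

    ``roi`` is a boolean mask matching the 3-D volume shape.
    """
    if len(volumes) != len(times):
        raise ValueError("one volume per time point required")
    if len(volumes) == 0:
        raise ValueError("at least one (pre) volume required")
    roi = np.asarray(roi, bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    shape = np.asarray(volumes[0]).shape
    if roi.shape != shape:
        raise ValueError(f"ROI shape {roi.shape} != volume shape {shape}")

    means = []
    for v in volumes:
        v = np.asarray(v, dtype=float)
        if v.shape != shape:
            raise ValueError("all volumes must share one shape")
        means.append(float(v[roi].mean()))
    means = np.asarray(means)
    pre = means[0]
    enh = np.array([enhancement(pre, m) for m in means])
    return ROITimeSeries(
        roi_label=roi_label,
        times=list(times),
        mean_signal=means,
        enhancement_percent=enh,
    )


@dataclass(frozen=True)
class OrganIron:
    """Blank-corrected iron content of one organ."""

    organ: str
    fe_mass_ug: float
    tissue_mass_g: float
    blank_fe_per_g: float

    @property
    def fe_per_g(self) -> float:
        return self.fe_mass_ug / self.tissue_mass_g

    @property
    def corrected(self) -> float:
        return self.fe_per_g - self.blank_fe_per_g


def organ_iron_normalize(
    fe_mass_ug: float, tissue_mass_g: float, blank_fe_per_g: float = 0.0
) -> float:
    """Iron per gram of tissue after blank subtraction, ug/g.

    Values below the untreated-control blank come out negative; they are
    returned unclamped with a warning.
    """
    if tissue_mass_g <= 0:
        raise ValueError("tissue mass must be > 0")
    corrected = fe_mass_ug / tissue_mass_g - blank_fe_per_g
    if corrected < 0:
        warnings.warn(
            f"corrected iron content {corrected:.4g} ug/g is negative "
            "(sample below blank); returned unclamped",
            stacklevel=2,
        )
    return float(corrected)
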