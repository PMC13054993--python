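"""Voxel-wise mono-versus-bi model comparison and parametric map assembly.

Information criteria follow the forms

    AIC = n ln(RSS) + 2 k
    BIC = n ln(RSS) + k ln(n)

with RSS (not RSS/n) inside the logarithm — implemented exactly as
printed in the analysis protocol this pipeline reproduces. At fixed n the
ranking of candidate models is unaffected by that choice. RSS is floored
at a small epsilon before the logarithm so that noiseless (RSS = 0) fits
remain comparable.

The bi-exponential model is deemed superior when the mono-minus-bi
criterion difference exceeds a threshold (default 10); the "OR" rule asks
either Delta-AIC or Delta-BIC to exceed it, the "AND" rule (default, the
conservative choice matching binary overlay maps) asks for both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from relaxmap.relaxation_models import AcquisitionSchedule
from relaxmap.voxel_fitting import FitResult, FittedVolume, fit_volume

__all__ = [
    "K_MONO",
    "K_BI",
    "SelectionResult",
    "ParametricMaps",
    "information_criteria",
    "select_model",
    "build_maps",
]

K_MONO = 2  # S0, T2
K_BI = 4    # A1, A2, T2_fast, T2_slow

DEFAULT_THRESHOLD = 10.0
RSS_FLOOR_SCALE = 1e-12  # floor = scale * n * max_signal^2


def information_criteria(
    rss: float, n: int, k: int, rss_floor: float = 1e-300
) -> tuple[float, float]:
    """Return (AIC, BIC) = (n ln RSS + 2k, n ln RSS + k ln n).

    ``rss`` is floored at ``rss_floor`` before the logarithm so exact fits
    (RSS = 0) do not produce -inf.
    """
    if n < 1 or k < 1:
        raise ValueError("require n >= 1 and k >= 1")
    if rss < 0:
        raise ValueError("rss must be >= 0")
    log_rss = np.log(max(rss, rss_floor))
    aic = n * log_rss + 2 * k
    bic = n * log_rss + k * np.log(n)
    return float(aic), float(bic)


def rss_floor_for(n: int, max_signal: float) -> float:
    """Epsilon floor for RSS: 1e-12 * n * max_signal^2 (min 1e-300)."""
    return max(RSS_FLOOR_SCALE * n * max_signal**2, 1e-300)


@dataclass(frozen=True)
class SelectionResult:
    """Mono-versus-bi criterion comparison for one curve.

    ``delta_aic = aic_mono - aic_bi`` (positive favours bi), likewise for
    BIC. ``chosen`` applies the rule at the given threshold.
    """

    aic_mono: float
    aic_bi: float
    bic_mono: float
    bic_bi: float
    chosen: str
    rule: str
    threshold: float = DEFAULT_THRESHOLD

    @property
    def delta_aic(self) -> float:
        return self.aic_mono - self.aic_bi

    @property
    def delta_bic(self) -> float:
        return self.bic_mono - self.bic_bi


def select_model(
    fit_mono: FitResult,
    fit_bi: FitResult,
    rule: str = "AND",
    threshold: float = DEFAULT_THRESHOLD,
    max_signal: float | None = None,
) -> SelectionResult:
    """Choose mono or bi for one curve from AIC/BIC differences.

    Both fits must come from the same curve (same n). k is 2 for mono and
    4 for bi. A bi fit flagged "effectively_mono" (collapsed components)
    forces the mono choice regardless of the criteria.
    """
    rule = rule.upper()
    if rule not in ("OR", "AND"):
        raise ValueError(f"rule must be 'OR' or 'AND', got {rule!r}")
    if fit_mono.n != fit_bi.n:
        raise ValueError(
            f"fits disagree on n: {fit_mono.n} vs {fit_bi.n}"
        )
    n = fit_mono.n
    if max_signal is None:
        floor = 1e-300
    else:
        floor = rss_floor_for(n, max_signal)

    aic_m, bic_m = information_criteria(fit_mono.rss, n, K_MONO, floor)
    aic_b, bic_b = information_criteria(fit_bi.rss, n, K_BI, floor)

    d_aic = aic_m - aic_b
    d_bic = bic_m - bic_b
    if rule == "OR":
        bi_wins = d_aic > threshold or d_bic > threshold
    else:
        bi_wins = d_aic > threshold and d_bic > threshold
    if fit_bi.effectively_mono or not fit_bi.converged:
        bi_wins = False
    if not fit_mono.converged and fit_bi.converged:
        bi_wins = True

    return SelectionResult(
        aic_mono=aic_m,
        aic_bi=aic_b,
        bic_mono=bic_m,
        bic_bi=bic_b,
        chosen="bi" if bi_wins else "mono",
        rule=rule,
        threshold=threshold,
    )


@dataclass
class ParametricMaps:
    """Voxel maps of fitted relaxation times and the binary selection map.

    ``t2_fast_map``/``t2_slow_map`` are populated (ms) only where the bi
    model was selected, NaN elsewhere; ``t2_mono_map`` is populated
    everywhere inside the mask. ``binary_map`` is 1 exactly where bi was
    selected.
    """

    t2_fast_map: np.ndarray
    t2_slow_map: np.ndarray
    t2_mono_map: np.ndarray
    binary_map: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        shapes = {
            a.shape
            for a in (
                self.t2_fast_map,
                self.t2_slow_map,
                self.t2_mono_map,
                self.binary_map,
                self.mask,
            )
        }
        if len(shapes) != 1:
            raise ValueError("all maps must share one shape")


def build_maps(
    volume: np.ndarray,
    schedule: AcquisitionSchedule,
    mask: np.ndarray | None = None,
    rule: str = "AND",
    threshold: float = DEFAULT_THRESHOLD,
    voxel_size: tuple[float, float, float] | None = None,
    fitted: FittedVolume | None = None,
) -> ParametricMaps:
    """Fit every masked voxel and assemble parametric + binary maps.

    Pass ``fitted`` to reuse an existing :func:`fit_volume` result.
    Unfittable voxels propagate as NaN in every parametric map.
    """
    volume = np.asarray(volume, dtype=float)
    if fitted is None:
        fitted = fit_volume(volume, schedule, mask=mask)
    shape = fitted.shape
    max_signal = float(np.max(np.abs(volume)))

    t2_fast = np.full(shape, np.nan)
    t2_slow = np.full(shape, np.nan)
    t2_mono = np.full(shape, np.nan)
    binary = np.zeros(shape, dtype=np.int8)

    for idx, fm, fb in fitted.voxels():
        sel = select_model(fm, fb, rule=rule, threshold=threshold,
                           max_signal=max_signal)
        if fm.converged and fm.params is not None:
            t2_mono[idx] = fm.params.T
        if sel.chosen == "bi" and fb.params is not None:
            binary[idx] = 1
            t2_fast[idx] = fb.params.T2_fast
            t2_slow[idx] = fb.params.T2_slow

    return ParametricMaps(
        t2_fast_map=t2_fast,
        t2_slow_map=t2_slow,
        t2_mono_map=t2_mono,
        binary_map=binary,
        mask=fitted.mask,
        voxel_size=voxel_size,
    )
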