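"""Nonlinear least-squares estimation of relaxation parameters.

Per-curve fitters for mono-exponential decay, bi-exponential decay and
inversion recovery, plus whole-volume helpers. Fits minimise the plain
(unweighted) residual sum of squares with bounded trust-region
Levenberg-Marquardt steps; initial guesses come from a log-linear
regression (mono), from the mono fit (bi), or from the null-point
heuristic (IR). Per-voxel failures are reported via ``converged=False``,
never raised, so whole-volume runs always complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.optimize import least_squares

from relaxmap.relaxation_models import (
    AcquisitionSchedule,
    BiParams,
    MonoParams,
    SequenceKind,
)

__all__ = [
    "DecayCurve",
    "FitResult",
    "FittedVolume",
    "fit_mono",
    "fit_bi",
    "fit_t1_ir",
    "fit_volume",
    "subtract_background",
    "mask_volume",
]

# optimizer bounds and tolerances (see module docstring)
T2_BOUNDS_MS = (1.0, 5000.0)
T1_BOUNDS_MS = (1.0, 20000.0)
AMPLITUDE_FACTOR = 10.0          # amplitude upper bound = factor * max signal
FIT_TOL = 1e-12
MAX_ITER = 500
COLLAPSE_RATIO = 1.2             # bi fit "effectively mono" if T2_slow/T2_fast below
COLLAPSE_AMPLITUDE_FRACTION = 0.01


@dataclass(frozen=True)
class DecayCurve:
    """One voxel's (or sample's) signal versus sampling time."""

    schedule: AcquisitionSchedule
    signal: np.ndarray

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 1 or sig.size != len(self.schedule):
            raise ValueError(
                f"signal length {sig.size} != schedule length {len(self.schedule)}"
            )
        object.__setattr__(self, "signal", sig)

    @property
    def n(self) -> int:
        return int(self.signal.size)

    @property
    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.signal)))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single-curve fit.

    ``params`` is ``None`` when the fit failed (``converged=False``);
    otherwise it satisfies its type's invariants. ``flags`` carries
    quality annotations such as ``"effectively_mono"`` (bi fit collapsed
    to one component) or ``"wide_confidence"`` (ill-conditioned).
    """

    model: str
    params: MonoParams | BiParams | None
    rss: float
    n: int
    converged: bool
    iterations: int = 0
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.converged and self.rss < 0:
            raise ValueError("rss must be >= 0")

    @property
    def effectively_mono(self) -> bool:
        return "effectively_mono" in self.flags


def _failure(model: str, n: int) -> FitResult:
    return FitResult(model=model, params=None, rss=np.inf, n=n, converged=False)


def _loglinear_guess(times: np.ndarray, signal: np.ndarray) -> tuple[float, float]:
    """OLS of log(signal) on time over positive samples -> (S0, T2)."""
    pos = signal > 0
    if pos.sum() >= 2:
        coef = np.polyfit(times[pos], np.log(signal[pos]), 1)
        slope, intercept = coef[0], coef[1]
        if slope < 0:
            return float(np.exp(intercept)), float(-1.0 / slope)
        return float(np.exp(intercept)), float(times[-1])
    return float(np.max(np.abs(signal))), float(np.median(times))


def fit_mono(curve: DecayCurve) -> FitResult:
    """Fit S(t) = S0 exp(-t/T2) to a decay curve.

    Requires >= 3 samples. Degenerate input (all zero, non-finite) yields
    ``converged=False`` rather than an exception.
    """
    if curve.n < 3:
        raise ValueError("mono fit requires at least 3 samples")
    t, y = curve.schedule.times, curve.signal
    if not curve.is_finite or np.all(y == 0):
        return _failure("mono", curve.n)

    s0_init, t2_init = _loglinear_guess(t, y)
    max_sig = float(np.max(np.abs(y)))
    lo = [0.0, T2_BOUNDS_MS[0]]
    hi = [AMPLITUDE_FACTOR * max_sig, T2_BOUNDS_MS[1]]
    x0 = np.clip([s0_init, t2_init], lo, hi)

    res = least_squares(
        lambda x: x[0] * np.exp(-t / x[1]) - y,
        x0,
        bounds=(lo, hi),
        method="trf",
        ftol=FIT_TOL, xtol=FIT_TOL, gtol=FIT_TOL,
        max_nfev=MAX_ITER,
    )
    s0, t2 = res.x
    rss = float(np.sum(res.fun**2))
    return FitResult(
        model="mono",
        params=MonoParams(float(s0), float(t2)),
        rss=rss,
        n=curve.n,
        converged=bool(res.success),
        iterations=int(res.nfev),
    )


def fit_bi(curve: DecayCurve) -> FitResult:
    """Fit S(t) = A1 exp(-t/T2_fast) + A2 exp(-t/T2_slow).

    Requires >= 5 samples. Initialised from the mono fit
    (A1 = A2 = S0/2, T2_fast = T2/2, T2_slow = 2 T2); the result is
    reordered so T2_fast < T2_slow. If the components collapse
    (T2_slow/T2_fast < 1.2 or either amplitude < 1% of the total) the
    result is flagged ``"effectively_mono"``.
    """
    if curve.n < 5:
        raise ValueError("bi fit requires at least 5 samples")
    t, y = curve.schedule.times, curve.signal
    if not curve.is_finite or np.all(y == 0):
        return _failure("bi", curve.n)

    mono = fit_mono(curve)
    if mono.params is not None:
        s0_m, t2_m = mono.params.S0, mono.params.T
    else:
        s0_m, t2_m = _loglinear_guess(t, y)

    max_sig = float(np.max(np.abs(y)))
    lo = [0.0, 0.0, T2_BOUNDS_MS[0], T2_BOUNDS_MS[0]]
    hi = [
        AMPLITUDE_FACTOR * max_sig,
        AMPLITUDE_FACTOR * max_sig,
        T2_BOUNDS_MS[1],
        T2_BOUNDS_MS[1],
    ]
    x0 = np.clip([s0_m / 2, s0_m / 2, t2_m / 2, 2 * t2_m], lo, hi)

    res = least_squares(
        lambda x: x[0] * np.exp(-t / x[2]) + x[1] * np.exp(-t / x[3]) - y,
        x0,
        bounds=(lo, hi),
        method="trf",
        ftol=FIT_TOL, xtol=FIT_TOL, gtol=FIT_TOL,
        max_nfev=MAX_ITER,
    )
    a1, a2, tf, ts = res.x
    if tf > ts:
        a1, a2, tf, ts = a2, a1, ts, tf
    if tf >= ts:  # exactly degenerate; keep the ordering invariant
        ts = tf * (1.0 + 1e-9)

    flags: list[str] = []
    total = a1 + a2
    if ts / tf < COLLAPSE_RATIO or (
        total > 0
        and min(a1, a2) < COLLAPSE_AMPLITUDE_FRACTION * total
    ):
        flags.append("effectively_mono")

    rss = float(np.sum(res.fun**2))
    return FitResult(
        model="bi",
        params=BiParams(float(a1), float(a2), float(tf), float(ts)),
        rss=rss,
        n=curve.n,
        converged=bool(res.success),
        iterations=int(res.nfev),
        flags=tuple(flags),
    )


def _ir_t1_guess(t: np.ndarray, y: np.ndarray, magnitude: bool) -> float:
    ln2 = np.log(2.0)
    if magnitude:
        return float(max(t[np.argmin(np.abs(y))] / ln2, T1_BOUNDS_MS[0]))
    crossing = np.nonzero(y >= 0)[0]
    if crossing.size and crossing[0] > 0:
        return float(t[crossing[0]] / ln2)
    return float(np.median(t))


def fit_t1_ir(
    curve: DecayCurve,
    fit_beta: bool = False,
    magnitude: bool | None = None,
) -> FitResult:
    """Fit the inversion-recovery model S(TI) = S0 (1 - beta exp(-TI/T1)).

    beta is fixed at 2 (ideal inversion) unless ``fit_beta=True``.
    ``magnitude=None`` auto-detects: curves without negative samples are
    fitted through |model|, emulating magnitude-reconstructed data. A
    ``"wide_confidence"`` flag marks T1 estimates whose linearised standard
    error exceeds 50% (e.g. all TIs long compared to T1).
    """
    if curve.schedule.kind is not SequenceKind.IR:
        raise ValueError("fit_t1_ir requires an IR schedule")
    if curve.n < 3:
        raise ValueError("IR fit requires at least 3 samples")
    t, y = curve.schedule.times, curve.signal
    if not curve.is_finite or np.all(y == 0):
        return _failure("ir", curve.n)

    if magnitude is None:
        magnitude = bool(np.min(y) >= 0)

    max_sig = float(np.max(np.abs(y)))
    t1_init = _ir_t1_guess(t, y, magnitude)

    def model(x: np.ndarray) -> np.ndarray:
        s0, t1 = x[0], x[1]
        beta = x[2] if fit_beta else 2.0
        pred = s0 * (1.0 - beta * np.exp(-t / t1))
        return np.abs(pred) if magnitude else pred

    lo = [0.0, T1_BOUNDS_MS[0]]
    hi = [AMPLITUDE_FACTOR * max_sig, T1_BOUNDS_MS[1]]
    if fit_beta:
        lo.append(1.0)
        hi.append(2.5)

    # multi-start on T1: magnitude fits have spurious local minima
    t1_starts = {
        t1_init,
        float(np.median(t)) / np.log(2.0),
        float(t[-1]) / 3.0,
        # fully-recovered curves (no null crossing) imply T1 << first TI
        max(float(t[0]) / 5.0, T1_BOUNDS_MS[0]),
    }
    res = None
    for t1_0 in t1_starts:
        x0 = [max_sig, t1_0] + ([2.0] if fit_beta else [])
        candidate = least_squares(
            lambda x: model(x) - y,
            np.clip(x0, lo, hi),
            bounds=(lo, hi),
            method="trf",
            ftol=FIT_TOL, xtol=FIT_TOL, gtol=FIT_TOL,
            max_nfev=MAX_ITER,
        )
        if res is None or candidate.cost < res.cost:
            res = candidate
    s0, t1 = res.x[0], res.x[1]
    rss = float(np.sum(res.fun**2))

    flags: list[str] = []
    # rss-independent conditioning check: relative sensitivity of the
    # model to T1 at the solution; tiny values mean a flat T1 direction
    # (e.g. every TI several T1s long) and a wide confidence interval.
    y_norm = float(np.linalg.norm(y))
    t1_sensitivity = float(np.linalg.norm(res.jac[:, 1])) * t1
    if y_norm > 0 and t1_sensitivity < 0.05 * y_norm:
        flags.append("wide_confidence")

    return FitResult(
        model="ir",
        params=MonoParams(float(s0), float(t1)),
        rss=rss,
        n=curve.n,
        converged=bool(res.success),
        iterations=int(res.nfev),
        flags=tuple(flags),
    )


def subtract_background(r2_sample: float, r2_background: float) -> float:
    """Background-corrected rate: sample R2 minus agarose R2, in s^-1.

    Not clamped at zero — blank replicates may legitimately fall slightly
    below the background, and preserving that keeps the blank SD honest.
    """
    if not (np.isfinite(r2_sample) and np.isfinite(r2_background)):
        raise ValueError("rates must be finite")
    return float(r2_sample - r2_background)


def mask_volume(volume: np.ndarray, fraction_threshold: float = 0.05) -> np.ndarray:
    """Boolean foreground mask from the first-time-point signal.

    A voxel is included iff its signal at the first sampling time is
    >= ``fraction_threshold`` times the volume-wide maximum.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError("expected a 4-D (x, y, z, time) volume")
    first = volume[..., 0]
    return first >= fraction_threshold * float(np.max(volume))


@dataclass
class FittedVolume:
    """Per-voxel mono and bi fit results over a masked 4-D volume."""

    shape: tuple[int, int, int]
    mask: np.ndarray
    mono: np.ndarray  # object array of FitResult (None outside mask)
    bi: np.ndarray

    def voxels(self) -> Iterator[tuple[tuple[int, int, int], FitResult, FitResult]]:
        for idx in zip(*np.nonzero(self.mask)):
            yield idx, self.mono[idx], self.bi[idx]


def fit_volume(
    volume: np.ndarray,
    schedule: AcquisitionSchedule,
    mask: np.ndarray | None = None,
    fit_bi_too: bool = True,
) -> FittedVolume:
    """Fit every masked voxel of a 4-D volume with mono (and bi) models."""
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError("expected a 4-D (x, y, z, time) volume")
    if volume.shape[-1] != len(schedule):
        raise ValueError("time axis length does not match the schedule")
    if mask is None:
        mask = mask_volume(volume)
    shape = volume.shape[:3]
    mono = np.empty(shape, dtype=object)
    bi = np.empty(shape, dtype=object)
    for idx in zip(*np.nonzero(mask)):
        curve = DecayCurve(schedule, volume[idx])
        mono[idx] = fit_mono(curve)
        bi[idx] = fit_bi(curve) if fit_bi_too else None
    return FittedVolume(shape=shape, mask=np.asarray(mask, bool), mono=mono, bi=bi)
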