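"""Forward signal models for CPMG/MSME decay and inversion recovery.

Unit conventions used throughout the package: times in ms, relaxation
rates in s^-1 (conversion factor 1000), concentrations in mM, magnetic
fields in T, Larmor frequencies in MHz. Signals are magnitude-valued
arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "SequenceKind",
    "AcquisitionSchedule",
    "MonoParams",
    "BiParams",
    "mono_decay",
    "bi_decay",
    "ir_signal",
    "rate_time_convert",
]


class SequenceKind(str, Enum):
    """Pulse-sequence family a sampling schedule belongs to."""

    CPMG = "cpmg"  # multi-echo spin echo; times are echo times TE
    IR = "ir"      # inversion recovery; times are inversion times TI


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Ordered sampling times (TE or TI) of an acquisition, in ms.

    Parameters
    ----------
    kind : SequenceKind
        CPMG (multi-echo decay) or IR (inversion recovery).
    times : ndarray
        Strictly increasing, positive sampling times in ms.
    repetition_time : float, optional
        TR in ms; metadata only, not used by the fitters.
    """

    kind: SequenceKind
    times: np.ndarray
    repetition_time: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size < 1:
            raise ValueError("times must be a non-empty 1-D sequence")
        if np.any(times <= 0):
            raise ValueError("all sampling times must be > 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "kind", SequenceKind(self.kind))

    def __len__(self) -> int:
        return int(self.times.size)

    @classmethod
    def cpmg(
        cls,
        n_echoes: int = 40,
        first_te: float = 10.0,
        last_te: float = 400.0,
        repetition_time: float | None = None,
    ) -> "AcquisitionSchedule":
        """Evenly spaced multi-echo schedule (default 40 echoes, 10-400 ms)."""
        return cls(
            kind=SequenceKind.CPMG,
            times=np.linspace(first_te, last_te, n_echoes),
            repetition_time=repetition_time,
        )

    @classmethod
    def ir(
        cls,
        times: Sequence[float],
        repetition_time: float | None = None,
    ) -> "AcquisitionSchedule":
        """Inversion-recovery schedule from explicit TIs (ms)."""
        return cls(kind=SequenceKind.IR, times=np.asarray(times, float),
                   repetition_time=repetition_time)


@dataclass(frozen=True)
class MonoParams:
    """Mono-exponential parameters: amplitude S0 (a.u.) and T (ms).

    T is a T2 for decay curves or a T1 for inversion recovery.
    """

    S0: float
    T: float

    def __post_init__(self) -> None:
        if self.S0 < 0:
            raise ValueError(f"S0 must be >= 0, got {self.S0}")
        if self.T <= 0:
            raise ValueError(f"relaxation time must be > 0, got {self.T}")


@dataclass(frozen=True)
class BiParams:
    """Bi-exponential parameters with the ordering convention T2_fast < T2_slow."""

    A1: float
    A2: float
    T2_fast: float
    T2_slow: float

    def __post_init__(self) -> None:
        if self.A1 < 0 or self.A2 < 0:
            raise ValueError("amplitudes must be >= 0")
        if not (0 < self.T2_fast < self.T2_slow):
            raise ValueError(
                f"require 0 < T2_fast < T2_slow, got "
                f"({self.T2_fast}, {self.T2_slow})"
            )

    @property
    def total_amplitude(self) -> float:
        return self.A1 + self.A2

    @property
    def fast_fraction(self) -> float:
        tot = self.total_amplitude
        return self.A1 / tot if tot > 0 else float("nan")


def mono_decay(p: MonoParams, te: float | np.ndarray) -> float | np.ndarray:
    """Mono-exponential echo decay S(TE) = S0 * exp(-TE / T2).

    ``te`` may be a scalar or array of echo times in ms; must be >= 0.
    """
    te = np.asarray(te, dtype=float)
    if np.any(te < 0):
        raise ValueError("echo time must be >= 0")
    out = p.S0 * np.exp(-te / p.T)
    return out.item() if out.ndim == 0 else out


def bi_decay(p: BiParams, te: float | np.ndarray) -> float | np.ndarray:
    """Bi-exponential decay S(TE) = A1 exp(-TE/T2_fast) + A2 exp(-TE/T2_slow)."""
    te = np.asarray(te, dtype=float)
    if np.any(te < 0):
        raise ValueError("echo time must be >= 0")
    out = p.A1 * np.exp(-te / p.T2_fast) + p.A2 * np.exp(-te / p.T2_slow)
    return out.item() if out.ndim == 0 else out


def ir_signal(
    p: MonoParams,
    ti: float | np.ndarray,
    beta: float = 2.0,
    magnitude: bool = False,
) -> float | np.ndarray:
    """Inversion-recovery signal S(TI) = S0 * (1 - beta * exp(-TI / T1)).

    beta = 2 is ideal inversion: S(0) = -S0, S(inf) -> S0, null point at
    TI = T1 ln 2. With ``magnitude=True`` the absolute value is returned,
    emulating magnitude-reconstructed scanner data.
    """
    ti = np.asarray(ti, dtype=float)
    if np.any(ti < 0):
        raise ValueError("inversion time must be >= 0")
    out = p.S0 * (1.0 - beta * np.exp(-ti / p.T))
    if magnitude:
        out = np.abs(out)
    return out.item() if out.ndim == 0 else out


def rate_time_convert(value: float | np.ndarray) -> float | np.ndarray:
    """Convert relaxation time (ms) to rate (s^-1) or vice versa.

    R [s^-1] = 1000 / T [ms]; the mapping is an involution, so the same
    function serves both directions.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("value must be > 0 for rate/time conversion")
    out = 1000.0 / arr
    return out.item() if out.ndim == 0 else out
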