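"""Synthetic phantom and injected-tissue volume generators with ground truth.

The phantom emulates a multi-tube agarose phantom imaged with a multi-echo
spin-echo sequence: eight cylindrical tubes on a ring, each holding a
contrast-agent dilution whose transverse rate follows
``R2 = background_rate + relaxivity_slope * [Fe]``, embedded in an agarose
background relaxing at ``background_rate`` alone. The injected-tissue
generator places a bi-exponentially decaying region (injection site) and a
mono-exponential contralateral control inside a mono-exponential background.

Ground truth is recorded before noise is added, so every downstream fitting
stage can be validated against the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from relaxmap.relaxation_models import (
    AcquisitionSchedule,
    BiParams,
    MonoParams,
    bi_decay,
    mono_decay,
)

__all__ = [
    "PhantomSpec",
    "InjectionSpec",
    "GroundTruth",
    "generate_phantom",
    "generate_injection_volume",
    "add_noise",
    "default_injection_regions",
]

#: default tube iron concentrations, mM (water blank + 2.5-100 uM)
DEFAULT_CONCENTRATIONS_MM = (0.0, 0.0025, 0.005, 0.01, 0.025, 0.05, 0.075, 0.1)

NOISE_MODELS = ("gaussian", "rician")


def _default_schedule() -> AcquisitionSchedule:
    return AcquisitionSchedule.cpmg()


@dataclass
class PhantomSpec:
    """Parameters of the synthetic multi-tube calibration phantom.

    Concentrations are in mM, the relaxivity slope in mM^-1 s^-1, the
    background (agarose) rate in s^-1, the voxel size in mm.
    """

    tube_concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS_MM
    relaxivity_slope: float = 145.0
    background_rate: float = 7.0
    grid_shape: tuple[int, int, int] = (64, 64, 4)
    voxel_size: tuple[float, float, float] = (0.08, 0.1, 0.5)
    tube_radius: int = 3
    schedule: AcquisitionSchedule = field(default_factory=_default_schedule)
    s0: float = 100.0
    noise_sd: float = 0.0
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.tube_concentrations, dtype=float)
        if np.any(conc < 0):
            raise ValueError("concentrations must be >= 0")
        if len(np.unique(conc)) != conc.size:
            raise ValueError("concentrations must be unique")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        self.tube_concentrations = tuple(conc.tolist())


@dataclass
class InjectionSpec:
    """Parameters of the synthetic injected-tissue volume.

    ``injection_region`` and ``contralateral_region`` are boolean voxel
    masks over ``grid_shape``; they must be disjoint. Injection voxels decay
    bi-exponentially, everything else mono-exponentially.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 4)
    injection_region: np.ndarray | None = None
    contralateral_region: np.ndarray | None = None
    injection_params: BiParams = field(
        default_factory=lambda: BiParams(50.0, 50.0, 20.0, 200.0)
    )
    background_params: MonoParams = field(
        default_factory=lambda: MonoParams(100.0, 100.0)
    )
    schedule: AcquisitionSchedule = field(default_factory=_default_schedule)
    noise_sd: float = 0.0
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.injection_region is None or self.contralateral_region is None:
            inj, contra = default_injection_regions(self.grid_shape)
            if self.injection_region is None:
                self.injection_region = inj
            if self.contralateral_region is None:
                self.contralateral_region = contra
        self.injection_region = np.asarray(self.injection_region, bool)
        self.contralateral_region = np.asarray(self.contralateral_region, bool)
        for name, mask in (
            ("injection_region", self.injection_region),
            ("contralateral_region", self.contralateral_region),
        ):
            if mask.shape != tuple(self.grid_shape):
                raise ValueError(f"{name} shape {mask.shape} != grid {self.grid_shape}")
        if np.any(self.injection_region & self.contralateral_region):
            raise ValueError("injection and contralateral regions overlap")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class GroundTruth:
    """Per-voxel generating parameters, recorded before noise.

    ``model_label`` is 0 where the voxel decays mono-exponentially and 1
    where it is bi-exponential. Mono voxels carry (``mono_s0``, ``mono_t2``);
    bi voxels carry the four bi-exponential arrays; unused entries are NaN.
    ``regions`` maps region names (tube labels, "injection", ...) to boolean
    masks, and ``tube_table`` holds per-tube concentration and true rate.
    """

    model_label: np.ndarray
    mono_s0: np.ndarray
    mono_t2: np.ndarray
    bi_a1: np.ndarray
    bi_a2: np.ndarray
    bi_t2_fast: np.ndarray
    bi_t2_slow: np.ndarray
    regions: dict[str, np.ndarray]
    tube_table: pd.DataFrame | None = None

    @classmethod
    def _empty(cls, shape: tuple[int, ...]) -> "GroundTruth":
        nan = np.full(shape, np.nan)
        return cls(
            model_label=np.zeros(shape, dtype=np.int8),
            mono_s0=nan.copy(),
            mono_t2=nan.copy(),
            bi_a1=nan.copy(),
            bi_a2=nan.copy(),
            bi_t2_fast=nan.copy(),
            bi_t2_slow=nan.copy(),
            regions={},
        )


def _tube_centers(
    grid_shape: tuple[int, int, int], n_tubes: int, tube_radius: int
) -> list[tuple[float, float]]:
    """Centers of n tubes evenly spaced on a ring in the axial (x, y) plane."""
    cx = (grid_shape[0] - 1) / 2.0
    cy = (grid_shape[1] - 1) / 2.0
    ring = 0.5 * min(cx, cy) + tube_radius
    max_ring = min(cx, cy) - tube_radius - 1
    ring = min(ring, max_ring)
    if ring <= tube_radius:
        raise ValueError(
            f"tube layout (radius {tube_radius}, {n_tubes} tubes) does not fit "
            f"in grid {grid_shape}"
        )
    angles = 2.0 * np.pi * np.arange(n_tubes) / n_tubes
    return [(cx + ring * np.cos(a), cy + ring * np.sin(a)) for a in angles]


def _cylinder_mask(
    grid_shape: tuple[int, int, int], center: tuple[float, float], radius: float
) -> np.ndarray:
    xx, yy = np.meshgrid(
        np.arange(grid_shape[0]), np.arange(grid_shape[1]), indexing="ij"
    )
    disc = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2
    return np.repeat(disc[:, :, None], grid_shape[2], axis=2)


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize a 4-D (x, y, z, time) phantom volume and its ground truth.

    Every tube voxel follows a mono-exponential decay at rate
    ``background_rate + relaxivity_slope * [Fe]``; agarose background voxels
    decay at ``background_rate``. With ``noise_sd == 0`` each voxel equals
    the forward model exactly.
    """
    conc = np.asarray(spec.tube_concentrations, dtype=float)
    centers = _tube_centers(spec.grid_shape, conc.size, spec.tube_radius)

    gt = GroundTruth._empty(tuple(spec.grid_shape))
    rates = spec.background_rate + spec.relaxivity_slope * conc  # s^-1
    t2s = 1000.0 / rates  # ms

    # agarose background everywhere, tubes painted on top
    gt.mono_s0[:] = spec.s0
    gt.mono_t2[:] = 1000.0 / spec.background_rate

    rows = []
    claimed = np.zeros(tuple(spec.grid_shape), dtype=bool)
    for i, (c, center, t2) in enumerate(zip(conc, centers, t2s)):
        mask = _cylinder_mask(tuple(spec.grid_shape), center, spec.tube_radius)
        if np.any(mask & claimed):
            raise ValueError("tube regions overlap; reduce tube_radius")
        claimed |= mask
        gt.mono_t2[mask] = t2
        label = f"tube_{i}"
        gt.regions[label] = mask
        rows.append(
            {
                "label": label,
                "fe_mM": c,
                "r2_s": spec.background_rate + spec.relaxivity_slope * c,
                "t2_ms": t2,
                "n_voxels": int(mask.sum()),
            }
        )
    gt.regions["background"] = ~claimed
    gt.tube_table = pd.DataFrame(rows)

    times = spec.schedule.times
    volume = gt.mono_s0[..., None] * np.exp(
        -times[None, None, None, :] / gt.mono_t2[..., None]
    )
    volume = add_noise(volume, spec.noise_sd, spec.noise_model, spec.seed)
    return volume, gt


def default_injection_regions(
    grid_shape: tuple[int, int, int], radius: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """A spherical injection blob in one hemisphere and its mirror control."""
    if radius is None:
        radius = max(1.5, min(grid_shape[:2]) / 8.0)
    cx = grid_shape[0] * 0.25
    cy = (grid_shape[1] - 1) / 2.0
    cz = (grid_shape[2] - 1) / 2.0
    xx, yy, zz = np.meshgrid(
        *(np.arange(s) for s in grid_shape), indexing="ij"
    )
    # anisotropic voxels: treat z distance in voxel units, fine for a test blob
    inj = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= radius**2
    contra = (xx - (grid_shape[0] - 1 - cx)) ** 2 + (yy - cy) ** 2 + (
        zz - cz
    ) ** 2 <= radius**2
    return inj, contra


def generate_injection_volume(spec: InjectionSpec) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize a 4-D injected-tissue volume and its ground truth.

    Injection voxels decay bi-exponentially with ``spec.injection_params``;
    all other voxels (including the contralateral control) decay
    mono-exponentially with ``spec.background_params``.
    """
    shape = tuple(spec.grid_shape)
    gt = GroundTruth._empty(shape)
    inj = spec.injection_region

    gt.mono_s0[:] = spec.background_params.S0
    gt.mono_t2[:] = spec.background_params.T

    gt.model_label[inj] = 1
    gt.mono_s0[inj] = np.nan
    gt.mono_t2[inj] = np.nan
    gt.bi_a1[inj] = spec.injection_params.A1
    gt.bi_a2[inj] = spec.injection_params.A2
    gt.bi_t2_fast[inj] = spec.injection_params.T2_fast
    gt.bi_t2_slow[inj] = spec.injection_params.T2_slow
    gt.regions["injection"] = inj.copy()
    gt.regions["contralateral"] = spec.contralateral_region.copy()

    times = spec.schedule.times
    volume = np.empty(shape + (times.size,), dtype=float)
    volume[~inj] = mono_decay(spec.background_params, times)[None, :]
    volume[inj] = bi_decay(spec.injection_params, times)[None, :]
    volume = add_noise(volume, spec.noise_sd, spec.noise_model, spec.seed)
    return volume, gt


def add_noise(
    volume: np.ndarray,
    noise_sd: float,
    noise_model: str = "gaussian",
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Add measurement noise to a signal array.

    gaussian: zero-mean additive noise (signed output allowed).
    rician: magnitude of (signal + n1, n2) with two independent gaussian
    components of SD ``noise_sd``; output is non-negative by construction.
    ``noise_sd == 0`` returns the input unchanged.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_model not in NOISE_MODELS:
        raise ValueError(f"unknown noise model {noise_model!r}")
    if noise_sd == 0:
        return volume
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if noise_model == "gaussian":
        return volume + rng.normal(0.0, noise_sd, size=volume.shape)
    real = volume + rng.normal(0.0, noise_sd, size=volume.shape)
    imag = rng.normal(0.0, noise_sd, size=volume.shape)
    return np.hypot(real, imag)
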