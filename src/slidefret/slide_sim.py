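"""Monte Carlo simulator of dsDNA sliding 1D along a rigid RecA filament.

The duplex performs an unbiased +/- ``step_size`` random walk in register
units (nt) at the micro time step tau = step**2 / (2 D), reflected at the
boundaries of the allowed overlap range.  After each micro-step the
donor-acceptor distance and its FRET efficiency are evaluated; camera
frames average the efficiency over their micro-steps and allocate a fixed
photon budget (default 500 a.u. per 30 ms bin) between the channels, with
additive Gaussian noise per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .geometry import (FAR_RED_COUPLING, FilamentGeometry, FretCoupling,
                       fret_from_distance, register_to_distance)
from .traces import IntensityTrace

_SEED_MAX = 2**31 - 1


@dataclass
class SlideSimConfig:
    """Full specification of one sliding simulation.

    ``d_um2`` is the 1D sliding diffusion coefficient in um^2/s; it is
    converted internally to register units using the filament rise.
    ``noise_amplitude`` is the per-channel Gaussian SD in a.u.
    ``min_overlap`` is the minimum filament-duplex contact (bp) that the
    reflecting boundaries enforce; ``x_max`` overrides the derived range
    when set.
    """

    d_um2: float = 0.9e-3
    step_size: float = 0.1
    frame_interval: float = 0.030
    n_frames: int = 1000
    total_intensity: float = 500.0
    noise_amplitude: float = 40.0
    min_overlap: float = 9.0
    x_max: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.step_size <= 0.1:
            raise ValueError("step_size must be in (0, 0.1]")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be > 0")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be > 0")
        if self.d_um2 < 0:
            raise ValueError("d_um2 must be >= 0")
        if self.x_max is not None and self.x_max < 0:
            raise ValueError("x_max must be >= 0")


def register_diffusion(config: SlideSimConfig, geometry: FilamentGeometry) -> float:
    """D in register units (nt^2/s), using the filament rise per residue."""
    rise_nm = geometry.rise_per_residue / 10.0
    return config.d_um2 * 1e6 / rise_nm**2


def allowed_range(config: SlideSimConfig, geometry: FilamentGeometry) -> float:
    """Reflecting-boundary range of the walk coordinate.

    The duplex may slide while keeping at least ``min_overlap`` bp of
    contact with the filament, giving a range of
    ``filament_length + duplex_length - 2 * min_overlap`` register units.
    """
    if config.x_max is not None:
        return float(config.x_max)
    x_max = geometry.filament_length + geometry.duplex_length - 2 * config.min_overlap
    if x_max < 0:
        raise ValueError("min_overlap too large for this geometry")
    return float(x_max)


def alignment_center(config: SlideSimConfig, geometry: FilamentGeometry,
                     acceptor_index: int = 0) -> float:
    """Walk coordinate at which the donor axially aligns with an acceptor."""
    a = geometry.acceptor_positions[acceptor_index]
    return a + (geometry.duplex_length - config.min_overlap) - geometry.donor_position


def micro_steps_per_frame(config: SlideSimConfig, geometry: FilamentGeometry) -> int:
    """Number of micro-steps that one camera frame integrates over."""
    d_reg = register_diffusion(config, geometry)
    if d_reg == 0:
        return 1
    tau = config.step_size**2 / (2.0 * d_reg)
    return max(1, int(round(config.frame_interval / tau)))


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(_SEED_MAX))


def _init_position(config, geometry, rng) -> float:
    x_max = allowed_range(config, geometry)
    if x_max == 0:
        if config.d_um2 > 0:
            warnings.warn("zero sliding range with D > 0: trace is static")
        return 0.0
    return float(rng.uniform(0, x_max))


def simulate_trajectory(config: SlideSimConfig, geometry: FilamentGeometry,
                        n_steps: Optional[int] = None,
                        rng: Optional[np.random.Generator] = None,
                        x_init: Optional[float] = None,
                        bounded: bool = True) -> np.ndarray:
    """Register position after each micro-step of the walk.

    Intended for validation at small sizes (the array holds every
    micro-step); the trace renderers use fused kernels instead.
    ``bounded=False`` removes the reflecting boundaries (free diffusion,
    for mean-squared-displacement checks).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if n_steps is None:
        n_steps = config.n_frames * micro_steps_per_frame(config, geometry)
    if x_init is None:
        x_init = _init_position(config, geometry, rng) if bounded else 0.0
    if config.d_um2 == 0:
        return np.full(n_steps, x_init)
    x_max = allowed_range(config, geometry) if bounded else -1.0
    return _kernels.walk_positions(
        n_steps, x_init, config.step_size, x_max, _kernel_seed(rng)
    )


def render_intensities(positions: np.ndarray, geometry: FilamentGeometry,
                       coupling: FretCoupling, config: SlideSimConfig,
                       rng: Optional[np.random.Generator] = None,
                       noise: bool = True,
                       molecule_id: str = "") -> IntensityTrace:
    """Bin a micro-step trajectory into a noisy two-color intensity trace.

    Frames average the Forster efficiency over their micro-steps; the
    noiseless acceptor and donor channels are ``T * E`` and ``T * (1-E)``
    so their sum is exactly the photon budget.
    """
    k = micro_steps_per_frame(config, geometry)
    positions = np.asarray(positions, dtype=float)
    if len(positions) % k != 0:
        raise ValueError(
            f"trajectory length {len(positions)} is not a multiple of "
            f"{k} micro-steps per frame"
        )
    center = alignment_center(config, geometry)
    dist = register_to_distance(positions, center, geometry)
    e = fret_from_distance(dist, coupling)
    e_frames = e.reshape(-1, k).mean(axis=1)
    return _to_trace_2c(e_frames, config, rng, noise, molecule_id)


def _to_trace_2c(e_frames, config, rng, noise, molecule_id) -> IntensityTrace:
    T = config.total_intensity
    acceptor = T * e_frames
    donor = T * (1.0 - e_frames)
    if noise and config.noise_amplitude > 0:
        rng = np.random.default_rng(config.seed) if rng is None else rng
        donor = donor + rng.normal(0, config.noise_amplitude, len(e_frames))
        acceptor = acceptor + rng.normal(0, config.noise_amplitude, len(e_frames))
    return IntensityTrace(
        {"donor": donor, "acceptor1": acceptor},
        frame_interval=config.frame_interval,
        molecule_id=molecule_id,
        metadata={"d_um2": config.d_um2},
    )


def simulate_slide_trace(config: SlideSimConfig, geometry: FilamentGeometry,
                         coupling: Optional[FretCoupling] = None,
                         rng: Optional[np.random.Generator] = None,
                         noise: bool = True,
                         molecule_id: str = "") -> IntensityTrace:
    """Simulate one two-color sliding trace end to end (fused fast path)."""
    coupling = FretCoupling() if coupling is None else coupling
    rng = np.random.default_rng(config.seed) if rng is None else rng
    k = micro_steps_per_frame(config, geometry)
    x_init = _init_position(config, geometry, rng)
    center = alignment_center(config, geometry)
    g = geometry
    if config.d_um2 == 0:
        dist = register_to_distance(x_init, center, g)
        e_frames = np.full(config.n_frames, fret_from_distance(dist, coupling))
    else:
        e_frames, _ = _kernels.walk_frame_efficiency(
            config.n_frames, k, x_init, config.step_size,
            allowed_range(config, g), center,
            g.lateral_offset_r**2, 1.0 / coupling.forster_radius**2,
            g.rise_per_residue, _kernel_seed(rng),
        )
    return _to_trace_2c(e_frames, config, rng, noise, molecule_id)


def simulate_three_color(config: SlideSimConfig, geometry: FilamentGeometry,
                         couplings: Optional[Sequence[FretCoupling]] = None,
                         rng: Optional[np.random.Generator] = None,
                         noise: bool = True,
                         molecule_id: str = "") -> IntensityTrace:
    """Simulate a three-color trace: one donor, two acceptors on the filament.

    Donor excitations are partitioned among donor/acceptor1/acceptor2 by
    the two distance-dependent Forster rates each micro-step, so the
    noiseless three-channel sum is exactly the photon budget and the two
    acceptor efficiencies are anticorrelated for a diffusing trajectory.
    """
    if len(geometry.acceptor_positions) < 2:
        raise ValueError("three-color simulation needs two acceptor positions")
    a1, a2 = geometry.acceptor_positions[:2]
    if a1 == a2:
        raise ValueError("acceptor positions coincide")
    if couplings is None:
        couplings = (FretCoupling(), FAR_RED_COUPLING)
    c1, c2 = couplings
    rng = np.random.default_rng(config.seed) if rng is None else rng
    k = micro_steps_per_frame(config, geometry)
    x_init = _init_position(config, geometry, rng)
    center1 = alignment_center(config, geometry, 0)
    center2 = alignment_center(config, geometry, 1)
    g = geometry
    if config.d_um2 == 0:
        k1 = (c1.forster_radius / register_to_distance(x_init, center1, g)) ** 6
        k2 = (c2.forster_radius / register_to_distance(x_init, center2, g)) ** 6
        denom = 1.0 + k1 + k2
        f1 = np.full(config.n_frames, k1 / denom)
        f2 = np.full(config.n_frames, k2 / denom)
    else:
        f1, f2, _ = _kernels.walk_frame_partition3(
            config.n_frames, k, x_init, config.step_size,
            allowed_range(config, g), center1, center2,
            g.lateral_offset_r**2,
            1.0 / c1.forster_radius**2, 1.0 / c2.forster_radius**2,
            g.rise_per_residue, _kernel_seed(rng),
        )
    T = config.total_intensity
    chans = {
        "donor": T * (1.0 - f1 - f2),
        "acceptor1": T * f1,
        "acceptor2": T * f2,
    }
    if noise and config.noise_amplitude > 0:
        for name in chans:
            chans[name] = chans[name] + rng.normal(
                0, config.noise_amplitude, config.n_frames
            )
    return IntensityTrace(
        chans, frame_interval=config.frame_interval,
        molecule_id=molecule_id, metadata={"d_um2": config.d_um2},
    )


def simulate_molecules(config: SlideSimConfig, geometry: FilamentGeometry,
                       n_molecules: int,
                       coupling: Optional[FretCoupling] = None,
                       seed: Optional[int] = None,
                       noise: bool = True) -> list:
    """Independent two-color traces with per-molecule derived seeds."""
    root = np.random.default_rng(config.seed if seed is None else seed)
    traces = []
    for m in range(n_molecules):
        rng = np.random.default_rng(root.integers(_SEED_MAX))
        traces.append(
            simulate_slide_trace(config, geometry, coupling, rng=rng,
                                 noise=noise, molecule_id=f"mol{m:04d}")
        )
    return traces
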