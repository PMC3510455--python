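"""Synthetic homology-recognition traces: a continuous-time Markov chain
over the NH / HS2 / HS1 states with Gaussian FRET emissions, plus
binding/dissociation event streams for dwell-time analysis.

NH is the low-FRET (~0.1) non-homologous sliding state; HS2 and HS1 are
the mid- (~0.5) and high-FRET (~0.9) homology sites.  Dwells are
exponential with mean 1 / sum_j k(i->j); the next state is chosen with
probability proportional to k(i->j).  Camera frames that straddle a
transition take the occupancy-weighted mean of the state means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .traces import FretTrace, IntensityTrace

_SEED_MAX = 2**31 - 1

#: Default per-second rate matrix k(i->j), states ordered (NH, HS2, HS1).
#: NH branches 55:45 toward the nearer homology site; the total exit rate
#: from either homology site is one third of the NH exit rate.
DEFAULT_RATES = np.array([
    [0.0, 1.1, 0.9],
    [0.40, 0.0, 0.27],
    [0.40, 0.27, 0.0],
])


@dataclass
class StateModel:
    """Three-state kinetic scheme with Gaussian FRET emissions."""

    state_names: Sequence[str] = ("NH", "HS2", "HS1")
    fret_means: Sequence[float] = (0.1, 0.5, 0.9)
    emission_sd: Sequence[float] = (0.05, 0.05, 0.05)
    rate_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_RATES.copy())
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        n = len(self.state_names)
        self.fret_means = np.asarray(self.fret_means, dtype=float)
        self.emission_sd = np.asarray(self.emission_sd, dtype=float)
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        if len(self.fret_means) != n or len(self.emission_sd) != n:
            raise ValueError("means/SDs must match the number of states")
        if np.any(np.diff(self.fret_means) <= 0):
            raise ValueError("fret_means must be strictly increasing")
        if np.any(self.emission_sd <= 0):
            raise ValueError("emission SDs must be > 0")
        if self.rate_matrix.shape != (n, n):
            raise ValueError("rate_matrix must be n_states x n_states")
        if np.any(self.rate_matrix < 0):
            raise ValueError("rates must be >= 0")
        np.fill_diagonal(self.rate_matrix, 0.0)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def exit_rates(self) -> np.ndarray:
        return self.rate_matrix.sum(axis=1)


Dwell = Tuple[int, float, float]  # (state index, start time s, length s)


def simulate_ctmc(model: StateModel, duration: float,
                  rng: Optional[np.random.Generator] = None,
                  initial: Optional[int] = None) -> List[Dwell]:
    """Gillespie simulation of the chain for ``duration`` seconds.

    Returns (state, start, length) dwells that exactly partition
    [0, duration]; the final dwell is truncated at the horizon.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(model.seed) if rng is None else rng
    k_exit = model.exit_rates()
    state = int(rng.integers(model.n_states)) if initial is None else int(initial)
    t = 0.0
    dwells: List[Dwell] = []
    while t < duration:
        if k_exit[state] == 0:
            dwells.append((state, t, duration - t))
            break
        dt = rng.exponential(1.0 / k_exit[state])
        if t + dt >= duration:
            dwells.append((state, t, duration - t))
            break
        dwells.append((state, t, dt))
        p = model.rate_matrix[state] / k_exit[state]
        state = int(rng.choice(model.n_states, p=p))
        t += dt
    return dwells


def emit_fret(dwells: List[Dwell], model: StateModel, frame_interval: float,
              rng: Optional[np.random.Generator] = None,
              noise: bool = True, molecule_id: str = "") -> FretTrace:
    """Render a dwell sequence as a framed FRET trace.

    Each frame takes the occupancy-weighted mean of the state FRET means
    (and of the state SDs for its noise), mimicking camera integration.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    duration = dwells[-1][1] + dwells[-1][2]
    n_frames = int(round(duration / frame_interval))
    # occupancy-weighted state means per frame via fine overlap bookkeeping
    mean = np.zeros(n_frames)
    sd = np.zeros(n_frames)
    edges = np.arange(n_frames + 1) * frame_interval
    for state, start, length in dwells:
        stop = start + length
        i0 = int(np.searchsorted(edges, start, side="right")) - 1
        i1 = int(np.searchsorted(edges, stop, side="left"))
        for f in range(max(i0, 0), min(i1, n_frames)):
            overlap = min(stop, edges[f + 1]) - max(start, edges[f])
            w = overlap / frame_interval
            mean[f] += w * model.fret_means[state]
            sd[f] += w * model.emission_sd[state]
    if noise:
        rng = np.random.default_rng(model.seed) if rng is None else rng
        mean = mean + rng.normal(0, 1, n_frames) * sd
    return FretTrace({"efret1": mean}, frame_interval=frame_interval,
                     molecule_id=molecule_id)


def dominant_state_path(dwells: List[Dwell], frame_interval: float,
                        n_frames: Optional[int] = None) -> np.ndarray:
    """Per-frame state index occupying the majority of each frame."""
    duration = dwells[-1][1] + dwells[-1][2]
    if n_frames is None:
        n_frames = int(round(duration / frame_interval))
    centers = (np.arange(n_frames) + 0.5) * frame_interval
    starts = np.array([d[1] for d in dwells])
    idx = np.clip(np.searchsorted(starts, centers, side="right") - 1, 0, None)
    return np.array([dwells[i][0] for i in idx])


def simulate_state_traces(model: StateModel, n_traces: int, n_frames: int,
                          frame_interval: float = 0.030,
                          seed: Optional[int] = None, noise: bool = True):
    """Independent CTMC traces with per-molecule derived seeds.

    Returns (FretTrace list, list of true dwell sequences).
    """
    root = np.random.default_rng(model.seed if seed is None else seed)
    duration = n_frames * frame_interval
    traces, truths = [], []
    for m in range(n_traces):
        rng = np.random.default_rng(root.integers(_SEED_MAX))
        dwells = simulate_ctmc(model, duration, rng=rng)
        traces.append(emit_fret(dwells, model, frame_interval, rng=rng,
                                noise=noise, molecule_id=f"mol{m:04d}"))
        truths.append(dwells)
    return traces, truths


def simulate_docking_series(on_rate: float, mean_dwell: float, duration: float,
                            frame_interval: float = 0.030,
                            rng: Optional[np.random.Generator] = None,
                            seed: Optional[int] = None,
                            bright_total: float = 500.0,
                            efficiency: float = 0.5,
                            noise_sd: float = 0.0,
                            molecule_id: str = ""):
    """Alternating dark/bright epochs of dsDNA docking to one filament.

    Unbound (dark) waits are exponential with mean ``1/on_rate``; bound
    (bright) dwells exponential with mean ``mean_dwell``.  Epoch
    boundaries are quantized to the frame grid.  Returns the
    IntensityTrace and the list of true (start_frame, end_frame) bound
    epochs (end exclusive).
    """
    if mean_dwell <= 0:
        raise ValueError("mean_dwell must be > 0")
    if on_rate < 0:
        raise ValueError("on_rate must be >= 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    n_frames = int(round(duration / frame_interval))
    donor = np.zeros(n_frames)
    acceptor = np.zeros(n_frames)
    events = []
    f = 0
    while f < n_frames:
        if on_rate == 0:
            break
        wait = rng.exponential(1.0 / on_rate)
        f += max(1, int(round(wait / frame_interval)))
        if f >= n_frames:
            break
        dwell = rng.exponential(mean_dwell)
        end = min(n_frames, f + max(1, int(round(dwell / frame_interval))))
        donor[f:end] = bright_total * (1.0 - efficiency)
        acceptor[f:end] = bright_total * efficiency
        events.append((f, end))
        f = end
    if noise_sd > 0:
        donor = donor + rng.normal(0, noise_sd, n_frames)
        acceptor = acceptor + rng.normal(0, noise_sd, n_frames)
    trace = IntensityTrace({"donor": donor, "acceptor1": acceptor},
                           frame_interval=frame_interval,
                           molecule_id=molecule_id)
    return trace, events
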