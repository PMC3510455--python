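"""In-memory trace containers shared by simulators and analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

#: Storage clip range for noisy apparent FRET efficiencies.
STORE_CLIP = (-0.2, 1.2)
#: Clip range applied when histogramming efficiencies.
HIST_CLIP = (0.0, 1.0)


@dataclass
class IntensityTrace:
    """Per-frame channel intensities for one molecule.

    ``channels`` maps channel name ("donor", "acceptor1", optionally
    "acceptor2") to an equal-length float array in arbitrary units.
    """

    channels: Dict[str, np.ndarray]
    frame_interval: float = 0.030
    molecule_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not self.channels:
            raise ValueError("at least one channel required")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def channel_names(self) -> tuple:
        return tuple(self.channels)

    def total_intensity(self) -> np.ndarray:
        """Per-frame sum over all channels."""
        return np.sum(list(self.channels.values()), axis=0)

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class FretTrace:
    """Per-frame FRET efficiency series (one per acceptor) for one molecule."""

    efficiencies: Dict[str, np.ndarray]
    frame_interval: float = 0.030
    molecule_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not self.efficiencies:
            raise ValueError("at least one efficiency series required")
        self.efficiencies = {
            k: np.asarray(v, dtype=float) for k, v in self.efficiencies.items()
        }
        lengths = {len(v) for v in self.efficiencies.values()}
        if len(lengths) != 1:
            raise ValueError("all efficiency series must have equal length")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.efficiencies.values())))

    def clipped(self, mode: str = "store") -> "FretTrace":
        """Return a copy with efficiencies clipped.

        ``mode='store'`` clips to [-0.2, 1.2] (keeps noise excursions
        visible); ``mode='hist'`` clips to [0, 1] for histogramming.
        """
        lo, hi = STORE_CLIP if mode == "store" else HIST_CLIP
        return FretTrace(
            {k: np.clip(v, lo, hi) for k, v in self.efficiencies.items()},
            frame_interval=self.frame_interval,
            molecule_id=self.molecule_id,
            metadata=dict(self.metadata),
        )
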