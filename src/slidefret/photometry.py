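"""Channel corrections and FRET efficiency computation.

Correction order follows standard smFRET practice: per-channel background
subtraction, then leakage subtraction (donor -> acceptor1, acceptor1 ->
acceptor2), then the gamma factor scaling of the far-red acceptor channel.
Gamma is the ratio of the acceptor-1 to acceptor-2 intensity changes
across an acceptor-2 photobleaching step, gamma = dI_A1 / dI_A2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .traces import FretTrace, IntensityTrace


@dataclass
class CorrectionSet:
    """Background, leakage and gamma corrections for one emission pathway."""

    background: Dict[str, float] = field(default_factory=dict)
    leakage_donor_to_a1: float = 0.0
    leakage_a1_to_a2: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for frac in (self.leakage_donor_to_a1, self.leakage_a1_to_a2):
            if not 0 <= frac < 1:
                raise ValueError("leakage fractions must be in [0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


#: Typical dual-view leakage defaults (configurable everywhere).
DEFAULT_CORRECTIONS = CorrectionSet(
    leakage_donor_to_a1=0.12, leakage_a1_to_a2=0.05
)


def apply_corrections(trace: IntensityTrace, corr: CorrectionSet) -> IntensityTrace:
    """Background -> leakage -> gamma, in that order."""
    chans = {k: v.copy() for k, v in trace.channels.items()}
    for name, bg in corr.background.items():
        if name not in chans:
            raise KeyError(f"background given for missing channel {name!r}")
        chans[name] -= bg
    if corr.leakage_donor_to_a1:
        if "acceptor1" not in chans or "donor" not in chans:
            raise KeyError("donor->acceptor1 leakage needs both channels")
        chans["acceptor1"] = chans["acceptor1"] - corr.leakage_donor_to_a1 * chans["donor"]
    if corr.leakage_a1_to_a2:
        if "acceptor2" not in chans or "acceptor1" not in chans:
            raise KeyError("acceptor1->acceptor2 leakage needs both channels")
        chans["acceptor2"] = chans["acceptor2"] - corr.leakage_a1_to_a2 * chans["acceptor1"]
    if "acceptor2" in chans and corr.gamma != 1.0:
        chans["acceptor2"] = corr.gamma * chans["acceptor2"]
    return IntensityTrace(chans, frame_interval=trace.frame_interval,
                          molecule_id=trace.molecule_id,
                          metadata=dict(trace.metadata))


def estimate_gamma(trace: IntensityTrace, channel: str = "acceptor2",
                   reference: str = "acceptor1", window: int = 20,
                   min_step_sigma: float = 5.0) -> float:
    """Gamma from an acceptor-2 photobleach step.

    Finds the largest single-frame drop in the ``channel`` series; it must
    exceed ``min_step_sigma`` times a robust (MAD-based) noise SD, else no
    step is declared.  Pre/post means over up to ``window`` frames on each
    side give the signed intensity changes, and
    gamma = |dI_reference| / |dI_channel|.
    """
    a2 = trace.channels[channel]
    a1 = trace.channels[reference]
    diffs = np.diff(a2)
    step = int(np.argmin(diffs))  # largest drop
    noise_sd = stats.median_abs_deviation(diffs, scale="normal")
    if noise_sd > 0 and -diffs[step] < min_step_sigma * noise_sd:
        raise ValueError("no photobleaching step detected in acceptor2")
    lo = max(0, step - window + 1)
    hi = min(len(a2), step + 1 + window)
    pre = slice(lo, step + 1)
    post = slice(step + 1, hi)
    d_a2 = a2[pre].mean() - a2[post].mean()
    d_a1 = a1[pre].mean() - a1[post].mean()
    if d_a2 == 0:
        raise ValueError("acceptor2 intensity change across the step is zero")
    return abs(d_a1) / abs(d_a2)


def fret_efficiencies(trace: IntensityTrace) -> FretTrace:
    """Per-frame E_i = I_A,i / (sum_A I_A + I_D) for each acceptor channel.

    Frames with non-positive total intensity are flagged invalid (NaN)
    and their indices recorded under ``metadata['invalid_frames']``.
    """
    if "donor" not in trace.channels:
        raise KeyError("donor channel required")
    acceptors = [k for k in trace.channel_names if k.startswith("acceptor")]
    if not acceptors:
        raise KeyError("at least one acceptor channel required")
    total = trace.total_intensity()
    invalid = total <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        effs = {
            f"efret{i + 1}": np.where(invalid, np.nan, trace.channels[a] / total)
            for i, a in enumerate(sorted(acceptors))
        }
    return FretTrace(effs, frame_interval=trace.frame_interval,
                     molecule_id=trace.molecule_id,
                     metadata={**trace.metadata,
                               "invalid_frames": np.flatnonzero(invalid)})


def pearson_correlation(e1: np.ndarray, e2: np.ndarray) -> float:
    """Pearson r between two equal-length efficiency series (NaNs dropped)."""
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if len(e1) != len(e2):
        raise ValueError("series must have equal length")
    ok = ~(np.isnan(e1) | np.isnan(e2))
    e1, e2 = e1[ok], e2[ok]
    if len(e1) < 3:
        raise ValueError("need at least 3 paired points")
    if np.std(e1) == 0 or np.std(e2) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(e1, e2).statistic)


class IntensityCorrector(TransformerMixin, BaseEstimator):
    """sklearn-style transformer applying the full correction chain.

    Parameters mirror :class:`CorrectionSet`; ``gamma='auto'`` estimates
    the gamma factor during :meth:`fit` from the first trace showing an
    acceptor-2 photobleach step.
    """

    def __init__(self, background=None, leakage_donor_to_a1: float = 0.0,
                 leakage_a1_to_a2: float = 0.0,
                 gamma: Union[float, str] = 1.0):
        self.background = background
        self.leakage_donor_to_a1 = leakage_donor_to_a1
        self.leakage_a1_to_a2 = leakage_a1_to_a2
        self.gamma = gamma

    def fit(self, X: Sequence[IntensityTrace], y=None):
        if self.gamma == "auto":
            err = None
            for trace in X:
                if "acceptor2" not in trace.channels:
                    continue
                try:
                    self.gamma_ = estimate_gamma(trace)
                    break
                except ValueError as e:  # no step in this trace
                    err = e
            else:
                raise ValueError(f"gamma='auto' but no usable bleach step: {err}")
        else:
            self.gamma_ = float(self.gamma)
        self.corrections_ = CorrectionSet(
            background=dict(self.background or {}),
            leakage_donor_to_a1=self.leakage_donor_to_a1,
            leakage_a1_to_a2=self.leakage_a1_to_a2,
            gamma=self.gamma_,
        )
        return self

    def transform(self, X: Sequence[IntensityTrace]) -> List[IntensityTrace]:
        if not hasattr(self, "corrections_"):
            raise RuntimeError("IntensityCorrector is not fitted")
        return [apply_corrections(t, self.corrections_) for t in X]
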