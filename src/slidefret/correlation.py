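"""Cross-correlation kinetics and dwell-time analysis.

The normalized cross-correlation

    CC(tau) = < da(t) * db(t + tau) > / (SD(a) * SD(b))

of donor and acceptor intensity traces (or of two FRET efficiency series)
decays on the timescale of the distance fluctuations; fitting
A * exp(-tau_lag / tau) to |CC| (lag 0 excluded) gives the
cross-correlation time tau_xcorr.  Binding events are maximal
above-threshold runs of the total intensity; bound-state dwell times are
fit by the exponential maximum-likelihood estimator with optional right
censoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .traces import IntensityTrace


@dataclass
class CCResult:
    """Cross-correlation curve with an optional exponential fit."""

    lags: np.ndarray          # seconds, starting at 0
    cc: np.ndarray
    frame_interval: float
    n_molecules: int = 1
    tau: Optional[float] = None
    amplitude: Optional[float] = None


@dataclass
class BindingEvent:
    """One above-threshold run: [start_frame, end_frame) at dwell seconds."""

    start_frame: int
    end_frame: int
    dwell: float

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")


def cross_correlate(a: np.ndarray, b: np.ndarray, frame_interval: float,
                    max_lag: float = 1.0) -> CCResult:
    """Normalized cross-correlation of two series up to ``max_lag`` seconds.

    Negative at short lags for anticorrelated donor/acceptor pairs and
    approaching 0 at long lags.  CC(0) of a series with itself is 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("series must have equal length")
    n_lags = int(round(max_lag / frame_interval))
    if len(a) < 10 * max(n_lags, 1):
        raise ValueError("series too short for the requested max_lag")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero variance")
    da, db = a - a.mean(), b - b.mean()
    n = len(a)
    cc = np.empty(n_lags + 1)
    for k in range(n_lags + 1):
        cc[k] = np.mean(da[: n - k] * db[k:]) / (sa * sb)
    lags = np.arange(n_lags + 1) * frame_interval
    return CCResult(lags=lags, cc=cc, frame_interval=frame_interval)


def average_cc(results: Sequence[CCResult]) -> CCResult:
    """Equal-weight arithmetic mean of per-molecule correlation curves."""
    if not results:
        raise ValueError("no curves to average")
    lags = results[0].lags
    for r in results[1:]:
        if len(r.lags) != len(lags):
            raise ValueError("curves have mismatched lag grids")
    cc = np.mean([r.cc for r in results], axis=0)
    return CCResult(lags=lags.copy(), cc=cc,
                    frame_interval=results[0].frame_interval,
                    n_molecules=sum(r.n_molecules for r in results))


def fit_cc_exponential(cc: CCResult, noise_floor_sigma: float = 3.0
                       ) -> Tuple[float, float]:
    """Fit A * exp(-t / tau) to |CC| excluding lag 0.

    Returns (tau, amplitude) and stores them on the result.  Raises if
    the curve carries no decay (flat zero), the fit fails to converge,
    or the fitted decay at the first lag does not rise above
    ``noise_floor_sigma`` times the tail noise level (a sub-frame
    decorrelation leaves only the statistical noise floor, from which no
    correlation time can be read).
    """
    t = cc.lags[1:]
    y = np.abs(cc.cc[1:])
    if len(t) < 5:
        raise ValueError("need at least 5 nonzero lags")
    if np.all(y == 0):
        raise ValueError("flat zero correlation: nothing to fit")
    a0 = max(y[0], 1e-6)
    # crude initial tau from the first sub-1/e crossing
    below = np.flatnonzero(y < a0 / np.e)
    tau0 = t[below[0]] if len(below) else t[-1]

    def _fit(tt, yy, p0):
        try:
            popt, _ = curve_fit(
                lambda x, A, tau: A * np.exp(-x / tau), tt, yy, p0=p0,
                bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=10000,
            )
        except RuntimeError as e:
            raise ValueError(
                f"cross-correlation fit did not converge: {e}"
            ) from e
        return float(popt[0]), float(popt[1])

    amplitude, tau = _fit(t, y, [a0, max(tau0, cc.frame_interval / 10)])
    # refit over a window of ~5 tau: lags far beyond the decay carry only
    # the noise floor, which biases tau upward when included
    for _ in range(2):
        n_win = int(np.clip(round(5 * tau / cc.frame_interval), 8, len(t)))
        if n_win == len(t):
            break
        amplitude, tau = _fit(t[:n_win], y[:n_win], [amplitude, tau])
    tail = y[-max(len(y) // 4, 2):]
    floor = float(np.std(tail))
    first_lag_value = amplitude * np.exp(-t[0] / tau)
    if floor > 0 and first_lag_value < noise_floor_sigma * floor:
        raise ValueError(
            "correlation amplitude below the noise floor: decay unresolved"
        )
    cc.amplitude, cc.tau = amplitude, tau
    return cc.tau, cc.amplitude


def detect_binding_events(trace: IntensityTrace,
                          threshold: Optional[float] = None,
                          min_frames: int = 2) -> List[BindingEvent]:
    """Maximal runs of total intensity above threshold, >= ``min_frames``.

    When ``threshold`` is None, background statistics are taken from the
    frames below the midpoint of the intensity range, and the threshold
    is background mean + 4 background SD.
    """
    total = trace.total_intensity()
    if threshold is None:
        midpoint = 0.5 * (total.min() + total.max())
        bg = total[total <= midpoint]
        if len(bg) == 0 or bg.std() == 0:
            threshold = midpoint
        else:
            threshold = bg.mean() + 4.0 * bg.std()
    above = total > threshold
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(total))
    events = []
    for s, e in zip(starts, ends):
        if e - s >= min_frames:
            events.append(BindingEvent(s, e, (e - s) * trace.frame_interval))
    return events


def fit_dwell_exponential(dwells: Sequence[float],
                          censored: Optional[Sequence[bool]] = None
                          ) -> Tuple[float, float]:
    """Exponential MLE of the mean dwell, with right censoring.

    The MLE is (sum of all durations) / (number of uncensored events);
    right-censored dwells (e.g. cut short by photobleaching or the end of
    the movie) contribute their observed duration to the numerator only.
    Returns (mean, SE) with SE = mean / sqrt(n_uncensored).
    """
    dwells = np.asarray(dwells, dtype=float)
    if censored is None:
        censored = np.zeros(len(dwells), dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    n_unc = int((~censored).sum())
    if n_unc == 0:
        raise ValueError("all dwells censored: mean unidentifiable")
    if n_unc < 10:
        raise ValueError("need at least 10 uncensored dwells")
    mean = dwells.sum() / n_unc
    return float(mean), float(mean / np.sqrt(n_unc))
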