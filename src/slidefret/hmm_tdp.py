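"""HMM idealization of FRET traces, transition density plots, and
transition-rate / recognition-efficiency statistics.

A single Gaussian-emission HMM is fit to all molecules pooled (tied
emission parameters), then each trace is idealized by Viterbi decoding.
Transitions between idealized states feed a transition density plot
(2D histogram of FRET before vs after), per-pair rates
k(i->j) = N(i->j) / time-in-i, and the homology-recognition efficiency
N(NH->HS2) / (N(NH->HS2) + N(NH->HS1)) for the three-state scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from hmmlearn.hmm import GaussianHMM
from hmmlearn.base import ConvergenceMonitor
from sklearn.base import BaseEstimator

from .traces import FretTrace


class _HistoryMonitor(ConvergenceMonitor):
    """Convergence monitor that retains the full log-likelihood history."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: List[float] = []

    def report(self, log_prob):
        self.full_history.append(log_prob)
        super().report(log_prob)


def _series(trace) -> np.ndarray:
    if isinstance(trace, FretTrace):
        return next(iter(trace.efficiencies.values()))
    return np.asarray(trace, dtype=float)


class FretHmm(BaseEstimator):
    """Pooled Gaussian-emission HMM over FRET traces (sklearn estimator).

    ``fit`` runs EM on all traces concatenated; fitted attributes are
    ``means_`` (ascending), ``sds_``, ``transmat_``, ``startprob_`` and
    ``loglik_history_``.  A state collapsing below ``min_sd`` triggers a
    restart from a perturbed initialization (up to ``max_restarts``).
    """

    def __init__(self, n_states: int = 3, max_iter: int = 200,
                 tol: float = 1e-4, min_sd: float = 1e-3,
                 max_restarts: int = 5, random_state: Optional[int] = None):
        self.n_states = n_states
        self.max_iter = max_iter
        self.tol = tol
        self.min_sd = min_sd
        self.max_restarts = max_restarts
        self.random_state = random_state

    def _initial_means(self, x: np.ndarray, rng, attempt: int) -> np.ndarray:
        q = (np.arange(self.n_states) + 0.5) / self.n_states
        means = np.quantile(x, q)
        if attempt > 0:
            means = means + rng.normal(0, 0.05 * np.ptp(x), self.n_states)
        return np.sort(means)

    def fit(self, X: Sequence, y=None):
        traces = [_series(t) for t in (X if isinstance(X, (list, tuple)) else [X])]
        if not traces:
            raise ValueError("need at least one trace")
        x = np.concatenate(traces)
        lengths = [len(t) for t in traces]
        if len(x) < 50 * self.n_states:
            raise ValueError("too few frames to fit the requested states")
        rng = np.random.default_rng(self.random_state)
        last_err = None
        for attempt in range(self.max_restarts + 1):
            model = GaussianHMM(
                n_components=self.n_states, covariance_type="diag",
                n_iter=self.max_iter, tol=self.tol,
                init_params="", params="stmc",
                random_state=int(rng.integers(2**31)),
            )
            model.monitor_ = _HistoryMonitor(model.tol, model.n_iter)
            means = self._initial_means(x, rng, attempt)
            model.means_ = means.reshape(-1, 1)
            model.covars_ = np.full((self.n_states, 1), max(x.var() / 4, 1e-4))
            model.startprob_ = np.full(self.n_states, 1.0 / self.n_states)
            if self.n_states == 1:
                model.transmat_ = np.ones((1, 1))
            else:
                sticky = 0.95
                off = (1 - sticky) / (self.n_states - 1)
                model.transmat_ = np.full((self.n_states,) * 2, off)
                np.fill_diagonal(model.transmat_, sticky)
            model.fit(x.reshape(-1, 1), lengths)
            sds = np.sqrt(model.covars_.ravel())
            if np.all(sds >= self.min_sd):
                break
            last_err = f"state SD collapsed below {self.min_sd}"
        else:
            raise RuntimeError(f"HMM fit failed after restarts: {last_err}")
        order = np.argsort(model.means_.ravel())
        self.means_ = model.means_.ravel()[order]
        self.sds_ = sds[order]
        self.transmat_ = model.transmat_[np.ix_(order, order)]
        self.startprob_ = model.startprob_[order]
        self.loglik_history_ = list(model.monitor_.full_history)
        self._order = order
        self._model = model
        return self

    def predict(self, trace) -> np.ndarray:
        """Most-probable (Viterbi) state path, states relabeled ascending."""
        if not hasattr(self, "_model"):
            raise RuntimeError("FretHmm is not fitted")
        x = _series(trace).reshape(-1, 1)
        raw = self._model.predict(x)
        relabel = np.empty_like(self._order)
        relabel[self._order] = np.arange(len(self._order))
        return relabel[raw]


def fit_hmm(traces: Sequence, n_states: int = 3,
            seed: Optional[int] = None, **kwargs) -> FretHmm:
    """Fit a pooled Gaussian HMM; thin wrapper over :class:`FretHmm`."""
    return FretHmm(n_states=n_states, random_state=seed, **kwargs).fit(traces)


@dataclass
class Idealization:
    """Viterbi state path of one trace with its dwell segments."""

    states: np.ndarray                    # per-frame state index
    segments: List[Tuple[int, int, int]]  # (state, start_frame, n_frames)
    trace_id: str = ""

    @property
    def n_transitions(self) -> int:
        return max(len(self.segments) - 1, 0)


def segments_from_path(states: np.ndarray) -> List[Tuple[int, int, int]]:
    """Run-length encode a state path into (state, start, length) segments."""
    states = np.asarray(states)
    if len(states) == 0:
        return []
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(states)]])
    return [(int(states[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def idealize(model: FretHmm, trace, trace_id: str = "",
             min_dwell: Optional[int] = None) -> Idealization:
    """Viterbi-idealize one trace with a fitted model.

    ``min_dwell`` (frames) optionally removes shorter dwells by merging
    them into the preceding segment.  Camera integration turns a direct
    low<->high jump that lands mid-frame into an apparent one-frame visit
    to the intermediate state; filtering at 2 frames suppresses these
    spurious visits when extracting transition rates.  Default: retained.
    """
    if not trace_id and isinstance(trace, FretTrace):
        trace_id = trace.molecule_id
    states = model.predict(trace)
    if min_dwell is not None and min_dwell > 1:
        states = merge_short_dwells(states, min_dwell)
    return Idealization(states=states, segments=segments_from_path(states),
                        trace_id=trace_id)


def merge_short_dwells(states: np.ndarray, min_frames: int) -> np.ndarray:
    """Reassign dwells shorter than ``min_frames`` to the preceding state.

    Applied iteratively (shortest first) until every remaining dwell
    reaches the threshold or a single segment is left.
    """
    states = np.asarray(states).copy()
    while True:
        segs = segments_from_path(states)
        if len(segs) <= 1:
            return states
        lengths = [n for (_, _, n) in segs]
        i = int(np.argmin(lengths))
        if lengths[i] >= min_frames:
            return states
        target = segs[i - 1][0] if i > 0 else segs[i + 1][0]
        _, start, n = segs[i]
        states[start:start + n] = target


@dataclass
class TDP:
    """Transition density plot: 2D histogram of (E before, E after)."""

    hist: np.ndarray
    edges: np.ndarray
    n_transitions: int


def build_tdp(idealizations: Sequence[Idealization], model: FretHmm,
              bins: int = 50, traces: Optional[Sequence] = None) -> TDP:
    """Histogram every segment boundary at (E_before, E_after).

    Coordinates are the fitted state means by default; passing ``traces``
    (parallel to ``idealizations``) uses each segment's measured mean
    instead.  The diagonal is empty by construction since consecutive
    segments differ in state.
    """
    import warnings

    before, after = [], []
    for i, ideal in enumerate(idealizations):
        segs = ideal.segments
        data = _series(traces[i]) if traces is not None else None
        for (s0, f0, n0), (s1, f1, n1) in zip(segs[:-1], segs[1:]):
            if data is not None:
                before.append(data[f0:f0 + n0].mean())
                after.append(data[f1:f1 + n1].mean())
            else:
                before.append(model.means_[s0])
                after.append(model.means_[s1])
    edges = np.linspace(0.0, 1.0, bins + 1)
    if not before:
        warnings.warn("no transitions: TDP is empty")
        return TDP(hist=np.zeros((bins, bins)), edges=edges, n_transitions=0)
    hist, _, _ = np.histogram2d(np.clip(before, 0, 1), np.clip(after, 0, 1),
                                bins=[edges, edges])
    return TDP(hist=hist, edges=edges, n_transitions=len(before))


@dataclass
class TransitionStats:
    """Transition counts, occupancy times and per-second rates."""

    counts: np.ndarray        # N(i->j)
    occupancy: np.ndarray     # seconds spent in each state
    rates: np.ndarray         # k(i->j) = N(i->j)/occupancy[i]; NaN if unvisited
    state_names: Tuple[str, ...] = ()


def transition_stats(idealizations: Sequence[Idealization],
                     frame_interval: float, n_states: int,
                     state_names: Sequence[str] = ()) -> TransitionStats:
    """Pool transition counts and occupancies over all idealizations."""
    if not idealizations:
        raise ValueError("no idealizations given")
    counts = np.zeros((n_states, n_states))
    frames_in = np.zeros(n_states)
    for ideal in idealizations:
        for state, _, length in ideal.segments:
            frames_in[state] += length
        for (s0, _, _), (s1, _, _) in zip(ideal.segments[:-1], ideal.segments[1:]):
            counts[s0, s1] += 1
    occupancy = frames_in * frame_interval
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = counts / occupancy[:, None]
    rates[occupancy == 0] = np.nan  # unvisited state: rates undefined, not zero
    return TransitionStats(counts=counts, occupancy=occupancy, rates=rates,
                           state_names=tuple(state_names))


def recognition_efficiency(stats: TransitionStats, nh: int = 0,
                           near: int = 1, far: int = 2) -> float:
    """Fraction of NH exits that pair first at the nearer homology site.

    N(NH->HS2) / (N(NH->HS2) + N(NH->HS1)) with the default state order
    (NH, HS2, HS1) ascending in FRET.
    """
    n_near = stats.counts[nh, near]
    n_far = stats.counts[nh, far]
    total = n_near + n_far
    if total == 0:
        raise ValueError("no NH exits toward either homology site")
    return float(n_near / total)
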