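"""Calibration of the sliding diffusion coefficient.

Simulated traces at a grid of diffusion coefficients and filament lengths
yield a surface of cross-correlation times tau(D, L); an observed set of
tau values (one per filament length) is matched to the surface by least
squares in log tau, with log-linear interpolation in log D, giving the
estimated D_slide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .correlation import average_cc, cross_correlate, fit_cc_exponential
from .geometry import FilamentGeometry, FretCoupling, diffusion_um2_to_bp2
from .slide_sim import (SlideSimConfig, allowed_range, register_diffusion,
                        simulate_molecules)

_SEED_MAX = 2**31 - 1


@dataclass
class CalibrationTable:
    """tau_xcorr surface over (D, filament length)."""

    d_grid: np.ndarray          # um^2/s, ascending
    lengths: np.ndarray         # nt, ascending
    tau: np.ndarray             # (n_d, n_len) seconds
    se: np.ndarray              # same shape
    n_reps: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.d_grid = np.asarray(self.d_grid, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.tau.shape != (len(self.d_grid), len(self.lengths)):
            raise ValueError("tau shape must be (n_d, n_lengths)")

    def check_monotone(self) -> None:
        """tau must fall with D (each length) and rise with length (each D).

        Dropped cells (NaN, unresolvable decay) are skipped; ordering is
        checked on consecutive finite cells only.
        """
        def _descending(v):
            v = v[np.isfinite(v)]
            return np.all(np.diff(v) < 0)

        for j in range(self.tau.shape[1]):
            if not _descending(self.tau[:, j]):
                raise ValueError("tau not decreasing in D")
        for i in range(self.tau.shape[0]):
            if not _descending(self.tau[i, ::-1]):
                raise ValueError("tau not increasing in length")


def measure_cc_time(config: SlideSimConfig, geometry: FilamentGeometry,
                    coupling: FretCoupling, n_reps: int, seed: int,
                    max_lag: float,
                    enforce_resolution: bool = True) -> Tuple[float, float]:
    """tau of the molecule-averaged CC over fresh simulated molecules.

    SE comes from fits to 3 disjoint molecule subgroups.  With
    ``enforce_resolution`` a fitted tau below one frame interval is
    reported as NaN (dropped cell): such a decay completes between
    samples and its time constant is extrapolation, not measurement.
    """
    traces = simulate_molecules(config, geometry, n_reps, coupling, seed=seed)
    curves = [
        cross_correlate(t.channels["donor"], t.channels["acceptor1"],
                        t.frame_interval, max_lag)
        for t in traces
    ]
    try:
        tau, _ = fit_cc_exponential(average_cc(curves))
    except ValueError:
        return np.nan, np.nan  # unresolvable cell, reported as dropped
    if enforce_resolution and tau < config.frame_interval:
        # decay completes inside one camera frame: the fitted constant is
        # extrapolation below the sampling interval, not a measurement
        return np.nan, np.nan
    group_taus = []
    for g in range(3):
        sub = curves[g::3]
        if sub:
            try:
                gt, _ = fit_cc_exponential(average_cc(sub))
                group_taus.append(gt)
            except ValueError:
                pass
    se = float(np.std(group_taus) / np.sqrt(len(group_taus))) if len(group_taus) > 1 else np.nan
    return tau, se


def build_calibration_table(d_grid: Sequence[float], lengths: Sequence[float],
                            config: Optional[SlideSimConfig] = None,
                            geometry_kwargs: Optional[dict] = None,
                            coupling: Optional[FretCoupling] = None,
                            n_reps: int = 30, seed: int = 0,
                            max_lag: float = 1.0) -> CalibrationTable:
    """Simulate the tau(D, L) surface.

    Each cell averages the donor/acceptor cross-correlation over
    ``n_reps`` independent molecules and fits a single exponential.
    The monotonicity of the finished surface is asserted.
    """
    d_grid = np.sort(np.asarray(d_grid, dtype=float))
    lengths = np.sort(np.asarray(lengths, dtype=float))
    config = SlideSimConfig() if config is None else config
    coupling = FretCoupling() if coupling is None else coupling
    geometry_kwargs = geometry_kwargs or {}
    root = np.random.default_rng(seed)
    tau = np.empty((len(d_grid), len(lengths)))
    se = np.empty_like(tau)
    for i, d in enumerate(d_grid):
        for j, L in enumerate(lengths):
            geom = FilamentGeometry(filament_length=float(L),
                                    duplex_length=39.0, **geometry_kwargs)
            cell_cfg = SlideSimConfig(
                d_um2=float(d), step_size=config.step_size,
                frame_interval=config.frame_interval,
                n_frames=config.n_frames,
                total_intensity=config.total_intensity,
                noise_amplitude=config.noise_amplitude,
                min_overlap=config.min_overlap,
            )
            # resolution requirement: the trace must span many relaxation
            # times (tau_pred ~ X^2 / pi^2 D) and the lag window a few
            tau_pred = (allowed_range(cell_cfg, geom) ** 2
                        / (np.pi**2 * register_diffusion(cell_cfg, geom)))
            n_frames = max(config.n_frames,
                           int(np.ceil(50 * tau_pred / config.frame_interval)))
            if n_frames != cell_cfg.n_frames:
                cell_cfg.n_frames = n_frames
            lag_cap = (n_frames // 10 - 1) * config.frame_interval
            cell_lag = float(np.clip(5 * tau_pred,
                                     10 * config.frame_interval,
                                     min(max_lag * 10, lag_cap)))
            tau[i, j], se[i, j] = measure_cc_time(
                cell_cfg, geom, coupling, n_reps,
                int(root.integers(_SEED_MAX)), cell_lag,
            )
    table = CalibrationTable(d_grid=d_grid, lengths=lengths, tau=tau, se=se,
                             n_reps=n_reps,
                             config={"n_frames": config.n_frames,
                                     "frame_interval": config.frame_interval,
                                     "step_size": config.step_size,
                                     "noise_amplitude": config.noise_amplitude,
                                     "seed": seed})
    table.check_monotone()
    return table


@dataclass
class DEstimate:
    """Estimated diffusion coefficient with its surrounding grid bracket."""

    d_um2: float
    bracket: Tuple[float, float]
    residual: float

    @property
    def d_bp2(self) -> float:
        return diffusion_um2_to_bp2(self.d_um2)


def _log_tau_at(table: CalibrationTable, log_d: float) -> np.ndarray:
    """Log tau per length at log10 D, log-linearly interpolated on the grid.

    Dropped (NaN) cells are skipped.  Beyond a column's finite range the
    log-linear trend of the two nearest finite cells is extended: tau is
    monotone in D by construction (tau ~ 1/D), so the trend, not a flat
    clamp, is the physical continuation past an unresolved cell.
    """
    log_grid = np.log10(table.d_grid)
    out = np.empty(len(table.lengths))
    for j in range(len(table.lengths)):
        col = table.tau[:, j]
        ok = np.isfinite(col)
        if ok.sum() < 2:
            out[j] = np.nan
            continue
        xg, yg = log_grid[ok], np.log(col[ok])
        if log_d <= xg[0]:
            slope = (yg[1] - yg[0]) / (xg[1] - xg[0])
            out[j] = yg[0] + slope * (log_d - xg[0])
        elif log_d >= xg[-1]:
            slope = (yg[-1] - yg[-2]) / (xg[-1] - xg[-2])
            out[j] = yg[-1] + slope * (log_d - xg[-1])
        else:
            out[j] = np.interp(log_d, xg, yg)
    return out


def estimate_D(observed_lengths: Sequence[float], observed_tau: Sequence[float],
               table: CalibrationTable, margin: float = 0.25) -> DEstimate:
    """Match observed tau-per-length values to the calibration surface.

    Minimizes the sum of squared log-tau residuals over log D within the
    grid span; columns with dropped edge cells contribute their extended
    log-linear trend there.  An observed tau outside a length's surface
    range by more than ``margin`` in log space refuses extrapolation
    (smaller excursions are sampling scatter around an edge cell).
    """
    lengths = np.asarray(observed_lengths, dtype=float)
    taus = np.asarray(observed_tau, dtype=float)
    cols = []
    for L in lengths:
        j = np.flatnonzero(table.lengths == L)
        if len(j) == 0:
            raise ValueError(f"length {L} nt not in the calibration table")
        cols.append(int(j[0]))
    for tau_obs, j in zip(taus, cols):
        col = table.tau[:, j]
        ok = np.isfinite(col)
        if ok.sum() < 2:
            raise ValueError(
                f"length {table.lengths[j]:.0f} nt has fewer than 2 usable "
                "calibration cells"
            )
        lo, hi = col[ok].min(), col[ok].max()
        if not lo * np.exp(-margin) <= tau_obs <= hi * np.exp(margin):
            raise ValueError(
                f"observed tau {tau_obs:.4g}s outside table range "
                f"[{lo:.4g}, {hi:.4g}] for length {table.lengths[j]:.0f} nt: "
                "extrapolation refused"
            )
    log_obs = np.log(taus)

    def objective(log_d: float) -> float:
        pred = _log_tau_at(table, log_d)[cols]
        return float(np.nansum((pred - log_obs) ** 2))

    log_lo, log_hi = np.log10(table.d_grid[0]), np.log10(table.d_grid[-1])
    res = minimize_scalar(objective, bounds=(log_lo, log_hi), method="bounded",
                          options={"xatol": 1e-10})
    d_hat = 10 ** res.x
    idx = np.searchsorted(table.d_grid, d_hat)
    lo = table.d_grid[max(idx - 1, 0)]
    hi = table.d_grid[min(idx, len(table.d_grid) - 1)]
    return DEstimate(d_um2=float(d_hat), bracket=(float(lo), float(hi)),
                     residual=float(res.fun))


class SlidingDiffusionEstimator(BaseEstimator):
    """sklearn-style estimator wrapping the calibration workflow.

    ``fit`` builds (or adopts) the simulated tau(D, L) surface;
    ``predict`` maps observed (length, tau) pairs to the estimated
    diffusion coefficient in um^2/s.
    """

    def __init__(self, d_grid=(0.09e-3, 0.9e-3, 9e-3),
                 lengths=(21, 39, 69, 99), n_reps: int = 30,
                 n_frames: int = 1000, step_size: float = 0.1,
                 noise_amplitude: float = 40.0, max_lag: float = 1.0,
                 random_state: int = 0):
        self.d_grid = d_grid
        self.lengths = lengths
        self.n_reps = n_reps
        self.n_frames = n_frames
        self.step_size = step_size
        self.noise_amplitude = noise_amplitude
        self.max_lag = max_lag
        self.random_state = random_state

    def fit(self, X=None, y=None, table: Optional[CalibrationTable] = None):
        """Build the calibration surface (or adopt a prebuilt ``table``)."""
        if table is not None:
            self.table_ = table
        else:
            cfg = SlideSimConfig(step_size=self.step_size,
                                 n_frames=self.n_frames,
                                 noise_amplitude=self.noise_amplitude)
            self.table_ = build_calibration_table(
                self.d_grid, self.lengths, config=cfg, n_reps=self.n_reps,
                seed=self.random_state, max_lag=self.max_lag,
            )
        return self

    def predict(self, X) -> DEstimate:
        """X: array-like of shape (n_lengths, 2) with columns (length, tau)."""
        if not hasattr(self, "table_"):
            raise RuntimeError("SlidingDiffusionEstimator is not fitted")
        X = np.asarray(X, dtype=float)
        return estimate_D(X[:, 0], X[:, 1], self.table_)
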