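"""Delimited-text serialization of traces, idealizations, TDPs and
calibration tables, plus the reproducible end-to-end pipeline.

The canonical trace format is tab-separated text with ``# key = value``
metadata header lines (frame_interval, kind, channels, free-form
``meta:`` entries) and one row per (molecule, frame).  Text keeps every
artifact human-diffable and language-neutral; values round-trip at full
precision via the shortest-repr float format.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationTable
from .hmm_tdp import TDP, Idealization, segments_from_path
from .traces import FretTrace, IntensityTrace

logger = logging.getLogger("slidefret")

MAGIC = "# slidefret-trace v1"


def _parse_header(path: Path) -> Tuple[dict, int]:
    meta = {}
    n = 0
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != MAGIC:
            raise ValueError(f"{path}: not a slidefret trace file")
        n = 1
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta, n


def write_traces(traces: Sequence[Union[IntensityTrace, FretTrace]],
                 path, extra_meta: Optional[dict] = None) -> None:
    """Serialize traces (all of one kind) to the delimited-text format."""
    path = Path(path)
    if not traces:
        raise ValueError("no traces to write")
    first = traces[0]
    is_fret = isinstance(first, FretTrace)
    kind = "fret" if is_fret else "intensity"
    cols = sorted(first.efficiencies if is_fret else first.channels)
    rows = []
    for t in traces:
        data = t.efficiencies if is_fret else t.channels
        if sorted(data) != cols:
            raise ValueError("traces have inconsistent channel sets")
        df = pd.DataFrame({c: data[c] for c in cols})
        df.insert(0, "frame", np.arange(t.n_frames))
        df.insert(0, "molecule_id", t.molecule_id)
        rows.append(df)
    body = pd.concat(rows, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(MAGIC + "\n")
        fh.write(f"# frame_interval = {first.frame_interval!r}\n")
        fh.write(f"# kind = {kind}\n")
        fh.write(f"# channels = {','.join(cols)}\n")
        fh.write(f"# version = {__version__}\n")
        for k, v in (extra_meta or {}).items():
            fh.write(f"# meta:{k} = {v}\n")
        body.to_csv(fh, sep="\t", index=False)


def read_traces(path) -> List[Union[IntensityTrace, FretTrace]]:
    """Read a trace file back into IntensityTrace/FretTrace objects."""
    path = Path(path)
    meta, n_header = _parse_header(path)
    for key in ("frame_interval", "kind", "channels"):
        if key not in meta:
            raise ValueError(f"{path}: malformed header, missing {key!r}")
    frame_interval = float(meta["frame_interval"])
    channels = meta["channels"].split(",")
    df = pd.read_csv(path, sep="\t", skiprows=n_header,
                     float_precision="round_trip")
    if df.empty:
        warnings.warn(f"{path}: empty trace file")
        return []
    missing = set(channels) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: declared channels missing from body: {missing}")
    extra = dict(
        (k[5:], v) for k, v in meta.items() if k.startswith("meta:")
    )
    out: List[Union[IntensityTrace, FretTrace]] = []
    for mol, grp in df.groupby("molecule_id", sort=False):
        frames = grp["frame"].to_numpy()
        if len(np.unique(frames)) != len(frames):
            raise ValueError(f"{path}: duplicate (molecule, frame) for {mol}")
        if not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
            raise ValueError(f"{path}: non-contiguous frames for {mol}")
        data = {c: grp[c].to_numpy(dtype=float) for c in channels}
        if meta["kind"] == "fret":
            out.append(FretTrace(data, frame_interval=frame_interval,
                                 molecule_id=str(mol), metadata=dict(extra)))
        else:
            out.append(IntensityTrace(data, frame_interval=frame_interval,
                                      molecule_id=str(mol), metadata=dict(extra)))
    return out


def write_idealizations(ideals: Sequence[Idealization], path,
                        frame_interval: float) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# slidefret-ideal v1\n")
        fh.write(f"# frame_interval = {frame_interval!r}\n")
        rows = []
        for ideal in ideals:
            df = pd.DataFrame({"state": ideal.states})
            df.insert(0, "frame", np.arange(len(ideal.states)))
            df.insert(0, "molecule_id", ideal.trace_id)
            rows.append(df)
        pd.concat(rows, ignore_index=True).to_csv(fh, sep="\t", index=False)


def read_idealizations(path) -> List[Idealization]:
    path = Path(path)
    with open(path) as fh:
        if fh.readline().rstrip("\n") != "# slidefret-ideal v1":
            raise ValueError(f"{path}: not an idealization file")
        n = 1
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
    df = pd.read_csv(path, sep="\t", skiprows=n,
                     float_precision="round_trip")
    out = []
    for mol, grp in df.groupby("molecule_id", sort=False):
        states = grp["state"].to_numpy(dtype=int)
        out.append(Idealization(states=states,
                                segments=segments_from_path(states),
                                trace_id=str(mol)))
    return out


def write_calibration_table(table: CalibrationTable, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# slidefret-calibration v1\n")
        fh.write(f"# n_reps = {table.n_reps}\n")
        fh.write(f"# config = {json.dumps(table.config)}\n")
        rows = []
        for i, d in enumerate(table.d_grid):
            for j, L in enumerate(table.lengths):
                rows.append((d, L, table.tau[i, j], table.se[i, j]))
        pd.DataFrame(rows, columns=["d_um2", "length_nt", "tau_s", "se_s"]) \
            .to_csv(fh, sep="\t", index=False)


def read_calibration_table(path) -> CalibrationTable:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        if fh.readline().rstrip("\n") != "# slidefret-calibration v1":
            raise ValueError(f"{path}: not a calibration table")
        n = 1
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", skiprows=n,
                     float_precision="round_trip")
    d_grid = np.sort(df["d_um2"].unique())
    lengths = np.sort(df["length_nt"].unique())
    tau = np.empty((len(d_grid), len(lengths)))
    se = np.empty_like(tau)
    for _, row in df.iterrows():
        i = int(np.flatnonzero(d_grid == row["d_um2"])[0])
        j = int(np.flatnonzero(lengths == row["length_nt"])[0])
        tau[i, j] = row["tau_s"]
        se[i, j] = row["se_s"]
    return CalibrationTable(
        d_grid=d_grid, lengths=lengths, tau=tau, se=se,
        n_reps=int(meta.get("n_reps", 0)),
        config=json.loads(meta["config"]) if "config" in meta else {},
    )


def write_tdp(tdp: TDP, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# slidefret-tdp v1\n")
        fh.write(f"# n_transitions = {tdp.n_transitions}\n")
        fh.write(f"# edges = {','.join(repr(float(e)) for e in tdp.edges)}\n")
        np.savetxt(fh, tdp.hist, delimiter="\t", fmt="%.17g")


def read_tdp(path) -> TDP:
    path = Path(path)
    meta = {}
    n = 0
    with open(path) as fh:
        if fh.readline().rstrip("\n") != "# slidefret-tdp v1":
            raise ValueError(f"{path}: not a TDP file")
        n = 1
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    hist = np.loadtxt(path, delimiter="\t", skiprows=n)
    edges = np.array([float(e) for e in meta["edges"].split(",")])
    return TDP(hist=hist, edges=edges,
               n_transitions=int(meta.get("n_transitions", int(hist.sum()))))


@dataclass
class RunConfig:
    """Resolved configuration of a full simulate -> calibrate pipeline run."""

    d_true: float = 0.9e-3
    d_grid: Sequence[float] = (0.09e-3, 0.9e-3, 9e-3)
    lengths: Sequence[float] = (21, 39, 69, 99)
    n_molecules: int = 30
    n_frames: int = 1000
    step_size: float = 0.1
    noise_amplitude: float = 40.0
    max_lag: float = 1.0
    seed: int = 0
    out_dir: str = "slidefret_run"

    def __post_init__(self) -> None:
        self.d_grid = tuple(float(d) for d in self.d_grid)
        self.lengths = tuple(float(L) for L in self.lengths)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["d_grid"] = list(out["d_grid"])
        out["lengths"] = list(out["lengths"])
        return out


def run_pipeline(config: RunConfig) -> Path:
    """Simulate -> correct -> cross-correlate -> calibrate, end to end.

    Simulates traces at ``d_true`` for every filament length, measures
    their cross-correlation times, builds the calibration surface over
    ``d_grid`` and inverts it, writing every artifact plus the resolved
    config into ``out_dir``.  Deterministic given (config, seed).
    """
    from .calibration import build_calibration_table, estimate_D
    from .correlation import average_cc, cross_correlate, fit_cc_exponential
    from .geometry import FilamentGeometry
    from .photometry import CorrectionSet, apply_corrections
    from .slide_sim import SlideSimConfig, simulate_molecules

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(config.seed)
    sim_cfg = SlideSimConfig(d_um2=config.d_true, step_size=config.step_size,
                             n_frames=config.n_frames,
                             noise_amplitude=config.noise_amplitude)
    identity = CorrectionSet()
    observed = []
    all_traces = []
    for L in config.lengths:
        geom = FilamentGeometry(filament_length=float(L), duplex_length=39.0)
        traces = simulate_molecules(sim_cfg, geom, config.n_molecules,
                                    seed=int(root.integers(2**31)))
        traces = [apply_corrections(t, identity) for t in traces]
        all_traces.extend(traces)
        curves = [
            cross_correlate(t.channels["donor"], t.channels["acceptor1"],
                            t.frame_interval, config.max_lag)
            for t in traces
        ]
        tau, _ = fit_cc_exponential(average_cc(curves))
        observed.append((float(L), tau))
        logger.info("stage=observe length=%s molecules=%d tau=%.4f",
                    L, len(traces), tau)
    write_traces(all_traces, out / "traces.tsv",
                 extra_meta={"d_true": config.d_true})
    pd.DataFrame(observed, columns=["length_nt", "tau_s"]).to_csv(
        out / "observed.tsv", sep="\t", index=False)
    table = build_calibration_table(
        config.d_grid, config.lengths, config=sim_cfg,
        n_reps=config.n_molecules, seed=int(root.integers(2**31)),
        max_lag=config.max_lag,
    )
    write_calibration_table(table, out / "table.tsv")
    est = estimate_D([o[0] for o in observed], [o[1] for o in observed], table)
    logger.info("stage=calibrate d_hat=%.3g bracket=%s", est.d_um2, est.bracket)
    with open(out / "dhat.json", "w") as fh:
        json.dump({"d_um2": est.d_um2, "d_bp2": est.d_bp2,
                   "bracket": list(est.bracket), "residual": est.residual},
                  fh, indent=2)
    resolved = {"config": config.to_dict(), "version": __version__}
    with open(out / "resolved_config.json", "w") as fh:
        json.dump(resolved, fh, indent=2)
    return out
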