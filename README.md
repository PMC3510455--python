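# slidefret

Simulation and kinetic analysis of one-dimensional sliding of double-stranded
DNA along RecA nucleoprotein filaments, as observed by single-molecule FRET.

During homologous recombination a RecA filament assembled on ssDNA must locate
a matching sequence in a vast excess of heterologous dsDNA. One proposed
accelerant is 1D sliding: the captured duplex diffuses along the filament axis
between binding and dissociation, scanning hundreds of base pairs per
encounter. In smFRET experiments this sliding appears as rapid anticorrelated
donor/acceptor intensity fluctuations whose cross-correlation time
τ<sub>xcorr</sub> reports the diffusion timescale; embedding short homology
repeats turns the same assay into a real-time homology-recognition readout
with discrete FRET states.

`slidefret` packages the computational machinery of such a study:

- **`slide_sim`** — Monte Carlo simulator of free 1D diffusion of a duplex
  along a rigid filament (register random walk at micro time step
  τ = δ²/2D, reflecting boundaries), rendered as binned, noisy two- or
  three-color intensity traces with a fixed 500 a.u. photon budget per 30 ms
  frame. The distance → efficiency map is
  L = √(r² + (d·|x−x₀|)²) with d = 5.1 Å per nucleotide of the stretched
  filament, followed by the Förster relation E = 1/(1+(L/R₀)⁶).
- **`state_sim`** — continuous-time Markov generator of homology-recognition
  traces over the NH/HS2/HS1 states (FRET means ≈ 0.1/0.5/0.9) and
  docking/dissociation event streams for dwell-time analysis.
- **`photometry`** — background/leakage/γ corrections
  (γ = ΔI<sub>A1</sub>/ΔI<sub>A2</sub> across an acceptor-2 photobleach step)
  and per-frame efficiencies E<sub>i</sub> = I<sub>A,i</sub>/(ΣI<sub>A</sub>+I<sub>D</sub>).
- **`correlation`** — normalized donor/acceptor cross-correlation, single
  exponential fits yielding τ<sub>xcorr</sub>, binding-event detection, and
  the censoring-aware exponential dwell-time MLE.
- **`calibration`** — the τ(D, L<sub>filament</sub>) calibration surface and
  its inversion to the sliding diffusion coefficient D<sub>slide</sub>
  (sklearn-style `SlidingDiffusionEstimator`).
- **`hmm_tdp`** — pooled Gaussian-emission HMM idealization (`FretHmm`),
  transition density plots, transition rates k(i→j) = N(i→j)/t<sub>i</sub>,
  and the recognition efficiency
  E<sub>recognition</sub> = N(NH→HS2)/(N(NH→HS2)+N(NH→HS1)).
- **`search_model`** — per-encounter sliding length s = √(Dt) and the
  facilitated-search rate enhancement
  (1+2s) / (1 + 2s(1−p<sub>bind</sub>)/(1+2s²p<sub>bind</sub>)).
- **`io` / `cli`** — delimited-text trace/idealization/table formats and a
  `slidefret` command with subcommands for every stage plus a full
  reproducible pipeline.

## Worked example

```python
import numpy as np
from slidefret import (FilamentGeometry, SlideSimConfig, FretCoupling,
                       measure_cc_time, diffusion_um2_to_bp2,
                       sliding_length, rate_enhancement)

# cross-correlation time of simulated sliding on a 99-nt filament
tau, se = measure_cc_time(SlideSimConfig(d_um2=0.9e-3),
                          FilamentGeometry(filament_length=99, duplex_length=39),
                          FretCoupling(), n_reps=30, seed=7, max_lag=3.0)
print(f"tau_xcorr = {tau:.3f} s")          # tau_xcorr = 0.151 s

d_bp2 = diffusion_um2_to_bp2(0.9e-3, 0.34)
print(f"D_slide = {d_bp2:.0f} bp^2/s")     # D_slide = 7785 bp^2/s
print(f"scan {sliding_length(7700, 0.5):.0f}-"
      f"{sliding_length(7700, 10):.0f} bp per encounter")  # scan 62-277 bp
print(f"{rate_enhancement(200, 0.01):.0f}-fold search acceleration")  # 268-fold
```

A duplex sliding with D ≈ 0.9×10⁻³ μm²/s (≈7800 bp²/s on the B-DNA length
scale) produces donor/acceptor fluctuations with a sub-second correlation
time that grows with filament length; over a 0.5–10 s bound lifetime it scans
roughly 60–280 bp, which at a 1 % per-site recognition probability
accelerates homology search by more than two hundred fold relative to a
non-sliding searcher.

The same pipeline runs from the shell:

```sh
slidefret simulate-slide --d-um2 0.9e-3 --filament-nt 99 --n-molecules 30 \
    --frames 1000 --seed 7 --out traces.tsv
slidefret analyze-cc --traces traces.tsv --max-lag 3.0 --out cc.tsv
slidefret run --seed 1 --out pipeline_run   # simulate -> correct -> cc -> calibrate
```

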