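# Methods

## Physical model

A RecA filament on ssDNA is treated as a rigid 1D rod (its persistence
length, ≈0.8 μm, far exceeds the ≤100-nt constructs modeled here). Register
coordinates count nucleotides from the ssDNA/dsDNA junction toward the free
filament end; RecA stretches bound DNA to a rise of d = 5.1 Å per
nucleotide, 1.5× the B-form 3.4 Å. A donor–acceptor pair separated by
Δx register units sits at physical distance

    L = sqrt(r^2 + (d·Δx)^2)

where r is a fixed lateral offset accounting for the filament radius and
dye linkers (default 20 Å; no measured value exists, so it is exposed in
`FilamentGeometry`). Distance maps to FRET efficiency through the static
Förster relation E = 1/(1+(L/R₀)⁶) with defaults R₀ = 56 Å for the
green/red pair and 38 Å for the green/far-red pair — standard literature
values for cyanine pairs, exposed in `FretCoupling`. No photophysics beyond
this static coupling is modeled (no blinking, no κ² dynamics, no
acceptor–acceptor transfer; the three-color construct is designed so the
two acceptors are ~33 nt apart and transfer between them is negligible).

## Sliding simulator (`slide_sim`)

The duplex performs an unbiased ±δ random walk (δ = 0.1 bp by default,
configurable down to 0.01) at the micro time step τ = δ²/(2D), the unique
choice that reproduces the target diffusion coefficient exactly; a 30 ms
camera frame then integrates 10³–10⁵ micro-steps. D is specified in μm²/s
and converted to register units with the 5.1 Å rise (0.9×10⁻³ μm²/s ≈
3460 nt²/s). The B-DNA convention (0.34 nm/bp), used when quoting D in
bp²/s, gives 7785 bp²/s for the same coefficient; `geometry` exposes both
conversions because the two conventions differ by (5.1/3.4)² ≈ 2.25.

Boundaries: the duplex may slide while retaining at least `min_overlap`
(default 9 bp) of contact with the filament, giving a reflecting range of
`filament_length + duplex_length − 2·min_overlap` register units. The
boundary condition of the real system is not observable; reflection is the
minimal choice that conserves probability and reproduces fluctuations even
when filament and duplex lengths are equal.

Donor placement: by default the donor sits on the duplex end *distal* from
the junction-proximal end. With the acceptor at the junction this keeps the
high-FRET configuration at the edge of the accessible range for every
filament length, which makes the mean FRET fall and the cross-correlation
time grow monotonically with filament length — the behavior the
length-titration assay shows. Placing the donor on the proximal end instead
puts the FRET-sensitive site in the interior of the range; for particular
length combinations it lands at the exact center, where the slowest
diffusive relaxation mode is symmetric and carries no FRET signal, producing
a spurious dip in τ(L). The label position is a `FilamentGeometry` field.

Rendering: each frame takes the mean efficiency over its micro-steps;
noiseless channels are I_A = 500·Ē and I_D = 500·(1−Ē) a.u. (three-color:
donor photons partitioned by the two Förster rate ratios, so the channel
sum is conserved exactly). Gaussian noise of SD 40 a.u. is added per
channel — the "peak intensity 40 a.u." noise specification is read as a
per-channel Gaussian SD, the simplest interpretation; the knob is
`noise_amplitude`. Intensity allocation is deterministic given Ē (no
per-photon shot noise): the fixed-budget-plus-additive-noise recipe is the
model, not an approximation to one.

The inner walk/render loop is a numba kernel; coin flips are drawn 30 per
random integer. Random streams derive from one root seed via per-molecule
`numpy` generator spawning, so every simulation is reproducible and
molecules are independent.

## Cross-correlation analysis (`correlation`)

CC(τ) = ⟨δa(t)·δb(t+τ)⟩ / (SD(a)·SD(b)), per molecule, averaged across
molecules with equal weights; the fit of A·exp(−t/τ) uses |CC|, excludes
lag 0 (uncorrelated-noise spike), and iteratively restricts itself to lags
≲ 5τ̂ — including lags far beyond the decay only adds the statistical noise
floor and biases τ̂ upward. A fit whose decay at the first lag does not
exceed 3× the tail noise level is rejected (nothing but floor to fit), and
a fitted τ below one frame interval is reported as unresolved: a decay
completing between samples cannot be timed from binned data.

Binding events are maximal runs of total intensity above threshold
(default: mean + 4 SD of the sub-midpoint frames) lasting ≥2 frames. Dwell
times use the exponential MLE with right censoring: mean = (sum of all
durations)/(number of uncensored events), SE = mean/√n.

## Calibration of D_slide (`calibration`)

The calibration surface τ(D, L) is simulated on a grid (defaults: the
three-decade D grid 0.09/0.9/9 × 10⁻³ μm²/s; lengths 21/39/69/99 nt;
30 molecules per cell, 1000 frames minimum). Each cell fits the
molecule-averaged CC; the cell SE comes from three disjoint molecule
subgroups. Because the slowest relaxation time of diffusion in a box of
size X is ≈ X²/(π²D), cell trace lengths and lag windows scale with this
prediction (≥50 relaxation times of trace, ~5 of lag window): a fixed
window either drowns fast cells in noise floor or truncates slow ones.
Cells whose decay is still sub-frame after this (high D, short filament)
are dropped as unresolvable; the surface's monotonicity — τ falling with D,
rising with L — is asserted on the remaining cells at every build.

Inversion minimizes summed squared log-τ residuals over log D
(log–log because τ ∝ 1/D approximately), with log-linear interpolation
between grid points. Beyond a column's last usable cell the column's
log-linear trend is extended — τ is monotone in D by construction, so the
trend, not a flat clamp, is the physical continuation past a dropped
cell, and without it a single column would dominate the fit whenever the
others end early. Observations outside a length's τ range by more than
25 % in log space refuse extrapolation (smaller excursions are sampling
scatter around an edge cell). How multiple filament
lengths combine into one D̂ is an open design choice; the joint
least-squares fit was chosen over per-length inversion plus averaging
because it weights lengths by their sensitivity automatically.

## State simulator and HMM analysis (`state_sim`, `hmm_tdp`)

Homology-recognition traces are a three-state continuous-time Markov chain
(NH/HS2/HS1, FRET means 0.1/0.5/0.9, Gaussian emission SD 0.05) sampled by
the Gillespie algorithm. Default rates: NH exits at 2.0 s⁻¹ splitting
55:45 toward the nearer homology site (1.1 vs 0.9 s⁻¹), and each homology
site exits at 0.67 s⁻¹ — one third of the NH exit rate — splitting 0.40 to
NH and 0.27 to the other site. These defaults mirror the regime the assay
reports: ≈55 % recognition efficiency at 6-nt homology, a ~3-fold
stabilization of homology-paired states, and a transition density of
roughly 55 transitions per molecule per minute. Frames straddling a
transition take the occupancy-weighted mean of the state means (and SDs),
mimicking camera integration.

Idealization fits a single Gaussian-emission HMM to all molecules pooled
(tied emissions stabilize state means across a heterogeneous molecule set),
initialized deterministically from pooled quantiles with a sticky uniform
transition matrix, then Viterbi-decodes each trace; states are relabeled in
ascending mean order. EM log-likelihood is recorded per iteration and is
asserted non-decreasing. A state whose SD collapses below 10⁻³ triggers a
perturbed restart (≤5).

Camera integration has one systematic consequence: a direct NH↔HS1 jump
landing mid-frame produces a frame at ≈0.5, which the HMM must read as a
one-frame HS2 visit. Roughly half of all direct low↔high transitions are
therefore split into two spurious transitions through the middle state. By
default idealizations retain all dwells (no filter), but rate extraction
uses the configurable `min_dwell=2` filter, which merges sub-threshold
dwells into the preceding segment; true one-frame HS2 dwells are rare
(P ≈ 3 % at the default rates), so the filter removes the artifact at
negligible cost. Rates are estimated as counts over occupancy,
k(i→j) = N(i→j)/t_i — the exponential-exit estimator, unbiased in
expectation and robust at low counts. The transition density plot places
one count per segment boundary at (E_before, E_after), using fitted state
means by default or measured segment means on request; both axis
conventions exist in the literature.

## Facilitated-search model (`search_model`)

Sliding length uses s = √(Dt): with D = 7700 bp²/s this gives 62 bp at
t = 0.5 s and 277 bp at t = 10 s. The enhancement formula
(1+2s)/(1+2s(1−p)/(1+2s²p)) equals 1 at s = 0, equals 1+2s at p = 1 (a
perfect recognizer scans 2s+1 sites per encounter), is ≥1 and monotone in
both arguments, and yields ~270-fold at s = 200 bp, p = 0.01.

## What the generators do and do not emulate

The synthetic traces carry the designed geometry, kinetics, photon budget
and Gaussian noise — nothing else. Real traces additionally contain
photobleaching, blinking, baseline drift, heterogeneous total intensities,
molecule-to-molecule D variation and off-axis motions. Passing recovery
tests therefore demonstrates that the *analysis* is correct and unbiased
under the stated model, not that the model exhausts real data; in
particular the recovered D applies to on-axis sliding only (off-axis
motion would make it an underestimate of the true on-axis coefficient).

## Problem sizes and numerics

Default test-suite scales: 100 walks × 10⁴ steps for MSD checks; 30
molecules per calibration cell over the 3 × 4 (D, L) grid; 200 molecules ×
2000 frames for HMM/TDP recovery. Floating-point trace serialization uses
shortest-repr writing and round-trip parsing, so files reproduce arrays
bit-exactly. All tolerance choices (3σ noise floor, 5τ̂ fit window,
25 % extrapolation margin, 50 relaxation times of trace) are stated above
next to their rationale.

## Known limitations

- The boundary condition and donor placement of the sliding model are
  conventions, not measurements; τ(L) magnitudes (not orderings) depend
  on them.
- τ_xcorr is unresolvable outside roughly [frame interval, trace/10];
  the calibration drops such cells rather than reporting pseudo-values.
- The HMM assumes Gaussian emissions with state-independent width per
  state and no photobleach truncation; traces dominated by one-frame
  dwells would defeat the `min_dwell` artifact filter.
- `estimate_D` assumes the observed molecules share one D; molecule
  heterogeneity biases τ̄ toward slow molecules.
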