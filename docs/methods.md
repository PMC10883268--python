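# Methods note

This note records the models, assumptions, parameters and numerical
choices behind `secgate`. It describes what the code computes; all
quantitative claims about behaviour are the ones exercised by the test
suite and `scripts/acceptance.py`.

## 1. Measurement model

A confocal smFRET measurement with pulsed interleaved excitation (PIE)
yields a stream of photons, each with an arrival time (integer ticks of a
50 ns clock, `DEFAULT_CLOCK_PERIOD = 5e-8 s`) and one of three stream
labels:

| code | stream | meaning |
|------|--------|---------|
| 0 | DexDem | donor-excited, donor-emitted |
| 1 | DexAem | donor-excited, acceptor-emitted (FRET) |
| 2 | AexAem | acceptor-excited, acceptor-emitted |

Raw FRET efficiency and stoichiometry are defined per photon set as
`E_raw = n_DA / (n_DD + n_DA)` and
`S_raw = (n_DD + n_DA) / (n_DD + n_DA + n_AA)`. "Raw" means no gamma/beta
detection-efficiency correction is applied; background subtraction is a
separate, optional step (section 6).

## 2. Synthetic data generator

`SimConfig` defaults are the study conditions, not free dials:

- Species fractions: 50 % dual-labelled, 35 % donor-only, 15 %
  acceptor-only (stochastic maleimide labelling).
- Per-state (E, S) signatures: open (0.40, 0.60), closed (0.75, 0.60),
  donor-only (0.05, 0.95), acceptor-only (0.80, 0.05).
- Apo gating kinetics: tau_open = 6.1 ms, tau_closed = 27.5 ms.
- Diffusion bursts: exponential durations (mean 2.5 ms), 40 kHz in-burst
  photon rate, 5 bursts/s arrivals; Poisson background (1.0, 0.6, 0.8)
  kHz per stream.
- Orientation mixture: membrane channels reconstitute in both
  orientations, so in motor-bound conditions a fraction
  `orientation_weight` (default 0.5) of dual-labelled molecules cannot
  bind the motor and retain apo kinetics.

Channel gating is a two-state telegraph (continuous-time Markov) process:
exponential dwells, stationary initial state, final dwell truncated at the
record end. Photons arrive as a homogeneous Poisson process within
bursts; each photon's stream is multinomial with the occupying state's
probabilities; per-stream Poisson background is superposed; timestamps are
quantized to clock ticks. Ground truth (per-photon state and species,
true burst spans) is attached for oracle tests.

Generator fidelity limits: in-burst intensity is constant (no diffusion
profile through the confocal volume), detector dead time and afterpulsing
are not modelled, and dye photophysics beyond static donor-only /
acceptor-only species (e.g. blinking) is absent.

## 3. Background and burst search

Per-stream background rates are estimated per 30 s window by an iterative
exponential-tail fit to inter-photon delays (threshold 3/rate, repeated to
convergence), then averaged; at least 10 photons per stream per window are
required. On bursty records this estimates the between-burst rate, which
is below the naive mean rate.

Burst search is the sliding-window method: a window of m = 10 consecutive
photons is "in burst" when its local rate exceeds F = 6 times the channel
background, i.e. its time span is at most `m / (F * bg)`; photons of
qualifying windows are merged into maximal runs; bursts with fewer than
50 photons are discarded. Two channel logics are provided:

- `and` (default): donor-excitation photons (DexDem+DexAem) and
  acceptor-excitation photons (AexAem) must each exceed 6x their own
  background; span intersection suppresses donor-only and acceptor-only
  molecules. Used for burst-level E/S analysis and BVA.
- `all`: a single search over all photons. Used upstream of hidden-state
  modelling, where the photophysical species must be retained so the
  model can classify them.

The implementation is verified photon-for-photon against a brute-force
reference on random records.

Because the search keeps every photon contained in *any* qualifying
window, up to m - 1 sub-threshold background photons are appended at each
burst edge (a window straddling the dense core still qualifies). Between
bursts the photon stream is pure background, whose stream mixture has its
own (E, S) signature, so those edge stretches mimic short visits to a
distinct state and inflate fitted transition rates. `refine_burst_edges`
applies a two-sided variant before kinetic modelling: a photon is
retained only when the m-photon window starting at it *and* the one
ending at it both meet the rate criterion; each burst is reduced to the
maximal retained runs (splitting bursts that the search bridged across a
sub-threshold gap between two nearby molecule transits) and the
minimum-size filter is re-applied. Up to m - 1 genuine edge photons are
sacrificed with the background stretch; dwell-time estimates are
insensitive to this loss but very sensitive to the fake edge dwells.

## 4. Burst variance analysis (BVA)

Consecutive donor-excitation photons of each burst are partitioned into
windows of n = 5; the standard deviation of window E_raw is compared,
per burst, to the 99 % quantile of Monte-Carlo window-sd draws from a
binomial null at the burst's mean E. The dynamic fraction is the share of
bursts exceeding the envelope. The shot-noise reference curve is
`sd(E) = sqrt(E(1-E)/n)`.

Power caveats (documented behaviour, not bugs): dwells faster than one
window (~0.2 ms at 24 kHz donor-excitation rate) are averaged out within
windows, and at diffusion-sized bursts (~12 windows) the per-burst test
has low power. Discrimination tests therefore use long two-state records
(50 ms), where static records give a dynamic fraction near the 1 % false
positive rate and ms-dynamic records are detected in most bursts.

## 5. Photon-by-photon hidden Markov model

The hidden state is a continuous-time Markov chain with generator Q
(off-diagonal rates in 1/ms); each photon emits its stream label from the
occupying state's 3-vector B row. The likelihood conditions on the
observed arrival times: with inter-photon intervals dt_k,

```
L = pi^T diag(b_0) prod_k [ expm(Q dt_k) diag(b_k) ] 1
```

Propagators are computed by eigendecomposition of Q (complex-safe, with a
perturbation fallback for defective matrices); forward recursions are
scaled per photon. This is the continuous-time formulation of the
photon-by-photon HMM: expm(Q dt) equals the limit of per-tick transition
matrices (I + Q delta)^(dt/delta).

Fitting is expectation-maximization with exact interval-resolved expected
statistics for Markov-jump processes: expected state occupation times and
transition counts on each interval are computed from spectral integrals
`I_ab(t) = (exp(mu_a t) - exp(mu_b t)) / (mu_a - mu_b)` (with the
degenerate limit `t exp(mu_a t)` below a 1e-10 eigenvalue gap). The
M-step is closed form: rates = expected jumps / expected time, emission
rows and pi from expected counts (clipped at 1e-12 and renormalized).
Each EM iteration provably does not decrease the likelihood; the trace is
monitored and convergence is declared at a relative tolerance (default
1e-6). Initialization: k-means on burst (E, S) for emission rows plus
jitter, uniform pi, 1 ms dwell guesses; several seeded restarts run a
short pre-phase and the best is continued. Kernels are numba-compiled
(cached).

Likelihood and Viterbi are verified against exhaustive path enumeration
(all N^K hidden paths, N <= 3, K <= 8 photons) to 1e-10 relative error.

State classification from fitted (E, S): S >= 0.8 is donor-only, S <= 0.2
acceptor-only; exactly two mid-S FRET states must remain, separated by
more than 0.05 in E; the lower-E state is the open channel (larger
inter-dye distance across the lateral gate), the higher-E state closed.

Model-count selection: for N = 1..5 states, BIC = -2 lnL + p ln(n_photons)
with p = N(N-1) + 2N + (N-1) free parameters;
BIC' = (BIC - min BIC)/|min BIC|; the smallest N with BIC' < 0.005 is
chosen.

Two-pass kinetic fitting: the pass-1 multi-class fit (or selection) on
all bursts establishes the state classes; `conformational_burst_mask`
then keeps only bursts whose Viterbi path stays within the open/closed
states, and a two-state model is refit on that subset. The excluded
bursts are donor-only / acceptor-only molecules (no gating information)
and bursts in which a dual-labelled molecule co-occurs with another
species — coincidence artefacts whose apparent state changes would
otherwise contaminate the conformational rates. Residual
dual-labelled/dual-labelled coincidences cannot be separated this way
and leave a small (few percent) fast bias at realistic burst rates.

## 6. Dwell analysis

Dwells are maximal constant-state runs of the per-burst Viterbi paths;
a dwell's duration spans its photons plus half of each flanking
inter-photon gap (no flank at burst edges). Dwell positions
(initial/mid/terminal/whole-burst) are recorded.

Kinetic dwell times are read from the fitted generator: for the
conformational pair, only the open<->closed rates count
(tau_open = 1/k_open->closed), because exits into photophysical states
connect distinct molecules, not kinetic exchange. Percent open =
100 tau_open/(tau_open + tau_closed). Repeats are summarized by the mean
and two-sided Student-t confidence interval (default 90 %).

Per-state emission summaries aggregate dwell photon counts; with
background rates supplied, expected background counts (rate x dwell
duration per stream) are subtracted before forming E and S — the standard
burst-analysis background correction, which removes the dilution of state
signatures by background photons inside bursts.

Orientation correction removes the admixed apo population
(weight w, default 0.5) in motor-bound conditions, in one of two modes:

- `occupancy-unmixing`: per-repeat open occupancy is linearly unmixed,
  `P = (P_obs - w P_apo) / (1 - w)` (clipped to the physical range with a
  warning), and the dwell times rescaled to preserve the per-repeat
  relaxation rate `1/tau_open + 1/tau_closed`.
- `dwell-mixture`: per-repeat dwell-duration lists are fit by maximum
  likelihood as `w Exp(tau_apo) + (1-w) Exp(tau)` with the apo component
  fixed.

## 7. Energy landscape and ATPase clock

The equilibrium free-energy difference along the gating coordinate is
`dG(open - closed) = -ln(tau_open / tau_closed)` in k_B T. Barrier
heights require an attempt-rate prefactor k0 that the data cannot supply,
so `barrier_profile(tau_open, tau_closed, k0)` reports
`ln(k0 tau)` values always flagged qualitative; their difference equals
dG for any k0 (gauge invariance, tested).

The ATPase clock partitions each catalytic cycle (1000/k_cat = 153.4 ms
at k_cat = 6.52 /s) deterministically into an ATP-bound phase of
1000/17.9 = 55.9 ms (phosphate release rate) and a post-hydrolysis
ADP phase of the remaining 97.5 ms; an optional loosely-bound ADP phase
is off by default (its contribution is marginal). Default phase gating
kinetics: ATP (0.4, 1.1) ms; ADP post-hydrolysis (3.5, 1.9) ms. Within
each phase the channel runs the telegraph process with that phase's
kinetics, and the occupied state carries over across boundaries
(memorylessness makes restarting the dwell clock exact).

Because of the carry-over, each phase starts at the previous phase's
stationary occupancy and relaxes with time constant
`tau_relax = (1/tau_open + 1/tau_closed)^-1`, which biases the raw phase
time-average by O(tau_relax / phase duration) (~2e-3 for the ATP phase).
The reported `phase_open_occupancy` is therefore the quasi-stationary
estimate with a 5 tau_relax burn-in after each boundary (residual bias
~1e-5, far below the sampling error at 1e4 cycles); the uncorrected
average is available as `phase_open_occupancy_raw`.

## 8. Transport kinetics

Translocation lag times versus probe insertion position are modelled as
`lag = t0 + position / v`; `fit_transport_rate` performs ordinary least
squares on (position, lag) and inverts the slope, with the delta-method
standard error `se_v = se_slope / slope^2` and a Student-t 95 % CI
(undefined at n = 2; non-positive slopes are flagged invalid). Coupling
efficiency is `v / k_cat` in amino acids per ATP, with quadrature error
propagation on the relative scale when standard errors are given.

## 9. Numerical choices and limitations

- Eigendecomposition-based propagators assume Q is diagonalizable; a
  tiny random perturbation (1e-12 scale) handles defective cases, and
  degenerate eigenvalue pairs in the E-step integrals switch to the
  analytic limit below a 1e-10 gap.
- EM is a local optimizer; restarts reduce but cannot eliminate the risk
  of local optima. Selection flags per-N fit failures and proceeds.
- Dwell times from Viterbi paths are biased at dwells shorter than the
  inter-photon time; kinetic parameters are therefore always reported
  from the fitted rate matrix, with Viterbi dwells used for durations
  lists, positions and emission summaries.
- Burst search behaves pathologically when the background estimate is
  near zero (the window-span threshold diverges and separate molecules
  merge); realistic background levels or ground-truth spans should be
  used in that regime.
- Kinetic recovery at the ~3000-burst scale has a per-dataset scatter of
  roughly 15 % on the slow-exchange dwell times (few hundred observed
  transitions after burst censoring); single-dataset estimates at that
  scale should be read with that uncertainty, and repeats averaged where
  available.
- Confidence intervals over repeats assume approximate normality of
  per-repeat estimates (Student-t, small n).
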