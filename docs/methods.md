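# Methods

## The gating model

A channel is modelled as two independent two-state "fast" gates (one per
protopore) in series with one common "slow" gate described by a
continuous-time Markov chain over named states, each conducting or
nonconducting. The shipped presets are

* `model1` — `O ↔ inhibited ↔ inactivated`: one conducting and two
  nonconducting states, the minimal scheme for bi-phasic recovery;
* `model2` — `O ↔ I1 ↔ I2 ↔ I3`: a linear ladder of three progressively
  deeper inactivated states. A connected n-state chain has one zero
  eigenvalue and n−1 decaying modes, so this scheme relaxes
  tri-exponentially — the structural counterpart of three-component
  recovery fits;
* `c212s`, `y512a`, `e166a`, `e166q` — `model2` rate sets emulating the
  qualitative behaviours of the corresponding channel variants (see
  "Synthetic data" below). These are illustrative calibrations, not fitted
  parameters.

Rates are condition-labelled constants (1/ms) looked up by a label such as
`pH7.4` or `pH5`. Voltage and [Cl⁻] dependence enter through per-condition
rate tables and through the initial occupancy at the start of a relaxation,
not through a parametric rate law: the observation driving this choice is
that recovery time constants are largely insensitive to voltage while the
component *fractions* (initial occupancies) are voltage dependent. An
optional multiplicative factor `k(V) = k0·exp(V/Vs)` can be enabled per
rate key (`voltage_slope_mv`) for schemes that need explicit voltage
acceleration (used here to emulate depolarization-favoured deepening); it
is off by default because no rate law is established.

Quantities derived from a generator `Q` (row convention, rows sum to 0):

* `occupancy(gen, p0, t)` — `p(t) = p0·e^{Qt}` via eigendecomposition, with
  a scaling-and-squaring fallback when the eigenvector matrix is
  ill-conditioned (condition number > 1e10). Probability is renormalised to
  machine precision at each time.
* `relaxation_spectrum(gen, p0, w)` — the observable `p(t)·w` decomposed
  over eigenmodes into `offset + Σ Aᵢ e^(−t/τᵢ)`, `τᵢ = −1/λᵢ`. Components
  with `|Aᵢ|` below 1e−6 of the dynamic range are dropped but reported;
  components with relative tau difference below 1e−9 are merged. Complex
  eigenvalues (possible only for non-reversible schemes; the chain models
  here are reversible) raise with guidance to fit a numeric trajectory.
* `stationary_distribution(gen)` — the null space of `Qᵀ`, normalised.

## Experimental conditions

`IonCondition` carries membrane potential, intra/extracellular pH, anion
composition (mM) and temperature; `Protocol` strings timed segments
together with a sampling interval and an optional solution-exchange time
constant. Reversal potentials come from the Nernst equation
`E = (RT/zF)·ln(c_out/c_in)`; driving force is `V_m − E_rev`. Anion species
other than Cl⁻ (SCN⁻, Br⁻) are represented by name, and selectivity
differences enter only through user-specified per-condition rate tables —
measured reversal potentials, not a permeability model, are the primary
data in this setting, so no GHK machinery is included.

Defaults and assumptions:

* temperature 295 K (≈22 °C room temperature) — an assumption, surfaced in
  every config;
* solution exchange instantaneous (`exchange_tau = 0`), matching a fast
  exchanger. A nonzero `exchange_tau` applies an exponential mixing weight
  `w(t) = 1 − e^(−Δt/τ)`; the deterministic macroscopic simulator honours
  it by blending generators on a fine sub-grid over the first 6τ of each
  segment, while the stochastic simulator treats switches as instantaneous
  (and warns), since time-dependent rates would break the exact
  waiting-time construction.

## Synthetic data

`simulate_single_channel` runs an exact event-driven (Gillespie)
simulation of the joint (slow gate, pore gates) process with exponential
waiting times. While the slow gate conducts, the two pores flip
independently with the condition's fast rates, giving current levels 0/1/2;
in any nonconducting slow-gate state the pores are silent and their gates
frozen (fast gating is not observed during inactivation, so the simulator
does not generate it there). The level path is binned to the sampling grid
by time-weighted averaging within each sample — this avoids discretisation
bias at heavy (5-Hz) analysis filtering — then scaled to pA by the
single-pore amplitude, linear in driving force relative to a reference
(−60 mV by default), and overlaid with additive white Gaussian noise
(default SD 0.1× the single-pore amplitude, applied after gating and
before filtering, mimicking the recording chain order).

`simulate_macroscopic` produces either the deterministic expectation
`n_channels · P_conducting(t) · n_pores · p_fast · i_pore` from the
occupancy solution, or an ensemble sum of independent stochastic channels
with one shared noise realisation. `apply_filter` is a zero-phase Gaussian
low-pass with its −3 dB point at the requested cutoff (σ_t = √(ln 2)/(2π f_c)),
unit DC gain, and an error if the cutoff reaches Nyquist. Typical
acquisition emulation: 5 kHz sampling for macroscopic work, 2 kHz for
single-channel presets, 100 Hz and 5 Hz analysis filters.

What the generator emulates: two-pore fast gating under a common slow gate,
pH-step inhibition and recovery, condition-dependent occupancy of deeper
inactivated states, Gaussian noise, Gaussian filtering. What it does not:
capacitive transients, series-resistance artifacts, flicker/1-f noise,
baseline drift, multi-channel patches, rundown. Tests passing on this
generator therefore validate the *estimators* under clean, known-truth
conditions; they do not certify performance against those real-data
artifacts.

The variant presets encode the qualitative study conditions: the
C212S-like set keeps all three recovery components and slows acidic-phase
`I1→I2` deepening to τ = 370 ms, so the fast recovery fraction decays with
exposure duration; the Y512A-like and E166A-like sets empty `I1` within the
shortest (50-ms) exposure and equilibrate `I2↔I3` quickly, so their
fractions are exposure-independent; the E166Q-like set barely deepens past
`I1`. Recovery-side rates in all model-2 presets are 0.1/0.01/0.001 per ms,
placing the relaxation constants at the 10/100/1000-ms reference scales.

## Trace processing

* `normalize_to_preacid` divides by the mean current over a window ending
  at acid onset; the signed divisor is recorded, so negative (inward)
  pre-acid currents yield positive normalized traces. Normalization is
  refused when the pre-acid mean is under 5× a robust (median absolute
  difference) noise estimate.
* `estimate_levels` seeds 1-D k-means from the most prominent peaks of a
  lightly smoothed all-points histogram, then enforces (for three levels)
  an equidistant ladder when the two spacings agree within 20%, flagging
  non-equidistance otherwise. The ladder is oriented so level 0 (all pores
  shut) is the extreme nearest zero current. Separation under 3× the
  robust within-level spread raises an error ("fewer modes than levels").
* `idealize` applies half-amplitude thresholds (midpoints between adjacent
  level amplitudes) and merges events shorter than a dead time into their
  longer neighbours. The default dead time is `0.5322/f_c` (≈2× the
  Gaussian filter rise time `0.3321/f_c`), configurable. Half-amplitude
  idealization was chosen over HMM methods as the transparent standard
  that can be validated directly against the simulator's true event
  sequence; note that for exponential dwells of mean `m` a fraction
  `p = 1 − e^(−t_d/m)` is intrinsically unresolvable, and each censored
  dwell merges its two neighbours, so the expected recovered event
  fraction is ≈ 1 − 2p (→ 1 as dwells lengthen relative to the filter
  rise time).

## Dwell-time and open-probability analysis

The fast-gate open probability is the time-fraction statistic
`Pₒ = f₁/2 + f₂` over a three-level idealization. Level-0 events longer
than 50 ms (configurable) are attributed to slow-gate closures and removed
from numerator and denominator alike, making `Pₒ` a conditional time
fraction over fast-gating activity — the interpretation that keeps the
statistic a pure fast-gate quantity. The slow-gate `Pₒ` is the open-time
fraction of the two-level (5-Hz) view. Dwell histograms use fixed bins
(8 ms fast / 200 ms slow by default) with an overflow tally beyond an
optional display cutoff (200 ms mirrors the usual separation of fast-gate
closures from inactivation events; the cutoff is a parameter, not a claim).

`fit_dwell_exponential` reports both estimators, since either may be
preferred: the maximum-likelihood exponential mean of the raw durations,
and the least-squares slope of log-counts over nonzero bins. Deviation
from mono-exponentiality — the operational signature of slow-gate closures
mixed into the nonconducting dwells — is flagged by a likelihood-ratio
test against a two-exponential mixture (EM fit, df = 2, α = 0.01).

## Recovery fitting

`fit_recovery` fits `I(t) = Σᵢ Aᵢ e^(−t/τᵢ) + C` (n ≤ 3) by trust-region
reflective least squares with an analytic Jacobian. Time constants are
parameterised on a log scale and bounded to `[0.5·dt, 10·span]`; eight
starts with log-spaced tau seeds (amplitudes initialised by linear least
squares at each seed) are attempted and the best RSS wins, ties broken by
the smaller parameter norm. Components are returned sorted by tau; a tau
ratio under 1.5 triggers a collinearity warning; a largest tau above a
third of the fitted span sets a truncation flag. Fractions
`Fᵢ = Aᵢ/ΣAⱼ` sum to 1 identically; mixed-sign amplitude sets trigger a
warning because the definition is ill-behaved there.

`select_model_order` fits n = 1..3 and prefers the minimum-AIC order
(incremental F-test at 5% offered as an alternative). Two heuristics are
reported alongside, mirroring how under-fitting is usually recognised:
whether the fitted amplitude sum covers ≥95% of the observed recovery
span, and a Wald–Wolfowitz runs test (p < 0.01) for systematic residual
structure.

`condition_sweep` fits each (condition, trace) pair, labels components
consistently across the sweep by nearest-log-tau matching to the
highest-order fit's taus (3× guard band, order-preserving), and tabulates
per-replicate tau/fraction rows plus mean ± SEM summaries.

`exposure_series_fit` tracks the fast component across exposure durations
(matched by nearest log-tau to the smallest pooled tau) and fits
`F(T) = plateau + (F₀ − plateau)·e^(−T/τ)` with bounded parameters
(endpoints confined near [0, 1] since F is a fraction; τ within what the
exposure grid resolves). The series is declared time dependent only when
the exponential beats a constant model by small-sample AIC (AICc — the
series has few points) *and* predicts a fraction change of at least 0.05
across the measured range: fractions are rarely resolved better than ~0.05
across replicates, so smaller drifts are treated as noise. A fast
`I1→I2` transition (complete before the shortest exposure) then yields the
expected null: no time dependence.

## Numerical choices and degenerate inputs

* Probability vectors are validated (nonnegative, sum 1 within 1e−9);
  occupancies are clipped and renormalised against eigen-solver roundoff.
* Eigendecomposition is guarded by the eigenvector condition number;
  beyond 1e10 the spectral path falls back (occupancy) or refuses with
  guidance (spectrum).
* Constant traces: level estimation errors out (one mode); idealization
  returns a single spanning event; normalization of a zero-mean window is
  refused.
* Zero-rate deadlocks in a protocol segment freeze the state for that
  segment with a warning (multi-segment protocols only — a single
  absorbing segment is a legitimate steady recording).
* All stochastic components take explicit integer seeds; identical
  (spec, protocol, seed) produce bitwise-identical traces.

## Problem sizes

Defaults throughout the tests and the acceptance script were chosen as the
smallest sizes at which the statistical envelopes are sharp: macroscopic
fits use 1-ms sampling over ~10-s protocols (≈10⁴ points), parameter
recovery uses 100 replicates (50 for model-order selection), single-channel
estimator checks use 60–150 s of simulated recording at 2-kHz sampling,
and dwell calibration uses 5000 events. Larger sizes change none of the
conclusions, only the tightness of the Monte-Carlo envelopes.

## Known limitations

* No missed-event (dead-time) statistical correction for dwell fits; the
  idealization's censoring model is documented instead.
* No global Q-matrix likelihood fitting of rate constants to trace
  ensembles; recovery analysis is deliberately the empirical
  multi-exponential route.
* The voltage factor `e^(V/Vs)` is a phenomenological convenience, not a
  mechanistic claim.
* Component matching across conditions assumes time constants stay within
  a 3× band of their reference; sweeps whose taus drift further apart are
  labelled as unmatched rather than silently reassigned.
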