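# Methods

This note records the models implemented in `protospike`, the numerical
choices behind them, and what the synthetic-data generator does and does
not emulate. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and data model

The package analyses slow electrical spiking of proteinoid microspheres
(thermal proteins that self-assemble into neuron-like excitable
compartments) and how a proton-pump-inhibitor dose modulates it. All
stages exchange a single carrier, `VoltageTrace` (seconds, millivolts).
Because no raw laboratory recording is available to ship, the
synthetic-data generator is a first-class module: it produces inputs
whose *generator parameters* are the statistics the downstream stages
are expected to recover, giving every stage a ground truth.

## Synthetic recordings (`synthgen`)

A recording is `baseline + 1/f^beta noise + sparse spikes`:

- **Background noise.** White Gaussian noise shaped in the Fourier
  domain by `f^(-beta/2)` (DC removed), rescaled so the sample RMS
  matches the configured value exactly. This gives the exact expected
  power-law spectrum in O(n log n). Default `beta = 1` (pink), RMS
  0.02 mV — well below the 0.1 mV detection threshold.
- **Spike times.** Gamma-distributed inter-spike intervals
  (mean `isi_mean`, coefficient of variation `isi_cv`). The gamma family
  spans perfectly periodic (CV→0) through Poisson-like (CV=1) firing
  with two interpretable parameters. Times are snapped to the sampling
  grid and forced strictly increasing. Default `isi_mean = 7520.47 s`
  and `amp_mean = 0.85 mV` are the highest-dose (1.30 mg/mL) regime;
  `DOSE_REGIMES` carries all three reported dose conditions
  (0.72 mg/mL: 1.91 mV / 4285.28 s; 0.83: 0.46 / 6461.62;
  1.30: 0.85 / 7520.47).
- **Amplitudes.** Normal (mean, sd), truncated positive by rejection
  sampling — amplitudes are physical magnitudes. Note the truncation
  means extreme lower-tail draws can fall below a detector threshold;
  completeness guarantees are therefore stated conditional on all
  injected amplitudes reaching the threshold.
- **Waveform.** Single-sample impulse by default, so the injected
  amplitude equals the trace excursion exactly and detector scoring is
  unambiguous; an exponential-decay kernel (configurable time constant)
  is available when waveform shape matters.
- **Sampling rate.** The long recordings' source rate is not stated;
  1 Hz is assumed for multi-day records (a typical electrode-logger
  setting) and is configurable.
- **Control trace.** Pink noise rescaled to a fixed 0.04 mV
  peak-to-peak span and centred, guaranteeing `max |v| < 0.05 mV`, so
  the standard detector finds nothing — the water-control condition.

Capacitance and impedance spectra are evaluated directly from the model
parameter sets (below), with optional additive Gaussian noise
(capacitance, in Farads) or proportional complex Gaussian noise
(impedance, `Z → Z(1 + γ(g₁ + j g₂))`).

Everything is deterministic per seed; identical config + seed gives
bit-identical arrays.

**What the generator does not emulate:** electrode drift and
electrochemical artefacts, spike-shape variability, bursting or
rate nonstationarity over days, the capacitive-discharge outliers seen
in real records (e.g. isolated multi-mV events), or any physics of the
proteinoid membrane. Tests passing on synthetic data therefore validate
the *analysis chain* — detection, statistics, spectral and circuit
fitting — not the biology.

## Spike detection and statistics (`spikes`)

Local maxima with excursion above baseline ≥ threshold (default
0.1 mV) and pairwise separation ≥ `min_distance` (default 50 ms),
larger peak winning a conflict — `scipy.signal.find_peaks` implements
exactly this exclusion rule. Baseline is fixed 0 mV by default (the
published amplitudes appear baseline-referenced); a running-median
baseline is available for drifting records. Endpoint samples cannot be
local maxima and are never reported.

Statistics: quartiles by linear interpolation between closest ranks
(the most common convention; the original quartile convention is not
recoverable from the published tables), sample standard deviation
(n−1). "Period" is the inter-spike interval, the difference of
successive detected times; the first spike contributes none, and with
fewer than two spikes period statistics are reported as absent rather
than zero. No outlier rejection is applied anywhere — extreme
amplitudes and periods are reported as seen.

## Thalamocortical Izhikevich model (`izhikevich`)

    dv/dt = 0.04 v² + 5 v + 140 − u + I
    du/dt = a (b v − u),   v ≥ 30 mV ⇒ emit 30, v ← c, u ← u + d

Defaults a=0.02, b=0.25, c=−65 mV, d=0.05 — published thalamocortical
values, fully overridable. Integration is explicit Euler at
dt = 0.1 ms (the model's standard treatment). The sample at each
threshold crossing is emitted as exactly +30 mV before the reset, so
trace maxima are uniform and the emitted trace never exceeds the peak.
The result object exposes the post-reset state arrays so the reset
contract is directly testable.

Euler's step error grows with firing rate: halving dt changes the
spike count by at most one for moderate tonic drive (I ≈ 2), but
strongly driven regimes (I ≥ 5, > 100 Hz equivalent) show larger
count drift; use a smaller dt there if counts matter.

The stimulation helper rescales the simulated trace by a gain
(default 0.1, mapping 30 mV model peaks to 3 mV stimulation pulses).
The response emulator — a stand-in for the physical sample so overlap
analyses are testable — is a first-order (RC) filter plus optional
offset and white noise; its discrete update uses
`alpha = 1 − exp(−dt/τ)`, exact for step-hold inputs.

## Persistence spectrum and power-law fit (`spectral`)

The persistence spectrum is the time-occupancy histogram of short-time
power spectra: Hann windows (default 1024 samples, 50 % overlap), PSD
in dB (10·log₁₀, floored at −150 dB so silent bins stay finite),
histogrammed per frequency in 1 dB bins and normalised per frequency
column. The summary curve per frequency is the modal-occupancy bin by
default; max-hold and mean summaries are configurable. The modal
estimate carries bin-level sampling noise (a few dB for a few hundred
windows), so the flatness and exponent pipelines use the mean summary.

The summary curve is fitted with `y = a − b ln(x + c)` (unweighted
nonlinear least squares, c ≥ 0, lmfit), reporting reduced χ², R²,
adjusted R² and standard errors. The spectral exponent is reported as
`beta = −b`. Unit consistency: for a PSD ∝ f^(−β), the dB curve has
slope −(10/ln 10)·β per ln(Hz); the end-to-end exponent estimator
therefore converts the summary curve from dB to natural-log power
(× ln 10⁄10) before fitting, so the fitted b equals the generator's β
and the estimator returns −β (pink noise → −1). The zero-frequency row
is dropped and c is pinned at 0 in this estimator. The one-sided DC and
Nyquist bins carry different PSD scaling and are excluded from flatness
claims.

## Dielectric relaxation (`dielectric`)

- Relative permittivity from cell geometry:
  `εr = C·d / (ε₀·A)` with d = 0.01 m electrode separation and
  A = π(thickness/2)², thickness 0.002 m (needle electrodes),
  ε₀ = 8.85418782×10⁻¹² F/m.
- Logistic dispersion: `C(f) = A2 + (A1 − A2)/(1 + (f/x0)^p)`, with A1
  the low-frequency plateau (the standard four-parameter orientation,
  consistent with identifying A1 with the static permittivity).
  Fitting is least squares via lmfit; uniform weighting by default,
  proportional (1/|C|) weighting available — the right choice under
  multiplicative noise, and what the noisy-recovery tests use.
- Debye mapping: `eps_s = A1`, `eps_inf = A2`, `tau = 1/(2π·x0)`.
  A fitted A2 < 0 is physically impossible for a permittivity but is a
  known artefact of the logistic form at high frequency; it is kept and
  flagged with a warning, never rejected. Dimensional note: the
  plateaus are capacitances (F) yet are conventionally quoted as
  permittivities (F/m) by this mapping; the numbers are stored exactly
  as assigned and the tension is documented rather than resolved.
- Debye dispersion `ε* = ε∞ + (εs − ε∞)/(1 + jωτ)` uses the physics
  sign convention (+jωτ), giving Im ε* < 0 for εs > ε∞ with the loss
  maximum |Im| = (εs − ε∞)/2 at ωτ = 1.
- Consistency check: the logistic profile with p = 2 and A2 = 0
  coincides with the *real part* of the Debye dispersion at
  τ = 1/(2πx0) for every frequency (an analytic identity:
  Re ε* = εs/(1+(f/x0)²)); the suite asserts it numerically. No
  such identity exists for p = 1.

Cole–Cole, Davidson–Cole and Havriliak–Negami generalisations are
deliberate extension points, not implemented.

## Impedance models (`impedance`)

- **Exp3P2** `Z = exp(a + b f + c f²)` is a real magnitude model; it is
  fitted to |Z| by an exact linear solve on ln|Z| (design matrix
  [1, f, f²], `numpy.linalg.lstsq`), requiring ≥ 3 distinct
  frequencies. Residuals are orthogonal to the design columns by
  construction, which the suite asserts. Arguments beyond exp's float
  range raise a range error naming the offending frequency.
- **Randles circuit**
  `Z(ω) = Rs + [jωCdl + 1/(Rct + W)]⁻¹`, `W = Zw ω^(−1/2)(1 − j)` —
  a solution resistance in series with the double-layer capacitance in
  parallel with the faradaic branch (charge transfer + semi-infinite
  Warburg diffusion). The published source gives the topology but not
  the formula; this is the standard form matching the stated Zw units
  (Ω·s^(−1/2)).

`fit_randles` performs complex least squares on stacked real/imaginary
residuals with three standard weighting schemes (unit, modulus,
component-wise proportional; proportional is the default and is exact
for noise-free data — use modulus for noisy experimental spectra, as
the noisy-recovery test does). Three numerical choices matter:

1. **Log-space parameters** — enforces positivity and equalises
   sensitivities across the many decades circuit elements span.
2. **Analytic Jacobian** — for capacitor-dominated spectra (large Cdl)
   the faradaic parameters perturb Z only at the ~10⁻⁹ relative level,
   far below what finite-difference derivatives (step ≈ √ε) can
   resolve; the closed-form Jacobian keeps the fit well-conditioned all
   the way to the float rounding floor. The published parameter set
   (Cdl = 6.95×10³ F, reproduced as printed despite its physical
   implausibility) is exactly such a spectrum: over 10⁻²–10⁵ Hz the
   faradaic branch contributes ≲ 10⁻¹³ of Re Z and ~5×10⁻⁹ of Im Z,
   yet the fit recovers all four elements to ~10⁻⁷ relative.
3. **Deterministic multi-start** — the supplied initial guess plus a
   data-driven heuristic start (Rs from the high-frequency real limit,
   Rct from the low-frequency rise, Cdl from the −Im Z apex), keeping
   the lower-cost solution. Weakly identifiable spectra admit local
   minima whose cost exceeds the global one by many orders of
   magnitude, so the cost comparison is decisive.

Termination: xtol = gtol = 10⁻¹⁴ (the information floor sits at float
rounding); standard errors come from the Gauss–Newton covariance in
log space. The Nyquist transform is the pointwise map (Re Z, −Im Z);
for Zw = 0 the locus is the semicircle of diameter Rct centred at
Rs + Rct/2, asserted to 10⁻⁹.

## Boolean encoding (`boolgates`)

`high = [v > +2 mV]`, `low = [v < −2 mV]` (strict comparisons: a value
exactly at a threshold yields 0, per "exceeds"/"falls below"). With
ordered thresholds the states are mutually exclusive. Seven gates are
evaluated row-wise on (high, low); NOT is unary on the high state (a
switch allows NOT(low)). The emitted table always satisfies
NAND = 1−AND, NOR = 1−OR, XNOR = 1−XOR, asserted on construction, and
is written as TSV in the canonical column order
`time high low AND OR XOR NOT NAND NOR XNOR`.

## I/O and pipeline (`io`, `pipeline`, `cli`)

CSV with unit-bearing headers (`time_s,potential_mV`;
`frequency_Hz,capacitance_F`; `frequency_Hz,Z_real_ohm,Z_imag_ohm`,
magnitude-only accepted for Exp3P2). Floats are written with 17
significant digits and parsed with round-trip precision, so
write→read is bit-exact. NaN rows are dropped with a counted warning;
wrong headers raise a format error naming the missing column. All
writes are atomic (temp file + rename). Reports are schema-versioned
JSON without timestamps; a run is identified by its seed and config
hash, and identical config + seed reproduce byte-identical reports.
Per-stage seeds are derived deterministically from the global seed.

## Problem sizes used by tests and the acceptance script

Spectral-exponent checks use 10⁵-sample traces (window 1024); spike
recovery uses ~500-spike records at 1 Hz sampling (~3.8×10⁶ samples);
fit recoveries use 50–200-point spectra. The full suite runs in a few
seconds.

## Known limitations

- The persistence-spectrum construction (window, overlap, bin width)
  for the published spectra is unknown; published-spectrum parameters
  are validated by regenerating curves from the printed fit parameters,
  not by reconstructing the original spectrum.
- Quartile and period conventions of the published tables cannot be
  verified against raw data (none is deposited); the conventions here
  are documented defaults.
- The Exp3P2 model is treated as a magnitude model; whether the
  original fit used magnitude or the real part is unstated.
- Explicit Euler limits the Izhikevich model's fidelity at high firing
  rates (see above).
- `eps_s`/`eps_inf` inherit the capacitance-vs-permittivity unit
  tension described in the dielectric section.
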