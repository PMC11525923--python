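# Methods

## The kinetic model

A hyperpolarized experiment starts from a non-equilibrium longitudinal
polarization that only decays; there is no recovery term.  We model one
substrate pool and up to four product pools with unidirectional first-order
conversion:

    dS/dt  = -(1/T1_S + sum_p k_p) * S
    dP/dt  =  k_p * S - P / T1_p,        P(0) = 0.

Assumptions baked into this model:

* **No back-conversion.**  Rates are apparent, forward-only constants.  In a
  cell suspension they are a superposition of uptake and intracellular
  conversion; the package makes no attempt to separate the two.
* **Well-mixed pools.**  Each resonance is one kinetic compartment.  Rapidly
  exchanging species (CO2 and bicarbonate) are treated as one pooled signal.
* **RF sampling as discrete losses.**  Each excitation at flip angle alpha
  (degrees) multiplies every pool's longitudinal magnetization by cos(alpha)
  and produces an observed signal proportional to sin(alpha) times the
  pre-pulse magnetization.  The forward simulators apply the cosine loss
  discretely at every acquisition instant (0, TR, 2 TR, ...), matching the
  physical pulse sequence.  For closed-form work the same loss is absorbed
  into a continuous rate -ln(cos alpha)/TR; at 5 degrees every 3 s the two
  descriptions agree to better than 0.1% over a full acquisition, and on the
  sampling grid itself they coincide exactly for the substrate.
* **Time origin.**  t = 0 is the injection into the NMR tube.  The
  dissolution-to-injection transfer is a separate parameter
  (`transfer_time`), used to express peak times relative to dissolution and
  to back-extrapolate polarization between instruments.

Three routes through the same physics are implemented and cross-checked in
the tests rather than trusted individually: an adaptive ODE integration
(`simulate_magnetization`, LSODA), an exact piecewise-analytic propagation
between pulses (`propagate_pulsed`, the fast path used in fitting), and the
textbook two-pool solution (`closed_form_product`).

Derived metrics use the effective decay rates
rho_s = 1/T1_S + sum(k) - ln(cos a)/TR and rho_p = 1/T1_p - ln(cos a)/TR:

* time of maximum, t_max = ln(rho_p/rho_s)/(rho_p - rho_s) — independent of
  k and of the amplitude, so it is a pure relaxation/sampling observable;
* normalized AUC = k/(rho_s * rho_p) — the model curve integrated over
  [0, inf) divided by the initial substrate signal.  With equal product
  decay rates, AUC ratios equal rate ratios, which is what justifies
  comparing phenomenological AUCs across conditions.

## Parameters that matter

| parameter | unit | default / typical | why |
|---|---|---|---|
| `T1` per pool | s | channel presets: 51.4 / 35.4 (pyruvate C1 -> BCO2), 34.5 / 11.2 (pyruvate C2 -> ethanol), 55.2 (fumarate) | sets the observation window; product T1 strongly limits how much product signal ever exists |
| `k` per product | 1/s | presets: 2.92e-3 (BCO2), 2.15e-3 (ethanol) | the quantity of interest; scales linearly with cell density |
| `flip_angle` | deg | 5 | small tip preserves magnetization across ~60 acquisitions while sin(alpha) stays measurable |
| `repetition_time` | s | 3 | time resolution vs RF depletion trade-off |
| `n_acquisitions` | – | 60 | ~3 min window, a few substrate T1s |
| `transfer_time` | s | 26.2 | delay between dissolution and first spectrum |
| `noise_sd` | signal units | from substrate-peak SNR (50 by default in presets) | i.i.d. Gaussian noise on every integral |

The fumarate preset's product parameters (malate T1 = 30 s, k = 2.0e-3 1/s)
are plausible synthetic choices, not measured values; they exist so the
pipeline has a second substrate family to exercise.

## The synthetic generator: what it emulates, what it does not

`generate_timeseries` forward-simulates the model at the acquisition
instants and adds i.i.d. Gaussian noise to every integral — the structure of
a per-resonance integral table exported from a spectrometer.
`generate_spectra` renders each acquisition as a sum of Lorentzian peaks
(areas equal to the sampled signals, area-normalized on the generated ppm
axis), optionally a smooth cubic baseline, an optional symmetric doublet for
a 13C-13C coupled label (off by default), and per-point Gaussian noise.
Chemical shifts and linewidths are conventional placements for synthesis,
not measurements.

Deliberately **not** emulated: FID-level phase errors, field drift,
lineshape distortion, radiation damping, intra- vs extracellular relaxation
differences, substrate depletion of the thermal bath, vendor raw formats.
Consequently, passing tests demonstrate that the analysis chain is
self-consistent and recovers known ground truth under the stated noise
model — not that it is robust to every artifact of real spectrometer data.

## Fitting

`fit_kinetics` minimizes `sum_pools w_pool * sum_t (model - data)^2` with
BFGS.  Choices:

* **Log-space parameters** (amplitude, rates, free T1s): enforces
  positivity without bound handling and equalizes scales across rates that
  can span orders of magnitude.
* **Initial guesses**: amplitude from the first substrate point; T1s from
  the user-supplied nominal values; each rate from (early product rise) /
  (substrate area over the same interval).
* **Restarts**: the best of 3 seeded, jittered starts (sd 0.1 in log space)
  is kept; a stalled optimizer returns `converged=False` instead of raising.
* **Convergence**: gradient tolerance 1e-10 on the scaled objective (data
  normalized by the substrate maximum).
* **Fixed zeros**: products declared unobserved contribute k = 0 exactly and
  their columns are excluded from the residual.
* **Weights**: per-pool residual multipliers (default 1) let a user
  down-weight an untrusted trace; boosting one substrate/product pair's
  weights by 1e6 reproduces the fit on that pathway alone to 1%.
* **Uncertainty proxy**: sqrt(2 * SSR/dof * diag(H^-1)) on the log
  parameters from the BFGS inverse-Hessian approximation — a quick relative
  error indicator, not a formal confidence interval.

The dual-exponential decay fit (`fit_dual_exponential`, used for T1
determination) runs through lmfit with non-negative amplitudes, orders the
two time constants, and coalesces them when they agree within 0.5% so that
single-exponential data cleanly yield one amplitude ~ 0.

### Recovery protocol and its information limits

The statistical recovery runs (acceptance script and tests) generate the
two natural-abundance pyruvate channels at substrate-peak SNR 50, 60 points
every 3 s, and fit the rate and amplitude with the T1s held at their known
scenario values; the noiseless exact-recovery runs instead leave all T1s
free and demand 0.1% agreement.

A Cramér–Rao analysis of these conditions is sobering and worth recording.
For the BCO2 channel the per-replicate bound on sd(k)/k is ~7%, combining
the product-amplitude information with the substrate-decay information; the
observed median |relative error| over 50 replicates is ~4.6%.  For the
ethanol channel the short product T1 (11.2 s) suppresses the product signal
to ~1.3% of the substrate peak (peak SNR < 1 at substrate SNR 50), and the
bound is ~17% per replicate even with every other parameter known; the
observed median |relative error| is ~12%, i.e. the estimator sits at the
information limit, and no fitting procedure could recover that rate to a
few percent from a single such dataset.  The *median over replicates* is
still accurate (bias ~1%), which is why median rates are the reported
recovery outputs.

## Numerical choices

* ODE integration: LSODA, rtol 1e-10, atol 1e-14 (rates span ~1e-7..1e-1
  1/s and the conservation checks require <1e-9 relative).
* Degenerate closed forms (rho_p -> rho_s) switch to their analytic limits
  at a relative rate difference of 1e-12.
* Baseline correction fits the polynomial on the flank margins only — never
  through the peak — and degrades the order with a warning when the flanks
  are too sparse for a cubic.
* Trapezoidal integration on the ascending ppm axis; integration windows
  are user-set per peak.  A window of +-x half-widths of a Lorentzian
  captures the fraction (2/pi) * arctan(x) of its area, so windows should be
  generous (tens of linewidths) when absolute areas matter.
* CSV round-trips are bit-lossless (`%.17g` on write, round-trip float
  parsing on read).

## Known limitations

* Rates are apparent (uptake + conversion); no compartmental separation.
* No formal confidence intervals; the residual-based proxy underestimates
  uncertainty when residuals are correlated.
* The polarization back-extrapolation between spectrometers is a
  mono-exponential in a single effective T1; with transfer-time spreads of
  several seconds its systematic error can reach a few percentage points of
  polarization.
* The Henderson–Hasselbalch helper is the textbook relation; it does not
  attempt to model activity corrections or temperature dependence of the
  bicarbonate pKa.
* Fitting more than ~2 free T1s plus rates from a single noisy dataset is
  ill-conditioned; hold T1s fixed at nominal values when SNR is modest.
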