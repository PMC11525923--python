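# hypermet

Simulation and kinetic analysis of **hyperpolarized ¹³C NMR metabolism
experiments** — the kind of dissolution-DNP study in which a hyperpolarized
substrate (pyruvate, fumarate) is injected into a metabolizing cell
suspension (e.g. a dense baker's-yeast "metabolic phantom") and its
conversion into product pools is followed in real time, one small-flip-angle
spectrum every few seconds.

It is written for spectroscopists and methods developers who need to turn
per-resonance signal tables or spectra into conversion rate constants,
relaxation times, normalized areas under the curve and peak times — and to
test that whole analysis chain against synthetic data with known ground
truth.

## The model

One substrate pool S feeds up to four product pools P by irreversible
first-order kinetics, while every pool relaxes with its own longitudinal
relaxation time T₁ and is depleted by the RF sampling itself:

```
dS/dt  = −(1/T₁ˢ + Σₚ kₚ) · S
dPₚ/dt = kₚ · S − Pₚ / T₁ᵖ
```

Each excitation with flip angle α converts sin α of the longitudinal
magnetization into signal and leaves cos α behind; with repetition time TR
this is equivalent, on average, to an extra decay rate −ln(cos α)/TR.  The
effective decay rates

```
ρ_s = 1/T₁ˢ + Σₚ kₚ − ln(cos α)/TR        ρ_p = 1/T₁ᵖ − ln(cos α)/TR
```

give the two-pool closed form P(t) = k·s₀·(e^(−ρ_s t) − e^(−ρ_p t))/(ρ_p − ρ_s),
the peak time t_max = ln(ρ_p/ρ_s)/(ρ_p − ρ_s), and the normalized area under
the curve AUC = k/(ρ_s·ρ_p), all used as independent oracles for the
numerical machinery.

All observed trajectories are fitted **simultaneously** by weighted least
squares with BFGS over log-transformed parameters (positivity without
bounds; rates may span many orders of magnitude).  Unobserved metabolites
can be pinned to k = 0 exactly.  Because conversion losses are modeled
explicitly, the fitted relaxation times are "T₁,real", not conflated with
metabolism.

Around the core sit: a seeded synthetic-data generator (integral tables and
Lorentzian spectra with Gaussian noise), the spectrum-to-integral path
(exponential apodization, per-peak cubic baseline fitted on the flanks,
phase correction, trapezoidal integration), polarization bookkeeping
(thermal polarization, enhancement factors, flip-angle/gain/scan-count
corrections, mono-exponential transfer decay) and the deterministic bench
formulas (hemocytometer counting, dilutions, Henderson–Hasselbalch pH).

## Worked example

Simulate the natural-abundance pyruvate → BCO₂ (pooled CO₂ + bicarbonate)
channel — T₁ 51.4 s / 35.4 s, k = 2.92×10⁻³ 1/s, 5° pulses every 3 s,
substrate-peak SNR 50 — and fit it back:

```python
from hypermet import FitSpec, fit_kinetics, generate_timeseries, preset_na_pyruvate_c1

scenario = preset_na_pyruvate_c1(seed=1, snr=50.0)
table, truth = generate_timeseries(scenario)
spec = FitSpec(
    substrate="pyruvate_c1",
    products=("bco2",),
    t1_init={"pyruvate_c1": 51.4, "bco2": 35.4},
)
fit = fit_kinetics(table, spec, scenario.scheme)
print(f"k (pyruvate -> BCO2)  : {fit.rates['bco2']:.3e} 1/s  (truth {truth.rates['bco2']:.3e})")
print(f"T1,real pyruvate      : {fit.t1_real['pyruvate_c1']:.1f} s")
print(f"T1,real BCO2          : {fit.t1_real['bco2']:.1f} s")
print(f"normalized AUC (BCO2) : {fit.auc_norm['bco2']:.2f}")
print(f"t_max (BCO2)          : {fit.t_max['bco2']:.1f} s after injection, "
      f"{fit.t_max_dissolution['bco2']:.1f} s after dissolution")
print(f"converged             : {fit.converged}")
```

which prints:

```
k (pyruvate -> BCO2)  : 3.047e-03 1/s  (truth 2.920e-03)
T1,real pyruvate      : 51.4 s
T1,real BCO2          : 29.8 s
normalized AUC (BCO2) : 3.68
t_max (BCO2)          : 34.5 s after injection, 60.7 s after dissolution
converged             : True
```

The rate comes back within ~4% of the generating value at this noise level;
the peak time lands near the ~63 s (after dissolution) that such a channel
peaks at.  The same works from the shell:

```bash
hypermet simulate --preset na-pyruvate-c1 --seed 1 --outdir run/
hypermet fit --input run/timeseries.csv --outdir run/fit \
    --t1 pyruvate_c1=51.4 --t1 bco2=35.4
hypermet polarization --hyper-integral 2.1e5 --thermal-integral 640 \
    --thermal-scans 1800 --hyper-flip 5 --thermal-flip 90 --field 1.0
```

`simulate` writes the integral table (a commented CSV carrying the
acquisition metadata), the generating truth and the resolved config;
`fit` writes a parameter report, fitted curves and a QC plot.

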