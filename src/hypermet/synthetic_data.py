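"""Seeded synthetic hyperpolarized experiments with known ground truth.

Emulates the data structure a dissolution-DNP metabolism run produces: a
hyperpolarized substrate decaying by T1, sampled every TR seconds with a
small flip angle, feeding up to four product pools, observed either as
pre-integrated per-resonance signal tables or as frequency-domain spectra of
Lorentzian peaks with additive Gaussian noise.

The bundled presets encode the natural-abundance pyruvate study conditions
(printed relaxation times 51.4 / 34.5 / 35.4 / 11.2 s and conversion rates
2.92e-3 and 2.15e-3 1/s, 5 degree pulses every 3 s) as two independent
channels, one per co-hyperpolarized carbon:

* C1 channel: [1-13C]pyruvate -> pooled CO2 + bicarbonate ("BCO2");
* C2 channel: [2-13C]pyruvate -> [1-13C]ethanol;

plus a fumarate -> malate preset.  Chemical shifts and linewidths are
conventional placements for spectral synthesis, not measured values.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SignalTimeSeries
from .kinetic_model import (
    AcquisitionScheme,
    ConversionSet,
    Pool,
    simulate_magnetization,
)
from .spectral_processing import Spectrum

#: 13C gyromagnetic ratio over 2*pi, MHz/T — used to convert Hz linewidths
#: to ppm on the synthetic axis.
CARBON13_MHZ_PER_T = 10.7084


@dataclass(frozen=True)
class Scenario:
    """Full description of one synthetic experiment.

    ``noise_sd`` is the standard deviation of the i.i.d. Gaussian noise added
    to every integral (signal units); ``spectral_noise_sd`` the per-point
    noise of synthetic spectra.  ``density_scale`` records the cumulative
    rate scaling applied by :func:`scale_density` (the rates in
    ``conversions`` are always the ones actually used).  A fixed ``seed``
    makes every output byte-identical.
    """

    substrate: Pool
    products: tuple[Pool, ...]
    conversions: ConversionSet
    scheme: AcquisitionScheme
    noise_sd: float = 0.0
    spectral_noise_sd: float = 0.0
    baseline_coefficients: tuple[float, ...] = ()
    doublet_splitting_hz: Mapping[str, float] = field(default_factory=dict)
    density_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "products", tuple(self.products))
        object.__setattr__(
            self, "doublet_splitting_hz", dict(self.doublet_splitting_hz)
        )
        if self.substrate.role != "substrate":
            raise ValueError("scenario substrate must have role 'substrate'")
        if self.noise_sd < 0 or self.spectral_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if not self.density_scale > 0:
            raise ValueError("density_scale must be positive")

    @property
    def pools(self) -> tuple[Pool, ...]:
        return (self.substrate,) + self.products


@dataclass(frozen=True)
class ScenarioTruth:
    """Generating parameters emitted alongside the data for recovery tests."""

    rates: dict[str, float]
    t1: dict[str, float]
    s0: float
    noise_sd: float
    density_scale: float
    seed: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _truth(scenario: Scenario) -> ScenarioTruth:
    return ScenarioTruth(
        rates=dict(scenario.conversions.rates),
        t1={p.name: p.T1 for p in scenario.pools},
        s0=scenario.substrate.s0,
        noise_sd=scenario.noise_sd,
        density_scale=scenario.density_scale,
        seed=scenario.seed,
    )


def _noiseless_observed(scenario: Scenario) -> pd.DataFrame:
    sim = simulate_magnetization(
        scenario.substrate,
        scenario.products,
        scenario.conversions,
        scenario.scheme,
        scenario.scheme.acquisition_times(),
    )
    return sim.observed


def generate_timeseries(scenario: Scenario) -> tuple[SignalTimeSeries, ScenarioTruth]:
    """Forward-simulate the scenario and sample noisy integral trajectories."""
    observed = _noiseless_observed(scenario)
    values = observed.to_numpy(copy=True)
    if scenario.noise_sd > 0:
        rng = np.random.default_rng([scenario.seed, 0])
        values = values + rng.normal(0.0, scenario.noise_sd, values.shape)
    scheme = scenario.scheme
    ts = SignalTimeSeries(
        times=scenario.scheme.acquisition_times(),
        signals=pd.DataFrame(values, columns=observed.columns),
        time_reference="injection",
        meta={
            "flip_angle_deg": scheme.flip_angle,
            "repetition_time_s": scheme.repetition_time,
            "transfer_time_s": scheme.transfer_time,
            "field_T": scheme.field,
            "temperature_K": scheme.temperature,
            "noise_sd": scenario.noise_sd,
            "substrate": scenario.substrate.name,
        },
    )
    return ts, _truth(scenario)


def _lorentzian_unit(ppm: np.ndarray, center: float, fwhm_ppm: float) -> np.ndarray:
    hwhm = fwhm_ppm / 2.0
    shape = (hwhm / math.pi) / ((ppm - center) ** 2 + hwhm**2)
    # normalize on the generated axis so peak areas equal injected signals
    return shape / np.trapezoid(shape, ppm)


def generate_spectra(
    scenario: Scenario,
    ppm_axis: np.ndarray | None = None,
    points: int = 4096,
    margin_ppm: float = 8.0,
) -> list[Spectrum]:
    """Render each acquisition as a sum of Lorentzian peaks plus noise.

    Each pool contributes a Lorentzian centered at its chemical shift whose
    area (on the generated axis) equals its noiseless sampled signal;
    optionally a smooth cubic baseline (``baseline_coefficients``, evaluated
    in ppm relative to the axis midpoint) and per-point Gaussian noise are
    added.  A warning is emitted when two peaks sit closer than three
    linewidths, since integration windows are then ill-defined.
    """
    f0_mhz = CARBON13_MHZ_PER_T * scenario.scheme.field
    pools = scenario.pools
    fwhms = {p.name: p.linewidth_hz / f0_mhz for p in pools}
    shifts = {p.name: p.chemical_shift for p in pools}

    if ppm_axis is None:
        lo = min(shifts.values()) - margin_ppm
        hi = max(shifts.values()) + margin_ppm
        ppm_axis = np.linspace(lo, hi, points)
    ppm_axis = np.asarray(ppm_axis, dtype=float)

    names = sorted(shifts, key=shifts.get)
    for a, b in zip(names[:-1], names[1:]):
        gap = shifts[b] - shifts[a]
        if gap < 3.0 * max(fwhms[a], fwhms[b]):
            warnings.warn(
                f"peaks {a!r} and {b!r} are {gap:.3g} ppm apart, closer than three "
                "linewidths: integration windows are ill-defined",
                stacklevel=2,
            )

    shapes = {}
    for p in pools:
        split_hz = scenario.doublet_splitting_hz.get(p.name, 0.0)
        if split_hz > 0:
            half = split_hz / f0_mhz / 2.0
            shapes[p.name] = 0.5 * (
                _lorentzian_unit(ppm_axis, p.chemical_shift - half, fwhms[p.name])
                + _lorentzian_unit(ppm_axis, p.chemical_shift + half, fwhms[p.name])
            )
        else:
            shapes[p.name] = _lorentzian_unit(ppm_axis, p.chemical_shift, fwhms[p.name])

    baseline = np.zeros_like(ppm_axis)
    if scenario.baseline_coefficients:
        baseline = np.polynomial.Polynomial(
            scenario.baseline_coefficients
        )(ppm_axis - ppm_axis.mean())

    observed = _noiseless_observed(scenario)
    rng = np.random.default_rng([scenario.seed, 1])
    spectra = []
    for t, row in zip(observed.index.to_numpy(), observed.to_numpy()):
        trace = baseline.copy()
        for name, signal in zip(observed.columns, row):
            trace += signal * shapes[name]
        if scenario.spectral_noise_sd > 0:
            trace = trace + rng.normal(0.0, scenario.spectral_noise_sd, trace.shape)
        spectra.append(
            Spectrum(ppm=ppm_axis, intensity=trace, acquisition_time=float(t))
        )
    return spectra


def scale_density(scenario: Scenario, factor: float) -> Scenario:
    """Scale every conversion rate by ``factor``, leaving T1s unchanged.

    Models changing the yeast cell density: observed conversion rates grow
    proportionally with the number of cells while relaxation does not.
    """
    if not factor > 0:
        raise ValueError("factor must be positive")
    return replace(
        scenario,
        conversions=scenario.conversions.scaled(factor),
        density_scale=scenario.density_scale * factor,
    )


def noise_sd_for_substrate_snr(scenario: Scenario, snr: float) -> float:
    """Noise level giving the requested peak substrate signal-to-noise ratio."""
    if not snr > 0:
        raise ValueError("snr must be positive")
    peak = float(np.max(np.abs(_noiseless_observed(scenario)[scenario.substrate.name])))
    return peak / snr


def _scheme_9p4T(
    n_acquisitions: int, repetition_time: float, transfer_time: float, gain: float
) -> AcquisitionScheme:
    return AcquisitionScheme(
        flip_angle=5.0,
        repetition_time=repetition_time,
        n_acquisitions=n_acquisitions,
        field=9.4,
        temperature=310.0,
        transfer_time=transfer_time,
        receiver_gain=gain,
        gain_unit="linear",
    )


def _with_snr(scenario: Scenario, snr: float | None) -> Scenario:
    if snr is None:
        return scenario
    return replace(scenario, noise_sd=noise_sd_for_substrate_snr(scenario, snr))


def preset_na_pyruvate_c1(
    seed: int = 0,
    snr: float | None = 50.0,
    n_acquisitions: int = 60,
    repetition_time: float = 3.0,
) -> Scenario:
    """C1 channel of natural-abundance pyruvate: [1-13C]pyruvate -> BCO2.

    T1s 51.4 s (substrate) and 35.4 s (BCO2), conversion 2.92e-3 1/s,
    5 degree pulses, 26.2 s dissolution-to-first-spectrum transfer.
    ``snr`` sets the substrate-peak signal-to-noise ratio (None = noiseless).
    """
    scenario = Scenario(
        substrate=Pool(
            "pyruvate_c1", T1=51.4, role="substrate", s0=1.0,
            chemical_shift=170.7, linewidth_hz=2.0,
        ),
        products=(
            Pool("bco2", T1=35.4, chemical_shift=160.9, linewidth_hz=2.0),
        ),
        conversions=ConversionSet({"bco2": 2.92e-3}),
        scheme=_scheme_9p4T(n_acquisitions, repetition_time, transfer_time=26.2, gain=101.0),
        seed=seed,
    )
    return _with_snr(scenario, snr)


def preset_na_pyruvate_c2(
    seed: int = 0,
    snr: float | None = 50.0,
    n_acquisitions: int = 60,
    repetition_time: float = 3.0,
) -> Scenario:
    """C2 channel of natural-abundance pyruvate: [2-13C]pyruvate -> ethanol.

    T1s 34.5 s (substrate) and 11.2 s (ethanol), conversion 2.15e-3 1/s.
    """
    scenario = Scenario(
        substrate=Pool(
            "pyruvate_c2", T1=34.5, role="substrate", s0=1.0,
            chemical_shift=205.8, linewidth_hz=2.0,
        ),
        products=(
            Pool("ethanol", T1=11.2, chemical_shift=57.9, linewidth_hz=2.0),
        ),
        conversions=ConversionSet({"ethanol": 2.15e-3}),
        scheme=_scheme_9p4T(n_acquisitions, repetition_time, transfer_time=26.2, gain=101.0),
        seed=seed,
    )
    return _with_snr(scenario, snr)


def preset_fumarate(
    seed: int = 0,
    snr: float | None = 50.0,
    n_acquisitions: int = 60,
    repetition_time: float = 3.0,
) -> Scenario:
    """Labeled fumarate -> malate.

    Substrate T1 55.2 s; the malate T1 (30 s) and the conversion rate
    (2.0e-3 1/s) are synthetic choices of a plausible magnitude — the study
    conditions print no absolute values for them.
    """
    scenario = Scenario(
        substrate=Pool(
            "fumarate", T1=55.2, role="substrate", s0=1.0,
            chemical_shift=175.4, linewidth_hz=2.0,
        ),
        products=(
            Pool("malate", T1=30.0, chemical_shift=181.6, linewidth_hz=2.0),
        ),
        conversions=ConversionSet({"malate": 2.0e-3}),
        scheme=_scheme_9p4T(n_acquisitions, repetition_time, transfer_time=26.0, gain=10.0),
        seed=seed,
    )
    return _with_snr(scenario, snr)


PRESETS = {
    "na-pyruvate-c1": preset_na_pyruvate_c1,
    "na-pyruvate-c2": preset_na_pyruvate_c2,
    "fumarate": preset_fumarate,
}
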