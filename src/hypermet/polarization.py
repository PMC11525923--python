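"""Polarization bookkeeping for dissolution-DNP experiments.

Thermal-equilibrium polarization, hyperpolarization enhancement factors,
quantification of hyperpolarized signal against an averaged thermal
reference (with flip-angle, receiver-gain and scan-count corrections), and
mono-exponential back-extrapolation of polarization between spectrometers
with different transfer times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.constants import hbar, k as k_B

from .kinetic_model import AcquisitionScheme

#: 13C gyromagnetic ratio, rad s^-1 T^-1 (gamma/2pi = 10.7084 MHz/T)
GAMMA_13C = 2.0 * math.pi * 10.7084e6


@dataclass(frozen=True)
class PolarizationEstimate:
    """A polarization level (fraction) with its measurement context."""

    P: float
    field: float
    temperature: float
    reference_time: float | None = None
    T1_used: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.P <= 1.0:
            raise ValueError(f"polarization must be a fraction in [0, 1], got {self.P}")


def thermal_polarization(
    field: float, temperature: float, gyromagnetic_ratio: float = GAMMA_13C
) -> float:
    """Boltzmann polarization tanh(hbar*gamma*B / (2*kB*T)) of a spin-1/2."""
    if field < 0:
        raise ValueError("field must be >= 0")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    return math.tanh(hbar * gyromagnetic_ratio * field / (2.0 * k_B * temperature))


def enhancement_factor(
    P: float, field: float, temperature: float, gyromagnetic_ratio: float = GAMMA_13C
) -> float:
    """Signal enhancement over thermal equilibrium at the stated field/temperature."""
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must be a fraction in [0, 1]")
    return P / thermal_polarization(field, temperature, gyromagnetic_ratio)


def linear_gain(value: float, unit: str) -> float:
    """Receiver gain as a linear voltage multiplier (dB uses 20*log10)."""
    if unit == "dB":
        return 10.0 ** (value / 20.0)
    if unit == "linear":
        if not value > 0:
            raise ValueError("linear gain must be positive")
        return value
    raise ValueError(f"unknown gain unit {unit!r}")


def quantify_polarization(
    hyper_integral: float,
    thermal_integral: float,
    hyper_scheme: AcquisitionScheme,
    thermal_scheme: AcquisitionScheme,
    thermal_scan_count: int,
    gyromagnetic_ratio: float = GAMMA_13C,
) -> PolarizationEstimate:
    """Polarization of the first hyperpolarized spectrum vs a thermal reference.

    ``P = (S_hyper / S_thermal_per_scan) * (sin a_th / sin a_hyper)
    * (g_th / g_hyper) * P_thermal``.  The thermal integral is divided by its
    scan count (per-scan mean of the averaged spectrum); gains are converted
    to linear multipliers according to each scheme's ``gain_unit``.
    """
    if thermal_integral == 0:
        raise ValueError("thermal integral is zero; cannot quantify polarization")
    if thermal_scan_count < 1:
        raise ValueError("thermal_scan_count must be >= 1")
    if hyper_scheme.flip_angle <= 0:
        raise ValueError("hyperpolarized flip angle must be > 0")
    s_thermal = thermal_integral / thermal_scan_count
    flip = math.sin(math.radians(thermal_scheme.flip_angle)) / math.sin(
        math.radians(hyper_scheme.flip_angle)
    )
    gain = linear_gain(thermal_scheme.receiver_gain, thermal_scheme.gain_unit) / linear_gain(
        hyper_scheme.receiver_gain, hyper_scheme.gain_unit
    )
    p_th = thermal_polarization(
        thermal_scheme.field, thermal_scheme.temperature, gyromagnetic_ratio
    )
    P = (hyper_integral / s_thermal) * flip * gain * p_th
    return PolarizationEstimate(
        P=P,
        field=hyper_scheme.field,
        temperature=hyper_scheme.temperature,
        reference_time=hyper_scheme.transfer_time,
    )


def back_extrapolate(P_at_A: float, t_A: float, t_B: float, T1: float) -> float:
    """Mono-exponential transfer-decay model: P_B = P_A * exp(-(t_B - t_A)/T1).

    Projects a polarization measured at time ``t_A`` after dissolution to a
    different reference time ``t_B`` (e.g. between two spectrometers with
    different transfer lines).  Monotone decreasing in ``t_B``.
    """
    if not T1 > 0:
        raise ValueError("T1 must be positive")
    if not 0.0 <= P_at_A <= 1.0:
        raise ValueError("P_at_A must be a fraction in [0, 1]")
    return P_at_A * math.exp(-(t_B - t_A) / T1)
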