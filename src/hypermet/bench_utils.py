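"""Deterministic bench arithmetic: cell counting, dilutions, pH.

Hemocytometer counting (Neubauer chamber), aliquot and dilution arithmetic,
and the Henderson-Hasselbalch relation for the bicarbonate/CO2 pair.  All
closed forms; round-trips hold to 1e-12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: approximate pKa of the bicarbonate/CO2 equilibrium at physiological
#: ionic strength
BICARBONATE_PKA = 6.1


def cells_per_ml(counted: float, dilution: float) -> float:
    """Neubauer chamber density: counted cells x dilution x 10^4 per mL."""
    if counted < 0:
        raise ValueError("counted must be >= 0")
    if dilution < 1:
        raise ValueError("dilution must be >= 1")
    return counted * dilution * 1e4


def cells_in_aliquot(concentration: float, volume_ml: float) -> float:
    """Number of cells in a withdrawn volume (concentration in cells/mL)."""
    if concentration < 0 or volume_ml < 0:
        raise ValueError("inputs must be >= 0")
    return concentration * volume_ml


@dataclass(frozen=True)
class CellCount:
    """A hemocytometer count with its dilution factor."""

    counted: int
    dilution: float

    @property
    def concentration(self) -> float:
        """Cells per mL."""
        return cells_per_ml(self.counted, self.dilution)


def dilute(c0: float, v0: float, v_added: float) -> float:
    """Concentration after adding ``v_added`` of diluent: c0*v0/(v0+v_added)."""
    if not v0 > 0:
        raise ValueError("v0 must be positive")
    if v_added < 0:
        raise ValueError("v_added must be >= 0")
    return c0 * v0 / (v0 + v_added)


def henderson_hasselbalch_ph(ratio_base_to_acid: float, pKa: float) -> float:
    """pH = pKa + log10([base]/[acid]) — e.g. [HCO3-]/[CO2]."""
    if not ratio_base_to_acid > 0:
        raise ValueError("ratio must be positive")
    return pKa + math.log10(ratio_base_to_acid)


def ratio_from_ph(pH: float, pKa: float) -> float:
    """Inverse of :func:`henderson_hasselbalch_ph`: [base]/[acid] = 10^(pH-pKa)."""
    return 10.0 ** (pH - pKa)
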