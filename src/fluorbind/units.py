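"""Concentration-unit bookkeeping.

Quenching titrations in the binding literature are routinely reported with
concentrations in mM (or µM) while the derived constants are quoted in M⁻¹,
so every fit in this package carries the unit of the concentration grid it
was performed on and conversions are explicit.
"""

from __future__ import annotations

#: multiply a concentration in the given unit by this factor to obtain molar
TO_MOLAR: dict[str, float] = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
}


def _factor(unit: str) -> float:
    try:
        return TO_MOLAR[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; known units: "
            f"{sorted(TO_MOLAR)}"
        ) from None


def to_molar(concentration: float, unit: str) -> float:
    """Convert a concentration in *unit* to mol/L."""
    return concentration * _factor(unit)


def per_concentration_to_per_molar(value: float, unit: str) -> float:
    """Convert a reciprocal-concentration constant (e.g. Ksv in mM⁻¹, or a
    quenching rate constant in mM⁻¹s⁻¹) to the reciprocal-molar scale.

    1 mM⁻¹ = 1000 M⁻¹, so the value is divided by the unit's molar factor.
    """
    return value / _factor(unit)
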