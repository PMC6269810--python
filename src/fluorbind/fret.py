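"""Förster resonance energy transfer: overlap integral, Förster radius,
transfer efficiency and donor–acceptor distance.

The spectral overlap between the donor emission F(λ) and the acceptor molar
extinction ε(λ) is

    J = ∫ F(λ)·ε(λ)·λ⁴ dλ / ∫ F(λ) dλ        [cm³·M⁻¹, λ in cm]

(normalisation makes J independent of the donor intensity scale). The
Förster radius follows from

    R₀⁶ = 8.8×10⁻²⁵ · K² · n⁻⁴ · φ · J        [cm⁶]

with orientation factor K² (2/3 for freely rotating dipoles), medium
refractive index n (1.336 for aqueous buffer) and donor quantum yield φ,
which has no defensible universal default and must be supplied. The
transfer efficiency is E = 1 − F/F₀ = R₀⁶/(R₀⁶ + r⁶), whence the
donor–acceptor distance r = R₀·((1−E)/E)^(1/6); at E = 0.5, r = R₀ exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum

FORSTER_PREFACTOR = 8.8e-25  # cm^6 per (M^-1 cm^3) of overlap, dimensionless K²·n⁻⁴·φ
NM_PER_CM = 1e7


@dataclass
class FretConstants:
    """Physical constants of a FRET calculation. ``phi`` (donor quantum
    yield) is mandatory; ``k2`` defaults to the isotropic-rotation value 2/3
    and ``n_ri`` to aqueous buffer, 1.336."""

    phi: float
    k2: float = 2.0 / 3.0
    n_ri: float = 1.336

    def __post_init__(self) -> None:
        if self.phi is None:
            raise ValueError("donor quantum yield phi must be supplied "
                             "(no default is scientifically defensible)")
        if not (0 < self.phi <= 1):
            raise ValueError("phi must lie in (0, 1]")
        if not (0 < self.k2 <= 4):
            raise ValueError("orientation factor k2 must lie in (0, 4]")
        if self.n_ri <= 0:
            raise ValueError("refractive index must be positive")


@dataclass
class FretResult:
    """Overlap integral ``j`` (cm³·M⁻¹), efficiency ``e``, Förster radius
    ``r0`` and donor–acceptor distance ``r`` (both nm). The stored (e, r0, r)
    triple satisfies e = r0⁶/(r0⁶ + r⁶)."""

    j: float
    e: float
    r0: float
    r: float
    constants: FretConstants

    def __post_init__(self) -> None:
        if 0 < self.e < 1 and self.r0 > 0:
            implied = self.r0 ** 6 / (self.r0 ** 6 + self.r ** 6)
            if abs(implied - self.e) > 1e-9 * self.e:
                raise ValueError(
                    f"inconsistent FRET triple: e={self.e} but r0/r imply "
                    f"{implied}"
                )


def overlap_integral(donor_emission: Spectrum,
                     acceptor_extinction: Spectrum) -> float:
    """Overlap integral J in cm³·M⁻¹ by trapezoidal quadrature.

    The acceptor extinction (M⁻¹cm⁻¹) is linearly interpolated onto the donor
    grid restricted to the common wavelength interval; an empty overlap is
    refused.
    """
    lo = max(donor_emission.wavelengths[0], acceptor_extinction.wavelengths[0])
    hi = min(donor_emission.wavelengths[-1], acceptor_extinction.wavelengths[-1])
    if hi <= lo:
        raise ValueError("donor emission and acceptor absorption share no "
                         "wavelength interval")
    mask = (donor_emission.wavelengths >= lo) & (donor_emission.wavelengths <= hi)
    if mask.sum() < 2:
        raise ValueError("overlap interval holds fewer than 2 donor samples")
    lam_nm = donor_emission.wavelengths[mask]
    F = donor_emission.intensities[mask]
    eps = np.interp(lam_nm, acceptor_extinction.wavelengths,
                    acceptor_extinction.intensities)
    lam_cm = lam_nm / NM_PER_CM
    denom = np.trapezoid(F, lam_cm)
    if denom <= 0:
        raise ValueError("donor emission integrates to zero over the overlap")
    return float(np.trapezoid(F * eps * lam_cm ** 4, lam_cm) / denom)


def forster_radius(j: float, constants: FretConstants) -> float:
    """Förster radius R₀ in nm from the overlap integral.

    R₀⁶ = 8.8×10⁻²⁵·K²·n⁻⁴·φ·J in cm⁶ (the prefactor absorbs the numeric
    constants of the orientation-averaged dipole coupling), converted to nm.
    """
    if j < 0:
        raise ValueError("overlap integral must be nonnegative")
    r0_6_cm6 = (FORSTER_PREFACTOR * constants.k2 * constants.n_ri ** -4
                * constants.phi * j)
    return float(r0_6_cm6 ** (1.0 / 6.0) * NM_PER_CM)


def transfer_efficiency(f: float, f0: float) -> float:
    """E = 1 − F/F₀ from donor intensities with and without acceptor."""
    if f0 <= 0 or f <= 0:
        raise ValueError("intensities must be positive")
    if f > f0:
        raise ValueError("F > F0 would give a negative transfer efficiency")
    return 1.0 - f / f0


def donor_acceptor_distance(e: float, r0: float) -> float:
    """r = R₀·((1−E)/E)^(1/6); requires 0 < E < 1 (the distance is unbounded
    at E→0 and collapses to contact at E→1)."""
    if not (0 < e < 1):
        raise ValueError("transfer efficiency must lie strictly in (0, 1)")
    if r0 <= 0:
        raise ValueError("Förster radius must be positive")
    return float(r0 * ((1.0 - e) / e) ** (1.0 / 6.0))


def fret_analysis(donor_emission: Spectrum, acceptor_extinction: Spectrum,
                  f: float, f0: float, constants: FretConstants) -> FretResult:
    """Full Förster chain: J → R₀, E = 1 − F/F₀ → r."""
    j = overlap_integral(donor_emission, acceptor_extinction)
    r0 = forster_radius(j, constants)
    e = transfer_efficiency(f, f0)
    r = donor_acceptor_distance(e, r0)
    return FretResult(j=j, e=e, r0=r0, r=r, constants=constants)
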