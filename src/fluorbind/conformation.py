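"""Conformational probes: REES, synchronous-fluorescence slopes, red-shift
tracking and circular-dichroism bookkeeping.

REES (red-edge excitation shift) is the difference between the emission
maximum under red-edge excitation (305 nm) and under normal tryptophan
excitation (295 nm); a positive shift of a few nm reports motionally
restricted solvent dipoles around the indole ring. Synchronous scans at
Δλ = 15 nm and Δλ = 60 nm isolate the tyrosine and tryptophan
microenvironments respectively; the slope of F/F₀ against quencher
concentration compares how strongly each class of residue is involved in the
quenching. Circular-dichroism ellipticity is normalised to the mean residue
ellipticity [θ] = 100·θ_obs/(c·l); secondary-structure fractions are accepted
as externally deconvolved inputs and only differenced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import Spectrum, TitrationSeries, emission_maximum, peak_intensity

FRACTION_KEYS = ("helix_regular", "helix_distorted", "sheet_regular",
                 "sheet_distorted", "turn", "unordered")

FRACTION_SUM_TOL = 0.5  # percent; fractions must total 100 within this


@dataclass
class ReesResult:
    lam_max_295: float
    lam_max_305: float

    @property
    def rees(self) -> float:
        return self.lam_max_305 - self.lam_max_295


@dataclass
class SynchronousResult:
    """Slope of F/F₀ vs [Q] for a synchronous series at one Δλ, plus the
    total λmax shift over the titration and the straight-line residual RMS
    (any curvature of the F/F₀ trace shows up here, not in the model)."""

    delta_lambda: float
    slope: float
    intercept: float
    r: float
    residual_rms: float
    lam_max_shift: float
    unit: str = "M"


@dataclass
class ShiftTrack:
    """Per-point emission maxima over a titration."""

    lam_max: np.ndarray
    concentrations: np.ndarray

    @property
    def total_shift(self) -> float:
        return float(self.lam_max[-1] - self.lam_max[0])


@dataclass
class CdRecord:
    """One CD observation: observed ellipticity and/or externally computed
    secondary-structure percentages (regular/distorted helix, regular/
    distorted sheet, turn, unordered)."""

    system: str = ""
    theta_obs: float | None = None  # degrees
    mre: float | None = None        # deg·cm²·dmol⁻¹
    fractions: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.fractions is not None:
            unknown = set(self.fractions) - set(FRACTION_KEYS)
            if unknown:
                raise ValueError(f"unknown secondary-structure classes {sorted(unknown)}")
            self.validate_fractions()

    def validate_fractions(self) -> float:
        if self.fractions is None:
            raise ValueError("record carries no secondary-structure fractions")
        total = float(sum(self.fractions.values()))
        if abs(total - 100.0) > FRACTION_SUM_TOL:
            raise ValueError(
                f"secondary-structure fractions of {self.system or 'record'} "
                f"sum to {total:.2f}, outside 100 ± {FRACTION_SUM_TOL}"
            )
        return total


@dataclass
class StructureDelta:
    """Per-class percent changes (treated − native) with a monotonicity
    report for the canonical unfolding signature: helix and sheet down,
    unordered up."""

    deltas: dict[str, float]
    helix_down: bool
    sheet_down: bool
    unordered_up: bool


# ---------------------------------------------------------------------------


def rees(point_295: Spectrum, point_305: Spectrum,
         table_mode: bool = True) -> ReesResult:
    """REES from a matched pair of emission spectra of the same sample.

    ``point_295`` is the normally excited spectrum, ``point_305`` the
    red-edge one; both must carry excitation metadata. With ``table_mode``
    each λmax is rounded to integer nm before differencing (matching how
    REES tables are conventionally reported); otherwise the interpolated
    maxima are differenced raw.
    """
    for s, label in ((point_295, "normal-excitation"), (point_305, "red-edge")):
        if s.kind != "emission":
            raise ValueError(f"{label} spectrum must be an emission spectrum")
        if s.excitation is None:
            raise ValueError(f"{label} spectrum lacks excitation metadata")
    l295 = emission_maximum(point_295)
    l305 = emission_maximum(point_305)
    if table_mode:
        l295, l305 = round(l295), round(l305)
    return ReesResult(lam_max_295=float(l295), lam_max_305=float(l305))


def synchronous_slope(series: TitrationSeries) -> SynchronousResult:
    """Least-squares slope of F/F₀ (peak readout) against [Q] for a
    synchronous series at a single Δλ (mixed offsets are refused)."""
    offsets = {s.delta_lambda for s in series.spectra}
    if len(offsets) != 1 or None in offsets:
        raise ValueError(f"series must hold synchronous scans at one Δλ; "
                         f"found offsets {sorted(offsets, key=str)}")
    delta_lambda = offsets.pop()
    F = np.array([peak_intensity(s) for s in series.spectra])
    if np.any(F <= 0):
        raise ValueError("nonpositive intensity in synchronous series")
    y = F / F[0]
    q = series.concentrations
    reg = stats.linregress(q, y)
    resid = y - (reg.intercept + reg.slope * q)
    lam = [emission_maximum(s) for s in series.spectra]
    return SynchronousResult(
        delta_lambda=float(delta_lambda), slope=float(reg.slope),
        intercept=float(reg.intercept), r=float(reg.rvalue),
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        lam_max_shift=float(lam[-1] - lam[0]), unit=series.unit,
    )


def red_shift_track(series: TitrationSeries) -> ShiftTrack:
    """Emission maximum per titration point; ``total_shift`` is last − first."""
    lam = np.array([emission_maximum(s) for s in series.spectra])
    return ShiftTrack(lam_max=lam, concentrations=series.concentrations.copy())


def mean_residue_ellipticity(theta_obs: float, c: float, l: float) -> float:
    """Mean residue ellipticity [θ] = 100·θ_obs/(c·l).

    ``theta_obs`` in degrees, ``c`` in mol residue per cm³, ``l`` in cm;
    result in deg·cm²·dmol⁻¹.
    """
    if c <= 0 or l <= 0:
        raise ValueError("residue concentration and path length must be positive")
    return 100.0 * theta_obs / (c * l)


def structure_delta(native: CdRecord, treated: CdRecord) -> StructureDelta:
    """Treated − native secondary-structure changes per class.

    Both records must carry fraction sets totalling 100 ± 0.5 %. The
    monotonicity report states whether total helix and total sheet decreased
    and unordered coil increased — the canonical loosening signature of a
    ligand-destabilised protein.
    """
    native.validate_fractions()
    treated.validate_fractions()
    deltas = {k: treated.fractions[k] - native.fractions[k]
              for k in FRACTION_KEYS
              if k in native.fractions and k in treated.fractions}
    helix = deltas.get("helix_regular", 0.0) + deltas.get("helix_distorted", 0.0)
    sheet = deltas.get("sheet_regular", 0.0) + deltas.get("sheet_distorted", 0.0)
    return StructureDelta(
        deltas=deltas,
        helix_down=helix < 0,
        sheet_down=sheet < 0,
        unordered_up=deltas.get("unordered", 0.0) > 0,
    )


def load_cd_table(path: str | Path) -> list[CdRecord]:
    """Read a CSV of secondary-structure fractions (columns ``system`` plus
    the six class names in :data:`FRACTION_KEYS`, percentages)."""
    df = pd.read_csv(path)
    missing = [c for c in FRACTION_KEYS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing fraction columns {missing}")
    return [
        CdRecord(system=str(row.get("system", "")),
                 fractions={k: float(row[k]) for k in FRACTION_KEYS})
        for _, row in df.iterrows()
    ]
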