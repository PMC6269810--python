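"""Spectrum containers, CSV I/O, intensity corrections and peak location.

File formats
------------
Spectrum CSV: two columns with header ``wavelength_nm,intensity``.
Titration manifest CSV: columns
``concentration,unit,file,excitation_nm,delta_lambda_nm,added_volume_ml``,
one row per titration point, ``file`` relative to the manifest's directory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("fluorbind")

SPECTRUM_KINDS = frozenset({"emission", "absorption", "synchronous", "rls", "cd"})


@dataclass
class Spectrum:
    """A single wavelength-indexed trace.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm.
    intensities
        Fluorescence (arbitrary units), molar extinction (M⁻¹cm⁻¹) for
        ``kind="absorption"``, scattering intensity for ``kind="rls"`` or
        ellipticity (mdeg) for ``kind="cd"``.
    kind
        One of ``emission, absorption, synchronous, rls, cd``.
    excitation
        Excitation wavelength in nm (emission spectra), if known.
    delta_lambda
        Scan offset Δλ in nm (synchronous / RLS spectra), if known.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    kind: str = "emission"
    excitation: float | None = None
    delta_lambda: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(self.wavelengths)) and np.all(np.isfinite(self.intensities))):
            raise ValueError("spectrum contains non-finite values")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.kind == "absorption" and np.any(self.intensities < 0):
            raise ValueError("absorption/extinction values must be nonnegative")

    def interp_at(self, wavelength: float) -> float:
        """Linearly interpolated intensity at *wavelength* (nm)."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= wavelength <= hi):
            raise ValueError(
                f"wavelength {wavelength} nm outside scan range [{lo}, {hi}] nm"
            )
        return float(np.interp(wavelength, self.wavelengths, self.intensities))

    def scaled(self, factor: float) -> "Spectrum":
        """Copy with intensities multiplied by *factor*."""
        return replace(self, intensities=self.intensities * factor)


@dataclass
class TitrationSeries:
    """Concentration-aligned spectra sharing a quencher-free reference.

    The first point must be at concentration exactly 0: it defines F₀ for
    every quenching analysis downstream.
    """

    concentrations: np.ndarray
    spectra: list[Spectrum]
    unit: str = "M"
    protein_concentration: float | None = None  # mM
    ph: float | None = None
    temperature: float | None = None  # K
    initial_volume: float | None = None  # mL
    added_volumes: np.ndarray | None = None  # mL per point

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if len(self.spectra) != self.concentrations.size:
            raise ValueError("one spectrum per concentration required")
        if self.concentrations.size == 0:
            raise ValueError("empty titration series")
        if self.concentrations[0] != 0.0:
            raise ValueError(
                "first titration point must be at concentration exactly 0 "
                "(quencher-free reference defining F0)"
            )
        if np.any(np.diff(self.concentrations) < 0):
            raise ValueError("concentrations must be nondecreasing")
        if self.added_volumes is not None:
            self.added_volumes = np.asarray(self.added_volumes, dtype=float)
            if self.added_volumes.size != self.concentrations.size:
                raise ValueError("added_volumes must align with concentrations")

    def __len__(self) -> int:
        return int(self.concentrations.size)


# ---------------------------------------------------------------------------
# CSV I/O


def read_spectrum(path: str | Path, kind: str = "emission",
                  excitation: float | None = None,
                  delta_lambda: float | None = None) -> Spectrum:
    """Read a two-column ``wavelength_nm,intensity`` CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["wavelength_nm", "intensity"]
    if list(df.columns[:2]) != expected:
        raise ValueError(
            f"{path}: expected header {expected}, found {list(df.columns)}"
        )
    return Spectrum(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy(),
                    kind=kind, excitation=excitation, delta_lambda=delta_lambda)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)


MANIFEST_COLUMNS = ["concentration", "unit", "file", "excitation_nm",
                    "delta_lambda_nm", "added_volume_ml"]


def read_titration(manifest_path: str | Path, kind: str = "emission") -> TitrationSeries:
    """Load a titration series from a manifest CSV.

    Rows are sorted by concentration on load (with a logged notice if the
    manifest was out of order); a missing zero-concentration point is a hard
    error because no F₀ reference would exist. Malformed rows are reported
    with their (1-based, header-excluded) row numbers.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, float_precision="round_trip")
    missing_cols = [c for c in ("concentration", "unit", "file") if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{manifest_path}: manifest lacks columns {missing_cols}")

    bad: list[str] = []
    for i, row in df.iterrows():
        rowno = int(i) + 1
        if pd.isna(row["concentration"]):
            bad.append(f"row {rowno}: missing concentration")
        if pd.isna(row["file"]) or not (manifest_path.parent / str(row["file"])).exists():
            bad.append(f"row {rowno}: spectrum file {row.get('file')!r} not found")
    if bad:
        raise ValueError(f"{manifest_path}: malformed manifest rows: " + "; ".join(bad))

    units = sorted(set(df["unit"].astype(str)))
    if len(units) != 1:
        raise ValueError(f"{manifest_path}: mixed concentration units {units}")

    if not df["concentration"].is_monotonic_increasing:
        logger.warning("%s: manifest concentrations out of order; sorting on load",
                       manifest_path)
        df = df.sort_values("concentration", kind="stable").reset_index(drop=True)

    if df["concentration"].iloc[0] != 0.0:
        raise ValueError(
            f"{manifest_path}: no zero-concentration point — the first titration "
            "point must be the quencher-free reference (F0)"
        )

    spectra = []
    for _, row in df.iterrows():
        exc = row.get("excitation_nm")
        dl = row.get("delta_lambda_nm")
        spectra.append(read_spectrum(
            manifest_path.parent / str(row["file"]), kind=kind,
            excitation=None if pd.isna(exc) else float(exc),
            delta_lambda=None if pd.isna(dl) else float(dl),
        ))
    added = df["added_volume_ml"].fillna(0.0).to_numpy(dtype=float) \
        if "added_volume_ml" in df.columns else None
    return TitrationSeries(df["concentration"].to_numpy(dtype=float), spectra,
                           unit=units[0], added_volumes=added)


def write_titration(series: TitrationSeries, outdir: str | Path,
                    stem: str = "spectrum") -> Path:
    """Write one CSV per spectrum plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (c, s) in enumerate(zip(series.concentrations, series.spectra)):
        fname = f"{stem}_{i:03d}.csv"
        write_spectrum(s, outdir / fname)
        rows.append({
            "concentration": c,
            "unit": series.unit,
            "file": fname,
            "excitation_nm": s.excitation,
            "delta_lambda_nm": s.delta_lambda,
            "added_volume_ml": (series.added_volumes[i]
                                if series.added_volumes is not None else 0.0),
        })
    manifest = outdir / f"{stem}_manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# Corrections (§ both are multiplicative, hence commute)


def correct_inner_filter(f, a_ex: float, a_em: float):
    """Inner-filter correction F·10^((A_ex + A_em)/2).

    ``a_ex``/``a_em`` are the sample absorbances at the excitation and
    emission wavelengths. With a transparent sample (both 0) the intensity is
    returned unchanged.
    """
    if a_ex < 0 or a_em < 0:
        raise ValueError("absorbances must be nonnegative")
    return f * 10.0 ** ((a_ex + a_em) / 2.0)


def correct_dilution(f, v0: float, v_added: float):
    """Dilution correction F·(v0 + v_added)/v0 for cumulative titrant volume."""
    if v0 <= 0:
        raise ValueError("initial volume must be positive")
    if v_added < 0:
        raise ValueError("added volume must be nonnegative")
    return f * (v0 + v_added) / v0


def correct_series_dilution(series: TitrationSeries) -> TitrationSeries:
    """Apply per-point dilution corrections using the series' volume metadata.

    Returns the series unchanged when volume metadata is absent.
    """
    if series.initial_volume is None or series.added_volumes is None:
        return series
    spectra = [s.scaled((series.initial_volume + v) / series.initial_volume)
               for s, v in zip(series.spectra, series.added_volumes)]
    return replace(series, spectra=spectra)


# ---------------------------------------------------------------------------
# Peak location


def _locate_peak(s: Spectrum) -> tuple[float, float, bool]:
    """Return (wavelength, intensity, interpolated?) of the spectrum maximum.

    Three-point parabolic interpolation through the maximal sample and its
    neighbours; ties in the maximal value are broken toward the lower
    wavelength with no interpolation; a maximum on the grid boundary is
    returned as-is with a warning.
    """
    if len(s.wavelengths) < 3:
        raise ValueError("peak location needs at least 3 samples")
    y = s.intensities
    lam = s.wavelengths
    ymax = y.max()
    ties = np.flatnonzero(y == ymax)
    if ties.size > 1:
        i = int(ties.min())
        return float(lam[i]), float(y[i]), False
    i = int(ties[0])
    if i == 0 or i == len(y) - 1:
        warnings.warn("spectrum maximum lies on the grid boundary; "
                      "no interpolation performed", stacklevel=3)
        return float(lam[i]), float(y[i]), False
    coeffs = np.polyfit(lam[i - 1:i + 2], y[i - 1:i + 2], 2)
    a, b, _ = coeffs
    if a == 0:
        return float(lam[i]), float(y[i]), False
    vertex = -b / (2.0 * a)
    return float(vertex), float(np.polyval(coeffs, vertex)), True


def emission_maximum(s: Spectrum) -> float:
    """Wavelength (nm) of the emission maximum, sub-grid resolved.

    Uses parabolic interpolation through the maximal sample and its two
    neighbours so that ≲0.05-nm shifts of a smooth band are resolvable on a
    1-nm instrument grid. Equal-valued maxima resolve to the lower
    wavelength; a boundary maximum is flagged with a warning and returned
    without interpolation.
    """
    return _locate_peak(s)[0]


def peak_intensity(s: Spectrum) -> float:
    """Interpolated intensity at the spectrum maximum (same rules as
    :func:`emission_maximum`)."""
    return _locate_peak(s)[1]
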