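"""Resonance light scattering curves and aggregation-onset detection.

An RLS experiment scans excitation and emission monochromators together
(Δλ = 0); the scattered intensity tracks the square of the particle volume,
so it stays essentially flat while the drug–protein complexes remain small
and rises once aggregates start to form. The concentration at which the rise
begins is the critical induced aggregation concentration (C_CIAC).

C_CIAC is estimated by fitting a continuous two-segment hinge

    I([Q]) = b                      for [Q] ≤ c
    I([Q]) = b + m·([Q] − c)        for [Q] > c

by least squares over a grid of candidate knots (the observed concentrations
and their midpoints, followed by local refinement), and accepting the hinge
only when it beats the flat-only model by an F-ratio threshold (default 4.0)
with a positive rise slope. A curve that never rises yields "no onset".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RlsCurve:
    """RLS intensity vs quencher concentration at a fixed readout wavelength."""

    concentrations: np.ndarray
    intensities: np.ndarray
    readout_wavelength: float | None = None
    unit: str = "mM"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.concentrations.shape != self.intensities.shape:
            raise ValueError("concentrations and intensities must align")
        if np.any(np.diff(self.concentrations) < 0):
            raise ValueError("concentrations must be nondecreasing")


@dataclass
class CciacResult:
    """Detected aggregation onset: knot ``cciac`` (strictly inside the
    concentration range), flat ``baseline``, rise ``slope_above`` and the
    hinge-fit residual ``sse``; ``f_ratio`` is the acceptance statistic
    against the flat-only model (inf for an exact fit)."""

    cciac: float
    baseline: float
    slope_above: float
    sse: float
    f_ratio: float
    unit: str = "mM"


def extract_rls_curve(series, readout_wavelength: float | None = None) -> RlsCurve:
    """Reduce a titration series of Δλ=0 scans to intensity-vs-concentration.

    The readout defaults to the wavelength of the global scan maximum at the
    highest concentration (where aggregate scattering is strongest); the
    intensity at the readout is linearly interpolated per point. A readout
    outside any scan's range is refused.
    """
    bad = [i for i, s in enumerate(series.spectra) if s.kind != "rls"]
    if bad:
        raise ValueError(f"spectra at indices {bad} are not RLS scans "
                         "(kind must be 'rls')")
    if readout_wavelength is None:
        top = series.spectra[-1]
        readout_wavelength = float(top.wavelengths[int(np.argmax(top.intensities))])
    intensities = np.array([s.interp_at(readout_wavelength)
                            for s in series.spectra])
    return RlsCurve(series.concentrations.copy(), intensities,
                    readout_wavelength=readout_wavelength, unit=series.unit)


def _hinge_sse(q: np.ndarray, I: np.ndarray, knot: float):
    X = np.column_stack([np.ones_like(q), np.clip(q - knot, 0.0, None)])
    beta, *_ = np.linalg.lstsq(X, I, rcond=None)
    resid = I - X @ beta
    return float(resid @ resid), beta


def detect_cciac(curve: RlsCurve, f_threshold: float = 4.0,
                 refine_iters: int = 40) -> CciacResult | None:
    """Locate the aggregation onset of an RLS curve; ``None`` if no onset.

    Candidate knots are the interior observed concentrations and the
    midpoints between consecutive ones; the best candidate's bracketing
    interval is then repeatedly subdivided (``refine_iters`` rounds) so the
    knot resolves far below the grid spacing on clean data. The hinge is
    accepted when its rise slope is positive and the F-ratio against the
    flat-only model exceeds ``f_threshold``.
    """
    q, I = curve.concentrations, curve.intensities
    n = q.size
    if n < 6:
        raise ValueError("onset detection needs at least 6 points")

    sse_flat = float(np.sum((I - I.mean()) ** 2))
    scale = float(np.sum(I ** 2))
    if sse_flat <= 1e-12 * max(scale, 1.0):
        return None  # strictly flat curve

    uniq = np.unique(q)
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    candidates = np.unique(np.concatenate([uniq[1:-1], mids]))
    scored = [(_hinge_sse(q, I, c)[0], c) for c in candidates]
    best_sse, best_c = min(scored, key=lambda t: t[0])

    # local refinement between the neighbours of the best candidate
    idx = int(np.searchsorted(candidates, best_c))
    lo = candidates[idx - 1] if idx > 0 else uniq[0]
    hi = candidates[idx + 1] if idx < candidates.size - 1 else uniq[-1]
    for _ in range(refine_iters):
        grid = np.linspace(lo, hi, 17)
        sses = [_hinge_sse(q, I, c)[0] for c in grid]
        j = int(np.argmin(sses))
        if sses[j] < best_sse:
            best_sse, best_c = sses[j], float(grid[j])
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, 16)]
        if hi - lo <= 1e-12 * (uniq[-1] - uniq[0]):
            break

    sse_hinge, beta = _hinge_sse(q, I, best_c)
    baseline, slope = float(beta[0]), float(beta[1])

    if sse_hinge <= 1e-12 * sse_flat:
        f_ratio = np.inf
    else:
        f_ratio = ((sse_flat - sse_hinge) / 2.0) / (sse_hinge / max(n - 3, 1))

    if slope <= 0 or f_ratio < f_threshold:
        return None
    if not (uniq[0] < best_c < uniq[-1]):
        return None
    return CciacResult(cciac=best_c, baseline=baseline, slope_above=slope,
                       sse=sse_hinge, f_ratio=float(f_ratio), unit=curve.unit)
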